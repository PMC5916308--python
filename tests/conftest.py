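import numpy as np
import pytest

from karstcomm import phylo


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def newick_file(tmp_path):
    """Write a newick string to a temp file and return its path."""

    def _write(newick: str):
        path = tmp_path / "tree.nwk"
        path.write_text(newick + "\n")
        return path

    return _write


@pytest.fixture
def three_tip_tree(newick_file):
    return phylo.read_newick(newick_file("((A:1,B:1):1,C:2);"))
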