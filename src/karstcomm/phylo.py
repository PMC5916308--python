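"""Phylogenetic tree input, cophenetic distances, and lineage delimitation.

Trees are carried as :class:`dendropy.Tree` objects throughout.  All
branch lengths are in substitutions per site.  Operational "lineages" are
delimited from an ultrametric tree with a fixed node-depth cut: every
maximal clade whose crown node sits at most ``threshold`` substitutions/site
above the tips is one lineage, so clades that coalesce deeper than the cut
are separate lineages.  This is the standard height-cut (single-linkage)
reading of a divergence-threshold species proxy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from skbio import DistanceMatrix

from .exceptions import ValidationError

__all__ = [
    "read_newick",
    "write_newick",
    "is_ultrametric",
    "cophenetic_distances",
    "node_depth",
    "delimit_lineages",
    "LineagePartition",
    "write_distance_csv",
    "read_distance_csv",
]

DEFAULT_ULTRAMETRIC_RTOL = 1e-6


def _validate_tree(tree: dendropy.Tree) -> None:
    labels = [leaf.taxon.label if leaf.taxon else None for leaf in tree.leaf_node_iter()]
    if any(lab is None for lab in labels):
        raise ValidationError("tree contains unlabeled tips")
    if len(set(labels)) != len(labels):
        dupes = sorted({lab for lab in labels if labels.count(lab) > 1})
        raise ValidationError(f"duplicate tip labels: {dupes}")
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue  # a root edge length is optional
        if node.edge.length is None:
            name = node.taxon.label if node.taxon else f"internal node above {_first_leaf_label(node)}"
            raise ValidationError(f"missing branch length on edge leading to {name}")
        if node.edge.length < 0:
            raise ValidationError("negative branch length")


def _first_leaf_label(node: dendropy.Node) -> str:
    return next(node.leaf_iter()).taxon.label


def read_newick(path: str) -> dendropy.Tree:
    """Read a single rooted newick tree with branch lengths.

    Internal node labels are permitted and carried through unchanged.
    Raises :class:`ValidationError` for duplicate tip labels or missing
    branch lengths; malformed newick propagates dendropy's parse error,
    which reports line and column.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        if "multiple occurrences" in str(exc).lower():
            raise ValidationError(f"duplicate tip labels in {path}: {exc}") from exc
        raise
    tree.is_rooted = True
    _validate_tree(tree)
    return tree


def write_newick(tree: dendropy.Tree, path: str) -> None:
    """Write a tree to newick, preserving topology and branch lengths."""
    tree.write(path=str(path), schema="newick", suppress_rooting=True, unquoted_underscores=True)


def _leaf_depth_range(tree: dendropy.Tree) -> dict[dendropy.Node, tuple[float, float]]:
    """Postorder (min, max) distance from each node down to its descendant tips."""
    depth: dict[dendropy.Node, tuple[float, float]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            depth[node] = (0.0, 0.0)
        else:
            lows, highs = zip(
                *(
                    (depth[c][0] + (c.edge.length or 0.0), depth[c][1] + (c.edge.length or 0.0))
                    for c in node.child_nodes()
                )
            )
            depth[node] = (min(lows), max(highs))
    return depth


def is_ultrametric(
    tree: dendropy.Tree, rel_tol: float = DEFAULT_ULTRAMETRIC_RTOL
) -> tuple[bool, float]:
    """Check that all root-to-tip path lengths agree within ``rel_tol`` x height.

    Returns ``(ok, max_deviation)`` where the deviation is the spread
    (max - min) of root-to-tip path lengths in substitutions/site.
    """
    _validate_tree(tree)
    lo, hi = _leaf_depth_range(tree)[tree.seed_node]
    deviation = hi - lo
    return deviation <= rel_tol * hi if hi > 0 else True, deviation


def _require_ultrametric(tree: dendropy.Tree, rel_tol: float) -> None:
    ok, dev = is_ultrametric(tree, rel_tol)
    if not ok:
        raise ValidationError(
            f"tree is not ultrametric (root-to-tip spread {dev:g}); "
            "check it with is_ultrametric()"
        )


def cophenetic_distances(
    tree: dendropy.Tree,
    round_digits: int | None = 4,
    tips: list[str] | None = None,
) -> DistanceMatrix:
    """Patristic (cophenetic) distance matrix between tips.

    Entry (i, j) is the sum of branch lengths on the tip-to-tip path,
    rounded to ``round_digits`` decimal places (round-half-even, the IEEE
    default, for bit-reproducibility).  ``round_digits=None`` disables
    rounding.  ``tips`` restricts and orders the output, e.g. to one
    representative per lineage.
    """
    _validate_tree(tree)
    leaves = {leaf.taxon.label: leaf.taxon for leaf in tree.leaf_node_iter()}
    if len(leaves) < 2:
        raise ValidationError("cophenetic distances need at least two tips")
    if tips is None:
        labels = sorted(leaves)
    else:
        missing = [t for t in tips if t not in leaves]
        if missing:
            raise ValidationError(f"tips not in tree: {missing}")
        labels = list(tips)
    pdm = tree.phylogenetic_distance_matrix()
    n = len(labels)
    mat = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.distance(leaves[labels[i]], leaves[labels[j]])
            mat[i, j] = mat[j, i] = d
    if round_digits is not None:
        mat = np.round(mat, round_digits)
    return DistanceMatrix(mat, ids=labels)


def node_depth(
    tree: dendropy.Tree,
    node: dendropy.Node,
    rel_tol: float = DEFAULT_ULTRAMETRIC_RTOL,
) -> float:
    """Depth of a node: branch-length distance from the node down to its tips.

    Defined only for (numerically) ultrametric trees, where the distance is
    the same whichever descendant tip is used; the midpoint of the observed
    min/max is returned to average out rounding noise.  Tips have depth 0.
    """
    _require_ultrametric(tree, rel_tol)
    lo, hi = _leaf_depth_range(tree)[node]
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class LineagePartition:
    """Assignment of every tip to exactly one delimited lineage."""

    assignments: dict[str, str]
    threshold: float
    lineages: dict[str, tuple[str, ...]] = field(repr=False, default_factory=dict)

    @property
    def n_lineages(self) -> int:
        return len(self.lineages)

    def representative(self, lineage_id: str) -> str:
        """First member tip by sorted label — the default lineage representative."""
        return min(self.lineages[lineage_id])


def delimit_lineages(
    tree: dendropy.Tree,
    threshold: float,
    rel_tol: float = DEFAULT_ULTRAMETRIC_RTOL,
) -> LineagePartition:
    """Cut an ultrametric tree at ``threshold`` substitutions/site above the tips.

    Lineages are the maximal clades whose crown depth is <= threshold;
    clades whose crown sits strictly deeper than the cut split into
    separate lineages, and a tip whose first coalescence is deeper than the
    cut becomes a singleton.  Equivalent to single-linkage clustering of
    cophenetic distances at cut height 2 x threshold.
    """
    if threshold <= 0:
        raise ValidationError("delimitation threshold must be > 0")
    _require_ultrametric(tree, rel_tol)
    depths = _leaf_depth_range(tree)
    lineages: dict[str, tuple[str, ...]] = {}
    assignments: dict[str, str] = {}

    def visit(node: dendropy.Node) -> None:
        crown = 0.5 * (depths[node][0] + depths[node][1])
        if node.is_leaf() or crown <= threshold:
            lid = f"L{len(lineages) + 1:02d}"
            members = tuple(leaf.taxon.label for leaf in node.leaf_iter())
            lineages[lid] = members
            for m in members:
                assignments[m] = lid
        else:
            for child in node.child_nodes():
                visit(child)

    visit(tree.seed_node)
    return LineagePartition(assignments=assignments, threshold=threshold, lineages=lineages)


def write_distance_csv(dmat: DistanceMatrix, path: str) -> None:
    """Write a labeled square distance matrix as CSV (labels in row/column 1)."""
    import pandas as pd

    pd.DataFrame(dmat.data, index=list(dmat.ids), columns=list(dmat.ids)).to_csv(path)


def read_distance_csv(path: str) -> DistanceMatrix:
    import pandas as pd

    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValidationError("distance CSV row and column labels differ")
    return DistanceMatrix(df.to_numpy(dtype=float), ids=[str(i) for i in df.index])
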