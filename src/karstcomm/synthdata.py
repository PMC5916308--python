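"""Synthetic trees, traits, outlines and communities for end-to-end testing.

The generator mirrors the statistical structure the analysis assumes:

* pure-birth (Yule) ultrametric trees at the study scale (~15 lineages);
* phylogenetically conserved continuous traits evolved by Brownian motion,
  so closely related lineages have similar trait values;
* communities assembled under three rules — neutral (uniform sampling),
  environmental filtering (only taxa within a trait window around a
  per-area optimum) and competition / limiting similarity (sequential
  admission with a minimum trait spacing);
* closed shell-like outlines r(theta) = base * (1 + harmonics + aperture
  bump) with controllable size and shape and radial noise.

Competition and filtering act on trait distance; because traits are
Brownian on the tree, phylogenetic and trait signals are correlated, which
is exactly the assumption under which phylogenetic relatedness proxies
ecology in the community analyses.  All generators take explicit seeds and
touch no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from . import community as comm
from . import morpho, phylo
from .exceptions import ValidationError

__all__ = [
    "AssemblyParams",
    "OutlineParams",
    "simulate_yule_tree",
    "scale_tree_height",
    "simulate_bm_traits",
    "assemble_communities",
    "synthesize_outline",
    "make_paper_scale_dataset",
    "Bundle",
    "parameter_recovery_experiment",
]

DEFAULT_RETRY_CAP = 10_000


@dataclass(frozen=True)
class AssemblyParams:
    """Parameters of the community assembly simulator.

    ``filter_window`` is the full admissible trait width around a random
    per-area optimum (filtering mode); ``competition_delta`` the minimum
    pairwise trait spacing (competition mode).  Both are in trait units —
    for Brownian traits with sigma2 = 1 on a height-1 tree, one trait unit
    is one among-taxon standard deviation.
    """

    pool_size: int
    n_areas: int
    community_size: tuple[int, int]
    mode: str = "neutral"
    filter_window: float = 1.0
    competition_delta: float = 0.3
    seed: int = 0
    retry_cap: int = DEFAULT_RETRY_CAP

    def __post_init__(self):
        lo, hi = self.community_size
        if not (1 <= lo <= hi <= self.pool_size):
            raise ValidationError("community size range must fit within the pool")
        if self.mode not in ("neutral", "filtering", "competition"):
            raise ValidationError(f"unknown assembly mode {self.mode!r}")
        if self.mode == "filtering" and self.filter_window <= 0:
            raise ValidationError("filter_window must be > 0")
        if self.mode == "competition" and self.competition_delta <= 0:
            raise ValidationError("competition_delta must be > 0")


@dataclass(frozen=True)
class OutlineParams:
    """Parameters of the shell-outline synthesizer."""

    base_radius: float = 1.0
    aspect_ratio: float = 1.0
    aperture_amplitude: float = 0.0
    aperture_angle: float = 0.0
    harmonics: tuple[float, ...] = ()
    n_vertices: int = 400
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.base_radius <= 0:
            raise ValidationError("base_radius must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_vertices < 32:
            raise ValidationError("n_vertices must be >= 32")


# ---------------------------------------------------------------------------
# tree and traits


def simulate_yule_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> dendropy.Tree:
    """Pure-birth ultrametric tree with ``n_tips`` uniquely labeled tips.

    Standard Yule construction: two lineages from the root, exponential
    waiting times with total rate (#lineages x birth_rate), a uniformly
    chosen lineage splits, and all open branches are extended to the
    present when the target tip count is reached.
    """
    if n_tips < 2:
        raise ValidationError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValidationError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    root = tree.seed_node
    open_nodes = []
    birth_times = {}
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        birth_times[child] = 0.0
        open_nodes.append(child)
    t = 0.0
    while len(open_nodes) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(open_nodes)))
        idx = rng.integers(len(open_nodes))
        parent = open_nodes.pop(idx)
        parent.edge.length = t - birth_times[parent]
        for _ in range(2):
            child = dendropy.Node()
            parent.add_child(child)
            birth_times[child] = t
            open_nodes.append(child)
    t_end = t + rng.exponential(1.0 / (birth_rate * len(open_nodes)))
    for i, node in enumerate(open_nodes):
        node.edge.length = t_end - birth_times[node]
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = tns.new_taxon(label=f"T{i + 1:02d}")
    return tree


def scale_tree_height(tree: dendropy.Tree, height: float) -> dendropy.Tree:
    """Rescale all branch lengths so the root-to-tip height equals ``height``."""
    current = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    if current <= 0:
        raise ValidationError("tree has zero height")
    factor = height / current
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    return tree


def simulate_bm_traits(tree: dendropy.Tree, sigma2: float = 1.0, seed: int = 0) -> dict[str, float]:
    """Brownian-motion trait values at the tips, root value 0.

    Each branch adds an independent N(0, sigma2 x branch length) increment,
    so tip covariances equal sigma2 x shared root-path length.
    """
    if sigma2 <= 0:
        raise ValidationError("sigma2 must be > 0")
    rng = np.random.default_rng(seed)
    values: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    traits: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        length = node.edge.length or 0.0
        values[node] = values[node.parent_node] + rng.normal(0.0, np.sqrt(sigma2 * length))
        if node.is_leaf():
            traits[node.taxon.label] = values[node]
    return traits


# ---------------------------------------------------------------------------
# community assembly


def _assemble_one(taxa, trait_values, size, mode, params, rng):
    if mode == "neutral":
        return list(rng.choice(taxa, size=size, replace=False))
    if mode == "filtering":
        lo, hi = trait_values.min(), trait_values.max()
        for _ in range(params.retry_cap):
            optimum = rng.uniform(lo, hi)
            admitted = [t for t, v in zip(taxa, trait_values) if abs(v - optimum) <= params.filter_window / 2]
            if len(admitted) >= size:
                return list(rng.choice(admitted, size=size, replace=False))
        raise ValidationError(
            f"filtering infeasible: no optimum admits {size} taxa within window {params.filter_window}"
        )
    # competition: sequential admission with minimum trait spacing
    tmap = dict(zip(taxa, trait_values))
    for _ in range(params.retry_cap):
        members = [taxa[rng.integers(len(taxa))]]
        candidates = [t for t in taxa if t not in members]
        rng.shuffle(candidates)
        for cand in candidates:
            if len(members) == size:
                break
            if min(abs(tmap[cand] - tmap[m]) for m in members) >= params.competition_delta:
                members.append(cand)
        if len(members) == size:
            return members
    raise ValidationError(
        f"competition infeasible: cannot place {size} taxa with spacing {params.competition_delta}"
    )


def assemble_communities(pool_traits: dict[str, float], params: AssemblyParams) -> comm.CommunityMatrix:
    """Assemble an area x taxon presence/absence matrix under one rule.

    Modes: ``neutral`` draws each community uniformly without replacement;
    ``filtering`` admits only taxa within ``filter_window`` of a random
    per-area environmental optimum; ``competition`` grows each community
    sequentially, admitting only candidates at trait distance >=
    ``competition_delta`` from all current members (area re-drawn up to the
    retry cap when the target size is unreachable).  Taxa absent from every
    area are dropped from the returned matrix.
    """
    taxa = sorted(pool_traits)
    if len(taxa) != params.pool_size:
        raise ValidationError(
            f"pool_traits has {len(taxa)} taxa but params.pool_size = {params.pool_size}"
        )
    trait_values = np.array([pool_traits[t] for t in taxa])
    rng = np.random.default_rng(params.seed)
    lo, hi = params.community_size
    rows = {}
    for a in range(params.n_areas):
        size = int(rng.integers(lo, hi + 1))
        members = _assemble_one(taxa, trait_values, size, params.mode, params, rng)
        rows[f"A{a + 1:02d}"] = {t: int(t in members) for t in taxa}
    df = pd.DataFrame.from_dict(rows, orient="index")[taxa]
    df = df.loc[:, df.sum(axis=0) > 0]
    return comm.CommunityMatrix(data=df)


# ---------------------------------------------------------------------------
# outlines


def synthesize_outline(params: OutlineParams) -> morpho.Outline:
    """Closed shell-like polygon from a radial harmonic series.

    r(theta) = base * (1 + sum_m a_m cos((m+1) theta) + bump(theta)), with a
    Gaussian aperture bump at ``aperture_angle`` and radial N(0, noise_sd)
    perturbations; x is stretched by the aspect ratio.  The start vertex is
    placed at the aperture bump position.  Parameter combinations driving
    the radius non-positive raise.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_vertices
    theta = 2 * np.pi * np.arange(n) / n + params.aperture_angle
    r = np.ones(n)
    for m, amp in enumerate(params.harmonics, start=1):
        r = r + amp * np.cos((m + 1) * (theta - params.aperture_angle))
    if params.aperture_amplitude:
        ang = np.angle(np.exp(1j * (theta - params.aperture_angle)))
        r = r + params.aperture_amplitude * np.exp(-0.5 * (ang / 0.35) ** 2)
    r = params.base_radius * r
    if params.noise_sd > 0:
        r = r + rng.normal(0.0, params.noise_sd, size=n)
    if np.any(r <= 0):
        raise ValidationError("outline parameters produce non-positive radius (self-intersection)")
    x = params.aspect_ratio * r * np.cos(theta)
    y = r * np.sin(theta)
    return morpho.Outline(vertices=np.column_stack([x, y]), start_index=0)


# ---------------------------------------------------------------------------
# parameter recovery


def parameter_recovery_experiment(
    mode: str,
    n_datasets: int = 200,
    pool_size: int = 30,
    n_areas: int = 20,
    community_size: int = 5,
    n_reps: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Can the SES analysis recover the assembly rule that generated the data?

    For each dataset: simulate a Yule tree (rescaled to height 1), evolve
    Brownian traits (sigma2 = 1), assemble communities under ``mode``,
    build the trait distance matrix (absolute trait differences) and run
    the independent-swap SES analysis.  Returns one row per dataset with
    the across-area mean SES and mean permutation p.  Under competition
    mean SES should be positive, under filtering negative, and under
    neutrality near zero.
    """
    rng = np.random.default_rng(seed)
    from skbio import DistanceMatrix

    rows = []
    for _ in range(n_datasets):
        s_tree, s_trait, s_asm, s_null = (int(x) for x in rng.integers(0, 2**31, size=4))
        tree = simulate_yule_tree(pool_size, seed=s_tree)
        scale_tree_height(tree, 1.0)
        traits = simulate_bm_traits(tree, sigma2=1.0, seed=s_trait)
        params = AssemblyParams(
            pool_size=pool_size,
            n_areas=n_areas,
            community_size=(community_size, community_size),
            mode=mode,
            seed=s_asm,
        )
        cm = assemble_communities(traits, params)
        values = np.array([traits[e] for e in cm.entities])
        dmat = DistanceMatrix(np.abs(values[:, None] - values[None, :]), ids=cm.entities)
        report = comm.ses_report(
            cm, dmat, metric=comm.METRIC_TRAIT, n_reps=n_reps, rng=s_null
        )
        rows.append(
            {
                "mode": mode,
                "mean_ses": float(report.table["SES"].mean()),
                "mean_p": float(report.table["p_perm"].mean()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full study-scale bundle


@dataclass
class Bundle:
    """A complete synthetic dataset in the formats the pipeline reads."""

    tree: dendropy.Tree
    traits: dict[str, float]
    communities: comm.CommunityMatrix
    outlines: dict[str, morpho.Outline]
    landmarks: list[morpho.LandmarkConfiguration]
    metadata: pd.DataFrame
    directory: Path | None = None


def _assemble_full_coverage(taxa: list[str], n_areas: int, size_range, rng) -> pd.DataFrame:
    """Neutral assembly conditioned on every taxon occurring somewhere.

    Community sizes are drawn first (re-drawn until total slots >= pool
    size), each taxon is dealt once into a random free slot, and remaining
    slots are filled uniformly without within-area duplication.
    """
    lo, hi = size_range
    for _ in range(DEFAULT_RETRY_CAP):
        sizes = rng.integers(lo, hi + 1, size=n_areas)
        if sizes.sum() >= len(taxa):
            break
    else:
        raise ValidationError("cannot cover the pool with the requested community sizes")
    areas = [f"A{a + 1:02d}" for a in range(n_areas)]
    for _ in range(DEFAULT_RETRY_CAP):
        members: dict[str, set[str]] = {a: set() for a in areas}
        order = list(taxa)
        rng.shuffle(order)
        ok = True
        for taxon in order:
            free = [a for a, s in zip(areas, sizes) if len(members[a]) < s]
            if not free:
                ok = False
                break
            members[free[rng.integers(len(free))]].add(taxon)
        if not ok:
            continue
        for a, s in zip(areas, sizes):
            available = [t for t in taxa if t not in members[a]]
            extra = s - len(members[a])
            if extra > len(available):
                ok = False
                break
            for t in rng.choice(available, size=extra, replace=False):
                members[a].add(t)
        if ok:
            df = pd.DataFrame(
                [[int(t in members[a]) for t in taxa] for a in areas], index=areas, columns=taxa
            )
            return df
    raise ValidationError("full-coverage neutral assembly failed after retry cap")


def make_paper_scale_dataset(
    seed: int,
    out_dir: str | Path | None = None,
    n_lineages: int = 15,
    n_areas: int = 7,
    community_size: tuple[int, int] = (2, 3),
    n_outline_replicates: int = 5,
    tree_height: float = 0.3,
    include_extra_lineage: bool = True,
) -> Bundle:
    """Generate a study-scale dataset: 15 lineages, 7 areas, 2-3 per area.

    Tips of the 15-tip ultrametric tree stand for lineage representatives
    (labels ``L01``..``L15``), with the tree rescaled to a realistic
    substitutions/site depth.  Brownian traits set each lineage's shell
    size class; five outline replicates are synthesized per lineage x area
    occurrence, with a small area effect on size and lineage-specific shape
    harmonics.  One morphologically extreme extra lineage known from a
    single shell in one area is included in the morphometric data only
    (flagged ``extra`` in the metadata), mirroring datasets where a taxon
    lacks molecular data.  When ``out_dir`` is given, everything is written
    there in the standard formats plus a ready-to-run ``config.yaml``.
    """
    rng = np.random.default_rng(seed)
    tree = simulate_yule_tree(n_lineages, birth_rate=1.0, seed=int(rng.integers(2**31)))
    scale_tree_height(tree, tree_height)
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"L{i + 1:02d}"
    lineages = sorted(l.taxon.label for l in tree.leaf_node_iter())
    traits = simulate_bm_traits(tree, sigma2=1.0, seed=int(rng.integers(2**31)))

    cdf = _assemble_full_coverage(lineages, n_areas, community_size, rng)
    communities = comm.CommunityMatrix(data=cdf)

    trait_arr = np.array([traits[l] for l in lineages])
    trait_sd = trait_arr.std() or 1.0
    area_effect = {a: float(rng.normal(0.0, 0.04)) for a in communities.areas}
    shape_params = {
        lin: tuple(rng.normal(0.0, 0.03, size=3).round(4)) for lin in lineages
    }

    outlines: dict[str, morpho.Outline] = {}
    landmarks: list[morpho.LandmarkConfiguration] = []
    meta_rows = []

    def add_specimens(lineage, area, base, harmonics, n_specimens, extra=False):
        for i in range(n_specimens):
            spec_id = f"{lineage}_{area}_{i + 1:02d}"
            params = OutlineParams(
                base_radius=base * float(np.exp(rng.normal(0.0, 0.02))),
                aspect_ratio=1.05,
                aperture_amplitude=0.15,
                aperture_angle=0.0,
                harmonics=harmonics,
                n_vertices=400,
                noise_sd=0.004,
                seed=int(rng.integers(2**31)),
            )
            outline = synthesize_outline(params)
            outlines[spec_id] = outline
            landmarks.append(morpho.resample_semilandmarks(outline, morpho.DEFAULT_SEMILANDMARKS, spec_id))
            meta_rows.append(
                {"specimen_id": spec_id, "lineage_id": lineage, "area_id": area, "extra": extra}
            )

    for lineage in lineages:
        z = (traits[lineage] - trait_arr.mean()) / trait_sd
        for area in communities.areas:
            if communities.data.loc[area, lineage] == 1:
                base = float(np.exp(0.35 * z) * (1.0 + area_effect[area]))
                add_specimens(lineage, area, base, shape_params[lineage], n_outline_replicates)
    if include_extra_lineage:
        extra_id = f"L{n_lineages + 1:02d}"
        extra_area = communities.areas[int(rng.integers(len(communities.areas)))]
        add_specimens(extra_id, extra_area, 2.4, (0.05, -0.04, 0.02), 1, extra=True)

    metadata = pd.DataFrame(meta_rows)

    directory = None
    if out_dir is not None:
        directory = Path(out_dir)
        directory.mkdir(parents=True, exist_ok=True)
        phylo.write_newick(tree, directory / "tree.nwk")
        comm.write_community_csv(communities, directory / "community.csv")
        metadata.to_csv(directory / "metadata.csv", index=False)
        morpho.write_tps(landmarks, directory / "landmarks.tps")
        outline_dir = directory / "outlines"
        outline_dir.mkdir(exist_ok=True)
        for spec_id, outline in outlines.items():
            morpho.write_outline_csv(outline, outline_dir / f"{spec_id}.csv")
        pd.DataFrame(
            {"lineage_id": lineages, "trait": [traits[l] for l in lineages]}
        ).to_csv(directory / "traits.csv", index=False)
        config = {
            "tree": "tree.nwk",
            "community": "community.csv",
            "metadata": "metadata.csv",
            "landmarks": "landmarks.tps",
            "out_dir": "results",
            "lineage_threshold": 0.04,
            "semilandmarks": morpho.DEFAULT_SEMILANDMARKS,
            "keep_size": True,
            "include_extra_specimen": True,
            "n_reps": comm.DEFAULT_N_REPS,
            "constraint": True,
            "seed": int(seed),
        }
        with open(directory / "config.yaml", "w") as fh:
            yaml.safe_dump(config, fh, sort_keys=True)

    return Bundle(
        tree=tree,
        traits=traits,
        communities=communities,
        outlines=outlines,
        landmarks=landmarks,
        metadata=metadata,
        directory=directory,
    )
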