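"""End-to-end orchestration: configuration, the two SES analyses, reporting.

``run_phylo_analysis`` goes tree -> cophenetic distances (one representative
tip per lineage) -> SES of MNTD per area.  ``run_morpho_analysis`` goes
semilandmarks -> generalized Procrustes -> per-population (or per-lineage)
mean configurations -> relative-warp PCA with broken-stick retention ->
PC-score distances -> SES of the mean nearest trait distance per area,
with the same-lineage co-occurrence exclusion in the null model.
``merge_reports`` combines both into one table of the familiar
area / SES / p layout.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community as comm
from . import morpho, phylo
from .exceptions import ValidationError

__all__ = ["RunConfig", "run_phylo_analysis", "run_morpho_analysis", "merge_reports", "plot_ses_bars"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one analysis run.

    Relative paths are taken relative to the config file's directory.
    ``representatives`` optionally maps lineage id -> tip label; otherwise
    community entities must be tip labels themselves, or resolvable through
    node-depth delimitation (first member tip by sorted label represents
    each lineage).
    """

    tree: Path | None = None
    community: Path | None = None
    metadata: Path | None = None
    landmarks: Path | None = None
    out_dir: Path = Path("results")
    lineage_threshold: float = 0.04
    semilandmarks: int = morpho.DEFAULT_SEMILANDMARKS
    keep_size: bool = True
    include_extra_specimen: bool = True
    retained_components: int | None = None
    n_reps: int = comm.DEFAULT_N_REPS
    constraint: bool = True
    seed: int = 0
    representatives: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_reps < 99:
            raise ValidationError("n_reps must be >= 99")
        if self.lineage_threshold <= 0:
            raise ValidationError("lineage_threshold must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ValidationError(f"config file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = path.parent
        kwargs = {}
        for key, value in raw.items():
            if key in ("tree", "community", "metadata", "landmarks", "out_dir"):
                kwargs[key] = base / value
            elif key == "community_size":
                continue
            else:
                kwargs[key] = value
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        known = set(cls.__dataclass_fields__)
        unknown = set(kwargs) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def require(self, *names: str) -> None:
        for name in names:
            value = getattr(self, name)
            if value is None:
                raise ValidationError(f"config is missing required path: {name}")
            if not Path(value).exists():
                raise ValidationError(f"input path does not exist: {value}")

    def audit_dict(self) -> dict:
        out = {}
        for name in self.__dataclass_fields__:
            value = getattr(self, name)
            out[name] = str(value) if isinstance(value, Path) else value
        return out


def _resolve_representatives(tree, entities: list[str], config: RunConfig) -> dict[str, str]:
    """Map each community entity to one representative tip.

    Resolution order: an explicit representative map; identity (the entity
    is itself a tip label); node-depth delimitation at the configured
    threshold, taking the first member tip by sorted label per lineage.
    """
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if config.representatives:
        missing = [e for e in entities if e not in config.representatives]
        bad = [t for t in config.representatives.values() if t not in tips]
        if missing or bad:
            raise ValidationError(
                f"representative map incomplete (missing entities {missing}, unknown tips {bad})"
            )
        return {e: config.representatives[e] for e in entities}
    if all(e in tips for e in entities):
        return {e: e for e in entities}
    partition = phylo.delimit_lineages(tree, config.lineage_threshold)
    if all(e in partition.lineages for e in entities):
        return {e: partition.representative(e) for e in entities}
    unresolved = [e for e in entities if e not in tips and e not in partition.lineages]
    raise ValidationError(f"community entities unresolvable to tree tips or lineages: {unresolved}")


def run_phylo_analysis(config: RunConfig) -> comm.NullModelReport:
    """SES of MNTD on cophenetic distances, per karst area."""
    config.require("tree", "community")
    t0 = time.perf_counter()
    tree = phylo.read_newick(config.tree)
    matrix = comm.read_community_csv(config.community)
    reps = _resolve_representatives(tree, matrix.entities, config)
    dmat = phylo.cophenetic_distances(tree, round_digits=4, tips=[reps[e] for e in matrix.entities])
    dmat = dmat.__class__(dmat.data, ids=matrix.entities)  # relabel tips as entities
    report = comm.ses_report(
        matrix,
        dmat,
        metric=comm.METRIC_PHYLO,
        n_reps=config.n_reps,
        constraint=False,
        rng=config.seed,
    )
    report.config = config.audit_dict()
    logger.info(
        "phylo SES: %d areas, %d reps, %d rejections, %.2fs",
        len(report.table),
        config.n_reps,
        report.n_rejected,
        time.perf_counter() - t0,
    )
    return report


def _population_structure(matrix: comm.CommunityMatrix, metadata: pd.DataFrame, include_extra: bool):
    """Build the population-level community matrix and specimen grouping.

    A lineage found in a single area keeps its lineage id as the entity; a
    lineage spanning several areas contributes one ``lineage@area``
    population entity per occurrence, so area-specific morphologies enter
    the analysis separately.  Extra (morphology-only) specimens add their
    lineage to the area where they were found when included.
    """
    occurrences: dict[str, list[str]] = {}
    for area in matrix.areas:
        for lineage in matrix.members(area):
            occurrences.setdefault(lineage, []).append(area)
    if include_extra:
        for _, row in metadata[metadata["extra"]].iterrows():
            lin, area = str(row["lineage_id"]), str(row["area_id"])
            if area not in occurrences.get(lin, []):
                occurrences.setdefault(lin, []).append(area)

    def entity(lineage: str, area: str) -> str:
        return lineage if len(occurrences[lineage]) == 1 else f"{lineage}@{area}"

    entities, lineage_map, rows = [], {}, {a: {} for a in matrix.areas}
    for lineage, areas in sorted(occurrences.items()):
        for area in areas:
            ent = entity(lineage, area)
            entities.append(ent)
            lineage_map[ent] = lineage
            rows[area][ent] = 1
    df = pd.DataFrame(
        [[rows[a].get(e, 0) for e in entities] for a in matrix.areas],
        index=matrix.areas,
        columns=entities,
    )
    pop_matrix = comm.CommunityMatrix(data=df, lineage_map=lineage_map)

    specimen_groups = {}
    for _, row in metadata.iterrows():
        if bool(row["extra"]) and not include_extra:
            continue
        lin, area = str(row["lineage_id"]), str(row["area_id"])
        if lin not in occurrences or area not in occurrences[lin]:
            raise ValidationError(
                f"specimen {row['specimen_id']} is from {lin} in {area}, "
                "absent from the community table"
            )
        specimen_groups[str(row["specimen_id"])] = entity(lin, area)
    return pop_matrix, specimen_groups


def run_morpho_analysis(config: RunConfig) -> tuple[comm.NullModelReport, morpho.PCAResult]:
    """SES of the mean nearest trait distance per area, plus the PCA summary."""
    config.require("community", "metadata", "landmarks")
    t0 = time.perf_counter()
    matrix = comm.read_community_csv(config.community)
    metadata = pd.read_csv(config.metadata)
    if "extra" not in metadata.columns:
        metadata["extra"] = False
    metadata["extra"] = metadata["extra"].astype(bool)
    configs = morpho.read_tps(config.landmarks)
    ks = {c.k for c in configs}
    if len(ks) > 1:
        offender = next(c.specimen_id for c in configs if c.k != max(ks, key=list(ks).count))
        raise ValidationError(f"specimen {offender}: landmark count differs from the rest")

    pop_matrix, groups = _population_structure(matrix, metadata, config.include_extra_specimen)
    used = [c for c in configs if c.specimen_id in groups]
    missing_specs = sorted(set(groups) - {c.specimen_id for c in used})
    if missing_specs:
        raise ValidationError(f"specimens in metadata but not in landmark file: {missing_specs}")
    uncovered = sorted(set(pop_matrix.entities) - set(groups.values()))
    if uncovered:
        raise ValidationError(f"community entities without specimens: {uncovered}")

    gpa = morpho.procrustes_align(used, keep_size=config.keep_size)
    means = morpho.average_configuration(gpa.aligned, groups)
    pca = morpho.pca_relative_warps(means)
    n_keep = config.retained_components or pca.n_retained
    components = [f"PC{i + 1}" for i in range(n_keep)]
    dmat = morpho.trait_distance_matrix(pca.scores_frame(), components)
    report = comm.ses_report(
        pop_matrix,
        dmat,
        metric=comm.METRIC_TRAIT,
        n_reps=config.n_reps,
        constraint=config.constraint,
        rng=config.seed,
    )
    report.config = config.audit_dict()
    report.config["retained_components"] = n_keep
    report.config["pc1_percent_variance"] = float(pca.percent_variance[0])
    logger.info(
        "morpho SES: %d areas, PC1 %.2f%%, %d retained, %d rejections, %.2fs",
        len(report.table),
        pca.percent_variance[0],
        n_keep,
        report.n_rejected,
        time.perf_counter() - t0,
    )
    return report, pca


def merge_reports(
    phylo_report: comm.NullModelReport, trait_report: comm.NullModelReport
) -> pd.DataFrame:
    """Combine both analyses into one area-by-area table.

    Columns: area, SES_mntd, p_mntd, SES_trait, p_trait (permutation
    p-values).
    """
    left = phylo_report.table[["area", "SES", "p_perm"]].rename(
        columns={"SES": "SES_mntd", "p_perm": "p_mntd"}
    )
    right = trait_report.table[["area", "SES", "p_perm"]].rename(
        columns={"SES": "SES_trait", "p_perm": "p_trait"}
    )
    return left.merge(right, on="area", how="outer")


def plot_ses_bars(merged: pd.DataFrame, path: str | Path) -> None:
    """Optional bar chart of SES per area for both metrics."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.2), sharey=True)
    for ax, col, title in zip(axes, ["SES_mntd", "SES_trait"], ["phylogenetic", "morphological"]):
        ax.bar(merged["area"], merged[col], color="steelblue")
        ax.axhline(0.0, color="black", lw=0.8)
        ax.set_title(f"SES ({title})")
        ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
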