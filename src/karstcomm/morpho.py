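"""Outline geometric morphometrics: semilandmarks, Procrustes, relative warps.

The shell of each specimen is represented as a closed 2-D outline polygon
digitized in apertural view.  The analysis chain is

1. resample each outline to ``k`` semilandmarks equally spaced by arc
   length, starting at a biologically homologous vertex (the widest point
   of the aperture on the right side, supplied as a vertex index);
2. generalized Procrustes superimposition removing position and
   orientation — and, optionally, centroid size ("shape-only" variant);
3. coordinate-wise averaging of aligned specimens into lineage or
   population (lineage x area) mean configurations;
4. covariance PCA of the flattened mean configurations (relative warps
   with uniform weighting) with broken-stick component retention;
5. Euclidean distances between entities over the retained scores.

Shell size is ecologically meaningful for these snails, so the default
Procrustes mode retains centroid size; reflections are never permitted
because left/right shell asymmetry is biologically real.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .exceptions import ConvergenceWarning, ValidationError

__all__ = [
    "Outline",
    "LandmarkConfiguration",
    "ProcrustesResult",
    "PCAResult",
    "resample_semilandmarks",
    "centroid_size",
    "procrustes_align",
    "average_configuration",
    "pca_relative_warps",
    "broken_stick_retention",
    "trait_distance_matrix",
    "read_tps",
    "write_tps",
    "read_outline_csv",
    "write_outline_csv",
]

DEFAULT_SEMILANDMARKS = 200


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class Outline:
    """Closed-polygon shell outline.

    ``vertices`` is an (n, 2) array in a consistent length unit (for size-
    retained analyses the unit must be the same across the whole dataset).
    ``start_index`` marks the homologous start vertex (widest point of the
    aperture on the right side), judged at digitization time.
    """

    vertices: np.ndarray
    start_index: int = 0

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValidationError("outline needs an (n>=3, 2) vertex array")
        if not np.all(np.isfinite(v)):
            raise ValidationError("outline vertices must be finite")
        closed_pairs = np.vstack([v, v[:1]])
        seglen = np.linalg.norm(np.diff(closed_pairs, axis=0), axis=1)
        if np.any(seglen[:-1] == 0):
            raise ValidationError("outline has repeated consecutive vertices")
        if seglen.sum() == 0:
            raise ValidationError("outline has zero perimeter")
        if not (0 <= self.start_index < v.shape[0]):
            raise ValidationError("start_index out of range")
        object.__setattr__(self, "vertices", v)

    @property
    def perimeter(self) -> float:
        closed = np.vstack([self.vertices, self.vertices[:1]])
        return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())

    def signed_area(self) -> float:
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered (k, 2) landmark matrix."""

    specimen_id: str
    coords: np.ndarray
    aligned: bool = False

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] < 3:
            raise ValidationError(f"{self.specimen_id}: landmarks must be (k>=3, 2)")
        if not np.all(np.isfinite(c)):
            raise ValidationError(f"{self.specimen_id}: non-finite landmark coordinates")
        self.coords = c

    @property
    def k(self) -> int:
        return self.coords.shape[0]


@dataclass
class ProcrustesResult:
    aligned: list[LandmarkConfiguration]
    centroid_sizes: np.ndarray
    consensus: np.ndarray
    keep_size: bool
    n_iterations: int
    residual: float


@dataclass
class PCAResult:
    """Relative-warp scores with broken-stick retention bookkeeping."""

    row_labels: list[str]
    scores: np.ndarray
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    broken_stick_percent: np.ndarray
    n_retained: int

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.row_labels, columns=cols)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(len(self.eigenvalues))],
                "eigenvalue": self.eigenvalues,
                "percent_variance": self.percent_variance,
                "broken_stick_percent": self.broken_stick_percent,
                "retained": [i < self.n_retained for i in range(len(self.eigenvalues))],
            }
        )


# ---------------------------------------------------------------------------
# semilandmarks


def resample_semilandmarks(
    outline: Outline, k: int = DEFAULT_SEMILANDMARKS, specimen_id: str = ""
) -> LandmarkConfiguration:
    """Place ``k`` semilandmarks at equal arc-length spacing along the outline.

    The traversal direction is normalized to counter-clockwise (by signed
    area) so point sequences are homologous across specimens regardless of
    tracing direction; the first semilandmark falls exactly on the start
    vertex.
    """
    if k < 3:
        raise ValidationError("k must be >= 3")
    verts = outline.vertices
    start = outline.start_index
    if outline.signed_area() < 0:  # normalize to counter-clockwise
        n = len(verts)
        verts = verts[::-1]
        start = (n - 1) - start
    verts = np.roll(verts, -start, axis=0)
    closed = np.vstack([verts, verts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total == 0:
        raise ValidationError("degenerate outline: zero perimeter")
    targets = np.arange(k) * (total / k)
    idx = np.searchsorted(cum, targets, side="right") - 1
    idx = np.clip(idx, 0, len(seg) - 1)
    frac = (targets - cum[idx]) / np.where(seg[idx] > 0, seg[idx], 1.0)
    pts = closed[idx] + frac[:, None] * (closed[idx + 1] - closed[idx])
    pts[0] = verts[0]  # exact on the start landmark
    return LandmarkConfiguration(specimen_id=specimen_id, coords=pts)


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Square root of summed squared deviations of points from their centroid."""
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centered**2).sum()))
    if cs == 0:
        raise ValidationError("centroid size undefined: all points identical")
    return cs


# ---------------------------------------------------------------------------
# Procrustes


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation matrix R minimizing ||source @ R - target|| (no reflection)."""
    u, _, vt = np.linalg.svd(source.T @ target)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1.0
        r = u @ vt
    return r

def _canonical_frame(points: np.ndarray) -> np.ndarray:
    """Rotation carrying a centered configuration to a deterministic frame.

    Aligns the major principal axis of the point scatter with x and fixes
    the remaining 180-degree ambiguity with the third moment along x (then
    y as a tiebreak), so the overall Procrustes frame does not depend on
    which specimen happens to come first.
    """
    cov = points.T @ points
    theta = 0.5 * np.arctan2(2.0 * cov[0, 1], cov[0, 0] - cov[1, 1])
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    p = points @ rot
    mx3 = (p[:, 0] ** 3).sum()
    flip_stat = mx3 if abs(mx3) > 1e-12 * centroid_size(points) ** 3 else (p[:, 1] ** 3).sum()
    if flip_stat < 0:
        rot = rot @ np.array([[-1.0, 0.0], [0.0, -1.0]])
    return rot


def procrustes_align(
    configs: list[LandmarkConfiguration],
    keep_size: bool = True,
    tol: float = 1e-8,
    max_iterations: int = 100,
) -> ProcrustesResult:
    """Generalized Procrustes superimposition of homologous configurations.

    Each configuration is centered at the origin, scaled to unit centroid
    size when ``keep_size`` is false, and iteratively rotated (proper
    rotations only) into least-squares fit with the running consensus until
    the consensus moves by less than ``tol`` (RMS per coordinate).  With
    ``keep_size`` true, centroid sizes pass through unchanged.
    """
    if len(configs) < 2:
        raise ValidationError("Procrustes needs at least two configurations")
    ks = {c.k for c in configs}
    if len(ks) != 1:
        raise ValidationError(f"landmark counts differ across specimens: {sorted(ks)}")
    sizes = np.array([centroid_size(c) for c in configs])
    mats = []
    for c, cs in zip(configs, sizes):
        m = c.coords - c.coords.mean(axis=0)
        if not keep_size:
            m = m / cs
        mats.append(m)
    consensus = mats[0].copy()
    n_iter = 0
    for n_iter in range(1, max_iterations + 1):
        mats = [m @ _optimal_rotation(m, consensus) for m in mats]
        new_consensus = np.mean(mats, axis=0)
        shift = np.sqrt(np.mean((new_consensus - consensus) ** 2))
        consensus = new_consensus
        if shift < tol:
            break
    else:  # pragma: no cover - only on pathological input
        pass
    if n_iter == max_iterations:
        resid = float(sum(((m - consensus) ** 2).sum() for m in mats))
        warnings.warn(
            f"Procrustes did not converge in {max_iterations} iterations "
            f"(residual {resid:g})",
            ConvergenceWarning,
        )
    # rotate everything into a specimen-order-independent frame
    canon = _canonical_frame(consensus)
    consensus = consensus @ canon
    mats = [m @ canon for m in mats]
    residual = float(sum(((m - consensus) ** 2).sum() for m in mats))
    aligned = [
        LandmarkConfiguration(specimen_id=c.specimen_id, coords=m, aligned=True)
        for c, m in zip(configs, mats)
    ]
    return ProcrustesResult(
        aligned=aligned,
        centroid_sizes=sizes,
        consensus=consensus,
        keep_size=keep_size,
        n_iterations=n_iter,
        residual=residual,
    )


def average_configuration(
    aligned: list[LandmarkConfiguration], group_map: dict[str, str]
) -> dict[str, LandmarkConfiguration]:
    """Coordinate-wise mean configuration per group of aligned specimens.

    ``group_map`` sends specimen id to group id (a lineage, or a
    lineage-by-area population).  Every specimen must be mapped; every
    group must be nonempty.
    """
    groups: dict[str, list[np.ndarray]] = {}
    for cfg in aligned:
        if not cfg.aligned:
            raise ValidationError(f"{cfg.specimen_id}: configurations must be Procrustes-aligned")
        if cfg.specimen_id not in group_map:
            raise ValidationError(f"specimen {cfg.specimen_id} missing from group map")
        groups.setdefault(group_map[cfg.specimen_id], []).append(cfg.coords)
    empty = set(group_map.values()) - set(groups)
    if empty:
        raise ValidationError(f"empty groups: {sorted(empty)}")
    return {
        gid: LandmarkConfiguration(specimen_id=gid, coords=np.mean(mats, axis=0), aligned=True)
        for gid, mats in sorted(groups.items())
    }


# ---------------------------------------------------------------------------
# PCA / relative warps


def broken_stick_retention(eigenvalues: np.ndarray) -> tuple[int, np.ndarray]:
    """Broken-stick component retention.

    With p positive eigenvalues, the broken-stick expectation for
    component k is ``b_k = (1/p) * sum_{i=k..p} 1/i``.  The leading run of
    components whose observed variance proportion exceeds its expectation
    is retained; at least one component is always kept.  Returns
    ``(n_retained, expectations)`` with expectations as proportions.
    """
    eig = np.asarray(eigenvalues, dtype=float)
    if eig.size == 0 or np.all(eig <= 0):
        raise ValidationError("broken-stick model needs at least one positive eigenvalue")
    pos = eig[eig > 0]
    p = pos.size
    inv = 1.0 / np.arange(1, p + 1)
    expectations = np.cumsum(inv[::-1])[::-1] / p
    proportions = pos / pos.sum()
    n_retained = 0
    for k in range(p):
        if proportions[k] > expectations[k]:
            n_retained += 1
        else:
            break
    return max(n_retained, 1), expectations


def pca_relative_warps(group_configs: dict[str, LandmarkConfiguration]) -> PCAResult:
    """Covariance PCA of flattened aligned coordinates (uniform relative warps).

    Rows are entities (lineages or populations); the 2k coordinates of each
    mean configuration form the variable vector.  Scores are projections
    onto the eigenvectors of the coordinate covariance matrix, so pairwise
    Euclidean distances among full score rows equal distances among
    centered coordinate vectors.
    """
    if len(group_configs) < 2:
        raise ValidationError("PCA needs at least two entities")
    labels = list(group_configs)
    x = np.array([group_configs[g].coords.ravel() for g in labels])
    centered = x - x.mean(axis=0)
    n = centered.shape[0]
    u, s, _vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    keep = min(n - 1, centered.shape[1])
    eigenvalues = eigenvalues[:keep]
    scores = (u[:, :keep] * s[:keep])
    # deterministic sign convention: largest-|loading| coordinate positive
    for j in range(keep):
        lead = np.argmax(np.abs(_vt[j]))
        if _vt[j, lead] < 0:
            scores[:, j] *= -1.0
    total = eigenvalues.sum()
    percent = 100.0 * eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    n_retained, expectations = broken_stick_retention(eigenvalues)
    bs_percent = np.zeros_like(percent)
    bs_percent[: expectations.size] = 100.0 * expectations
    return PCAResult(
        row_labels=labels,
        scores=scores,
        eigenvalues=eigenvalues,
        percent_variance=percent,
        broken_stick_percent=bs_percent,
        n_retained=n_retained,
    )


def trait_distance_matrix(
    scores: pd.DataFrame, components: list[str] | None = None
) -> DistanceMatrix:
    """Euclidean distance between entities over selected PC scores.

    ``scores`` has one row per entity and PC columns; ``components``
    defaults to PC1 only (the typical size-dominated trait axis), in
    which case distances are absolute score differences.
    """
    if scores.index.duplicated().any():
        raise ValidationError("duplicate entity labels in score table")
    cols = components if components is not None else ["PC1"]
    missing = [c for c in cols if c not in scores.columns]
    if missing:
        raise ValidationError(f"score columns not found: {missing}")
    x = scores.loc[:, cols].to_numpy(dtype=float)
    diff = x[:, None, :] - x[None, :, :]
    mat = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(mat, 0.0)
    mat = 0.5 * (mat + mat.T)
    return DistanceMatrix(mat, ids=[str(i) for i in scores.index])


# ---------------------------------------------------------------------------
# file formats


def read_tps(path: str) -> list[LandmarkConfiguration]:
    """Read landmark configurations from a TPS file.

    Supports LM=, ID=, IMAGE= and SCALE= records (SCALE is ignored; all
    coordinates are kept in digitized units).
    """
    configs: list[LandmarkConfiguration] = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    i = 0
    record = 0
    while i < len(lines):
        m = re.match(r"^LM=(\d+)$", lines[i], flags=re.IGNORECASE)
        if not m:
            raise ValidationError(f"{path}: expected LM= record at line {i + 1}")
        k = int(m.group(1))
        coords = []
        i += 1
        for _ in range(k):
            parts = lines[i].split()
            if len(parts) != 2:
                raise ValidationError(f"{path}: bad coordinate line {i + 1!r}")
            coords.append([float(parts[0]), float(parts[1])])
            i += 1
        record += 1
        spec_id = f"specimen_{record}"
        while i < len(lines) and not lines[i].upper().startswith("LM="):
            key, _, value = lines[i].partition("=")
            if key.upper() == "ID":
                spec_id = value.strip()
            i += 1
        configs.append(LandmarkConfiguration(specimen_id=spec_id, coords=np.array(coords)))
    return configs


def write_tps(configs: list[LandmarkConfiguration], path: str) -> None:
    with open(path, "w") as fh:
        for cfg in configs:
            fh.write(f"LM={cfg.k}\n")
            for x, y in cfg.coords:
                fh.write(f"{x:.10g} {y:.10g}\n")
            fh.write(f"ID={cfg.specimen_id}\n")


def read_outline_csv(path: str, start_index: int = 0) -> Outline:
    df = pd.read_csv(path)
    if not {"x", "y"}.issubset(df.columns):
        raise ValidationError(f"{path}: outline CSV needs 'x' and 'y' columns")
    return Outline(vertices=df[["x", "y"]].to_numpy(dtype=float), start_index=start_index)


def write_outline_csv(outline: Outline, path: str) -> None:
    pd.DataFrame(outline.vertices, columns=["x", "y"]).to_csv(path, index=False)
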