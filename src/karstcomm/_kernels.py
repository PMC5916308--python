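"""Compiled inner loops for the independent-swap null model.

The swap chain and the per-replicate nearest-neighbour metric are the hot
path of the null-model analyses (thousands of replicates, each a fresh
chain of tens of thousands of attempted checkerboard swaps), so both run
under numba.  Randomness comes from an explicit 64-bit LCG (MMIX
multiplier) carried in the chain state: the same seed gives bit-identical
chains on every platform, independent of global RNG state.
"""

from __future__ import annotations

import numba as nb
import numpy as np

_LCG_A = np.uint64(6364136223846793005)
_LCG_C = np.uint64(1442695040888963407)
_SHIFT = np.uint64(33)


@nb.njit(cache=False)
def _mix_seed(seed, stream):
    """Expand (seed, stream) into a well-scrambled 64-bit LCG state."""
    z = np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15) * (np.uint64(stream) + np.uint64(1))
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@nb.njit(cache=False)
def swap_chain(mat, attempts, seed, stream):
    """Run ``attempts`` checkerboard-swap attempts in place; return swap count.

    Each attempt draws two rows and two columns uniformly; if the 2x2
    submatrix is a checkerboard it is flipped, conserving all row and
    column sums.  Attempts that draw a repeated row/column or a
    non-checkerboard submatrix count as attempts, as in the classic
    independent-swap formulation.
    """
    n_rows, n_cols = mat.shape
    ur = np.uint64(n_rows)
    uc = np.uint64(n_cols)
    s = _mix_seed(seed, stream)
    nswap = 0
    for _ in range(attempts):
        s = s * _LCG_A + _LCG_C
        r1 = np.int64((s >> _SHIFT) % ur)
        s = s * _LCG_A + _LCG_C
        r2 = np.int64((s >> _SHIFT) % ur)
        s = s * _LCG_A + _LCG_C
        c1 = np.int64((s >> _SHIFT) % uc)
        s = s * _LCG_A + _LCG_C
        c2 = np.int64((s >> _SHIFT) % uc)
        if r1 == r2 or c1 == c2:
            continue
        a = mat[r1, c1]
        b = mat[r1, c2]
        c = mat[r2, c1]
        d = mat[r2, c2]
        if a == 1 and d == 1 and b == 0 and c == 0:
            mat[r1, c1] = 0
            mat[r1, c2] = 1
            mat[r2, c1] = 1
            mat[r2, c2] = 0
            nswap += 1
        elif a == 0 and d == 0 and b == 1 and c == 1:
            mat[r1, c1] = 1
            mat[r1, c2] = 0
            mat[r2, c1] = 0
            mat[r2, c2] = 1
            nswap += 1
    return nswap


@nb.njit(cache=False)
def mntd_rows(mat, dmat):
    """Mean nearest-neighbour distance per row; NaN for rows with < 2 members."""
    n_rows, n_cols = mat.shape
    out = np.empty(n_rows, dtype=np.float64)
    for r in range(n_rows):
        total = 0.0
        count = 0
        for i in range(n_cols):
            if mat[r, i] == 0:
                continue
            best = np.inf
            for j in range(n_cols):
                if j == i or mat[r, j] == 0:
                    continue
                if dmat[i, j] < best:
                    best = dmat[i, j]
            if best < np.inf:
                total += best
                count += 1
        out[r] = total / count if count >= 2 else np.nan
    return out


@nb.njit(cache=False)
def _violates_lineage_constraint(mat, lineage_codes):
    """True if any row holds two entities with the same lineage code."""
    n_rows, n_cols = mat.shape
    for r in range(n_rows):
        for i in range(n_cols):
            if mat[r, i] == 0:
                continue
            for j in range(i + 1, n_cols):
                if mat[r, j] == 1 and lineage_codes[i] == lineage_codes[j]:
                    return True
    return False


@nb.njit(cache=False)
def null_metric_matrix(mat, dmat, n_reps, attempts, seed, lineage_codes, use_constraint, max_retries):
    """Null distribution of the nearest-neighbour metric per community.

    Runs ``n_reps`` independent swap chains from the observed matrix and
    evaluates the metric on each randomized matrix.  With the same-lineage
    constraint on, a randomized matrix in which any community holds two
    entities of the same lineage is rejected and its chain regenerated
    under a fresh stream.  Returns ``(metrics, n_rejected)`` with metrics
    of shape (n_reps, n_rows); raises no exceptions — a retry-cap overrun
    is signalled by n_rejected == -1.
    """
    n_rows = mat.shape[0]
    metrics = np.empty((n_reps, n_rows), dtype=np.float64)
    n_rejected = 0
    stream = 0
    for rep in range(n_reps):
        while True:
            work = mat.copy()
            swap_chain(work, attempts, seed, stream)
            stream += 1
            if use_constraint and _violates_lineage_constraint(work, lineage_codes):
                n_rejected += 1
                if n_rejected > max_retries:
                    return metrics, -1
                continue
            break
        metrics[rep] = mntd_rows(work, dmat)
    return metrics, n_rejected
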