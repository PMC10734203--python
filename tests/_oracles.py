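"""Independent brute-force oracles used to pin down exact semantics.

Everything here is written against the definitions directly (per-pair loops,
scipy reference routines), never by calling the package's vectorized paths.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.spatial import distance


def sim_pair(x: np.ndarray, y: np.ndarray, measure: str) -> float:
    """Similarity between two vectors, one pair at a time."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if measure == "pearson":
        if x.std() == 0 or y.std() == 0:
            return 0.0
        return float(stats.pearsonr(x, y).statistic)
    if measure == "spearman":
        if x.std() == 0 or y.std() == 0:
            return 0.0
        return float(stats.spearmanr(x, y).statistic)
    if measure == "cosine":
        nx, ny = np.linalg.norm(x), np.linalg.norm(y)
        if nx == 0 or ny == 0:
            return 0.0
        return float(x @ y / (nx * ny))
    if measure == "manhattan":
        return 1.0 / (1.0 + distance.cityblock(x, y))
    if measure == "canberra":
        return 1.0 / (1.0 + distance.canberra(x, y))
    if measure == "euclidean":
        return 1.0 / (1.0 + distance.euclidean(x, y))
    if measure == "rho_p":
        vx, vy = np.var(x), np.var(y)
        if vx + vy == 0:
            return 0.0
        return float(2 * np.cov(x, y, bias=True)[0, 1] / (vx + vy))
    if measure == "phi_s":
        vs = np.var(x + y)
        if vs == 0:
            return 0.0
        return 1.0 / (1.0 + np.var(x - y) / vs)
    if measure == "weighted_rank":
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        w = rx + ry
        mx = np.sum(w * rx) / w.sum()
        my = np.sum(w * ry) / w.sum()
        cov = np.sum(w * (rx - mx) * (ry - my))
        vx = np.sum(w * (rx - mx) ** 2)
        vy = np.sum(w * (ry - my) ** 2)
        if vx <= 0 or vy <= 0:
            return 0.0
        return float(cov / np.sqrt(vx * vy))
    if measure == "jaccard":
        sx = set(np.flatnonzero(x > 0).tolist())
        sy = set(np.flatnonzero(y > 0).tolist())
        if not sx and not sy:
            return 0.0
        return len(sx & sy) / len(sx | sy)
    raise ValueError(measure)


def sim_matrix(A: np.ndarray, B: np.ndarray, measure: str) -> np.ndarray:
    return np.array([[sim_pair(a, b, measure) for b in B] for a in A])


CORRELATION_LIKE = {"pearson", "spearman", "cosine", "rho_p", "weighted_rank"}


def knn_prediction(query_shared: np.ndarray, ref_shared: np.ndarray,
                   ref_target: np.ndarray, measure: str, k: int
                   ) -> np.ndarray:
    """Naive k-NN regression: per-cell loop, full sort, clamp, weighted mean."""
    m = query_shared.shape[0]
    out = np.zeros((m, ref_target.shape[1]))
    for i in range(m):
        sims = np.array([sim_pair(query_shared[i], ref_shared[j], measure)
                         for j in range(ref_shared.shape[0])])
        order = sorted(range(len(sims)), key=lambda j: (-sims[j], j))[:k]
        w = sims[order]
        if measure in CORRELATION_LIKE:
            w = np.maximum(w, 0.0)
        if w.sum() <= 0:
            w = np.ones_like(w)
        out[i] = (w[:, None] * ref_target[order]).sum(axis=0) / w.sum()
    return out


def morans_i_naive(x: np.ndarray, O: np.ndarray) -> float:
    """Double-loop Moran's I over an off-diagonal weight matrix."""
    n = len(x)
    z = x - x.mean()
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += O[i, j] * z[i] * z[j]
            s0 += O[i, j]
    return n / s0 * num / (z @ z)


def tie_aware_discrepancy(query_row, ref_shared, ref_target, measure, k,
                          impl_row, atol=1e-9):
    """Smallest max-abs difference between an implementation's prediction and
    any brute-force prediction that resolves exact similarity ties at the
    k-boundary differently (equal similarities carry equal weights, so every
    resolution is an equally valid k-NN regression)."""
    from itertools import combinations, islice

    sims = np.array([sim_pair(query_row, r, measure)
                     for r in ref_shared])
    order = sorted(range(len(sims)), key=lambda j: (-sims[j], j))
    v = sims[order[k - 1]]
    definite = [j for j in order[:k] if sims[j] > v + atol]
    group = [j for j in range(len(sims)) if abs(sims[j] - v) <= atol]
    need = k - len(definite)
    best = np.inf
    for combo in islice(combinations(group, need), 20000):
        idx = definite + list(combo)
        w = sims[idx]
        if measure in CORRELATION_LIKE:
            w = np.maximum(w, 0.0)
        if w.sum() <= 0:
            w = np.ones_like(w)
        pred = (w[:, None] * ref_target[idx]).sum(axis=0) / w.sum()
        best = min(best, float(np.abs(pred - impl_row).max()))
        if best < 1e-12:
            break
    return best
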