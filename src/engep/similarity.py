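"""Expression-similarity measures used for neighbor search.

Ten measures are provided, in three kinds:

* correlation-like (signed): Pearson, Spearman, cosine, the rho_p
  proportionality measure and a weighted rank correlation. Range [-1, 1];
  negative values are later clamped to zero when used as k-NN weights.
* distance (non-negative): Manhattan, Canberra, Euclidean and the phi_s
  proportionality measure. Distances are mapped to similarities through
  ``s = 1 / (1 + d)`` so that higher always means more similar.
* overlap: Jaccard index of the strictly-positive supports, range [0, 1].

The proportionality measures follow Quinn et al.:
``rho_p(x, y) = 2 cov(x, y) / (var x + var y)`` (equals 1 iff y = x + const)
and ``phi_s(x, y) = var(x - y) / var(x + y)`` (equals 0 iff y = x + const).
They are computed directly on the log-scale expression vectors.

All pairwise computations are vectorized; a brute-force per-pair oracle used
in the tests pins down the exact semantics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

__all__ = [
    "SimilarityMeasure",
    "MEASURES",
    "CORRELATION_MEASURES",
    "to_similarity",
    "pairwise_similarity",
    "jaccard_binarize",
]


@dataclass(frozen=True)
class SimilarityMeasure:
    name: str
    kind: str  # "correlation" | "distance" | "overlap"


MEASURES: dict[str, SimilarityMeasure] = {
    name: SimilarityMeasure(name, kind)
    for name, kind in [
        ("pearson", "correlation"),
        ("spearman", "correlation"),
        ("cosine", "correlation"),
        ("manhattan", "distance"),
        ("canberra", "distance"),
        ("euclidean", "distance"),
        ("rho_p", "correlation"),
        ("phi_s", "distance"),
        ("weighted_rank", "correlation"),
        ("jaccard", "overlap"),
    ]
}

CORRELATION_MEASURES = frozenset(
    name for name, m in MEASURES.items() if m.kind == "correlation"
)

_EPS = 1e-12


def as_measure(measure: str | SimilarityMeasure) -> SimilarityMeasure:
    if isinstance(measure, SimilarityMeasure):
        return measure
    try:
        return MEASURES[measure]
    except KeyError:
        raise ValueError(
            f"unknown measure {measure!r}; choose from {sorted(MEASURES)}"
        ) from None


def to_similarity(d):
    """Map a non-negative distance to a similarity in (0, 1] via 1/(1+d)."""
    d = np.asarray(d, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    return 1.0 / (1.0 + d)


def jaccard_binarize(x: np.ndarray) -> np.ndarray:
    """Support of an expression vector: indices with strictly positive value."""
    return np.flatnonzero(np.asarray(x) > 0)


def _center(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-centered matrix and per-row standard deviation (population)."""
    C = M - M.mean(axis=1, keepdims=True)
    sd = np.sqrt((C ** 2).mean(axis=1))
    return C, sd


def _pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    g = A.shape[1]
    CA, sa = _center(A)
    CB, sb = _center(B)
    bad_a, bad_b = sa < _EPS, sb < _EPS
    sa = np.where(bad_a, 1.0, sa)
    sb = np.where(bad_b, 1.0, sb)
    S = (CA / sa[:, None]) @ (CB / sb[:, None]).T / g
    if bad_a.any() or bad_b.any():
        warnings.warn("zero-variance vectors: similarity set to 0",
                      stacklevel=3)
        S[bad_a, :] = 0.0
        S[:, bad_b] = 0.0
    return np.clip(S, -1.0, 1.0)


def _rho_p(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    g = A.shape[1]
    CA, sa = _center(A)
    CB, sb = _center(B)
    cov = CA @ CB.T / g
    denom = (sa ** 2)[:, None] + (sb ** 2)[None, :]
    bad = (sa < _EPS)[:, None] | (sb < _EPS)[None, :]
    if bad.any():
        warnings.warn("zero-variance vectors: similarity set to 0",
                      stacklevel=3)
    S = np.where(bad, 0.0, 2.0 * cov / np.where(denom < _EPS, 1.0, denom))
    return np.clip(S, -1.0, 1.0)


def _phi_s(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    # var(x-y) = vx + vy - 2 cov, var(x+y) = vx + vy + 2 cov
    g = A.shape[1]
    CA, sa = _center(A)
    CB, sb = _center(B)
    cov = CA @ CB.T / g
    vsum = (sa ** 2)[:, None] + (sb ** 2)[None, :]
    num = vsum - 2.0 * cov
    den = vsum + 2.0 * cov
    num = np.maximum(num, 0.0)
    bad = den < _EPS
    d = np.where(bad, 0.0, num / np.where(bad, 1.0, den))
    S = to_similarity(d)
    if bad.any():
        # var(x+y) = 0: anti-proportional or doubly constant -> dissimilar
        S[bad] = 0.0
    return S


def _cosine(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    bad_a, bad_b = na < _EPS, nb < _EPS
    na = np.where(bad_a, 1.0, na)
    nb = np.where(bad_b, 1.0, nb)
    S = (A / na[:, None]) @ (B / nb[:, None]).T
    if bad_a.any() or bad_b.any():
        warnings.warn("zero vectors under cosine: similarity set to 0",
                      stacklevel=3)
        S[bad_a, :] = 0.0
        S[:, bad_b] = 0.0
    return np.clip(S, -1.0, 1.0)


def _weighted_rank(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Weighted Pearson on average-ranks, weights favoring high expression.

    Per pair (i, j) the weight of gene position t is
    ``w_t = (g - rx_t + 1) + (g - ry_t + 1)`` with rx, ry the *descending*
    average-ranks (1 = most expressed) of A[i] and B[j]; equivalently the sum
    of the ascending ranks, so highly expressed genes carry the largest
    weights. Because ``w_t`` is a sum of an A-only and a B-only term, every
    moment of the weighted correlation decomposes into matrix products.
    """
    X = rankdata(A, axis=1)  # ascending average ranks, 1..g
    Y = rankdata(B, axis=1)
    U, V = X, Y  # weights: w = rx_asc + ry_asc
    su = U.sum(axis=1)
    sv = V.sum(axis=1)
    Sw = su[:, None] + sv[None, :]
    Sx = (U * X).sum(axis=1)[:, None] + X @ V.T
    Sy = U @ Y.T + (V * Y).sum(axis=1)[None, :]
    Sxy = (U * X) @ Y.T + X @ (V * Y).T
    Sxx = (U * X * X).sum(axis=1)[:, None] + (X * X) @ V.T
    Syy = U @ (Y * Y).T + (V * Y * Y).sum(axis=1)[None, :]
    num = Sw * Sxy - Sx * Sy
    varx = Sw * Sxx - Sx ** 2
    vary = Sw * Syy - Sy ** 2
    bad = (varx < _EPS) | (vary < _EPS)
    denom = np.sqrt(np.where(bad, 1.0, varx * vary))
    S = np.where(bad, 0.0, num / denom)
    if bad.any():
        warnings.warn("tied-constant vectors under weighted_rank: "
                      "similarity set to 0", stacklevel=3)
    return np.clip(S, -1.0, 1.0)


def _jaccard(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    Ab = (A > 0).astype(np.float64)
    Bb = (B > 0).astype(np.float64)
    inter = Ab @ Bb.T
    union = Ab.sum(axis=1)[:, None] + Bb.sum(axis=1)[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1.0), 0.0)


def pairwise_similarity(A: np.ndarray, B: np.ndarray,
                        measure: str | SimilarityMeasure) -> np.ndarray:
    """All-pairs similarity between rows of ``A`` (m x g) and ``B`` (n x g).

    Distance-kind measures are returned already transformed by
    :func:`to_similarity`, so in every case a larger entry means a more
    similar pair.
    """
    m = as_measure(measure)
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise ValueError("A and B must be 2-D with a common gene axis")
    if A.shape[1] < 2:
        raise ValueError("at least two genes are required")

    if m.name == "pearson":
        return _pearson(A, B)
    if m.name == "spearman":
        return _pearson(rankdata(A, axis=1), rankdata(B, axis=1))
    if m.name == "cosine":
        return _cosine(A, B)
    if m.name == "manhattan":
        return to_similarity(cdist(A, B, metric="cityblock"))
    if m.name == "canberra":
        return to_similarity(cdist(A, B, metric="canberra"))
    if m.name == "euclidean":
        return to_similarity(cdist(A, B, metric="euclidean"))
    if m.name == "rho_p":
        return _rho_p(A, B)
    if m.name == "phi_s":
        return _phi_s(A, B)
    if m.name == "weighted_rank":
        return _weighted_rank(A, B)
    if m.name == "jaccard":
        return _jaccard(A, B)
    raise AssertionError(f"unhandled measure {m.name}")
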