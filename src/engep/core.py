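"""Ensemble k-NN regression for imputing unmeasured gene expression.

The method runs in two steps. Step 1 generates many *base* predictions: each
reference is randomly split into sub-references of at most ``n0`` cells, and
for every (sub-reference r, similarity measure t, neighbor count k) triple a
k-NN regression predicts each query cell's target-gene expression as the
similarity-weighted average of its k most similar reference cells

    yhat_il = sum_j w_ij x_jl / sum_j w_ij,   j in N_rtk(i),

where the weights are the (negativity-clamped, for signed measures)
similarities computed on the shared-gene block. Step 2 scores each
sub-reference by how well the same machinery predicts the *measured* shared
genes: the per-measure/per-k shared-gene predictions are averaged into a
consensus, and the squared Pearson correlation between that consensus and the
observed query expression is the sub-reference's predictive power s_r. A
min-max linear map converts s_r into ensemble weights omega_r in [0.1, 0.9],
and the final prediction is the omega-weighted average of all base results,

    yhat_il = sum_r sum_t sum_k omega_r yhat_il^(rtk) / (|T||K| sum_r omega_r).

With a single sub-reference overall the weighting is vacuous and the base
predictions are plainly averaged (single-reference mode).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import ExpressionMatrix, SubReference, log_normalize, shared_genes
from .similarity import (MEASURES, SimilarityMeasure, as_measure,
                         pairwise_similarity)

__all__ = [
    "EngepConfig",
    "PredictionStack",
    "EnsembleWeights",
    "partition_reference",
    "knn_neighbors",
    "clamp_negatives",
    "knn_predict",
    "consensus_shared",
    "predictive_power",
    "map_weights",
    "ensemble_combine",
    "engep_predict",
]

logger = logging.getLogger("engep")

DEFAULT_K = (20, 30, 40, 50)
DEFAULT_MEASURES = tuple(MEASURES)


@dataclass(frozen=True)
class EngepConfig:
    """Run parameters for the ensemble predictor.

    Defaults follow the method's recommended settings: sub-references of at
    most ``n0 = 8000`` cells, the full ten-measure panel, neighbor counts
    ``{20, 30, 40, 50}`` and ensemble weights mapped onto ``[0.1, 0.9]``.
    ``weight_map="minmax"`` rescales the observed predictive powers onto the
    weight range; ``"fixed"`` instead maps s_r in [0, 1] affinely onto it.
    """

    n0: int = 8000
    k_values: tuple[int, ...] = DEFAULT_K
    measures: tuple[str, ...] = DEFAULT_MEASURES
    seed: int = 0
    weight_range: tuple[float, float] = (0.1, 0.9)
    weight_map: str = "minmax"

    def __post_init__(self) -> None:
        if not self.k_values or any(k < 1 for k in self.k_values):
            raise ValueError("k_values must be positive integers")
        if self.n0 < max(self.k_values):
            raise ValueError("n0 must be at least max(k_values)")
        lo, hi = self.weight_range
        if not (0 < lo < hi < 1):
            raise ValueError("weight_range must satisfy 0 < low < high < 1")
        for m in self.measures:
            as_measure(m)
        if self.weight_map not in ("minmax", "fixed"):
            raise ValueError("weight_map must be 'minmax' or 'fixed'")


@dataclass
class PredictionStack:
    """Base predictions indexed by (sub-reference, measure, k).

    ``entries[(r, t, k)]`` is an ``m x G`` matrix; ``target_genes`` names the
    G columns; ``target_kind`` is ``"unique"`` for prediction targets and
    ``"shared"`` for the held-in measured genes used to score sub-references.
    """

    entries: dict[tuple[int, str, int], np.ndarray]
    target_genes: list[str]
    target_kind: str
    n_subrefs: int
    measures: tuple[str, ...]
    k_values: tuple[int, ...]

    def check_complete(self) -> None:
        for r in range(self.n_subrefs):
            for t in self.measures:
                for k in self.k_values:
                    if (r, t, k) not in self.entries:
                        raise KeyError(f"missing base prediction ({r}, {t}, {k})")


@dataclass(frozen=True)
class EnsembleWeights:
    s: np.ndarray      # predictive power per sub-reference, in [0, 1]
    omega: np.ndarray  # mapped ensemble weight per sub-reference


# ---------------------------------------------------------------------------
# step 1: base predictions
# ---------------------------------------------------------------------------

def partition_reference(ref: ExpressionMatrix, n0: int, seed: int
                        ) -> list[np.ndarray]:
    """Seeded random partition of reference cells into ceil(n/n0) equal parts.

    Returns row-index arrays; part sizes differ by at most one, parts are
    disjoint and cover every cell.
    """
    n = ref.n_cells
    if n < 1:
        raise ValueError("reference must contain at least one cell")
    n_parts = -(-n // n0)  # ceil
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    # first (n % n_parts) parts get the extra cell
    base, extra = divmod(n, n_parts)
    parts, start = [], 0
    for i in range(n_parts):
        size = base + (1 if i < extra else 0)
        parts.append(np.sort(perm[start:start + size]))
        start += size
    return parts


def knn_neighbors(sim_row: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest similarities, ties broken by ascending index."""
    sim_row = np.asarray(sim_row)
    n = sim_row.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available cells")
    # stable sort of the negated similarities gives the tie rule for free
    order = np.argsort(-sim_row, kind="stable")
    return order[:k]


def clamp_negatives(sims: np.ndarray, measure: str | SimilarityMeasure
                    ) -> np.ndarray:
    """Zero out negative similarities for signed (correlation-like) measures."""
    m = as_measure(measure)
    if m.kind == "correlation":
        return np.maximum(sims, 0.0)
    return np.asarray(sims, dtype=np.float64)


def _knn_from_sim(S: np.ndarray, target_values: np.ndarray, k: int,
                  measure: str, order: np.ndarray | None = None) -> np.ndarray:
    """Weighted k-NN regression given a precomputed m x n similarity matrix.

    ``order`` optionally reuses a full stable descending argsort of S so one
    sort serves every k.
    """
    m_cells, n_cells = S.shape
    if k > n_cells:
        raise ValueError(f"k={k} exceeds sub-reference size {n_cells}")
    if order is None:
        order = np.argsort(-S, axis=1, kind="stable")
    order = order[:, :k]
    w = np.take_along_axis(S, order, axis=1)
    w = clamp_negatives(w, measure)
    wsum = w.sum(axis=1)
    degenerate = wsum <= 0
    if degenerate.any():
        # all-negative (clamped) neighborhoods: unweighted mean of the k
        logger.debug("%d query cells fell back to unweighted neighbor mean",
                     int(degenerate.sum()))
        w[degenerate] = 1.0
        wsum = w.sum(axis=1)
    neigh_vals = target_values[order]            # (m, k, G)
    return np.einsum("mk,mkg->mg", w, neigh_vals) / wsum[:, None]


def knn_predict(subref: SubReference, query_shared: np.ndarray,
                measure: str, k: int, target_kind: str = "unique",
                sim: np.ndarray | None = None) -> np.ndarray:
    """One base prediction for a (sub-reference, measure, k) triple.

    ``target_kind="unique"`` predicts the sub-reference-exclusive genes;
    ``"shared"`` predicts the common genes back (used to score the
    sub-reference). ``sim`` optionally reuses a precomputed similarity matrix
    between the query and this sub-reference.
    """
    if target_kind not in ("unique", "shared"):
        raise ValueError("target_kind must be 'unique' or 'shared'")
    if sim is None:
        sim = pairwise_similarity(query_shared, subref.shared.values, measure)
    target = subref.unique if target_kind == "unique" else subref.shared
    return _knn_from_sim(sim, target.values, k, measure)


def compute_stack(subrefs: list[SubReference], query_shared: np.ndarray,
                  cfg: EngepConfig, target_kind: str,
                  target_genes: list[str]) -> PredictionStack:
    """All R x |T| x |K| base predictions, reusing one similarity matrix per
    (sub-reference, measure) pair across all k."""
    entries: dict[tuple[int, str, int], np.ndarray] = {}
    for r, sub in enumerate(subrefs):
        target = sub.unique if target_kind == "unique" else sub.shared
        for t in cfg.measures:
            sim = pairwise_similarity(query_shared, sub.shared.values, t)
            order = np.argsort(-sim, axis=1, kind="stable")
            for k in cfg.k_values:
                k_eff = min(k, sub.n_cells)
                if k_eff < k:
                    warnings.warn(
                        f"k={k} clipped to {k_eff} for sub-reference {r}",
                        stacklevel=2)
                entries[(r, t, k)] = _knn_from_sim(
                    sim, target.values, k_eff, t, order=order)
    return PredictionStack(entries, list(target_genes), target_kind,
                           len(subrefs), cfg.measures, cfg.k_values)


# ---------------------------------------------------------------------------
# step 2: ensemble
# ---------------------------------------------------------------------------

def consensus_shared(stack: PredictionStack, r: int) -> np.ndarray:
    """Plain average over measures and k of sub-reference r's shared-gene
    predictions."""
    mats = []
    for t in stack.measures:
        for k in stack.k_values:
            if (r, t, k) not in stack.entries:
                raise KeyError(f"missing base prediction ({r}, {t}, {k})")
            mats.append(stack.entries[(r, t, k)])
    return np.mean(mats, axis=0)


def predictive_power(pred: np.ndarray, observed: np.ndarray) -> float:
    """Squared Pearson correlation between flattened prediction and truth."""
    pred = np.asarray(pred, dtype=np.float64).ravel()
    observed = np.asarray(observed, dtype=np.float64).ravel()
    if pred.shape != observed.shape:
        raise ValueError("prediction and observation shapes differ")
    if pred.std() == 0 or observed.std() == 0:
        warnings.warn("zero variance in predictive_power input; s_r = 0",
                      stacklevel=2)
        return 0.0
    r = np.corrcoef(pred, observed)[0, 1]
    return float(min(r * r, 1.0))


def map_weights(s: np.ndarray, weight_range: tuple[float, float] = (0.1, 0.9),
                mode: str = "minmax") -> np.ndarray:
    """Map predictive powers to ensemble weights.

    ``minmax`` affinely rescales the observed s values onto the weight range
    (so the best sub-reference always gets the top weight); all-equal s —
    including a single sub-reference — maps to the midpoint. ``fixed``
    affinely maps the absolute scale [0, 1] onto the range instead.
    """
    s = np.asarray(s, dtype=np.float64)
    if s.size < 1:
        raise ValueError("need at least one predictive power")
    lo, hi = weight_range
    if mode == "fixed":
        return lo + s * (hi - lo)
    smin, smax = s.min(), s.max()
    if smax - smin == 0:
        return np.full(s.shape, (lo + hi) / 2.0)
    return lo + (s - smin) / (smax - smin) * (hi - lo)


def ensemble_combine(stack: PredictionStack, weights: EnsembleWeights,
                     gene_presence: np.ndarray | None = None) -> np.ndarray:
    """Weighted average of the full base-prediction stack.

    ``gene_presence`` is an optional ``(R, G)`` boolean mask marking which
    target genes each sub-reference actually contains; absent genes
    contribute nothing and the weight normalization for such a gene runs
    only over the sub-references carrying it.
    """
    stack.check_complete()
    R = stack.n_subrefs
    omega = np.asarray(weights.omega, dtype=np.float64)
    if omega.shape != (R,):
        raise ValueError("one omega per sub-reference is required")
    any_entry = next(iter(stack.entries.values()))
    m, G = any_entry.shape
    if gene_presence is None:
        gene_presence = np.ones((R, G), dtype=bool)
    ntk = len(stack.measures) * len(stack.k_values)
    num = np.zeros((m, G))
    for r in range(R):
        acc = np.zeros((m, G))
        for t in stack.measures:
            for k in stack.k_values:
                e = stack.entries[(r, t, k)]
                if e.shape != (m, G):
                    raise ValueError("inconsistent base prediction shapes")
                acc += e
        num += omega[r] * acc * gene_presence[r][None, :]
    den = ntk * (gene_presence * omega[:, None]).sum(axis=0)
    if np.any(den == 0):
        missing = [stack.target_genes[i] for i in np.flatnonzero(den == 0)[:5]]
        raise ValueError(f"no sub-reference contains target genes {missing}")
    return num / den[None, :]


# ---------------------------------------------------------------------------
# end-to-end
# ---------------------------------------------------------------------------

def _prepare(m: ExpressionMatrix) -> ExpressionMatrix:
    return m if m.normalized else log_normalize(m)


def build_subreferences(refs: list[ExpressionMatrix], common: list[str],
                        targets: list[str], n0: int, seed: int
                        ) -> tuple[list[SubReference], np.ndarray]:
    """Partition references and split each part into shared/unique blocks.

    Returns the sub-references plus an (R, G) presence mask saying which
    targets each sub-reference carries. References missing some targets get
    zero columns there (masked out of the ensemble by the presence mask).
    """
    subrefs: list[SubReference] = []
    presence_rows: list[np.ndarray] = []
    for ri, ref in enumerate(refs):
        have = set(ref.gene_ids)
        present = np.array([g in have for g in targets], dtype=bool)
        ref_targets = [g for g, p in zip(targets, present) if p]
        shared_block = ref.subset_genes(common)
        if ref_targets:
            unique_block = ref.subset_genes(ref_targets)
        else:
            unique_block = None
        for part in partition_reference(ref, n0, seed + ri):
            sh = shared_block.subset_cells(part)
            uniq_values = np.zeros((len(part), len(targets)))
            if unique_block is not None:
                sub_u = unique_block.subset_cells(part)
                uniq_values[:, present] = sub_u.values
            uniq = ExpressionMatrix(uniq_values, sh.cell_ids,
                                    np.asarray(targets, dtype=object),
                                    normalized=True)
            subrefs.append(SubReference(sh, uniq, origin=f"ref{ri}",
                                        index=len(subrefs)))
            presence_rows.append(present)
    return subrefs, np.array(presence_rows, dtype=bool)


def engep_predict(query: ExpressionMatrix, refs: list[ExpressionMatrix],
                  targets: list[str], cfg: EngepConfig = EngepConfig(),
                  return_details: bool = False):
    """Predict target-gene expression for every query cell.

    Runs the full pipeline: log-normalization (if needed), common-gene
    selection, sub-reference partitioning, base k-NN predictions, shared-gene
    consensus scoring, weight mapping, and the weighted ensemble. Returns an
    :class:`ExpressionMatrix` of predictions (and, with
    ``return_details=True``, a dict carrying the weights and base stack).
    """
    if not refs:
        raise ValueError("at least one reference is required")
    targets = list(targets)
    in_any_ref = set().union(*(set(r.gene_ids) for r in refs))
    absent = [g for g in targets if g not in in_any_ref]
    if absent:
        raise ValueError(f"no reference contains target genes: {absent[:10]}")

    query_n = _prepare(query)
    refs_n = [_prepare(r) for r in refs]
    common = [g for g in shared_genes(query_n, refs_n) if g not in targets]
    if len(common) < 2:
        raise ValueError("fewer than two common genes after removing targets")
    qy = query_n.subset_genes(common).values

    subrefs, presence = build_subreferences(refs_n, common, targets,
                                            cfg.n0, cfg.seed)
    R = len(subrefs)
    stack = compute_stack(subrefs, qy, cfg, "unique", targets)

    if R == 1:
        # single-reference mode: plain average of the base predictions
        omega = np.array([1.0])
        s = np.array([np.nan])
        pred = ensemble_combine(stack, EnsembleWeights(s, omega), presence)
        weights = EnsembleWeights(s, omega)
    else:
        shared_stack = compute_stack(subrefs, qy, cfg, "shared", common)
        s = np.array([
            predictive_power(consensus_shared(shared_stack, r), qy)
            for r in range(R)
        ])
        omega = map_weights(s, cfg.weight_range, cfg.weight_map)
        weights = EnsembleWeights(s, omega)
        pred = ensemble_combine(stack, weights, presence)
        for r in range(R):
            logger.info("sub-reference %d (%s): s=%.4f omega=%.3f",
                        r, subrefs[r].origin, s[r], omega[r])

    result = ExpressionMatrix(pred, query_n.cell_ids,
                              np.asarray(targets, dtype=object),
                              normalized=True)
    if return_details:
        return result, {"weights": weights, "stack": stack,
                        "subrefs": subrefs, "common_genes": common,
                        "presence": presence}
    return result
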