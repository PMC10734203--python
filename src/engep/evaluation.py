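"""Cross-validation protocol and per-gene accuracy metrics.

Measured genes are randomly split into N equal-sized folds; each fold is held
out in turn and predicted from the remaining shared genes, so that every
measured gene receives an out-of-fold prediction. Accuracy per gene is
summarized by Pearson and Spearman correlation and RMSE across cells, and two
methods are compared by the accuracy ratio (AR): the number of genes one
predicts strictly better divided by the number it predicts strictly worse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import EngepConfig, engep_predict
from .data_model import ExpressionMatrix

__all__ = [
    "CvScheme",
    "GeneMetrics",
    "make_folds",
    "gene_metrics",
    "cross_validate",
    "accuracy_ratio",
    "compare_metric_distributions",
]


@dataclass(frozen=True)
class CvScheme:
    """Fold layout: ``kfold`` with ``n_folds = N`` or ``loo`` (N = n genes)."""

    n_folds: int = 5
    mode: str = "kfold"
    seed: int = 0

    def resolve(self, n_genes: int) -> int:
        if self.mode == "loo":
            return n_genes
        if self.mode != "kfold":
            raise ValueError("mode must be 'kfold' or 'loo'")
        if not 2 <= self.n_folds <= n_genes:
            raise ValueError(
                f"n_folds={self.n_folds} invalid for {n_genes} genes")
        return self.n_folds


@dataclass(frozen=True)
class GeneMetrics:
    gene_id: str
    pcc: float
    scc: float
    rmse: float
    fold: int


def make_folds(genes: list[str], scheme: CvScheme) -> list[list[str]]:
    """Seeded random partition of genes into N folds of near-equal size."""
    genes = list(genes)
    n = scheme.resolve(len(genes))
    rng = np.random.default_rng(scheme.seed)
    perm = rng.permutation(len(genes))
    base, extra = divmod(len(genes), n)
    folds, start = [], 0
    for i in range(n):
        size = base + (1 if i < extra else 0)
        folds.append([genes[j] for j in perm[start:start + size]])
        start += size
    return folds


def gene_metrics(pred: np.ndarray, observed: np.ndarray, gene_ids: list[str],
                 fold: int = 0) -> list[GeneMetrics]:
    """Per-gene PCC / SCC / RMSE across cells.

    Genes with zero variance in the measured expression get NaN correlations
    (undefined) but still a valid RMSE.
    """
    pred = np.asarray(pred, dtype=np.float64)
    observed = np.asarray(observed, dtype=np.float64)
    if pred.shape != observed.shape:
        raise ValueError("prediction and observation shapes differ")
    out = []
    for j, g in enumerate(gene_ids):
        p, o = pred[:, j], observed[:, j]
        rmse = float(np.sqrt(np.mean((p - o) ** 2)))
        if o.std() == 0 or p.std() == 0:
            pcc = scc = float("nan")
        else:
            pcc = float(np.corrcoef(p, o)[0, 1])
            scc = float(stats.spearmanr(p, o).statistic)
        out.append(GeneMetrics(g, pcc, scc, rmse, fold))
    return out


def cross_validate(query: ExpressionMatrix, refs: list[ExpressionMatrix],
                   scheme: CvScheme = CvScheme(),
                   cfg: EngepConfig = EngepConfig(),
                   genes: list[str] | None = None) -> pd.DataFrame:
    """N-fold (or leave-one-out) cross-validation over measured genes.

    In each iteration one fold of genes is held out as prediction targets
    while the remaining folds form the common-gene block; the held-out genes
    never participate in neighbor search for their own fold. Returns a tidy
    frame with columns gene, pcc, scc, rmse, fold.
    """
    from .data_model import log_normalize, shared_genes as _shared

    query_n = query if query.normalized else log_normalize(query)
    refs_n = [r if r.normalized else log_normalize(r) for r in refs]
    if genes is None:
        genes = _shared(query_n, refs_n)
    folds = make_folds(list(genes), scheme)
    rows: list[GeneMetrics] = []
    for fi, heldout in enumerate(folds):
        remaining = [g for g in genes if g not in set(heldout)]
        if len(remaining) < 2:
            raise ValueError(
                f"fold {fi} leaves fewer than two common genes")
        pred = engep_predict(query_n.subset_genes(remaining), refs_n,
                             heldout, cfg)
        observed = query_n.subset_genes(heldout).values
        rows.extend(gene_metrics(pred.values, observed, heldout, fold=fi))
    return pd.DataFrame([vars(r) for r in rows])


def accuracy_ratio(metric_a: np.ndarray, metric_b: np.ndarray,
                   higher_better: bool = True) -> tuple[float, int, int]:
    """Accuracy ratio of method A over method B plus the better/worse counts.

    Ties count in neither direction; a zero denominator yields ``math.inf``.
    """
    a = np.asarray(metric_a, dtype=np.float64)
    b = np.asarray(metric_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("metric vectors must cover the same gene set")
    if higher_better:
        better = int(np.sum(a > b))
        worse = int(np.sum(a < b))
    else:
        better = int(np.sum(a < b))
        worse = int(np.sum(a > b))
    ar = math.inf if worse == 0 else better / worse
    return ar, better, worse


def compare_metric_distributions(metric_a: np.ndarray, metric_b: np.ndarray
                                 ) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two per-gene metric
    distributions (reporting convenience, not part of the method)."""
    res = stats.ranksums(np.asarray(metric_a), np.asarray(metric_b))
    return float(res.pvalue)
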