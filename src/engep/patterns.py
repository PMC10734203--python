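"""Spatial pattern discovery among measured and predicted genes.

Known patterns are found by graph-based clustering of the spatially variable
measured genes: a spatial weight matrix over cells is built from a
k-nearest-neighbor graph of the coordinates, spatially variable genes are
selected by Moran's I (BH-adjusted one-sided p < alpha) plus a minimum
expression fraction, a Spatial Cross-Correlation Index (SCI) is computed for
every gene pair, the weakest decile of pairwise scores is zeroed, and the
resulting weighted gene network is partitioned by Louvain clustering.

The SCI here keeps a self-loop of weight 0.5 on every cell (the off-diagonal
neighbor weights also sum to 0.5 per row), so gene pairs that agree in the
*same* cells score higher than under the purely off-diagonal cross
correlation.

Novel patterns among predicted (unmeasured) genes are found by scoring each
gene's maximum SCI against the known-pattern profiles (its likelihood
score), testing the score distribution for multimodality with Hartigan's dip
test, splitting the genes at the density valley between the two main modes
(+- 0.05 band), and re-clustering the low-likelihood genes at a lower
resolution with stringent cluster-level (3 SD) and gene-level (>= 10
within-cluster connections) filters.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree, Delaunay

from ._dip import dip_test
from .data_model import ExpressionMatrix, hvg_ranking

__all__ = [
    "SpatialWeights",
    "Pattern",
    "LikelihoodClassification",
    "build_spatial_weights",
    "morans_i",
    "filter_spatial_genes",
    "sci",
    "sci_matrix",
    "gene_network",
    "cluster_genes",
    "filter_singleton_patterns",
    "likelihood_scores",
    "detect_multimodality",
    "classify_by_likelihood",
    "assign_to_known",
    "discover_novel_patterns",
    "representative_genes",
    "find_known_patterns",
    "run_pattern_discovery",
]


# ---------------------------------------------------------------------------
# spatial weights
# ---------------------------------------------------------------------------

@dataclass
class SpatialWeights:
    """Symmetric cell-adjacency weight matrix with self-loops.

    Diagonal entries are 0.5 and each row's off-diagonal neighbor weights sum
    to (at most) 0.5, so spatial smoothing shares weight equally between a
    cell and its neighborhood.
    """

    W: np.ndarray
    k_spatial: int

    @property
    def n_cells(self) -> int:
        return self.W.shape[0]

    @property
    def off_diagonal(self) -> np.ndarray:
        O = self.W.copy()
        np.fill_diagonal(O, 0.0)
        return O


def _knn_adjacency(coords: np.ndarray, k: int) -> np.ndarray:
    tree = cKDTree(coords)
    # query k+1 because each point returns itself first; ties in distance are
    # resolved by the kd-tree's deterministic ordering
    _, idx = tree.query(coords, k=k + 1)
    n = coords.shape[0]
    A = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()
    A[rows, cols] = True
    np.fill_diagonal(A, False)
    return A | A.T  # union symmetrization


def _delaunay_adjacency(coords: np.ndarray) -> np.ndarray:
    tri = Delaunay(coords)
    n = coords.shape[0]
    A = np.zeros((n, n), dtype=bool)
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                A[simplex[a], simplex[b]] = True
                A[simplex[b], simplex[a]] = True
    return A


def build_spatial_weights(coords: np.ndarray, k_spatial: int = 6,
                          method: str = "knn") -> SpatialWeights:
    """Spatial weight matrix from a symmetrized k-NN (or Delaunay) graph.

    The off-diagonal adjacency is scaled to be symmetric with row sums of
    0.5: a symmetric Sinkhorn scaling is used, which on well-connected
    graphs makes the off-diagonal block exactly doubly stochastic; for
    graphs where no such scaling exists (e.g. chains) the weights fall back
    to ``0.5 / max(deg_i, deg_j)``, which keeps exact symmetry at the cost
    of smaller row sums at irregular nodes. Diagonal entries are 0.5.
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    if method == "knn":
        if k_spatial >= n:
            raise ValueError(f"k_spatial={k_spatial} must be < n_cells={n}")
        A = _knn_adjacency(coords, k_spatial)
    elif method == "delaunay":
        A = _delaunay_adjacency(coords)
    else:
        raise ValueError("method must be 'knn' or 'delaunay'")

    Af = A.astype(np.float64)
    deg = Af.sum(axis=1)
    if np.any(deg == 0):
        raise ValueError("isolated cells in the spatial graph")

    # symmetric Sinkhorn: find diagonal d with (d A d) having row sums 0.5
    d = np.sqrt(0.5 / deg)
    converged = False
    for _ in range(2000):
        r = d * (Af @ d)
        if np.max(np.abs(r - 0.5)) < 1e-12:
            converged = True
            break
        d = d * np.sqrt(0.5 / r)
    if converged:
        W = Af * np.outer(d, d)
    else:
        warnings.warn("doubly stochastic scaling infeasible; using "
                      "max-degree normalization", stacklevel=2)
        W = Af * (0.5 / np.maximum.outer(deg, deg))
    W = (W + W.T) / 2.0  # exact symmetry against round-off
    np.fill_diagonal(W, 0.5)
    return SpatialWeights(W, k_spatial)


# ---------------------------------------------------------------------------
# spatial statistics
# ---------------------------------------------------------------------------

def morans_i(x: np.ndarray, W: SpatialWeights,
             p_method: str = "normal", n_perm: int = 999,
             seed: int = 0) -> tuple[float, float]:
    """Moran's I spatial autocorrelation and a one-sided p-value.

    Computed on the off-diagonal part of the weight matrix. The p-value for
    positive autocorrelation comes from the normal approximation under the
    randomization assumption, or from a seeded permutation test
    (``p_method="permutation"``).
    """
    x = np.asarray(x, dtype=np.float64)
    if np.all(x == x[0]):
        raise ValueError("Moran's I is undefined for constant input")
    O = W.off_diagonal
    n = len(x)
    z = x - x.mean()
    s0 = O.sum()
    denom = float(z @ z)
    I = float(n / s0 * (z @ O @ z) / denom)

    if p_method == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            zp = rng.permutation(z)
            Ip = n / s0 * (zp @ O @ zp) / denom
            if Ip >= I:
                count += 1
        return I, (count + 1) / (n_perm + 1)

    # randomization-variance normal approximation
    EI = -1.0 / (n - 1)
    s1 = 0.5 * ((O + O.T) ** 2).sum()
    s2 = ((O.sum(axis=0) + O.sum(axis=1)) ** 2).sum()
    b2 = n * (z ** 4).sum() / denom ** 2
    num = n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 ** 2) \
        - b2 * ((n * n - n) * s1 - 2 * n * s2 + 6 * s0 ** 2)
    var = num / ((n - 1) * (n - 2) * (n - 3) * s0 ** 2) - EI ** 2
    if var <= 0:
        return I, 1.0
    p = float(stats.norm.sf((I - EI) / np.sqrt(var)))
    return I, p


def filter_spatial_genes(expr: ExpressionMatrix, W: SpatialWeights,
                         alpha: float = 0.05, min_frac: float = 0.05
                         ) -> list[str]:
    """Spatially variable genes: BH-adjusted Moran's p < alpha, and expressed
    (> 0) in at least ``min_frac`` of the cells. Constant genes are dropped."""
    frac = (expr.values > 0).mean(axis=0)
    candidates = [
        j for j in range(expr.n_genes)
        if frac[j] >= min_frac and expr.values[:, j].std() > 0
    ]
    if not candidates:
        return []
    pvals = np.array([morans_i(expr.values[:, j], W)[1] for j in candidates])
    adj = stats.false_discovery_control(pvals, method="bh")
    return [str(expr.gene_ids[j]) for j, a in zip(candidates, adj) if a < alpha]


def sci(x: np.ndarray, y: np.ndarray, W: SpatialWeights) -> float:
    """Spatial cross-correlation index between two per-cell value vectors.

    Uses the full weight matrix *including* the 0.5 self-loops, so genes
    co-expressed in the same cells are rewarded beyond neighborhood
    agreement. Symmetric in its arguments and translation invariant.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("SCI is undefined for constant input")
    n = len(x)
    zx = x - x.mean()
    zy = y - y.mean()
    s0 = W.W.sum()
    return float(n / s0 * (zx @ W.W @ zy)
                 / (np.linalg.norm(zx) * np.linalg.norm(zy)))


def sci_matrix(X: np.ndarray, W: SpatialWeights,
               Y: np.ndarray | None = None) -> np.ndarray:
    """All-pairs SCI between columns of X (and Y; default Y = X)."""
    X = np.asarray(X, dtype=np.float64)
    ZX = X - X.mean(axis=0)
    nx = np.linalg.norm(ZX, axis=0)
    if np.any(nx == 0):
        raise ValueError("SCI is undefined for constant input")
    if Y is None:
        ZY, ny = ZX, nx
    else:
        ZY = np.asarray(Y, dtype=np.float64) - np.asarray(Y).mean(axis=0)
        ny = np.linalg.norm(ZY, axis=0)
        if np.any(ny == 0):
            raise ValueError("SCI is undefined for constant input")
    n = X.shape[0]
    s0 = W.W.sum()
    M = n / s0 * (ZX.T @ W.W @ ZY)
    return M / np.outer(nx, ny)


# ---------------------------------------------------------------------------
# gene network and clustering
# ---------------------------------------------------------------------------

@dataclass
class Pattern:
    """A gene cluster with its per-cell mean-expression profile."""

    id: int
    member_genes: list[str]
    profile: np.ndarray
    kind: str = "known"  # "known" | "novel"

    def __post_init__(self) -> None:
        if not self.member_genes:
            raise ValueError("a pattern must have at least one member gene")


@dataclass
class LikelihoodClassification:
    scores: np.ndarray
    gene_ids: list[str]
    s_split: float
    groups: np.ndarray  # per-gene label in {known-associated, weak, novel-candidate}


def gene_network(S: np.ndarray, percentile: float = 10.0) -> np.ndarray:
    """Threshold a symmetric gene-gene similarity matrix into a weighted graph.

    Only the strongest ``percentile`` percent of off-diagonal values keep
    their weight (the threshold sits at the (100 - percentile)th percentile
    of the off-diagonal entries, inclusive, so a degenerate all-equal matrix
    keeps every edge); everything else — and the diagonal — is zeroed. A
    sparse network is essential here: community detection on a near-complete
    weighted graph cannot separate small gene programs from the sea of weak
    background similarities. Edges must carry positive similarity, so
    non-positive retained values are dropped too.
    """
    S = np.asarray(S, dtype=np.float64)
    if not 0 < percentile <= 100:
        raise ValueError("percentile must lie in (0, 100]")
    if S.shape[0] != S.shape[1] or not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("SCI matrix must be symmetric")
    G = (S + S.T) / 2.0
    off = G[~np.eye(G.shape[0], dtype=bool)]
    thresh = np.percentile(off, 100.0 - percentile)
    G = np.where((G >= thresh) & (G > 0), G, 0.0)
    np.fill_diagonal(G, 0.0)
    return G


def _louvain_membership(network: np.ndarray, resolution: float,
                        seed: int) -> np.ndarray:
    import igraph as ig

    n = network.shape[0]
    src, dst = np.nonzero(np.triu(network, k=1))
    g = ig.Graph(n=n, edges=list(zip(src.tolist(), dst.tolist())))
    weights = network[src, dst].tolist()
    state = random.Random(seed)
    ig.set_random_number_generator(state)
    try:
        if g.ecount():
            part = g.community_multilevel(weights=weights,
                                          resolution=resolution)
        else:
            part = g.community_multilevel(resolution=resolution)
    finally:
        ig.set_random_number_generator(random)
    return np.asarray(part.membership)


def cluster_genes(network: np.ndarray, expr: ExpressionMatrix,
                  gene_ids: list[str], resolution: float = 1.0,
                  seed: int = 0, kind: str = "known") -> list[Pattern]:
    """Louvain communities of the gene network, as patterns with mean profiles.

    ``expr`` supplies the per-cell expression of ``gene_ids`` (the network's
    node order) from which each pattern's profile (column mean over member
    genes) is computed. Seeded for reproducibility.
    """
    if network.shape[0] != len(gene_ids):
        raise ValueError("network size must match gene_ids")
    membership = _louvain_membership(network, resolution, seed)
    cols = expr.gene_index(gene_ids)
    patterns = []
    for pid in sorted(set(membership.tolist())):
        members = [gene_ids[i] for i in np.flatnonzero(membership == pid)]
        idx = cols[membership == pid]
        profile = expr.values[:, idx].mean(axis=1)
        patterns.append(Pattern(len(patterns), members, profile, kind=kind))
    return patterns


def filter_singleton_patterns(patterns: list[Pattern],
                              enabled: bool = True) -> list[Pattern]:
    """Drop single-gene patterns (used for the larger measured panels)."""
    if not enabled:
        return patterns
    kept = [p for p in patterns if len(p.member_genes) >= 2]
    if not kept:
        warnings.warn("all patterns were singletons; none retained",
                      stacklevel=2)
    return [Pattern(i, p.member_genes, p.profile, p.kind)
            for i, p in enumerate(kept)]


# ---------------------------------------------------------------------------
# novel-pattern discovery
# ---------------------------------------------------------------------------

def likelihood_scores(pred_expr: ExpressionMatrix, known: list[Pattern],
                      W: SpatialWeights) -> np.ndarray:
    """Per-gene likelihood: the maximum SCI against any known profile."""
    if not known:
        raise ValueError("at least one known pattern is required")
    profiles = np.column_stack([p.profile for p in known])
    S = sci_matrix(pred_expr.values, W, profiles)  # genes x patterns
    return S.max(axis=1)


def detect_multimodality(scores: np.ndarray, n_boot: int = 500,
                         seed: int = 0) -> tuple[float, float]:
    """Hartigan's dip statistic and bootstrap p-value for the score
    distribution; p < 0.05 is evidence of novel patterns."""
    scores = np.asarray(scores, dtype=np.float64)
    if len(scores) < 10:
        raise ValueError("need at least 10 likelihood scores")
    return dip_test(scores, n_boot=n_boot, seed=seed)


def classify_by_likelihood(scores: np.ndarray, gene_ids: list[str],
                           band: float = 0.05) -> LikelihoodClassification:
    """Split genes at the density valley between the two main score modes.

    A Gaussian KDE (Silverman bandwidth, 512-point grid padded by three
    bandwidths) is fit to the scores; the two tallest local maxima are
    located and ``s`` is the score at the density minimum between them.
    Genes with score > s + band are known-associated, < s - band are
    novel candidates, the rest are weak.
    """
    scores = np.asarray(scores, dtype=np.float64)
    kde = stats.gaussian_kde(scores, bw_method="silverman")
    bw = kde.factor * scores.std(ddof=1)
    grid = np.linspace(scores.min() - 3 * bw, scores.max() + 3 * bw, 512)
    dens = kde(grid)
    interior = np.flatnonzero(
        (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])) + 1
    if len(interior) < 2:
        raise ValueError(
            "fewer than two density peaks; treat as no novel patterns")
    top2 = sorted(interior[np.argsort(dens[interior])][-2:])
    valley = top2[0] + int(np.argmin(dens[top2[0]:top2[1] + 1]))
    s = float(grid[valley])
    groups = np.where(scores > s + band, "known-associated",
                      np.where(scores < s - band, "novel-candidate", "weak"))
    return LikelihoodClassification(scores, list(gene_ids), s, groups)


def assign_to_known(genes: list[str], pred_expr: ExpressionMatrix,
                    known: list[Pattern], W: SpatialWeights
                    ) -> dict[str, int]:
    """Map each known-associated gene to the pattern maximizing its SCI
    (ties broken toward the lowest pattern id)."""
    if not genes:
        return {}
    sub = pred_expr.subset_genes(genes)
    profiles = np.column_stack([p.profile for p in known])
    S = sci_matrix(sub.values, W, profiles)
    return {g: int(np.argmax(S[i])) for i, g in enumerate(genes)}


def _prune_low_degree(network: np.ndarray, members: np.ndarray,
                      min_degree: int) -> np.ndarray:
    """Iteratively drop member genes with fewer than ``min_degree`` retained
    network connections to other members; a fixed point of itself."""
    members = np.asarray(members)
    while True:
        sub = network[np.ix_(members, members)]
        deg = (sub > 0).sum(axis=1)
        keep = deg >= min_degree
        if keep.all() or not keep.any():
            return members[keep]
        members = members[keep]


def discover_novel_patterns(candidates: ExpressionMatrix, W: SpatialWeights,
                            resolution: float = 0.6, seed: int = 0,
                            percentile: float = 10.0, min_degree: int = 10,
                            drop_frac: float = 0.10) -> list[Pattern]:
    """Cluster novel-candidate genes into novel spatial patterns.

    Steps: (1) drop the lowest-decile genes by mean expression, then by
    variability (dispersion statistic); (2) build the SCI network and run
    Louvain at a lower resolution; (3) keep clusters whose mean
    within-cluster SCI exceeds the mean of all pairwise SCI scores by three
    standard deviations; (4) inside kept clusters, iteratively remove genes
    with fewer than ``min_degree`` retained-network connections. An empty
    result is a valid outcome.
    """
    if candidates.n_genes < 20:
        warnings.warn("fewer than 20 novel-candidate genes; skipping "
                      "novel-pattern discovery", stacklevel=2)
        return []
    means = candidates.values.mean(axis=0)
    keep = means >= np.quantile(means, drop_frac)
    kept = candidates.subset_genes([str(g) for g, k
                                    in zip(candidates.gene_ids, keep) if k])
    disp = hvg_ranking(kept)  # descending dispersion
    cutoff = int(np.ceil(len(disp) * (1 - drop_frac)))
    kept = kept.subset_genes(sorted(disp.index[:cutoff]))

    S = sci_matrix(kept.values, W)
    net = gene_network(S, percentile)
    patterns = cluster_genes(net, kept, [str(g) for g in kept.gene_ids],
                             resolution=resolution, seed=seed, kind="novel")

    off = S[~np.eye(S.shape[0], dtype=bool)]
    threshold = off.mean() + 3 * off.std()
    gene_pos = {str(g): i for i, g in enumerate(kept.gene_ids)}
    novel: list[Pattern] = []
    for p in patterns:
        idx = np.array([gene_pos[g] for g in p.member_genes])
        if len(idx) < 2:
            continue
        pair = S[np.ix_(idx, idx)]
        z = pair[~np.eye(len(idx), dtype=bool)].mean()
        if z <= threshold:
            continue
        survivors = _prune_low_degree(net, idx, min_degree)
        if len(survivors) == 0:
            continue
        members = [str(kept.gene_ids[i]) for i in survivors]
        profile = kept.values[:, survivors].mean(axis=1)
        novel.append(Pattern(len(novel), members, profile, kind="novel"))
    return novel


def representative_genes(pattern: Pattern, expr: ExpressionMatrix,
                         W: SpatialWeights, top_n: int = 3) -> list[str]:
    """The member genes with the highest SCI to the pattern's own profile."""
    sub = expr.subset_genes(pattern.member_genes)
    S = sci_matrix(sub.values, W, pattern.profile[:, None])[:, 0]
    order = np.argsort(-S, kind="stable")[:top_n]
    return [pattern.member_genes[i] for i in order]


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------

def find_known_patterns(expr: ExpressionMatrix, W: SpatialWeights,
                        alpha: float = 0.05, min_frac: float = 0.05,
                        percentile: float = 10.0, resolution: float = 1.0,
                        seed: int = 0, drop_singletons: bool = True
                        ) -> list[Pattern]:
    """Known spatial patterns from measured gene expression."""
    genes = filter_spatial_genes(expr, W, alpha=alpha, min_frac=min_frac)
    if not genes:
        return []
    sub = expr.subset_genes(genes)
    S = sci_matrix(sub.values, W)
    net = gene_network(S, percentile)
    patterns = cluster_genes(net, sub, genes, resolution=resolution,
                             seed=seed, kind="known")
    return filter_singleton_patterns(patterns, enabled=drop_singletons)


def run_pattern_discovery(measured: ExpressionMatrix,
                          predicted: ExpressionMatrix,
                          coords: np.ndarray,
                          k_spatial: int = 6,
                          alpha: float = 0.05, min_frac: float = 0.05,
                          percentile: float = 10.0,
                          resolution_known: float = 1.0,
                          resolution_novel: float = 0.6,
                          seed: int = 0,
                          drop_singletons: bool = True) -> dict:
    """Full known -> likelihood -> novel pipeline.

    Returns a dict with the spatial weights, known patterns, the filtered
    predicted genes with their likelihood scores, the dip-test result, the
    three-way classification (None when the scores are unimodal) and the
    novel patterns (empty when none survive).
    """
    W = build_spatial_weights(coords, k_spatial=k_spatial)
    known = find_known_patterns(measured, W, alpha=alpha, min_frac=min_frac,
                                percentile=percentile,
                                resolution=resolution_known, seed=seed,
                                drop_singletons=drop_singletons)
    out = {"weights": W, "known": known, "novel": [],
           "classification": None, "dip": None, "scored_genes": []}
    if not known:
        return out
    spatial_pred = filter_spatial_genes(predicted, W, alpha=alpha,
                                        min_frac=min_frac)
    if len(spatial_pred) < 10:
        return out
    pred_sub = predicted.subset_genes(spatial_pred)
    scores = likelihood_scores(pred_sub, known, W)
    dip, p = detect_multimodality(scores, seed=seed)
    out["scored_genes"] = spatial_pred
    out["scores"] = scores
    out["dip"] = (dip, p)
    if p >= 0.05:
        return out
    try:
        cls = classify_by_likelihood(scores, spatial_pred)
    except ValueError:
        return out
    out["classification"] = cls
    assigned = assign_to_known(
        [g for g, lab in zip(spatial_pred, cls.groups)
         if lab == "known-associated"], pred_sub, known, W)
    out["known_assignments"] = assigned
    novel_genes = [g for g, lab in zip(spatial_pred, cls.groups)
                   if lab == "novel-candidate"]
    if len(novel_genes) >= 20:
        out["novel"] = discover_novel_patterns(
            pred_sub.subset_genes(novel_genes), W,
            resolution=resolution_novel, seed=seed, percentile=percentile)
    return out
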