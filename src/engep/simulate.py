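"""Seeded generators for synthetic spatial queries and scRNA-seq references.

The generator emulates the setting the imputation method targets: a spatial
dataset measuring a limited gene panel over cells with 2-D coordinates, and
several references that profile the same tissue genome-wide but differ in
quality (noise, dropout, multiplicative batch factors).

Cells sit on a jittered square grid. Spatial programs come in two flavours:
*layered* programs are smooth Gaussian bands of the y-coordinate (emulating
cortical lamination) and *scattered* programs are sums of randomly placed
radial hotspots. Each patterned gene is its program's profile scaled by a
gene-specific amplitude plus Gaussian noise, floored at zero;
spatially-unstructured genes are permuted copies of profiles (variance
without spatial coherence). Known programs populate both the measured panel
and the unmeasured pool; novel programs appear only among unmeasured genes.

Values are generated directly on the log-normalized scale consumed by the
pipeline; ``to_counts`` provides an inverse transform for I/O round-trip
tests. All outputs are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_model import ExpressionMatrix, SpatialQuery

__all__ = ["SimSpec", "GroundTruth", "generate_spatial_truth",
           "generate_references", "simulate_dataset", "to_counts"]


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one synthetic dataset.

    ``ref_quality`` multiplies both the noise SD and the dropout rate of each
    reference (0 = pristine copy of the truth); ``None`` grades the
    references from 0.5x to 2x. ``batch_scale`` is the SD of the per-gene
    log-normal batch factors applied to each reference.
    """

    n_cells: int = 1000
    n_genes_measured: int = 60
    n_genes_unmeasured: int = 150
    n_patterns_known: int = 4
    n_patterns_novel: int = 2
    layout: str = "mixed"  # "layered" | "scattered" | "mixed"
    noise_sd: float = 0.3
    query_noise_sd: float | None = 0.1
    dropout_rate: float = 0.2
    n_refs: int = 3
    ref_quality: tuple[float, ...] | None = None
    batch_scale: float = 0.2
    n_ref_cells: int | None = None
    genes_per_novel: int = 30
    measured_pattern_frac: float = 0.8
    known_unmeasured_frac: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cells", "n_genes_measured", "n_genes_unmeasured",
                     "n_refs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_patterns_known < 1:
            raise ValueError("need at least one known pattern")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must lie in [0, 1]")
        if self.noise_sd < 0 or self.batch_scale < 0:
            raise ValueError("noise_sd and batch_scale must be >= 0")
        if self.query_noise_sd is not None and self.query_noise_sd < 0:
            raise ValueError("query_noise_sd must be >= 0")
        if self.layout not in ("layered", "scattered", "mixed"):
            raise ValueError("layout must be layered, scattered or mixed")
        if self.ref_quality is not None and len(self.ref_quality) != self.n_refs:
            raise ValueError("one ref_quality entry per reference")

    @property
    def quality(self) -> tuple[float, ...]:
        if self.ref_quality is not None:
            return tuple(self.ref_quality)
        if self.n_refs == 1:
            return (1.0,)
        return tuple(np.linspace(0.5, 2.0, self.n_refs))


@dataclass
class GroundTruth:
    pattern_of_gene: dict[str, str | None]
    true_expr: ExpressionMatrix   # cells x (measured + unmeasured), noiseless
    coords: np.ndarray
    measured_genes: list[str]
    unmeasured_genes: list[str]
    profiles: dict[str, np.ndarray]
    ref_quality_rank: list[int] = field(default_factory=list)


def _layered_profile(y: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-((y - center) ** 2) / (2 * width ** 2))


def _scattered_profile(coords: np.ndarray, rng: np.random.Generator,
                       extent: float, radius_frac: float = 0.12,
                       max_spots: int = 4) -> np.ndarray:
    n_spots = rng.integers(2, max_spots + 1) if max_spots > 1 else 1
    centers = rng.uniform(0, extent, size=(n_spots, 2))
    radius = radius_frac * extent
    d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    prof = np.exp(-d2 / (2 * radius ** 2)).sum(axis=1)
    return prof / prof.max()


def _make_profiles(coords: np.ndarray, spec: SimSpec,
                   rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Distinct spatial programs; pairwise profile correlation kept < 0.5."""
    extent = coords.max()
    total = spec.n_patterns_known + spec.n_patterns_novel
    if spec.layout == "layered":
        kinds = ["layered"] * total
    elif spec.layout == "scattered":
        kinds = ["scattered"] * total
    else:
        kinds = ["layered" if i % 2 == 0 else "scattered" for i in range(total)]
    n_layered = kinds.count("layered")
    centers = iter(np.linspace(0.1, 0.9, max(n_layered, 1)) * extent)
    width = extent / (2.5 * max(n_layered, 1))

    profiles: dict[str, np.ndarray] = {}
    names = [f"known{i}" for i in range(spec.n_patterns_known)] + \
            [f"novel{i}" for i in range(spec.n_patterns_novel)]
    for name, kind in zip(names, kinds):
        for _ in range(50):
            if kind == "layered":
                prof = _layered_profile(coords[:, 1], next(centers), width)
                kind = "scattered"  # retries fall back to scattered placement
            else:
                prof = _scattered_profile(coords, rng, extent)
            ok = all(abs(np.corrcoef(prof, q)[0, 1]) < 0.5
                     for q in profiles.values())
            if ok:
                profiles[name] = prof
                break
        else:
            raise RuntimeError(f"could not draw a distinct profile for {name}")
    return profiles


def _gene_block(profile: np.ndarray, n_genes: int, noise_sd: float,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    amp = rng.uniform(1.0, 3.0, size=n_genes)
    clean = profile[:, None] * amp[None, :]
    noisy = np.maximum(clean + rng.normal(0, noise_sd, clean.shape), 0.0)
    return clean, noisy


def generate_spatial_truth(spec: SimSpec) -> tuple[SpatialQuery, GroundTruth]:
    """The spatial query (noisy measured panel + coordinates) and the full
    noiseless ground truth over measured and unmeasured genes."""
    rng = np.random.default_rng([spec.seed, 0])
    side = int(np.ceil(np.sqrt(spec.n_cells)))
    gx, gy = np.meshgrid(np.arange(side), np.arange(side))
    coords = np.column_stack([gx.ravel(), gy.ravel()]).astype(np.float64)
    coords = coords[:spec.n_cells] + rng.uniform(-0.3, 0.3,
                                                 (spec.n_cells, 2))
    profiles = _make_profiles(coords, spec, rng)
    known_names = [f"known{i}" for i in range(spec.n_patterns_known)]
    novel_names = [f"novel{i}" for i in range(spec.n_patterns_novel)]

    # measured panel: known-program genes plus spatially shuffled noise genes
    n_meas_pat = int(round(spec.measured_pattern_frac * spec.n_genes_measured))
    per_pat = np.array_split(np.arange(n_meas_pat), spec.n_patterns_known)

    gene_ids: list[str] = []
    pattern_of: dict[str, str | None] = {}
    clean_cols: list[np.ndarray] = []
    noisy_cols: list[np.ndarray] = []

    q_sd = spec.noise_sd if spec.query_noise_sd is None else spec.query_noise_sd

    def add_block(name: str | None, profile: np.ndarray, count: int,
                  prefix: str) -> None:
        clean, noisy = _gene_block(profile, count, q_sd, rng)
        for j in range(count):
            gid = f"{prefix}{len(gene_ids):04d}"
            gene_ids.append(gid)
            pattern_of[gid] = name
        clean_cols.append(clean)
        noisy_cols.append(noisy)

    for name, idx in zip(known_names, per_pat):
        add_block(name, profiles[name], len(idx), "gM")
    n_noise_meas = spec.n_genes_measured - n_meas_pat
    for _ in range(n_noise_meas):
        base = profiles[rng.choice(known_names)]
        add_block(None, rng.permutation(base), 1, "gM")
    measured_genes = list(gene_ids)

    # unmeasured pool: novel programs, more known-program genes, noise genes
    n_novel_genes = spec.genes_per_novel * spec.n_patterns_novel
    n_known_unmeas = min(
        int(max(spec.n_genes_unmeasured - n_novel_genes, 0)
            * spec.known_unmeasured_frac),
        spec.n_genes_unmeasured)
    for name in novel_names:
        add_block(name, profiles[name], spec.genes_per_novel, "gU")
    per_pat_u = np.array_split(np.arange(n_known_unmeas),
                               spec.n_patterns_known)
    for name, idx in zip(known_names, per_pat_u):
        add_block(name, profiles[name], len(idx), "gU")
    # background: half spatially shuffled noise (caught by the Moran filter),
    # half genes with private small hotspots placed outside program territory
    # — spatially variable but uncorrelated with every program
    n_noise_unmeas = (spec.n_genes_unmeasured - n_novel_genes
                      - n_known_unmeas)
    extent = coords.max()
    prog_max = np.max(np.column_stack(list(profiles.values())), axis=1)
    quiet = np.flatnonzero(prog_max < 0.3)
    if quiet.size < 10:  # degenerate geometry: fall back to anywhere
        quiet = np.arange(spec.n_cells)
    radius = 0.045 * extent
    for i in range(max(n_noise_unmeas, 0)):
        if i % 2 == 0:
            centers = coords[rng.choice(quiet, size=1)]
            d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            base = np.exp(-d2 / (2 * radius ** 2)).sum(axis=1)
            add_block(None, base / base.max(), 1, "gU")
        else:
            base = profiles[rng.choice(known_names + novel_names)]
            add_block(None, rng.permutation(base), 1, "gU")
    unmeasured_genes = [g for g in gene_ids if g not in set(measured_genes)]

    clean = np.hstack(clean_cols)
    noisy = np.hstack(noisy_cols)
    cells = np.array([f"cell{i:05d}" for i in range(spec.n_cells)],
                     dtype=object)
    true_expr = ExpressionMatrix(clean, cells,
                                 np.asarray(gene_ids, dtype=object),
                                 normalized=True)
    query_expr = ExpressionMatrix(noisy[:, :len(measured_genes)], cells,
                                  np.asarray(measured_genes, dtype=object),
                                  normalized=True)
    truth = GroundTruth(pattern_of, true_expr, coords, measured_genes,
                        unmeasured_genes, profiles)
    return SpatialQuery(query_expr, coords), truth


def generate_references(truth: GroundTruth, spec: SimSpec,
                        gene_subsets: Sequence[Sequence[str]] | None = None
                        ) -> list[ExpressionMatrix]:
    """References of graded quality drawn from the ground-truth manifold.

    All references share one resampling of the truth cells; what
    distinguishes them is the injected corruption — per-gene multiplicative
    batch factors, Gaussian noise scaled by ``ref_quality`` and Bernoulli
    dropout scaled likewise — so equal-quality references are identical and
    cleaner references are strictly more faithful. ``gene_subsets``
    optionally restricts each reference's gene panel (partial coverage).
    """
    rng = np.random.default_rng([spec.seed, 1])
    n = spec.n_ref_cells or truth.true_expr.n_cells
    idx = rng.integers(0, truth.true_expr.n_cells, size=n)
    base = truth.true_expr.values[idx]
    quality = spec.quality
    refs = []
    for r in range(spec.n_refs):
        rng_r = np.random.default_rng([spec.seed, 2, r])
        vals = base.copy()
        if spec.batch_scale > 0:
            factors = rng_r.lognormal(0.0, spec.batch_scale,
                                      truth.true_expr.n_genes)
            vals = vals * factors[None, :]
        if spec.noise_sd * quality[r] > 0:
            vals = vals + rng_r.normal(0, spec.noise_sd * quality[r],
                                       vals.shape)
        vals = np.maximum(vals, 0.0)
        drop = min(spec.dropout_rate * quality[r], 0.95)
        if drop > 0:
            vals = vals * (rng_r.uniform(size=vals.shape) >= drop)
        gene_ids = truth.true_expr.gene_ids
        m = ExpressionMatrix(
            vals, np.array([f"ref{r}_c{i:05d}" for i in range(n)],
                           dtype=object),
            gene_ids, normalized=True)
        if gene_subsets is not None:
            m = m.subset_genes(sorted(gene_subsets[r]))
        refs.append(m)
    truth.ref_quality_rank = list(np.argsort(quality))
    return refs


def simulate_dataset(spec: SimSpec) -> tuple[SpatialQuery,
                                             list[ExpressionMatrix],
                                             GroundTruth]:
    """Convenience wrapper: spatial query, references and ground truth."""
    query, truth = generate_spatial_truth(spec)
    refs = generate_references(truth, spec)
    return query, refs, truth


def to_counts(m: ExpressionMatrix, scale: float = 1e4,
              depth: float = 2000.0, seed: int = 0) -> ExpressionMatrix:
    """Invert the log transform into Poisson pseudo-counts (for I/O tests)."""
    rng = np.random.default_rng(seed)
    rel = np.expm1(m.values) / scale
    rel = rel / np.maximum(rel.sum(axis=1, keepdims=True), 1e-12)
    counts = rng.poisson(rel * depth).astype(np.float64)
    counts[counts.sum(axis=1) == 0, 0] = 1.0  # keep every cell non-empty
    return ExpressionMatrix(counts, m.cell_ids, m.gene_ids, normalized=False)
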