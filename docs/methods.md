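# Methods

## Model and assumptions

The imputation model is non-parametric: a query cell's unmeasured expression
is a convex combination of reference cells' expression, with weights given
by expression similarity over the shared gene panel. The implicit
assumptions are (i) the references profile the same or a closely related
cell population, so every query cell has meaningful neighbors; (ii)
similarity on the shared panel is informative about the rest of the
transcriptome; and (iii) reference quality varies, which is why no single
reference, similarity measure or neighborhood size is trusted — the method
averages over all of them and only weights at the *sub-reference* level,
where predictive power can actually be estimated from the measured genes.

Batch effects between query and references are deliberately not corrected;
heterogeneous quality is handled by the ensemble weights instead.

### Predictive-power scoring

`s_r = cor²(Ŷ^(1,r), Y^(1))` is computed on the **flattened** matrices
(all cell×gene entries pooled). This is the literal reading of a matrix
correlation; it makes s_r sensitive to between-gene amplitude structure as
well as within-gene spatial structure. A consequence worth knowing: when
the query itself is very noisy, heavily smoothed predictions (from badly
corrupted references) can correlate with the noisy observations almost as
well as sharp predictions do, compressing the separation between
references. With a reasonably reliable query — the regime imaging-based
assays are in — s_r ranks references by their true fidelity.

### Weight map

`map_weights` min–max rescales the observed s_r onto [0.1, 0.9], so the
best and worst sub-references always receive the endpoint weights, matching
the stated range being attained. An all-equal vector (including the
single-sub-reference case) maps to the midpoint 0.5. A fixed affine map of
the absolute scale [0, 1] onto [0.1, 0.9] is available via
`weight_map="fixed"` for users who prefer weights that are comparable
across runs.

### Numerical details, k-NN step

* Neighbor ties are broken by ascending reference index (stable sort of the
  negated similarities). Mathematically tied similarities carry equal
  weights, so any resolution yields an equally valid prediction; the tests'
  brute-force oracle accepts all of them.
* Negative similarities of signed measures are clamped to zero *after*
  neighbor selection. If a cell's whole neighborhood clamps to zero, the
  prediction falls back to the unweighted mean of the k neighbors rather
  than 0/0.
* Zero-variance (or zero-norm) vectors get similarity 0 under every
  correlation-like measure, so degenerate cells never become preferred
  neighbors. Cells whose shared-panel expression is numerically constant
  are therefore predicted from an arbitrary neighborhood — such cells are
  intrinsically uninformative and should be filtered upstream.
* One similarity matrix and one sort are shared across all k values of a
  (sub-reference, measure) pair; results are bitwise independent of the
  evaluation order.
* k values larger than a sub-reference are clipped to its size with a
  warning.
* The weighted rank correlation uses per-gene weights
  `w = rank_asc(x) + rank_asc(y)` (equivalently `(g − r + 1)` on descending
  ranks), emphasizing highly expressed genes; ties get average ranks. The
  Jaccard operand is the strictly-positive support, and two empty supports
  score 0. ρ_p and φ_s are computed directly on the log-scale vectors:
  ρ_p = 2 cov(x,y)/(var x + var y), φ_s = var(x−y)/var(x+y) (a distance,
  mapped through 1/(1+d)).
* Partial gene coverage: a target gene absent from some reference simply
  contributes nothing from that reference, and the ensemble renormalizes
  over the ω of the references that do carry it.

## Spatial weights and SCI

The cell graph is a union-symmetrized k-nearest-neighbor graph
(`k_spatial = 6` by default; Delaunay triangulation available). The
off-diagonal adjacency is scaled so that it is symmetric with row sums 0.5
and the diagonal is 0.5. Exact double stochasticity and exact symmetry
cannot coexist on degree-irregular graphs (a 3-cell chain is a
counterexample), so a symmetric Sinkhorn scaling is used — it converges on
the well-connected graphs spatial data produce and then satisfies both
properties to machine precision — with a `0.5/max(deg_i, deg_j)`
normalization as the fallback for infeasible graphs (exact symmetry, row
sums ≤ 0.5 at irregular nodes).

The SCI between two per-cell vectors is the spatially smoothed
cross-correlation `(n/ΣW) · z_xᵀ W z_y / (‖z_x‖‖z_y‖)` over the **full** W
including the self-loops: co-expression in the same cell is rewarded, not
just co-expression among neighbors. Moran's I uses only the off-diagonal
part, with the one-sided normal approximation under randomization
(permutation p-values available for small n) and BH adjustment across
genes.

## Gene network and clustering

The SCI matrix is thresholded to keep only the **top decile** of
off-diagonal values (inclusive, so a degenerate all-equal matrix keeps all
edges; non-positive values never become edges). A sparse network is
essential: on a near-complete weighted graph, modularity optimization
absorbs every weakly connected background gene into the large communities,
diluting them beyond recognition — and the method's own choice of a *lower*
resolution for the novel-gene step only makes sense if the untouched
network tends to fragment into many small clusters. Louvain community
detection (python-igraph's multilevel algorithm, seeded) runs at resolution
1.0 for measured genes and 0.6 for novel candidates. Patterns of a single
gene are dropped for larger panels (flag `drop_singletons`).

## Novel-pattern discovery

Likelihood scores (max SCI against known profiles) are tested for
multimodality with Hartigan's dip statistic, implemented in-package via the
classical GCM/LCM iteration and validated against hand-derivable anchors
(equally spaced samples attain the minimum 1/(2n); half/half two-atom
samples attain 0.25). P-values come from a seeded parametric bootstrap from
the uniform distribution, the least-favorable unimodal null; the null table
is cached per sample size. Note the dip is affine-invariant but **not**
invariant under general monotone transforms — unimodality is a property of
the values, not the ranks.

If the dip p-value is below 0.05, a Gaussian KDE (Silverman bandwidth,
512-point grid padded by three bandwidths) locates the two tallest density
peaks; the score at the valley between them, s, splits genes into
known-associated (> s + 0.05), novel candidates (< s − 0.05) and a weak
band. Known-associated genes are appended to their best-matching pattern
(ties to the lowest pattern id); original profiles are retained for
scoring. Novel candidates are filtered (lowest decile by mean, then by
dispersion), clustered at resolution 0.6, and a cluster is kept only when
its mean within-cluster SCI exceeds the mean of **all** pairwise candidate
SCIs by three standard deviations — a global reference distribution, which
presumes genuine programs are a small minority of the candidates. Surviving
clusters are pruned by iteratively removing genes with fewer than ten
retained-network connections to other members (a fixed point of itself);
this is what eliminates small incidental co-expression cliques.
Representative genes of a pattern are the members with the highest SCI to
the pattern's own mean profile.

## Synthetic data

The generator emulates the study design, not any particular tissue:

* Cells on a jittered square grid; *layered* programs are Gaussian bands of
  the y-coordinate (cortical lamination), *scattered* programs are sums of
  2–4 radial hotspots (radius 12 % of the tissue extent).
* Program profiles are kept pairwise distinct (|correlation| < 0.5 by
  construction). Patterned genes are profile × amplitude (amplitude
  U(1, 3)) plus Gaussian noise, floored at zero. Values are generated
  directly on the log-normalized scale the pipeline consumes; `to_counts`
  inverts to Poisson pseudo-counts for I/O tests.
* The query carries its own noise level (`query_noise_sd`, default 0.1,
  lower than the reference default 0.3) — imaging-based assays are
  high-sensitivity, scRNA-seq references are where dropout and depth
  variation live. This asymmetry is what lets cor²-based predictive power
  discriminate reference quality (see the scoring note above).
* References share one resampling of the truth cells; corruption
  (per-gene log-normal batch factors, Gaussian noise × `ref_quality`,
  Bernoulli dropout × `ref_quality`) is what distinguishes them. Two
  references of equal quality and zero corruption are therefore identical,
  making the degenerate equal-weight case exact.
* Background (non-program) genes in the unmeasured pool are half spatially
  shuffled noise — removed by the Moran filter — and half genes with a
  private small hotspot (radius 4.5 %, placed outside program territory):
  spatially variable, but uncorrelated with every program and nearly
  uncorrelated with each other. The novel-discovery study conditions follow
  the planted-cluster design: one ~30-gene program among a few hundred
  background candidates, matching the global 3-SD rule's assumption that
  programs are rare.

What passing these tests shows — and does not show. The simulations
demonstrate the pipeline's internal correctness (exact composition
recovery, oracle equivalence, calibrated nulls) and its qualitative claims
(ensemble ≥ base, weights track quality, planted patterns recovered) under
controlled spatial structure and Gaussian corruption. They do not emulate
real count distributions, segmentation errors, cell-type composition shifts
between query and reference, or spatial domains with sharp boundaries;
quantitative accuracy on real tissue has to be established per dataset via
the cross-validation protocol.

## Problem sizes

Default test and acceptance runs use 150–2000 cells, 20–60 measured genes,
up to ~400 unmeasured genes, references of 300–800 cells and up to six
references of graded corruption — large enough for the asymptotic behaviors
(null means, dip calibration, weight separation) to express themselves,
small enough for the whole suite to run on a laptop in minutes. All
generators and algorithms are seeded; identical seeds give bit-identical
outputs.

## Known limitations

* The flattened-cor² predictive power conflates amplitude and spatial
  fidelity (see above); per-gene averaging is a possible alternative not
  explored here.
* The min–max weight map forces the endpoints onto the best/worst
  sub-reference even when their true quality gap is negligible; the
  `fixed` map avoids this at the cost of rarely reaching the endpoints.
* The dip-test bootstrap (500 draws by default) bounds attainable p-values
  at ~1/501.
* Louvain is seeded but not deterministic across igraph versions.
* The 3-SD cluster rule is conservative by design: when genuine novel
  programs make up a large fraction of the candidate genes, the global SD
  inflates and recall drops.
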