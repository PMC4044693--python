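# Methods

## Fingerprint model and conventions

All four comparison methods operate on 2D histograms of transformed channel
data. Channels are mapped to [0, 1] (linear or log10 with user-supplied
range; cytometers deliver log-amplified signals, so log10 is the usual
choice for real exports, and the synthetic generator emits transformed
values directly). Histogram conventions, fixed so results are bit-exact and
reproducible:

- bins are half-open `[k/R, (k+1)/R)` with the last bin closed; an event at
  exactly 1.0 falls in bin R−1;
- row index = DNA (y), column index = FSC (x), row 0 = lowest signal; image
  files are written with rows flipped for display only;
- supported resolutions R ∈ {64, 128, 256, 512, 1024}, default 128 (the
  resolution at which CHIC is customarily run);
- gray rendering is linear in count, `pixel = round(255·c/c_max)` with a
  floor of 1 for any non-zero count and round-half-up. The floor keeps rare
  populations *informative* (non-white); without it they would vanish from
  the N_i of the diversity indices;
- rows with non-finite values are dropped on load and counted, not raised:
  real list-mode exports contain saturated/invalid rows.

FCS reading/writing is a minimal in-package implementation of the 3.0/3.1
list-mode subset (integer/float parameters, either byte order); TSV event
files with channel headers are the interchange format for everything else.

## The four methods

**Dalmatian Plot.** Per-sample operator gates are rasterized by pixel-center
sampling (no anti-aliasing, so rasterization is exactly reproducible); a
pixel is black iff its center lies in ≥ 1 gate. Binary masks are compared
with the classical Jaccard distance on black-pixel sets; in gray mode each
blot carries `round(255·count/max_count)` (min 1) and masks are compared
with the Ruzicka / weighted Jaccard distance, which reduces to the binary
form when all intensities are equal. The literature's "modified" Jaccard
variant is not specified in detail anywhere we can implement from, so the
classical form is the default; the formula is isolated in
`dalmatian.jaccard_dissimilarity` for substitution.

**CHIC.** For a pair of gray images, the XOR image is the pixel-wise
absolute difference and the overlap image the pixel-wise maximum;
`P_sim = Σ XOR / #{overlap > 0}`. *Informative* means non-zero in at least
one image (union semantics), which keeps P_sim defined for disjoint
fingerprints and bounded by 255; intersection semantics are available via a
flag but are undefined on disjoint supports. P_sim is reported in raw
gray-level units as is customary; divide by 255 to compare across methods.

**CyBar.** Template gates may overlap; each gate counts independently and
relative abundances always use the sample's total event count as
denominator (how overlapping template gates should share cells is not
standardized anywhere; independent counting is the package's rule and is
recorded here). Barcode normalization is
`log2((a + ε) / gmean(a + ε))` per gate column with pseudo-abundance
ε = one cell in the largest sample by default — each column has log-mean 0,
constant gates map to zero, and per-gate rescaling cancels, which is the
stated purpose of the normalization (comparing high- and low-abundance
gates on one scale). The exact normalization of the published CyBar
protocol is not reproduced here; the formula is isolated in
`cybar.normalize_cybar`. Sample dissimilarity is Bray–Curtis on raw
relative abundances (standard for community abundance data). Gate–parameter
correlation is Spearman (abundances and performance parameters are not
assumed linearly related) with a two-sided permutation test.

**FlowFP.** The equal-count grid is fitted on *events*, not on the binned
histogram, because "equal number of cells" is an event-level statement.
At each node the pooled training events are split on the axis with larger
within-node variance (tie → x) at the midpoint between the two events
adjacent to the median; the lower child takes the extra event when the count
is odd; events exactly on a threshold go to the lower/left bin. These
tie-break rules follow the probability-binning literature and live behind
the model builder for substitution. Guarantees that hold by construction and
are enforced by tests: 2^r leaves partitioning [0, 1]² exactly, exact count
conservation on every sample, training leaf-count spread ≤ r, smaller bins
in denser regions. Sample dissimilarity is ½·L1 on bin fractions (the
method's own literature names no metric; this one is in [0, 1] and equals
total variation distance between the binned distributions).

## Diversity indices

`Rr = N_i / N_all` is support-only: intensities do not matter.
`So` is the mean absolute deviation of informative-pixel intensities from
their mean, with **background pixels excluded from both** — including the
zeros would conflate So with Rr. Both indices depend on resolution and
event count; `index_table` records both and warns on mixed settings.
`Dy`/`Da` accept any method's dissimilarity matrix (CHIC's is the
conventional source); the source is carried in the matrix's `method` tag.

A point worth understanding before interpreting So: with linear max-scaled
gray rendering, an isolated Gaussian cluster produces a log-uniform-like
intensity distribution whose MAD is roughly `255·k/ln(c_max)` — sharp
isolated peaks give high So, while heavily overlapping broad clusters merge
into an even carpet whose intensities concentrate and So falls. This is the
mechanism by which a specialized community (few distinct dominant clusters)
scores high So and low Rr, and a diverse community (many broad overlapping
clusters) the reverse.

## Ordination and inference

NMDS minimizes Kruskal stress-1 with primary treatment of ties (tied
dissimilarities may take different disparities; ties are broken by distance
order in the isotonic regression). Optimization is SMACOF (scikit-learn)
with one classical-scaling (Torgerson) initialization plus `n_starts`
seeded random initializations; the reported solution is the lowest-stress
one, re-scored by the package's own stress-1 implementation, centered.
Degenerate inputs: an all-zero matrix returns a zero-stress zero
configuration with a warning; n = 2 returns two collinear points at the
exact dissimilarity.

envfit fits each covariate by least squares on the ordination coordinates;
r² is the squared multiple correlation and the direction the normalized
coefficient vector. Procrustes allows translation, orthogonal rotation
*including reflections* (ordination solutions are sign-indeterminate) and
isotropic scaling; the standardized residual m² and correlation
√(1 − m²) follow the protest convention. All permutation p-values use the
add-one estimator `(1 + #{t* ≥ t})/(n_perm + 1)` — never exactly 0, minimum
1/1000 at the default 999 permutations — and are exactly reproducible given
(input, seed, n_perm). Permutation nulls are computed vectorized (batched
projections for envfit, batched SVD for protest, rank cross-products for
Spearman), which is what makes 1000-repeat calibration runs cheap.

## Synthetic communities

The generator emulates DAPI-stained community fingerprints as Gaussian
mixtures in transformed (FSC, DNA) space:

- cluster means in [0, 1]², standard deviations 0.02–0.15 in transformed
  units (real clusters at 128 channels span roughly 5–20 channels);
- a **proliferation satellite**: a per-component fraction of cells shifted
  by +log10(2) on the DNA axis — DNA doubling is multiplicative on the
  linear scale, hence additive on the log scale — with unchanged covariance;
- a broad low-abundance **background component** (σ = 0.25, 5%) for debris,
  noise and rare populations; real fingerprints have Rr ≈ 0.4 and that
  background, not the clusters, supplies most informative pixels;
- out-of-range draws are **clamped**, not rejected (mirroring detector
  saturation and keeping n exact); the clamped fraction is logged;
- component membership is multinomial in the abundance fractions, so
  component counts sum to n exactly and binomial oracles apply.

Reference conditions used by the examples, tests and the acceptance script:
`specialist_community()` (3 clusters, fractions 0.59/0.285/0.075,
σ ≈ 0.05), `diverse_community()` (12 overlapping clusters of equal
abundance, σ = 0.15), `two_group_specs()` (3 clusters whose means differ by
0.18 between groups — many σ, i.e. clearly distinct inocula). Series
schedules apply per-step linear drift and an optional changepoint that
replaces the abundance vector, renormalized to the simplex each step;
replicate groups differ by resampling only. A typical real measurement
records 250 000 cells; index computations use that size, while
multi-sample comparisons use 20 000 events per sample, which is ample for
the effect sizes above and keeps run times in seconds.

The operator's Dalmatian gating is emulated by `operator_gate_sets`: each
component gets a 3σ principal-axes ellipse gate, but only in samples where
its observed fraction reaches 5% — a human analyst does not encircle faint
blots. This is also why a changepoint that collapses a component below the
threshold is visible to the binary Dalmatian method at all.

What the generator does *not* model: spectral realism of scatter channels,
doublets, instrument drift, staining variability, non-Gaussian cluster
shapes. Passing tests therefore demonstrate correctness of the algorithms
and the claimed qualitative behaviors on mixture-structured data, not
performance on any particular real instrument's quirks.

## Numerical choices

- Gate membership is boundary-inclusive everywhere; polygon membership is
  even-odd ray casting with on-edge → inside (tolerance 1e-12); polygons
  must be simple. Gates live in transformed [0, 1] space so one gate file
  serves all samples.
- Dissimilarity matrices are validated symmetric within 1e-12 with a zero
  diagonal; matrix builders name the offending pair on failure.
- Seeds: every stochastic stage takes an explicit integer seed
  (`numpy.random.default_rng`); the pipeline re-uses its config seed for
  NMDS, envfit and all permutation tests, so a rerun is byte-identical.

## Known limitations

- The Dalmatian "modified" Jaccard and the published CyBar normalization
  are substituted by classical/standard forms (see above); both are single
  functions by design.
- Only 2D histograms are supported; the methods are defined on 2D
  fingerprints and ≥3-parameter variants are out of scope.
- envfit handles numeric covariates only (no factors); graphics are limited
  to a basic NMDS scatter with group hulls and the barcode heat map.
- Rr/So values are resolution- and event-count-dependent by definition;
  they are comparable only across samples measured and binned identically,
  and no benchmarking against taxonomic diversity is attempted.
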