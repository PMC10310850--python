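# Methods

## The design problem

Testing six environmental exposures one factor at a time in several
human neural progenitor lines is prohibitively sample-hungry: six
factors x four cell lines x five replicates is 120 samples. A two-level
fractional factorial based on the L8 orthogonal array covers the same
six main effects in 8 runs per (line, replicate) — 32 samples across
four lines — because every column of the array is balanced and mutually
orthogonal, so each factor's main effect is an independent contrast of
the same 8 runs.

The price of the fraction is confounding. We label the seven L8 columns
1..7 so that the entry of column *j* in run *r* is
(−1)^popcount((r−1) AND j). Under this convention the elementwise
product of two columns is again a column, and its label is the XOR of
their labels. A two-way interaction {A, B} is therefore aliased onto
column label(A) XOR label(B). With six factors assigned, one column is
free, and exactly three of the fifteen two-way interactions fall on it;
an exhaustive check over all injective assignments (in the test suite)
confirms these three pairs always partition the six factors. The default
assignment (factors in study order on columns 1..6) puts
(Pb, Zn−), (VPA, FH) and (BPA, EtOH) on free column 7 — three
interpretable interaction contrasts that share a single degree of
freedom. Levels are coded −1 = control, +1 = treated for every factor,
including zinc deficiency (treated = withdrawal of the 1.5 µM ZnSO4
supplement); run order is Yates by default with an optional seeded
randomization.

The emitted sample sheet reproduces the study layout: one full L8 set
per line, a full extra replicate for CTRL_Male and a 4-run partial for
CTRL_Female, i.e. 44 rows. (The study analysed 43 samples; the
difference is presumably a QC dropout and the generator keeps all 44.)

## Synthetic data

All pipeline inputs are simulated with known ground truth; every
generator is a pure function of (config, seed).

**Counts.** Gene counts are negative binomial with
Var = µ + αµ², α(µ) = a0/µ + a1 (defaults a0 = 2, a1 = 0.05) times
lognormal gene noise (log-SD 0.2). The log2 mean is
baseline (N(5, 2²)) + a per-(gene, line) offset drawn with SD 1.0 log2
units + sparse exposure effects (0/1 treated coding, so a planted effect
of 1.0 doubles the expectation) + aliased interaction effects, scaled by
a per-sample library size (uniform 0.5–2x). The line-offset SD is set
deliberately large so genetic background dominates the variance, as in
the study's PCA; a one-way decomposition test verifies line variance
exceeds exposure variance. Default scale is 2,000 genes x 44 samples —
small enough for routine runs, large enough for calibration and power
checks.

**Exon bins.** Gene totals are drawn as above and split multinomially
over bins (default 4, Dirichlet(5) base proportions). A switched gene
moves a stated usage fraction (default 0.25–0.3) from bin 1 to bin 2
either in treated samples (an exposure-dependent switch) or in all
samples of one cell line (a line-specific isoform preference, used to
verify blocking). The planted-switch demonstrations use a deeper
configuration (baseline log2 mean 8, SD 1): the gene-level calling rule
includes an absolute base-mean threshold, so usage switches are only
observable "given sufficient depth", and the demonstration is designed
to be in that regime.

**Metabolites.** Lognormal feature intensities in four lipid classes,
one internal-standard channel per class at a known concentration (2 µM),
multiplicative measurement noise (log-SD 0.1), and a 1.5x fold change on
five features of the first class in FH-treated samples. The layout
matches the study's ESI-MS design: 3 technical replicates x 2 exposure
groups x 4 cell lines (N = 24).

**Spatio-temporal expression.** FPKM-like lognormal values over
4 regions x 8 periods x 3 samples, per-gene scale lognormal(1, 0.4) and
per-sample noise lognormal(0, 0.3), with an additive shift planted in
chosen (region, period) cells for a chosen gene group, and RIN metadata
with ~10% of samples below 9 to exercise QC filtering. The noise scales
are budgeted so that the canonical planted signal (+2 FPKM on a 30-gene
group) sits far outside the permutation null of size-matched random
sets: the null SD of a 30-gene mean is ≈ 0.25, so the shift is a
high-confidence signal by design rather than a marginal one.

## Differential expression

A compact NB-Wald stack standing in for a full count-model package, at
the same inferential contract (NB GLM + Wald + BH at adj. p < 0.05):

- **Size factors**: median-of-ratios against the geometric-mean
  reference; genes with zeros drop out of the reference, and if no gene
  is expressed everywhere the estimator falls back to positive-count
  subsets with a warning.
- **Dispersion**: per-gene method of moments around an OLS fit of the
  model matrix on normalized counts — residual-df corrected, with the
  Poisson part µ/s subtracted per sample and the quadratic term
  normalized by Σ fitted µ² (using per-sample fitted means matters: with
  dominant line effects, E[µ²] exceeds µ̄² by ~60% and the naive
  estimator is badly inflated). Raw values are shrunk on the log scale,
  weight 0.5, toward a fitted a0/µ + a1 trend, and floored at 1e−8.
- **GLM**: log-link NB IRLS with log size-factor offset; convergence at
  max coefficient change < 1e−6 within 100 iterations (non-convergence
  flagged, not fatal); covariance from expected Fisher information.
  All-zero genes are flagged untestable. A rank-deficient model matrix
  raises an error naming the collinear columns — this is how aliased
  contrasts surface, and why the Level IV model fails by construction on
  single-replicate data.
- **Levels**: I = all samples; II = one clinical background; III = one
  cell line with design ~ exposure; IV = interaction coefficient under
  ~ cell line + replicate + interaction + cell line:interaction. The
  literal Level I/II model is ~ exposure alone; because the generator
  (and the real data) put most variance between lines, an optional
  cell-line blocking term is exposed (`include_blocking`) and the
  workflow enables it by default. Genes below a base-mean threshold
  (default 5) are excluded before BH adjustment (independent filtering).

Calibration under the null (2,000 genes, 44 samples): empirical type-I
error at p < 0.05 ≈ 0.047 and KS distance to uniform ≈ 0.02 with
blocking enabled; spiked log2FC = 1 effects are recovered with mean
estimate within ±0.1 and ~90% power at adj. p < 0.05.

No Cox–Reid adjustment, no MAP shrinkage of fold changes, no outlier
replacement: parity with any specific package's numerics is a non-goal.

## Enrichment

Preranked GSEA: the weighted Kolmogorov–Smirnov running sum (hits
weighted |score|^exponent, default exponent 1; misses 1/(N − |set|)),
ES = extremum by absolute value. Significance by gene permutation
(size-matched random sets, default 1,000 draws, shared across sets of
equal size): add-one tail p on the matching sign, NES = ES over the mean
same-sign null magnitude, FDR q as the GSEA-style null/observed NES tail
ratio clipped to [0, 1]. The ranking metric for RNK export is the Wald
statistic.

Enrichment-map network: nodes are sets at q < 0.05, edges at combined
similarity (half Jaccard, half overlap coefficient) ≥ 0.375 — the
EnrichmentMap defaults. An empty significant list yields an explicit
empty network rather than an error. Global metrics (networkx): node and
edge counts, diameter on the largest connected component, density, mean
local clustering coefficient (global transitivity is available through
networkx if preferred) and average degree; all verified against
brute-force BFS/triangle oracles. Cluster labels are deterministic
token-frequency summaries of member set names, replacing word-cloud
annotation with something reproducible.

Over-representation: upper-tail hypergeometric P(X ≥ k) with the
background restricted to expressed genes (base mean > 20 in the
workflow), BH across target lists. Hits outside the background raise an
error (background misspecification).

## Spatio-temporal enrichment

Samples below RIN 9.0 are dropped. Genes are dropped when they fail the
expression rule (≥ 1 FPKM in ≥ 2 samples) or are simultaneously sparse
(expressed in < 50% of samples) and flat (CV < 0.25). The CV is computed
over the samples where the gene is expressed: across all samples the
zeros of a sparse gene force its CV above any sensible cutoff and the
flatness clause could never fire. Gene groups are split into k = 2
clusters by average-linkage agglomeration on correlation distance of
their z-standardized region x period mean profiles (standardization
after per-cell averaging).

Per cell, the observed statistic is the group's mean expression; the
null is the mean of B size-matched uniformly random gene sets (default
B = 10,000; the demonstrations use 2,000). The source procedure scores
the proportion of permutations in which the observed mean is *higher*
than the random mean — a score near 1 for enriched cells; we report the
standard complement p = (1 + #{null ≥ observed})/(B + 1), so small p
means enrichment and ties count conservatively against the group, and
expose the literal proportion as `score = 1 − p`. BH-FDR is applied
across the 32 cells. Note that for a fixed group the 32 cells share the
group's baseline deviation, so null p-values are uniform marginally but
correlated across cells.

## Differential exon usage

Transcript exons are projected onto the genome and split at every
boundary into disjoint bins (input GFF-style 1-based inclusive,
internally 0-based half-open; bin ids gene:E001...). Genes with exon
overlap on the same chromosome and strand are excluded as aggregate
loci, and flattening is idempotent.

Usage is tested bin-vs-rest: for each bin, the stacked (bin, rest)
counts are fitted with a full NB model
(sample + exon + cell line:exon + exposure:exon) and a reduced model
without exposure:exon, sharing a per-bin moment-estimated dispersion,
and compared by a 1-df likelihood-ratio test; the sample term absorbs
per-sample totals, and the cell line:exon term blocks line-specific
isoform preferences out of the exposure contrast (verified by planting
line-specific switches: no calls). Usage log2FC is the log2 ratio of the
bin's count share, treated vs control, with 0.5/1.0 pseudocounts. Genes
are called with at least one bin at adjusted p < 0.05 (strict), exon
base mean ≥ 10 and |usage log2FC| ≥ 1.5 (both inclusive per the "≥"
rule). Replicate structure is folded into the sample term. This replaces
the heavyweight shared-dispersion machinery of dedicated DEU packages at
desk scale; parity with their numerics is a non-goal.

## Metabolite quantification

One-point calibration: C = C_IS x (I_metabolite / I_IS), per sample,
against the class-matched internal standard; zero IS intensity marks the
feature unquantifiable (NaN), and the quantification is exactly
invariant to instrument gain. An optional median-intensity signal filter
reduces the feature list; its threshold is configuration with no
endorsed default, since the criterion behind the study's reported
feature count is unstated. Testing is literally lm(concentration ~
exposure) per feature within each analysis level (global, per clinical
background, per cell line), p from the slope t-statistic — algebraically
the pooled two-sample t-test, which the tests confirm to 1e−10 — with BH
across features within each level. A blocked variant is deliberately not
the default, mirroring the expression stage's literal reading.

## Workflow

`ffed.io` provides readers/writers for all text formats (counts TSV,
sheet CSV, design CSV + YAML sidecar, GMT, RNK, GFF3, bin TSV, GraphML);
writers stamp a `#` provenance header (config hash + seed) where the
format allows, and write-then-read is the identity. `run_pipeline`
executes design → simulation → DGE (Level I per factor, Level IV for an
aliased pair) → enrichment → network metrics → DEU → metabolites →
spatio-temporal enrichment, writing a provenance-stamped report
directory; equal configs give equal reports. The numbered scripts under
`analysis/` drive the same stages step by step. Problem sizes in the
shipped configurations (2,000 genes, 44 samples, 60-gene exon sets,
400-gene spatial matrices, 1,000–2,000 permutations) are chosen so the
whole suite runs in well under a minute per stage on a laptop.

## Known limitations

- Interpretation of the three interactions sharing free column 7 as
  three separate analyses follows the study; statistically they are one
  contrast with three readings.
- The simulators emulate statistical structure (variance hierarchy,
  NB dispersion trends, usage switches, internal standards), not
  sequencing artifacts, batch chemistry, UMI structure or real pathway
  topology; passing tests demonstrate the machinery is correct and
  calibrated on that structure, not that real-data effect sizes will be
  recovered.
- Network "diameter" and pathway q-values of the study are
  data-dependent quantities of the real datasets and are out of scope
  here; only the algorithms that produce them are implemented and
  verified.
- No plotting is bundled; grids and networks are written as TSV/GraphML
  for any downstream plotting tool.
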