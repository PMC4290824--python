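# Methods

## Model overview

The pipeline treats a pooled CRISPR/Cas9 knockout screen as an M × N
matrix of sgRNA read counts over N sequencing experiments, with each of
the M sgRNAs assigned to one gene.  The statistical chain is:
per-sample normalization → an empirical variance law shared across
sgRNAs → a negative-binomial (NB) tail test per sgRNA → rank aggregation
per gene → rank aggregation per pathway.  Every stage is deterministic
given its inputs and, where randomness enters (permutations,
simulation), a seed.

## Normalization

Size factors follow the median-ratio construction: s_j is the median
over sgRNAs of x_ij / x̂_i, where x̂_i is the geometric mean of sgRNA i
across all samples.  sgRNAs with a zero anywhere have x̂_i = 0 and are
excluded from the median (the geometric mean is annihilated by a single
zero) but are still normalized; the count of contributing sgRNAs is
reported as `n_used`.  The median of an even-length vector is the mean
of the two central values.  Normalized counts are rounded
half-away-from-zero, once, immediately after division; all downstream
statistics (condition means included) see rounded integer counts.
Total-count normalization (scale each library to the mean library size)
is available as a fallback for tables in which no sgRNA is positive
everywhere.

## Mean-variance modeling

With n replicates of a condition, each sgRNA yields a sample mean μ̂ and
the unbiased (n−1) sample variance σ̂².  Counts are overdispersed, so the
variance is modeled as

    σ² = μ + k·μᵇ,   k ≥ 0, b ≥ 0,

estimated by unweighted OLS of log(σ̂² − μ̂) on log(μ̂).  Points with
μ̂ = 0 or σ̂² ≤ μ̂ have an undefined response and are excluded; their
count is reported.  A negative fitted exponent is clamped to zero with a
warning.  The model is fitted on the control replicates; when the
control condition has a single sample, moments are pooled over all
samples instead, which overestimates the variance whenever many sgRNAs
are truly selected and makes the test conservative — the trade-off is
logged at run time.

**Known bias.**  With two replicates the σ̂² > μ̂ exclusion truncates the
noise distribution of σ̂², which biases the fit: on simulated screens
generated with (k = 0.2, b = 1.5) at 10,000 sgRNAs the fitted b lands
near 1.31–1.34 and k near 0.42–0.50, consistently across seeds.  The
bias shrinks with more replicates.  The estimator is kept as the plain
OLS because the fitted law is only used to *predict* σ² at observed
means — in the region of the data the predicted variances are close
even when (k, b) individually are off — and the recovery tests bound b
to ±0.2 at this scale.

**NB parameterization.**  Method of moments: p = 1 − μ/σ²,
r = μ²/(σ² − μ), with real-valued (gamma-extended) r.  In this
convention the NB mean is r·p/(1 − p); scipy/numpy's success
probability is 1 − p = μ/σ².  The conversion requires σ² > μ; when a
prediction is not strictly overdispersed (Poisson fits, underflow) the
variance is inflated to μ(1 + ε) with ε = 10⁻².

## sgRNA test

For sgRNA i, μ_iA is the mean normalized count of the controls, σ²_iA
the model-predicted variance at μ_iA, and μ_iB the treatment mean.  Two
one-sided tail probabilities under NB(μ_iA, σ²_iA):

    p_high = P(X > μ_iB),  p_low = P(X < μ_iB),

with strict inequalities read on integer support — "x > μ_iB" means
x ≥ ⌊μ_iB⌋ + 1 and "x < μ_iB" means x ≤ ⌈μ_iB⌉ − 1.  When every control
replicate is zero, μ_iA is replaced by the pseudo-mean 0.5 before
variance prediction (the NB is undefined at mean zero).  p-values are
floored at 10⁻³⁰⁰ to keep logs finite.  Ranking per direction is by
ascending p-value, ties broken by larger |μ_iB − μ_iA|, then by sgRNA
id, so the order is total and reproducible.  sgRNAs with zero counts in
*every* sample carry no information and are forced to the bottom of both
rankings (and are never α-selected), but remain in M so that the rank
percentiles of everything else are unchanged.

The comparison is of condition means, not per-replicate: the treatment
replicates enter only through μ_iB.  The null p-values are only
approximately uniform — μ_iA is itself estimated from two replicates —
but on null simulations at 2,000 sgRNAs the Kolmogorov–Smirnov distance
from uniform stays in the 0.02–0.05 range, which the calibration tests
pin down.

## Gene ranking (α-RRA)

A gene with n sgRNAs at ranks r_1 < … < r_n has percentiles u_i = r_i/M.
Under the uniform null the k-th smallest percentile follows
Beta(k, n+1−k), giving order-statistic p-values
p_k = BetaCDF(u_(k); k, n+1−k).  The α modification selects the "good"
sgRNAs — directional NB p-value below `p_threshold` (default 0.05) *and*
rank within the top `alpha_percent` fraction — and scores

    ρ = min(p_1, …, p_j),   j = number of good sgRNAs,   ρ = 1 if j = 0.

By default `alpha_percent` is the realized fraction of sgRNAs passing
the threshold, which makes the two criteria coincide; both are
independently configurable.  Because sgRNAs are ranked by the same
p-value used for the threshold, the good set is always a contiguous top
slice of the ranking; the implementation verifies this and exploits it.

**Permutation null.**  sgRNAs are reassigned to genes at random with
gene sizes preserved, which is equivalent to drawing n ranks without
replacement from 1..M.  Since the null depends only on n, one shared
pool of `num_permutations` draws (default 100 × number of genes) is
generated per distinct gene size; drawing uses vectorized rejection
sampling (i.i.d. rows, duplicates redrawn) and falls back to row-wise
sampling without replacement when n² is not small relative to M.  The
empirical p-value is (#{null ρ ≤ ρ_obs} + 1)/(N + 1), never zero.  FDR
across genes is Benjamini-Hochberg; genes are ranked by
(permutation p, ρ, gene id) — the permutation p has resolution 1/(N+1),
so ρ breaks its ties deterministically.

Both directions (depletion and enrichment) can be scored from one sgRNA
table; the CLI does so by default and merges them into one summary.

## Pathway ranking

Identical machinery with genes as items: percentiles from gene ranks
over the n_g screened genes, a gene is good when its permutation
p-value is below the threshold and its rank within the top α fraction,
and the default permutation count is 100 × number of pathways.  Genes
in the GMT file that were not screened are ignored; pathways with no
screened gene are skipped with a warning; overlapping pathways are
tested independently.  Gene-set matching is case-sensitive by default
(an opt-in flag upper-cases symbols), because silent case-folding hides
annotation mismatches.

## Synthetic screens

The simulator generates data with exactly the structure the test
assumes: baseline sgRNA abundances log-normal (default median 300
reads, log-sd 1.0 — about two orders of magnitude of spread), replicate
counts NB with σ² = μ + k·μᵇ (defaults k = 0.2, b = 1.5; Poisson when
k = 0), and selected genes' treatment means multiplied by the effect
size (above one for enriched genes, reciprocal for depleted ones), with
optional per-sgRNA log-scale jitter emulating unequal knockout
efficiencies (off by default so recovery tests are clean).  Defaults
are 1,000 genes × 4 sgRNAs and 2 + 2 replicates; the calibration and
recovery studies use 500 genes (2,000 sgRNAs) and 2,500 genes (10,000
sgRNAs) respectively, sizes at which the measured properties are stable
while the full suite runs in seconds.

What the simulator does *not* emulate: PCR jackpotting and other
heavy-tailed count artifacts, guide-sequence-dependent efficiency,
off-target effects, correlated replicates, or selection acting on sgRNA
subsets within a gene.  Passing calibration and recovery tests on this
generator therefore demonstrates internal consistency of the statistics
under the model's own assumptions, not performance on any real screen.

## Numerical and design choices

- Tail probabilities use the exact NB CDF/SF (regularized incomplete
  beta), verified against brute-force PMF summation to 10⁻⁸.
- Beta order-statistic p-values are verified against the closed-form
  binomial-sum identity to 10⁻¹⁰ and against Monte-Carlo order
  statistics.
- BH is delegated to statsmodels and cross-checked against a
  from-scratch step-up implementation to 10⁻¹².
- All RNG is `numpy.random.default_rng` with explicit seeds; identical
  seeds give byte-identical output files.
- Degenerate inputs: empty conditions, single-sample moment requests,
  all-underdispersed regressions, zero-total libraries and non-prefix
  goodness flags all raise typed exceptions with actionable messages
  rather than propagating NaNs.

## Limitations

- The gene permutation p-value is lower-bounded by 1/(N+1); deeply
  significant genes tie there and are ordered by ρ.
- With α-selection active the null distribution of gene p-values is a
  point mass near 1 plus a significant tail — it is *not* uniform, and
  only the classic-RRA limit (threshold 1, α = 1) is calibrated as
  uniform.
- Two-replicate variance estimation biases (k, b) as described above.
- Paired designs, per-replicate testing, fold-change shrinkage and
  FASTQ-level processing are out of scope.
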