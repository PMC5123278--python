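# Methods

This note documents the models, algorithms and numerical conventions
behind `ampliconbench`, and the design choices made where more than one
reasonable convention exists.

## Synthetic OTU tables

The generator produces the three pathologies that characterize 16S
survey data and break naive statistics: high sparsity, strong library
size variation, and overdispersion.

Model. Sample depths are log-normal:
`L_j ~ round(LogNormal(log_mean, log_sd))`, defaults `log_mean =
log(3e4)` (a typical Illumina amplicon depth) and `log_sd = 1`, which
makes max/min depth across 100 samples exceed two orders of magnitude.
OTU mean proportions decay as a power law in abundance rank,
`q_i ∝ i^(-a·γ)`, normalized to sum 1 and shuffled so that abundance
rank is decoupled from row order. Counts are gamma-Poisson:
`c_ij ~ Poisson(q_i · L_j · G_ij)` with `G_ij ~ Gamma(1/φ, φ)`, giving
`Var(c|L) = μ + φμ²` (negative binomial with dispersion φ, default
0.5).

Sparsity calibration. The config carries both a tail exponent `a`
(default 1.5) and a target sparsity (default 0.85). These are
reconciled by a tempering exponent γ found by root-finding on the
closed-form expected zero fraction `E[#zeros]` of the NB model given
the drawn depths. Because a real OTU table never contains an OTU with
zero observed reads, each all-zero row is redrawn until non-empty
(rejection sampling = conditioning on presence), and the calibration
formula uses the matching zero-truncated expectation
`E[zeros_i | row non-empty] = n − s_i / (1 − Pall_i)` with
`s_i = Σ_j (1 − p0_ij)` and `Pall_i = Π_j p0_ij`, computed via
`expm1`/`log1p` to avoid catastrophic cancellation for very rare OTUs.
Configs whose target would require OTUs with < 1% chance of ever being
observed are rejected as infeasible rather than silently degraded.

What the generator does *not* emulate: phylogenetic correlation between
OTUs, taxon-specific dispersions (a single global φ by default),
compositional interactions beyond the shared depth constraint, and
sequencing artifacts (chimeras, contamination). Passing benchmarks on
these tables therefore demonstrates correct *mechanics* and the stated
distributional robustness, not performance on every real community
structure.

Dispersion recovery (`estimate_dispersion`) uses per-OTU
method-of-moments with depth offsets: `μ̂_ij = q̂_i L_j`,
`φ̂_i = Σ((c−μ̂)² − μ̂)/Σμ̂²`, median over informative OTUs. OTUs with
mean relative abundance above 2% are excluded because the relative
fluctuations of a dominant OTU are compositionally coupled to the
library size itself, which biases naive mean–variance regressions.

The within-OTU permutation null (`permute_within_otus`) permutes each
row independently across samples with one seeded stream; every
OTU-marginal statistic is exactly preserved while within-sample
structure is destroyed, so any label split of the result satisfies the
null hypothesis.

## Spike-in engine

Labels first, spikes second: case/control status is drawn uniformly
(`max(1, round(p·n))` cases), then targets are drawn from abundance
tertiles computed table-wide on mean relative abundance *before* label
assignment (ties broken by OTU id; when `n_otus % 3 ≠ 0` the remainder
goes to the lower tertiles). Only OTUs present in at least one case
sample are eligible; strict mode errors on a shortfall, lenient mode
takes all eligible OTUs and flags it.

Schemes. Multiplicative: case counts of target OTUs × magnitude.
Additive: each *nonzero* case count gains `round(m · magnitude · L_j)`
where `m` is the OTU's mean relative abundance over its nonzero samples
(table-wide). The additive magnitude is deliberately defined on the
relative-abundance scale and converted to counts per sample through
that sample's depth: a raw count-scale reading would make the same
magnitude mean different effect sizes in shallow and deep samples.
Mixed: multiplicative with per-OTU magnitudes assigned by one seeded
shuffle of the magnitude set followed by cycling, so every magnitude is
used ±1 times equally often.

Rescaling. After spiking, every case sample is rescaled to its original
depth with largest-remainder integer apportionment (floor + distribute
the shortfall by descending fractional remainder, remainder ties broken
by lower row index). This keeps counts integral, maps zeros to zeros,
and conserves library sizes *exactly* — asserted as an invariant for
every spike result. Controls are never touched. Note one consequence:
at large magnitudes a spiked high-abundance OTU displaces reads from
all other OTUs in case samples, which caps and can slightly erode
retrieval AUC at the top of the magnitude range (a real property of
depth-constrained spiking, visible as saturation in power curves).

## Differential abundance tests

All built-ins are two-sided per-OTU tests; the missing-p rule (no
p-value ⇒ p = 1) applies to degenerate OTUs, non-convergent fits and
failed plugins alike, so every result vector is complete.

* **t-test** — Welch (unequal variances, Satterthwaite df) on relative
  abundances. Where both group variances are zero the reference
  implementation raises instead of returning a p-value, so those OTUs
  get p = 1 via the missing rule.
* **log t-test** — Welch t on `log(count + 1)` cells. The alternative
  reading (log of relative abundances) is deliberately not used; the
  pseudocount of 1 is on the count scale and no re-normalization is
  applied after the transform.
* **Wilcoxon** — Mann–Whitney on relative abundances; exact null when
  both groups have ≤ 12 observations and the OTU has no ties, else the
  tie-corrected normal approximation with continuity correction.
* **NB GLM** — per-OTU negative binomial regression
  `log μ = β₀ + β₁·case + log(library size)` (offset fixed at 1). The
  NB2 likelihood is maximized directly in `(β, log α)` with analytic
  gradient (L-BFGS-B), started from group-wise moment estimates; the
  Wald p for β₁ comes from the inverse observed information at the
  optimum. If ML fails, a GLM with the moment-estimated dispersion held
  fixed supplies the Wald test; if that fails too, p = 1 with a logged
  warning. The direct fit is cross-checked against an independent ML
  implementation in the test suite (agreement breaks down only where
  the dispersion sits on its zero boundary, where numeric Hessians in
  the α-parametrization are unreliable).
* **Permutation test** — statistic `S = log(mean_case/mean_ctrl)²` on
  relative abundances; the empirical null reuses one seeded set of
  label permutations across all OTUs (valid, and much cheaper than
  fresh draws per OTU); `p = #{S_perm ≥ S_obs}/n_perm` with no +1
  smoothing, so p = 0 is attainable. Zero-mean conventions: one group
  mean zero ⇒ S = +∞ (ranks above every finite permuted value and ties
  with permuted +∞); both zero ⇒ S = 0. The observed statistic is
  computed through the same matrix path as the permuted ones and ties
  are detected with a relative tolerance, because symmetric label
  splits produce mathematically identical statistics that may differ in
  the last float ulp. An exhaustive mode enumerates all distinct case
  subsets and is tested for exact agreement with rational-arithmetic
  brute force.

Plugins: external methods run as subprocesses receiving the count TSV
and a labels TSV and printing `otu_id<TAB>p` lines; a crashed plugin
yields all-1 p-values with an error flag rather than a dropped run.

## Evaluation statistics and grids

FPR = fraction of OTUs with p strictly below α = 0.05 (α is part of
the definition, not a knob). AUC uses the orientation "lower p =
spiked" and mid-rank tie handling, equivalent to counting tied pairs
1/2 — important because permutation p-values tie heavily. The spiked
p-value quantile is the mean rank of the OTU's p divided by the OTU
count, so filtered/missing p's (= 1) can reach quantile 1.0.

Grid runners derive per-iteration seeds from the master seed via
`SeedSequence(master, spawn_key=(dataset, proportion, iteration[,
spike config]))`, reduced mod 2³¹. The seed depends on everything
*except* the method, which enforces the contract that all methods see
identical labels (and identical spiked tables) within an iteration.
Cells are pure functions of the grid and indices, so serial and
process-parallel execution (joblib, `n_jobs`) give identical tables.
Failed cells are recorded with a status string; aggregation skips them
and reports how many were skipped.

## Beta-diversity grid

Pipeline order per cell: normalize → transform → distance → PERMANOVA.

Normalizations. TSS divides by library size. Median-of-ratios size
factors use the sparse-data variant: per-OTU reference = geometric mean
over *nonzero* counts; per-sample factor = `exp(median(log ratios))`
over OTUs with positive reference and positive count (the log-scale
median matters for even counts); factors rescaled to geometric mean 1.
TMM follows the standard recipe (reference sample by 0.75-quantile
rule; per-OTU M and A values on counts shared with the reference; trim
30% from each M tail and 5% from each A tail; inverse asymptotic
variance weights; 2^weighted-mean; geometric mean 1), and is verified
to machine precision against the canonical implementation on a frozen
fixture. Because pure TMM factors exclude depth by construction,
`normalize(kind="tmm")` divides counts by the *relative effective
library size* `L_j·f_j / geomean(L·f)`; CSS and size factors already
carry depth and are used directly as divisors. TMM raises an explicit
error when extreme sparsity leaves no shared nonzero OTUs — such cells
are recorded with error status in the grid, not dropped. CSS sums each
sample's nonzero counts up to a quantile chosen by the data-driven
instability rule (smallest quantile where the median absolute deviation
profile changes by > 10% relatively, floored at 0.5) and divides by
1000, the reference implementation's scaling constant.

Transformations. `log(x + c)`, corrected by subtracting `log(c)` when
c < 1 so that zeros map exactly to zero for every pseudocount; square
and cubic roots. Pseudocount presets {1, 0.01, 1e-4} and the extended
set including 1e-5 are both shipped.

Distances. Bray-Curtis and Euclidean via standard routines; JSD with
natural log on per-sample probability vectors (the divergence itself,
not its square-root metric); UniFrac and weighted UniFrac via
scikit-bio, the weighted variant normalized to [0, 1] by default (raw
variant behind a flag). Both UniFracs are verified against an
independent R implementation on a frozen 12-taxon fixture. JSD and the
UniFracs are treated as normalization-independent: computed once per
transformation on the un-normalized branch and replicated across
normalization rows with a `shared` flag.

PERMANOVA. One-way decomposition from squared distances: `SS_total =
Σ_{i<j} d²/n`, `SS_within` pooled within groups, `R² =
(SS_T−SS_W)/SS_T`, pseudo-F with `(a−1, n−a)` degrees of freedom; the
p-value is `(1 + #{F_perm ≥ F_obs})/(1 + n_perm)` (default 999
permutations) with shuffles restricted within strata when given. R² is
deterministic — independent of the seed — and matches both a
brute-force sum-of-squares oracle and the canonical R implementation
to 10 decimal places on fixtures.

Agglomeration. Cophenetic (tree path) distances between tips; the
threshold is the `quantile` (default 0.001) *lower* order statistic of
the pairwise distance distribution — the "lower" convention makes a
vanishing quantile collapse onto the minimum distance, where the strict
`<` rule merges nothing. Clusters are connected components of the
under-threshold graph (single-linkage closure); counts are summed and
the member with the highest total count (ties: lexicographic id) names
the cluster. Total counts and library sizes are conserved exactly.

## Problem sizes in the default test run

The test suite exercises the benchmark end to end at sizes chosen as
the package's own desk-scale defaults: type-I calibration on one
default-config table (1,000 OTUs × 100 samples) with 150 label draws
and 1,000 permutations for the permutation test (p-resolution 0.001 is
ample at α = 0.05); magnitude-monotonicity on the same table with 25
iterations and the full 10⁴ permutations — at coarser resolution the
many p = 0 ties among top-ranked OTUs blur the AUC ranking precisely
where power saturates; NB GLM
fold-change recovery on 100 planted OTUs at 50 vs 50 samples. The
bookkeeping checks are exact and instantaneous.

## Known limitations

* The NB GLM Wald p-values are asymptotic; at very small sample sizes
  or boundary dispersions they are approximate (the fallback chain
  trades exactness for robustness, mirroring common practice).
* The CSS data-driven quantile follows the published description of the
  reference procedure; exact tie behavior of the original is not
  specified and may differ in edge cases.
* AUC saturation: with depth-constrained rescaling, retrieval power
  plateaus at high magnitudes and rank-based tests hit a tie-induced
  power ceiling on very sparse OTUs — both expected properties, not
  bugs.
* The beta-diversity grid treats JSD/UniFrac as normalization-invariant
  by convention; with nonlinear transforms this is an approximation
  inherited from the benchmark design it reproduces.
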