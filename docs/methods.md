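# Methods

This note documents the models, defaults and numerical choices behind
`bsmethkit`, and what the synthetic-data generators do and do not emulate.

## Data model and coordinates

A methylation record is a pair of read-level call counts per genomic unit:
`n_meth` (C calls, protected from bisulfite conversion) and `n_unmeth`
(T calls, converted), with percent methylation 100·n_meth/(n_meth+n_unmeth).
Coordinates are 1-based inclusive throughout (`start == end` at base
resolution), matching the per-base text dialect; BED input is converted from
0-based half-open on read, and bedGraph output converts back. Strand is
stored per cytosine (`*` for strand-agnostic tiles); records are keyed and
sorted by (chrom, start, strand) and duplicate keys are rejected.

When importing the per-base text dialect (columns `chrBase chr base strand
coverage freqC freqT`), counts are reconstructed as
`n_meth = round_half_up(coverage·freqC/100)`. Half-up rounding is a
convention choice — the dialect itself carries only percentages rounded to
two decimals, so any reconstruction is exact only to ±0.005·coverage/100 of
a read; round-tripping reproduces `coverage` exactly and `freqC/freqT`
within 0.01.

## Import filters

Defaults: a base must be covered by ≥ 10 reads, and each call must have
base quality ≥ 20 (PHRED). Both thresholds are inclusive. The optional
`high_coverage_percentile` cut (e.g. 99.9) removes records whose coverage is
strictly above that empirical percentile of the sample's coverage
distribution, guarding against PCR-duplication (clonal) artifacts that
inflate apparent coverage; records exactly at the percentile are retained.
The percentile is the standard linear-interpolated empirical quantile of the
current sample, which makes this a **one-shot QC step**: reapplying it to
already-truncated data would recompute a lower percentile and keep shaving
the tail, so pipelines apply it once at import time. The plain min-coverage
threshold, by contrast, is a projection and freely composable.

SAM import supports Bismark-style alignments whose `XM` tag carries a
per-read call string aligned to read bases (`Z/z` CpG, `X/x` CHG, `H/h`
CHH). The record's strand is the read's mapping strand (the strand of the
cytosine). PCR-duplicate collapsing is not performed; the high-coverage
percentile filter is the provided guard. Reference-based re-calling of
methylation from raw alignments is out of scope.

## Regional summarization

Tiling windows are anchored at position 1 of each chromosome: window *w*
(0-based) spans `[w·step+1, w·step+window]`. Anchoring at 1 (rather than at
the first covered base) keeps window identities stable across samples, which
matters because downstream joins are by unit key. Window counts are sums
over contained cytosines, strand-agnostic; windows with fewer than
`min_bases` covered cytosines (default 1) are dropped, because one-base
tiles are statistically indistinguishable from base resolution but
masquerade as regions. With `step < window`, a base intentionally
contributes to every window containing it. Region summarization follows the
same rules for arbitrary user intervals; a base inside two overlapping
regions contributes to both (no precedence is defined for summarization).
Consequences: non-overlapping tilings conserve total counts exactly, and a
region's percent methylation equals the coverage-weighted mean of its
bases' percentages.

## Cross-sample statistics

All cross-sample statistics operate on the complete-case join: only units
covered in every sample, never imputed. Correlation (Pearson, Kendall,
Spearman) is computed on the units×samples percent matrix; a zero-variance
sample produces NaN entries rather than a silent 0. Hierarchical clustering
supports the distances `correlation` (1 − Pearson r), `euclidean`,
`maximum` (Chebyshev), `manhattan`, `canberra`, `binary` (Jaccard on
nonzero pattern) and `minkowski`, with single/complete/average/Ward
linkages; Ward uses the squared-distance ("ward.D2"-style) update. PCA
treats samples as observations and units as variables, via SVD of the
(column-centered by default, unscaled) percent matrix; scaling unit
variances is available but off by default since all variables are already on
the common 0–100 scale. Component signs are fixed by forcing each
component's largest-magnitude loading positive, so scores are reproducible
across platforms.

## Differential methylation

Per unit, per-sample counts are binomial. With more than one sample in any
group the logistic model `logit(P_i) = β0 + β1·T_i (+ covariates)` is fitted
with per-sample successes `n_meth` out of coverage; multiple treatment
groups enter as dummies against control (df = #groups − 1). The default
test is the likelihood-ratio (deviance) chi-square; for treatment-only
designs the binomial MLE is the per-group pooled proportion, so the
statistic has the closed form

    G = 2·[ Σ_g ℓ(m_g, u_g) − ℓ(Σ m_g, Σ u_g) ],   ℓ(m,u) = m·log(m/(m+u)) + u·log(u/(m+u))

evaluated vectorized over all units (0·log 0 = 0). With covariates, or for
the optional Wald statistic, the model is fitted by IRLS (statsmodels GLM)
and the two routes are cross-checked against each other in the tests. Under
complete separation (one group all 0%, the other all 100%) the deviance —
and hence the LRT p-value — remains finite; the reported log odds ratio is
±∞. The reported methylation difference always uses pooled group counts,
`100·(Σ_T m/Σ_T cov − Σ_C m/Σ_C cov)`, because coverage-weighting is what
the binomial likelihood itself assumes; it is *not* the mean of per-sample
percentages. Overdispersion beyond binomial is not modelled.

With exactly one sample per group, Fisher's exact test (two-sided,
point-probability method: sum of hypergeometric probabilities of tables no
more likely than the observed one) replaces the regression. Fisher is never
used to pool replicates; replicated designs always go through the
regression, whose effective sample size is total coverage per group.

Work is chunked by genomic position; with `workers > 1` chunks run in a
process pool and are concatenated in unit order, so results are identical
for any worker count.

### Multiple-testing correction

`bh` is the Benjamini–Hochberg step-up procedure. `slim` additionally
estimates the null proportion π₀ from the p-value distribution: the
empirical CDF of p-values is locally linear with slope π₀ wherever only true
nulls contribute, so straight lines are fitted over sliding λ-windows
(width 0.3, step 0.05, spanning λ ∈ [0.4, 0.95]) and the smallest fitted
slope, clamped to [0, 1], is π̂₀; q = π̂₀·q_BH. When the fit is degenerate
(too few points, non-positive slope) π̂₀ falls back to 1, i.e. plain BH.
SLIM is therefore never more conservative than BH; on uniform p-values
π̂₀ ≈ 1 and the two coincide up to noise.

### Extraction defaults

DMCs/DMRs are units with q-value < 0.01 and |methylation difference| > 25
percentage points (both strict inequalities, so a difference of exactly 25.0
is excluded). Hyper/hypo classification is relative to the control group
(treatment indicator 0). Per-chromosome summaries report
100·(#hyper)/(#covered units) and likewise for hypo.

## Annotation

Overlap is strand-blind (methylation events hit features on either strand);
strand is used only to sign TSS distances, positive = downstream of the
TSS, with ties in absolute distance broken by lower TSS coordinate, then
name. Gene-part assignment is any-overlap with precedence promoter > exon >
intron > intergenic; promoters default to TSS ± 1000 bp (configurable — the
field has no single convention). CpG shores are the 2 kb flanks on both
sides of each island, clipped at position 1, with precedence island > shore
> other, so shores never claim events inside any island. Both label sets
partition the events, so summary percentages sum to 100.

## 5hmC adjustment

Paired bisulfite protocols measure 5hmC at the same cytosines as apparent
5mC. The adjustment is level subtraction: adjusted% = max(0, mc% − hmc%) on
bases covered in both samples, with counts re-derived from the 5mC sample's
coverage via half-up rounding (coverage is conserved). Rounding direction is
unspecified in the protocol literature; half-up is the documented choice
here. Bases absent from the 5hmC sample pass through unchanged (logged);
bases covered only in 5hmC are ignored — no imputation. The operation is
pure: re-applying subtracts again.

## Synthetic data

The generators emulate the features of a typical RRBS experiment that the
analysis code is sensitive to:

* **Coverage**: negative-binomial, mean 30, dispersion 8 (variance
  μ + μ²/8), floored at 1; an optional clonal mode (mean 300) mixed in with
  configurable probability reproduces the secondary high-coverage peak that
  PCR-duplication bias produces.
* **Baseline methylation**: a bimodal mixture — by default 70% of sites from
  Beta(1, 25) (almost all < 10% methylated), 20% from Beta(25, 1) (> 90%),
  the remainder uniform on [20%, 80%].
* **Effects**: a configurable fraction of sites is shifted by Δ percentage
  points in every non-control group, clipped to [0, 100]; the truth table
  records per-group true proportions.
* **SAM simulation**: one single-end read per call with an XM-style call
  string, high (40) or deliberately sub-threshold base qualities, and
  optional unmapped reads, so the reader's quality/coverage behavior can be
  verified by construction.

All generators are pure functions of their spec and seed (numpy PCG64).
What they do **not** emulate: spatial correlation of methylation along the
genome, context-dependent coverage (RRBS fragment enrichment), sequencing
error in the calls themselves, strand-paired CpG dyads, or overdispersion
between biological replicates beyond binomial sampling. Passing tests on
this data therefore demonstrate the correctness of the statistical
machinery, not robustness to every artifact of real libraries — in
particular, real replicates are often overdispersed, and the binomial
logistic test is anticonservative in that regime.

## Verification problem sizes

The verification suite and `scripts/acceptance.py` use: exhaustive Fisher
checks over all 2×2 tables with row margins ≤ 30 against exact integer
hypergeometric enumeration; null calibration on 2000 simulated units
(4-vs-4 logistic and 1-vs-1 Fisher, 30× coverage); power on 2000 units with
a +40-point shift at 10% of sites. The calibration simulations draw
baseline proportions uniformly from [20%, 80%] rather than from the bimodal
default: a calibration check targets the regime where the chi-square
reference is meaningful, whereas near-0%/near-100% sites yield degenerate
tables whose discrete null distribution makes *any* exact or asymptotic test
conservative (the exact Fisher test rejects well under 5% there by
construction). The power simulation draws baselines from the low mode only,
so that the planted +40-point shift is realizable without clipping at 100%.

## Known limitations

* No beta-binomial/overdispersion correction; no de novo DMR segmentation
  (fixed tiles and user regions only); no paired-end overlap deduplication.
* The SLIM π₀ estimator is a sliding-linear-model variant with the defaults
  stated above; it satisfies π₀ ∈ [0, 1], π̂₀ ≈ 1 under the global null and
  q_slim ≤ q_BH, but different published π₀ estimators can differ by a few
  percent on the same data.
* Fisher's two-sided p-value uses the point-probability convention; other
  conventions (doubling the one-sided p) give different values for
  asymmetric margins.
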