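# Methods

This note documents the models, the numerical choices and the synthetic
data behind `admixscan`, and states what the tests do and do not show.

## Scope and model

The pipeline targets a two-way admixed cohort (focal Native-American-side
ancestry, European admixing source) genotyped on a SNP array, with per-site
local-ancestry dosages from an external tool and a binary phenotype. Two
selection signatures are scanned:

1. **Pre-admixture sweeps** — PBSn1 computed on admixture-corrected focal
   frequencies against a sister population and an outgroup.
2. **Post-admixture selection** — per-site deviations of local-ancestry
   proportion from the genome-wide mean, stratified by case/control status.

All statistics are per-site functions of allele frequencies, sample sizes
and ancestry dosages; no haplotype information is used anywhere.

## Estimators and numerical choices

**Hudson FST.** Per site,
`[(p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)] / [p1(1-p2) + p2(1-p1)]`
with haploid sizes n1, n2 >= 2. The estimate is undefined (NaN) when both
populations are fixed for the same allele; such sites are skipped in
genome-wide aggregation and dropped (with a count) before PBS. Negative
per-site estimates are *retained*: clamping them to zero would bias the
genome-wide ratio-of-averages aggregate, which is used instead of the
average of per-site ratios.

**Branch transform.** `T = -ln(1 - FST)`, with FST clamped at `1 - 1e-8`
so fixed differences map to the finite `-ln(1e-8) ≈ 18.4` rather than
infinity. A test covers insensitivity to the exact clamp constant.

**Admixture correction.** `f* = (f_obs - alpha·f_EUR)/(1 - alpha)` with
per-site `alpha` = mean European dosage / 2. With noisy inputs the raw
value can leave [0, 1]; it is clipped with a per-site flag. Clipped sites
sit at exactly 0 or 1 and can produce large PBSn1 scores from correction
noise alone — visible in any scan of a modest cohort, and the reason the
scan table carries the flag. African ancestry is not modelled: the
correction is strictly two-way, matching the generator.

The corrected frequencies enter the FST estimator with an effective
haploid size `round(2·N·(1 - mean(alpha)))` — the chromosomes actually
carrying focal ancestry — since a corrected frequency estimated from a
cohort of N diploids is not as precise as 2N independent chromosomes.
The full `2N` is available via `effective_n=False`.

**Polymorphism filter.** A site monomorphic (frequency exactly 0 or 1) in
two or more of the three scan populations is dropped before PBS.

**PBS / PBSn1.** `PBS1 = (T12 + T13 - T23)/2` and cyclic permutations;
`PBSn1 = PBS1/(1 + PBS1 + PBS2 + PBS3)`, invalid when the denominator is
below 1e-8. The identity `PBS1+PBS2+PBS3 = (T12+T13+T23)/2` is enforced to
1e-12 in tests. Ranking ties break lexicographically on site id so output
is deterministic.

**QC.** Filters run in the fixed order: individual call rate, marker call
rate, MAF, HWE — the conventional order for the four named thresholds.
Defaults: call rates 0.90, MAF floor 0.01 (a MAF exactly 0.01 is
*removed*), HWE floor 1e-5. Allele frequencies use pairwise-complete
denominators. The HWE test is the exact conditional test (sum over
same-parity heterozygote counts with conditional probability <= observed,
computed in log space with a 1e-12 relative tie tolerance); the exact test
stays calibrated at low counts where the chi-square does not. HWE is
tested in the full cohort by default.

**GEV calibration.** Subsamples are drawn *without* replacement within a
replicate (sampling "from the full set" of scores). The GEV is fitted to
replicate maxima by maximum likelihood (SciPy's `genextreme`; shape
reported in the Coles convention, `xi = -c`), with the Gumbel case handled
as the continuous shape limit. At least 30 non-constant maxima are
required. Replicate means are returned for diagnostics but not modelled.
Tail probabilities are interpreted as `P(maximum of a size-m subsample >=
x)`; outside a bounded support the survival function returns exact 0 or 1.

**Ordered FWER.** `d` solves `prod_{k=1..n}(1 - d/k) = 1 - alpha` by
bisection to a residual below 1e-12 (the product is strictly decreasing in
d, so the root is unique on (0,1)). Rank k is tested at `d/k` with no
sequential gating — the reading under which the product is exactly the
no-false-rejection probability for independent tests — and a p-value equal
to its threshold is rejected. At alpha = 0.05, n = 10 the thresholds begin
0.017431, 0.008716, 0.005810 and end 0.001743.

**Association.** Additive logistic regression (IRLS via statsmodels GLM,
max 50 iterations, tolerance 1e-8), Wald p against the standard normal.
The coded allele is the derived allele, consistent with the scan
frequencies. Default covariates: age (years), sex, smoking (ever/never),
occupational risk factor (binary, mining folded in), and global
focal-ancestry proportion (on the proportion scale). Complete separation
is flagged and the p-value reported missing rather than fatal; a constant
dosage or single-class phenotype raises a typed error.

**Matched enrichment.** "Similar" background sites lie within ±5%
*relative* windows of the top site's recombination rate and derived-allele
frequency (a quantile-window mode is available). All top-set sites are
excluded from every pool; an empty pool falls back to the global
complement with a warning, and a zero covariate value collapses its window
to {0} (flagged). Null sets draw one site per pool without within-replicate
duplication — a vectorized collision-redraw resolves almost every
replicate, with an exact sequential pass and bounded whole-replicate
retries behind it; structurally impossible matchings (e.g. two pools
sharing a single member) raise an error. The observed top-k p-values are
compared against all reps x k pooled null draws by a one-tailed Welch
t-test (per-replicate-mean comparison available).

**Ancestry deviation.** The z statistic evaluates the binomial variance at
p0 (score-type standardization, stable under the null); Wald
standardization at `p_hat` is available. Two-sided p-values are reported,
with the deviation direction recoverable from the sign of z. When the
expected minor-class count `2N·min(p0, 1-p0)` is below 10 the normal
approximation is replaced by an exact two-sided binomial test. One shared
p0 — the whole-cohort genome-wide mean — is used for the whole-cohort,
cases and controls scans. The 5e-5 threshold is adopted as a constant.

## Synthetic data

The generator emulates the study design at the level the statistics
consume:

- **Panels.** Shared ancestral frequencies ~ Uniform(0.05, 0.95); each
  population's frequency ~ Balding-Nichols (Beta with mean = ancestral,
  dispersion set by its drift F). Defaults: outgroup EAS F = 0.09, sister
  MA F = 0.03, focal ANDES F = 0.03, source SPN F = 0.12, with panel sizes
  100/50/50/100 diploids. These drifts reproduce the study's
  differentiation ordering (focal-sister lowest, corrected-focal vs
  outgroup highest), verified over seeds in the tests. Balding-Nichols was
  chosen over coalescent simulation because the scan never touches
  haplotypes; frequency-level structure is exactly what is needed.
- **Cohort.** 200 diploids by default. Per individual and site, the
  focal-ancestry allele count is Binomial(2, theta) with theta = 0.44
  genome-wide; each focal allele is derived with the ANDES frequency, each
  European allele with the SPN frequency. Per-site truth (`alpha`, cohort
  frequency) is recorded. A site-level fast path draws the equivalent
  binomial totals directly — the exact distribution of the
  individual-level sums — and is used by many-seed recovery tests; the
  problem sizes the tests use (50,000 sites, 100 seeds for sweep recovery;
  20,000 sites, 50 seeds for the ancestry scan) were chosen to keep the
  default suite in the minutes range.
- **Planted signals.** A sweep pins the focal ancestor's derived frequency
  (default 0.95 against a pinned ancestral 0.2). An ancestry enrichment
  raises theta over an interval, in everyone or in controls only. The
  default controls-only enrichment is theta = 0.75: with balanced cases
  and controls this puts the whole-cohort ancestry mean near 0.6, the
  strength of the strongest deviations the scan design is meant to
  detect — a whole-cohort z near 6. (A controls-only enrichment of 0.60
  dilutes to a whole-cohort z ≈ 3.2, *below* the 5e-5 critical value 4.06,
  so the stratified filter retains only ~20% of such sites; a test pins
  this oracle-computed behaviour.)
- **Phenotype.** Covariates: age ~ Normal(60, 10), sex ~ Bernoulli(0.5),
  smoking ~ Bernoulli(0.4), occupational risk ~ Bernoulli(0.15) —
  arbitrary but configurable. Case status is Bernoulli with logit =
  intercept + beta·dosage(risk site) + covariate terms. When a
  controls-only enrichment is configured, balanced case/control *design*
  labels are assigned before cohort generation (a matched case-control
  design) and the logistic model is bypassed; the two signal types cannot
  be planted against the same labels otherwise.

**What the generator does not emulate.** Local ancestry is independent
across sites — no ancestry-tract LD — so the ancestry scan's null is
better behaved here than in real data, where admixture LD inflates the
tail; passing calibration tests bound the implementation's error, not the
field error of the method. There is no genotype LD, no three-way
(African) ancestry, no array artefacts, and sweeps are planted as
frequency overwrites rather than simulated trajectories.

## Design choices that were genuinely open

- Global FST as ratio-of-averages (the estimator literature's
  recommendation) rather than average-of-ratios.
- Per-rank thresholds without sequential gating in the ordered procedure.
- Relative (±5% of value) matching windows, with the quantile
  interpretation behind a flag.
- Pooled null comparison in the Welch test, with per-replicate means
  behind a flag.
- Score-type (null-variance) standardization in the ancestry scan, Wald
  behind a flag.
- Full-cohort HWE testing, controls-only behind a flag.

## Known limitations

- The admixture correction amplifies cohort sampling noise by
  `1/(1-alpha)`; clipped corrections concentrate at 0/1 and can dominate
  the extreme tail of small-cohort scans. Flags make this auditable but
  the scan does not model it away.
- The GEV tail probability conditions on the fitted subsample size; it is
  not a per-SNP p-value.
- The enrichment test's matching covariates (recombination rate, DAF) are
  the only confounders handled; B-value or gene-density matching is not
  implemented.
- `scan` assumes aligned site vectors across all populations; it does not
  harmonise strand or allele coding.
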