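# Methods

## Setting and model

`causalmr` implements summary-level two-sample Mendelian randomization.
For each genetic instrument j the inputs are estimated per-allele effects
on the exposure (β̂ₓⱼ, SE sₓⱼ) and on the outcome (β̂ᵧⱼ, sᵧⱼ), from two
non-overlapping GWAS samples. The working model is

    β̂ᵧⱼ = θ·γⱼ + αⱼ + εⱼ ,   γⱼ = true exposure effect,

with θ the causal effect (a log odds ratio when the outcome is binary) and
αⱼ a horizontal-pleiotropy effect, zero for a valid instrument. Different
estimators are consistent under different assumptions on {αⱼ}: IVW needs
all αⱼ = 0 (or balanced pleiotropy in the random-effects sense), the
weighted median needs a valid majority of weight, MR-Egger needs αⱼ
independent of γⱼ (InSIDE), and the contamination mixture needs a
plurality of exactly valid instruments.

## Harmonization

Exposure and outcome tables are intersected on variant id (no proxy
substitution). Outcome rows whose allele coding is swapped get β negated
and the effect-allele frequency complemented; codings that match only
after base complement are treated as strand flips and rescued (flagged in
the output). Palindromic variants (A/T or C/G) carry no strand information
in their labels, so their orientation is decided purely by which choice
puts the exposure and outcome frequencies on the same side of 0.5. Under
the default `drop_ambiguous` policy a palindrome whose **exposure**
effect-allele frequency lies strictly inside (0.45, 0.55) is dropped as
unresolvable; `drop_all` (the sensitivity-analysis switch) drops every
palindrome; `align_by_frequency` keeps all. The frequency window is
evaluated on the exposure study because that is where instruments are
defined; this choice is a documented assumption. Every excluded variant
appears in an audit list with a reason, and
|intersection| = |retained| + |dropped| always holds.

## Estimators and numerical choices

* **IVW.** Wald ratios θ̂ⱼ = β̂ᵧⱼ/β̂ₓⱼ with first-order SEs σⱼ = sᵧⱼ/|β̂ₓⱼ|
  are averaged with weights σⱼ⁻². The default is multiplicative random
  effects — the fixed-effect SE inflated by max(1, √(Q/(L−1))) — because
  moderate-to-high ratio heterogeneity is the norm for complex-trait
  exposures; a `fixed` switch exists. The IVW estimate is algebraically
  the zero-intercept weighted least-squares slope of β̂ᵧ on β̂ₓ with
  weights sᵧ⁻², an identity the tests assert numerically.
* **Cochran's Q** about the IVW mean, referred to χ²(L−1).
* **MR-Egger.** Instruments are oriented so β̂ₓⱼ > 0 (results are invariant
  to input orientation), then β̂ᵧ is regressed on β̂ₓ with weights sᵧ⁻² and
  a free intercept. Coefficient SEs carry the overdispersion factor
  max(1, √(RSS_w/(L−2))). The intercept estimates the mean directional
  pleiotropy; its two-sided p-value is the pleiotropy test.
* **Weighted median.** Ratio estimates sorted ascending; the estimate
  interpolates at cumulative mid-weight 0.5. The SE comes from a
  parametric bootstrap (θⱼ* ~ N(θ̂ⱼ, σⱼ²), 1000 draws by default, seed
  mandatory in the API so results are reproducible by construction).
* **Contamination mixture.** Each instrument contributes the larger of a
  valid log-density N(θ̂ⱼ; t, σⱼ²) and an invalid log-density
  N(θ̂ⱼ; 0, σⱼ² + ψ²), profiled over a 10 001-point grid spanning
  [min θ̂ − 3·max σ, max θ̂ + 3·max σ]. ψ defaults to 1.5× the SD of the
  ratio estimates. The 95% confidence set collects grid points within
  χ²₁(0.95)/2 log-likelihood units of the maximum; it may be a union of
  intervals and is reported as its envelope plus a multimodality flag.
* **P-values** are two-sided from the normal reference throughout; all
  confidence intervals are estimate ± z₀.₉₇₅·SE.

## MR-PRESSO

The observed statistic is RSS = Σⱼ wⱼ(β̂ᵧⱼ − θ̂₋ⱼ·β̂ₓⱼ)², wⱼ = sᵧⱼ⁻², with
θ̂₋ⱼ the leave-one-out IVW slope. Its null distribution is simulated by
drawing outcome effects around the leave-one-out fitted values with SDs
sᵧⱼ (1000 replicates by default, add-one smoothing so the global p is
never 0). The per-variant test compares each observed residual
contribution with its simulated null; raw empirical p-values are
Bonferroni-multiplied by L and flagged below α = 0.05. Because the
smoothed empirical p cannot fall below 1/(n_sim+1), the outlier test
automatically raises its simulation count to ⌈L/α⌉ whenever the
configured count is too small for the adjusted-p floor to reach α — with
1000 simulations and 100 instruments no variant could ever be flagged
otherwise. Outlier removal is one-shot, not iterative. The distortion
statistic (raw − corrected)/|corrected| is referred to the distribution
obtained by deleting 500 random subsets of the same size (seeded).

## Multivariable MR and mediation

Direct effects come from zero-intercept weighted least squares of β̂ᵧ on
the L×m matrix of exposure effects (weights sᵧ⁻², overdispersion factor
max(1, √(RSS_w/(L−m)))). With m = 1 this reduces exactly to univariable
IVW. The joint instrument set is the union of the per-exposure selections,
re-clumped at the same r² threshold keeping the smallest exposure p.

The mediated proportion is the difference method, 1 − direct/total on the
log-odds scale, with a delta-method SE. The total (univariable IVW) and
direct (MVMR) estimates are computed from the *same* outcome summary
statistics and are therefore strongly positively correlated; treating
them as independent makes the proportion's CI far too wide (empirical
coverage ≈ 100% instead of 95%). Both estimators are linear in the
outcome effects, so their covariance is available in closed form,
cov = Σⱼ aⱼcⱼsᵧⱼ² over shared instruments (aⱼ, cⱼ the two linear weights,
rescaled by each fit's overdispersion factor), and `mediation_study`
plugs it into the delta method; with it, coverage of the true mediated
proportion is at its nominal level in the simulation suite. The
lower-level `mediation()` function keeps covariance 0 as its default so
externally supplied, genuinely independent estimates are handled
conservatively; a seeded parametric bootstrap cross-checks the SE.
Proportions outside [0, 1] are reported as computed, never truncated.

## Meta-analysis, tiers, instrument strength, power

Discovery and replication IVW estimates are combined by fixed-effect
inverse-variance meta-analysis (the two-cohort convention; sensitivity
estimators are reported per stage, not combined). Associations are tiered
with a Bonferroni threshold 0.05/n_exposures — strict `<` for
"significant", the closed interval up to 0.05 for "suggestive".

Instrument strength: variance explained R² = Σⱼ 2fⱼ(1−fⱼ)βⱼ² on a
standardized exposure, and F = R²(n−k−1)/((1−R²)k), flagged weak at
F ≤ 10. Power for a binary outcome uses the standard summary-level
approximation power = Φ(|ln OR|·√(N·R²·P(1−P)) − z₁₋α/₂) with N the total
outcome sample and P its case fraction; the detectable OR at a target
power inverts this closed form, so the round trip is exact by
construction. This closed form is this package's definition of the power
calculation; published detectable-OR tables computed with other tools
agree only approximately (±0.02 on the OR scale is typical).

## Synthetic data: what it emulates, and what it does not

The generator mirrors the regime of a large continuous-trait exposure GWAS
(default n = 500 000) paired with a binary-outcome GWAS of
discovery-cohort shape (default 778 614 samples, case fraction 0.01083 —
8434 cases). Standard errors follow 1/√(2f(1−f)n), times 1/√(P(1−P)) on
the log-odds scale for a binary outcome, which makes the variance
explained, F statistics and power formulas mutually consistent. Instrument
effects default to γ ~ U(0.03, 0.10) with minor-allele frequencies
U(0.05, 0.50): about 0.13 variance explained at L = 100, inside the range
of well-powered metabolic-trait GWASs, with every instrument individually
genome-wide significant. Pleiotropy regimes: `balanced` (αⱼ ~ N(0, 0.01²)
for every instrument), `directional` (mean 0.05), `inside_violating`
(αⱼ correlated with γⱼ, correlation 0.5 by default). Outliers add
`outlier_shift`×sᵧⱼ (8 SEs in the test scenarios) to a random fraction of
outcome effects, one-sided. Replication cohorts remeasure the same
variants (same alleles, frequencies, γ, α) with fresh noise and their own
sample size. Allele bookkeeping is realistic but statistically inert: 5%
of variants are palindromic with frequencies clear of the ambiguity
window, and the outcome table re-codes 30% of rows (plus 10% strand
flips) for harmonization to undo.

Not emulated: sample overlap between the two GWAS, linkage beyond the
explicit block generator, winner's-curse selection effects, population
stratification, and individual-level genotypes. Passing simulation suites
therefore demonstrates correctness of the estimators under their stated
assumptions, not robustness to those additional real-data complications.

## Known limitations

* **Contamination mixture at low per-instrument precision.** With a
  binary outcome of discovery-cohort size, ratio-estimate SEs are 0.2–1.2
  around a true θ = 0.2. In that regime the contamination mixture with
  its conventional ψ default is measurably biased away from zero
  (≈ +0.04 here, about one per-replicate SD): instruments whose noisy
  ratio lands near 0 are absorbed by the invalid component centered at 0.
  The bias disappears as ψ grows (the estimator then tends to IVW) and in
  high-precision regimes; the implementation is verified against a
  brute-force classification-enumeration oracle. Treat ConMix point
  estimates as a consistency check, not a primary estimate, when the
  outcome GWAS is small.
* **MR-PRESSO correction is not a guarantee.** Removing correctly flagged
  outliers brings the estimate closer to the truth in most but not all
  replicates; with k outliers of displacement d·SE among L instruments
  the improvement probability is bounded near Φ(d·k/(2√L)) even in the
  most favorable equal-strength, one-sided case (≈ 0.88 for 3 outliers at
  8 SE among 100), because correction removes bias but not the shared
  sampling noise.
* The per-variant outlier test needs ⌈L/α⌉ simulations to be able to flag
  anything; runtime grows accordingly for large instrument sets.
* Mediation SEs assume the exposure-side covariance between total and
  direct fits is second-order (exposure GWAS much larger than outcome
  GWAS); with a small exposure GWAS the closed-form covariance
  underestimates the dependence.

## Problem sizes used by the verification suites

Simulation suites use L = 100 instruments with 500 replicates for null
calibration, 300 for effect recovery and mediation coverage, and 200 for
MR-PRESSO detection; `scripts/acceptance.py` re-runs the same designs from
scratch with seeds derived from its `--seed` argument.
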