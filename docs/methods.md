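# Methods

This note documents the models, estimators and numerical choices behind
`countersignal`, and what the synthetic-data tests do and do not establish
about real bioassay data.

## The assay and its mass balance

A male is held in a static bucket of *V* = 3 l. Released pheromone
accumulates for 30 min; a 50 ml water sample is withdrawn; 1 ml of treatment
solution (isotope-labelled pheromone or vehicle) is added; a second sample
follows 10 min later. With measured concentrations c_b, c_p (ng ml⁻¹):

* baseline rate x = c_b · V_ml · (60/30) · 10⁻⁶ mg h⁻¹;
* post rate y from the incremental mass
  Δm = c_p·V_post − c_b·(V_ml − 50), with V_post = V_ml − 50 + 1, over the
  10 min window.

The incremental reading is the only mass-balance-consistent way to assign a
rate to the post window: the bucket still contains what accumulated before
treatment. The 50 ml withdrawal and 1 ml addition are carried through the
volumes by default (`volume_correction`); freezing the volume at 3 l is
supported because published assay descriptions do not always state whether
such corrections were applied, and with both samples quantified at the same
volume the two conventions differ by under 2%.

If Δm ≤ 0 the male was not observed to release during the post window and
the record is flagged rather than given a negative rate. Exclusion rules
run in a fixed order so audit counts are deterministic: missing sample →
internal standard undetected → no concentration increase → release never
above the lake-water threshold (0.00025 mg h⁻¹, the maximum rate computed
from unconditioned lake water). The threshold is applied to the *larger* of
the two rates by default ("did not release more than lake water"), with a
baseline-only mode available. Background subtraction (mean lake-water
concentration 0.006 ng ml⁻¹) is off by default and available as a flag.

Molar conversions use the free-acid molar mass 472.64 g mol⁻¹ for the
natural analyte and the sodium salt 494.62 g mol⁻¹ for treatment masses:
the salt value reproduces the conventional "0.74 ng at 5 × 10⁻¹³ M in 3 l"
figure exactly, which suggests treatment solutions are prepared from the
salt; both constants are exposed.

## Synthetic experiments

The generator draws, per male (counter-based substream per
(seed, series, arm, male), so resizing one arm never reshuffles another):

* baseline rate log₁₀x ~ N(μ₁₀, σ₁₀²), defaults μ₁₀ = −2.0, σ₁₀ = 0.5
  (typical spermiating-male release rates of ~10⁻² mg h⁻¹ spanning roughly
  two orders of magnitude across males);
* with probability `low_releaser_prob`, a −2.5 shift of log₁₀x (immature
  males that release essentially nothing; 0 by default, 0.3 in the Series-3
  preset to emulate the maturity problems of that series);
* response ln(fold) = α(treatment) + β·(ln x − μ_ln) + ε,
  ε ~ N(0, 0.25²). α = ln 2.5 for arms at or above the 5 × 10⁻¹³ M response
  threshold and 0 for controls and sub-threshold arms; β = −0.3. The
  anchors: observed quartile summaries of responders put post-exposure
  release near 325% of baseline in the lowest baseline quartile and 200% in
  the third quartile ("% of baseline" reads fold-change × 100, per the
  end/baseline definition); α = ln 2.5 ≈ ln(250%) sits between them and
  β = −0.3 reproduces the decline. β applies to every male (controls
  included): marginally their median fold-change remains 1, which is the
  observed behaviour of unexposed males;
* lake-water background concentration ~ N(0.006, 0.004²) ng ml⁻¹ truncated
  at 0 (zero in the Series-1 preset, which uses deionized water);
* multiplicative lognormal measurement error with unit mean and CV 0.05 on
  each concentration (LC-MS-scale precision);
* internal-standard failure with probability 0.02 per sample.

Concentrations are then produced by the same mass balance the quantifier
inverts, so with all noise off and α = β = 0 the recovered fold-change is 1
to machine precision — the generator and quantifier are exact inverses.

What the generator does *not* emulate: temporal drift within a window
(release is treated as constant-rate), correlated assay batches/sets,
heavy-tailed or censored LC-MS errors near the quantification limit, and
any decrease of release under treatment (one real series showed a
significant *drop* at 5 × 10⁻¹⁵ M; the generator's sub-threshold arms are
pure nulls). Passing tests therefore establish correctness of the
statistical machinery under a realistic but well-behaved data-generating
process, not robustness to every pathology of field data.

## Rank-based treatment × time analysis

All N observations are converted to global mid-ranks R; the relative
treatment effect of cell (g, t) is p̂_gt = (R̄_gt − ½)/N. For a hypothesis
with projection matrix T (Kronecker products of centring and averaging
matrices over the factor levels), the ANOVA-type statistic is

    A = N · p̂ᵀ T p̂ / tr(T Ŝ),

with Ŝ the block-diagonal estimate of Cov(√N p̂) built from the empirical
covariance of each group's subject rank vectors. Numerator df
f = tr(TŜ)²/tr(TŜTŜ) (Box approximation). All effects are referred to
F(f, f₀) with denominator df f₀ = tr(TŜ)²/Σᵢbᵢ²/(nᵢ−1), bᵢ the trace of
group i's diagonal block of TŜ. The more common F(f, ∞) reference is
measurably anticonservative at bioassay group sizes — in our null
simulations (two lognormal groups of 10, 10 000 replicates) it rejects at
0.064–0.074 at nominal 0.05, versus 0.046–0.049 for F(f, f₀); the two
coincide as group sizes grow. Published ATS values computed under the
F(f, ∞) convention have identical statistics and numerator df, only
slightly smaller p-values.

Ties take global mid-ranks throughout, which yields the complete-tie
identity RTE = 0.5 exactly. A singular covariance estimate (e.g. a group
with identical rank vectors) raises an error suggesting more replicates.

The subject-relabelling permutation test for the interaction is the
package's internal oracle. For two groups the interaction projection has
rank 1 and the ATS reduces exactly to a Welch statistic on within-subject
rank differences d_k = R_baseline,k − R_post,k, which is evaluated fully
vectorised across permutations; the reduction is verified against the
general path in the test suite.

Series whose vehicle control collapses under QC (the Series-3 situation)
are analysed by a cascade that uses each male's baseline as his own
control: an exact Wilcoxon signed-rank test per treatment arm first, then a
treatment × time ATS restricted to the arms that showed a significant
increase. Arms with fewer than `min_group_n` (default 6) surviving males
are dropped from factorial analysis, with each drop logged.

## Exact Wilcoxon signed-rank

Zero differences are dropped and n reduced (Wilcoxon's convention). For
n ≤ 20 the distribution of W⁺ over all 2ⁿ sign assignments is built by
dynamic programming on doubled ranks (mid-ranks are half-integers), so
exact p-values are available under ties — the regime of 4–13 males per arm.
The two-sided p is min(1, 2·min(one-sided p's)): with ties the enumeration
distribution can be asymmetric, and doubling is the convention that keeps
one- and two-sided values consistent. Above n = 20 the normal approximation
with tie and continuity corrections takes over.

## Coupling-corrected baseline-dependence test

The question: does the fold-change y/x depend on the baseline x? The naive
test of corr(x, y/x) = 0 is inflated by mathematical coupling — x appears
in both variables — and rejects on the majority of *independent* (x, y)
datasets. The corrected test compares the observed correlation with the
null correlation expected from coupling alone,

    r_null = −√((1 − r_xy)/2),

which is the exact correlation of u with v − u for uncorrelated
equal-variance (u, v). Three numerical choices matter:

1. **Log scale.** Correlations are computed between ln x and
   ln(y/x) = ln y − ln x (and r_xy between ln x and ln y). On the log scale
   the ratio is a difference and r_null is exact for equal log-variances;
   on the raw scale the formula does not describe the coupled null of
   skewed rate data at all (simulated type-I error ≈ 1 at n = 160).
   Release rates are lognormal-like, making the log scale the natural home
   of the analysis.

2. **Standard error.** r_null is estimated from the same sample as r_obs,
   and the two Fisher transforms are positively correlated. Delta-method
   algebra at the uncoupled null (derivative of z(r_null) in r_xy is
   1/(4q(1−q²)) = 1/√2 at q = 1/√2, with asymptotic correlation between
   the estimates making Var(z_obs − z_null) ≈ 1/(2(n−3))) gives
   z = (z(r_obs) − z(r_null))·√(2(n−3)). Simulated type-I error is
   0.047–0.051 for n ∈ {40, 50, 160}; the uncorrected SE 1/√(n−3) yields a
   conservative 0.006 and is available via `variance_corrected=False`.

3. **Null formula reading.** An alternative algebraic reading,
   r_xy − (1 − r_xy)/2, is exposed as `null_method="literal"`; it is
   grossly miscalibrated on the same nulls (rejection > 0.5) and the
   permutation oracle's empirical null mean lands on −√((1 − r_xy)/2), not
   on it. The test suite records both facts rather than silently dropping
   the variant.

The permutation oracle shuffles y against x and recomputes r(x, y_perm/x):
pairing is destroyed, coupling retained. Its p-value (add-one smoothed,
two-sided around the empirical null mean) is reported alongside the
analytic test in the pipeline.

Scope of the null: the test asks whether (x, y) deviate from the
*uncoupled* benchmark in which y carries no relation to x. Data where y
tracks x proportionally (fold-change independent of baseline, β = 0) sit
between the coupled null and r_null and can register as positive z; the
test is a one-benchmark comparison, not a regression decomposition. Both
formulas also assume equal log-variances of x and y, which holds under the
generator and approximately in fold-change data where var(ln y) ≈ var(ln x).

The pipeline pools males from every treatment arm with a significant
exposure response (post hoc vs control, or Wilcoxon increase in cascade
series) at the configured α; a fixed pooling list can be forced through the
config. The quartile summary reports post-exposure release as a percentage
of baseline (fold × 100) by baseline quartile.

## Determinism and problem sizes

Every stochastic stage takes an explicit seed; the pipeline derives
per-stage seeds from one master seed, and identical config + seed produces
byte-identical CSV report tables (fixed float format `%.12g`).

Simulation-based checks use: 10 000 replicates at n = 160 for coupling
calibration; 500 seeded 160-male experiments for sign recovery of β; 5000
null replicates (two groups of 10) for ATS type-I error; 200 datasets ×
2000 permutations for ATS/permutation agreement; 100 datasets with n ≤ 12
against the brute-force Wilcoxon enumeration. These sizes give Monte-Carlo
standard errors a few times smaller than the tolerance bands they are
tested against while keeping the full suite in the low minutes on one CPU.

## Known limitations

* The ATS implementation covers one whole-plot factor × two timepoints
  (the design of these assays); no multi-factor or >2-timepoint designs,
  no RTE confidence intervals, no missing-data weighting.
* The coupling test offers no Oldham-style averaged-variable alternative
  or measurement-error deconvolution; with substantial assay noise in x,
  regression to the mean contributes to the negative association and is
  not separated from a biological baseline effect.
* The generator's response threshold is sharp (full response at or above
  5 × 10⁻¹³ M, none below); real dose-response transitions are presumably
  smooth.
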