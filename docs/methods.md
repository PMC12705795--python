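# Methods

This note documents the statistical machinery, the generative model behind
the synthetic data, the numerical conventions, and the known limitations of
`newssdt`.

## Rating-scale ROC statistics

Each (participant, phase) group holds ratings of true and fake items on a
1..K scale.  For criteria k = K..2 the operating point is

    HR(k)  = #(true items rated >= k) / n_true
    FAR(k) = #(fake items rated >= k) / n_fake

Cumulative proportions are used as-is: no log-linear (Snodgrass-style)
correction is applied.  With only two true items HR is granular ({0, .5, 1})
and boundary values are frequent; the trapezoidal integral is well defined
there, and a smoothing correction would change the estimand.

**Criterion set.**  The k = 1 criterion is excluded throughout: its
operating point is structurally (1,1) and its B"D is the constant -1, so it
carries no information and would only shift every participant's bias mean
toward the liberal end by the same amount.  Both the ROC points and the B"D
average therefore use the K-1 informative criteria k = K..2 (six points for
K = 7).  The policy is recorded in the analysis manifest.

**AUC.**  The polyline runs from (0,0) through the points in order of
decreasing criterion (cumulative, hence non-decreasing in both coordinates)
to (1,1); exactly coincident consecutive points are dropped (zero-width
segments do not change the area).  The trapezoidal area equals the tie-aware
pairwise concordance P(r_true > r_fake) + 0.5 P(tie) over all true x fake
item pairs; the test suite asserts this identity exactly on >= 1000 random
groups, which is the strongest available oracle for the implementation.

**B"D.**  Donaldson's index B"D = [(1-HR)(1-FAR) - HR.FAR] /
[(1-HR)(1-FAR) + HR.FAR] is averaged unweighted over the criterion set.
The formula is 0/0 at the two separation corners (HR,FAR) = (1,0) and
(0,1); those points are assigned 0.  Any constant is a convention; 0 is the
neutral one (a perfect separation point says nothing about bias) and keeps
the average defined for perfect discriminators.

**Estimator bias at few items.**  With 2 true / 6 fake items per phase the
mean-B"D estimator is not unbiased for the population value: the nonlinear
map from noisy proportions to B"D leaves a residual that depends on d'.
Numerically (400k simulated participants): at the study-like configuration
the residual moves by about -0.009 per +0.12 of d'.  This is a property of
the statistic itself, not of the implementation; it disappears as item
counts grow (the strong-signal test uses 25/25 items for exactly this
reason), and it sets the size of the discrimination shift used in the
recovery calibration (below).

## Inference battery

* **Paired t-tests** use the classical statistic with two-tailed p from the
  central t distribution on n-1 df; dz = mean(diff)/SD(diff) = t/sqrt(n).
  All-zero differences are guarded as t = 0, p = 1, dz = 0 with a runtime
  warning (tiny or degenerate fixtures otherwise crash the pipeline);
  constant non-zero differences raise an error, as t is genuinely undefined
  and the direction certain.
* **JZS Bayes factors.**  BF10 for a t statistic is the ratio of the
  marginal likelihood of t under a Cauchy(0, r) prior on the standardized
  effect (noncentral-t likelihood, ncp = delta*sqrt(n)) to the point-null
  likelihood, integrated adaptively to relative tolerance 1e-8.  The default
  prior scale is r = sqrt(2)/2 ("medium"), the convention of the standard
  software for these tests; it is configurable everywhere (`rscale`).  An
  independent fixed-grid quadrature (tan substitution, 1e6 nodes) agrees to
  1e-4 relative error in the tests.
* **Power analysis** finds the minimal n whose exact noncentral-t power
  (ncp = dz*sqrt(n), df = n-1) reaches the target, by doubling plus
  bisection; dz = 0.30, alpha = .05, power = .95 two-tailed gives n = 147.
* **2x2 mixed ANOVA** (test: pre/post within; condition: set A/B between)
  is computed by the split-plot sum/difference-score decomposition.  The
  within main effect and the interaction use unweighted (type III) cell
  means, so results follow the psychology convention (afex/ez/SPSS) for
  unbalanced groups; with balanced groups all conventions coincide.
  Generalized eta-squared treats the between factor as *observed*: every
  denominator pools the condition and interaction sums of squares with both
  error terms, and an effect's own SS is added only when the effect involves
  no observed factor.  Fully degenerate data (no variance anywhere) report
  F = 0, p = 1, ges = 0.
* **ANOVA Bayes factors** are Monte-Carlo estimates under the standard
  g-prior linear mixed model: orthonormal sum-to-zero contrasts per factor,
  participant as an additive random factor, independent scaled
  inverse-chi-squared priors on the g of each block (scale 0.5 for fixed
  effects, 1.0 for the random factor).  Conditional on g the Bayes factor
  against the intercept-only null is closed-form; the g-mixture is averaged
  over prior draws (g = r^2/chi^2_1), in log space for stability, with the
  Monte-Carlo standard error reported.  Main-effect BFs compare
  participant+effect against participant; the interaction BF compares the
  full model against the two-main-effect model.  These values carry MC error
  by construction and are reported with `~=`; they are not expected to
  reproduce any published ANOVA BF digit-for-digit.
* **Mean-ratings tests**: per category (Control, Conspiracy, Discrediting,
  Impersonation), participant-level mean ratings per phase compared with the
  paired t-test.  Provided deliberately: contrasting them with the ROC
  statistics is the point of the package.

## Generative model (synthetic data)

Equal-variance Gaussian SDT: participant i draws d'_i ~ N(dprime_mean,
dprime_sd^2); true items emit evidence N(d'_i + item offset, 1), fake items
N(0 + item offset, 1); the rating is 1 + #(criteria below the evidence).

The K-1 ordinal criteria form an equally spaced grid anchored at the
participant's *unbiased point*:

    c_j = d'_eff/2 + criterion_center + delta_criterion*[post] + spread*(j - K/2)

Anchoring at d'_eff/2 (the current phase's midpoint) is what makes the two
experimental dials orthogonal: `delta_criterion` shifts all criteria equally
(a pure response-bias manipulation that leaves the latent separation — and
hence the AUC — untouched), while `delta_dprime` changes separation without
changing the observer's bias relative to their own sensitivity.  With fixed,
non-anchored criteria a d' shift mechanically drags B"D by about -0.11 per
0.3 d' even in the population, which would make "discrimination-only" shifts
impossible to express.  Criteria are modelled as deterministic given d'
(no criterion jitter across items).

Defaults emulate the study design the package targets, chosen from
population calculations before any pipeline run and then frozen:

| parameter | default | rationale |
|---|---|---|
| n_participants | 150 | study sample size |
| n_true/n_fake per phase | 2 / 6 | study item counts |
| scale_max | 7 | 1..7 reliability scale |
| dprime_mean | 0.87 | population AUC Phi(d'/sqrt 2) = .73, the reported mean |
| dprime_sd | 0.3 | reproduces the reported per-participant AUC SD (~.21) |
| criterion_center | 0.16 | slight conservative offset, mean B"D ~ +.02-.05 |
| criterion_spread | 0.6 | realistic 1..7 rating marginals; B"D SD ~ .30 |
| completion time | N(1560 s, 300 s) | ~26 min mean completion |

Counterbalancing alternates participants deterministically between Set A
(item set A in the pre-test) and Set B (the reverse); `randomize_sets=True`
draws the assignment from the seeded generator instead.  `item_effect_setA`
/ `item_effect_setB` add a constant to the evidence of every item of that
item set, modelling non-counterbalanced item difficulty; making one item
set look less reliable reproduces the set-specific bias pattern that
motivates counterbalancing in the first place.

What the simulator does **not** model: headline content and political
congruence, unequal evidence variances, criterion jitter, participant
dropout or missing ratings, response times beyond a completion-time column.
Passing tests on simulated data therefore demonstrate the pipeline's
statistical behaviour under the stated model, not claims about any real
population.

## Calibration and recovery study conditions

The property-based acceptance checks run at study size (150 participants,
2/6 items) with these conditions, chosen a priori from the calculations
above:

* bias-only shift: delta_criterion = 0.3 (mean B"D moves by ~ +0.17, the
  AUC paired test stays at its nominal 5% level; 200 replicates, 3-SE
  binomial band);
* discrimination-only shift: delta_dprime = 0.12 (AUC change ~ +0.026,
  detected at > 5 MC standard errors and consistent with the closed-form
  target Phi((d'+delta)/sqrt(2+sd^2)) - Phi(d'/sqrt(2+sd^2)); the B"D
  paired test stays within the nominal band because the estimator residual
  at this shift size, ~ -0.009, is below Monte-Carlo resolution);
* type-I calibration: 500 replicates of the full null, both primary tests
  within 0.05 +/- 3 SE;
* confound demonstration: 50 replicates of the bias-only shift; the
  fake-news mean-rating test rejects in > 90% of replicates while the AUC
  test stays nominal.

Replicate counts are the package's own balance between the tightness of the
binomial bands and the cost of a default test run; the suite completes in
about two minutes.

## Numerical conventions and edge cases

* Exclusion threshold: mean - 3 SD of completion times with the sample
  (n-1) SD, computed over the table passed in, before removals; exclusion
  requires being strictly below the threshold, so an all-identical-times
  sample excludes nobody.  Raw seconds are used (no log transform).
* CSV I/O is strict: required header, integer ratings (no float coercion),
  case-insensitive categorical codes canonicalized on read; completion
  times are parsed with round-trip float precision so write-then-read is
  the identity.
* All stochastic procedures take explicit integer seeds and use local
  `numpy.random.Generator` state; replicate seeds are spawned from a
  `SeedSequence` and kept below 2^31.
* Quadrature failures, unreachable power targets (n > 1e7) and degenerate
  variance structures raise typed exceptions rather than returning NaN.

## Known limitations

* The mean-B"D estimator's d'-dependent small-sample residual (above) means
  "bias" comparisons between conditions that also differ strongly in
  discrimination should be interpreted with care at 2/6 items.
* The ANOVA Bayes factors use simple prior sampling for the g-mixture; the
  MC standard error is honest but larger than importance-sampling schemes
  would give, particularly for very large effects (where the BF's order of
  magnitude, not its digits, is the usable quantity).
* The mixed ANOVA is specialised to the 2x2 (one within, one between,
  two levels each) design of this paradigm; it is not a general ANOVA
  engine.
* No parametric SDT fitting (maximum-likelihood d', unequal-variance
  models): the analysis is deliberately the nonparametric-empirical one.
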