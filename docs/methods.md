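# Methods

`trajmix` reimplements, on synthetic data, a longitudinal analysis of
"youthful" neurocognition in older adults living with HIV: participants are
followed for up to ten six-month visits, their neuropsychological
performance is normed against young-adult ("peak-age") expectations, and a
growth mixture model (GMM) sorts the resulting trajectories into latent
classes that are then characterised with baseline health and reserve
measures.  This note records the models, the defaults, and the design
choices made where the design was genuinely open.

## Synthetic cohort generator (`trajmix.synth`)

The generator emulates a cohort of 184 older adults with HIV observed at 10
six-month visits.  For participant *i* at visit *t* (time coded
t = 0, 1, ..., 9 in visit units), the global peak-age T-score follows

    y_it = (a0k + b0i) + (a1k + b1i) t + a2k t^2 + e_it

with latent class k, random intercept b0 ~ N(0, 1.8^2), random linear slope
b1 ~ N(0, 0.2^2), and residual e ~ N(0, 3.5^2).  The class growth means and
mixing proportions default to the published estimates:

| class | share | intercept | linear | quadratic |
|---|---|---|---|---|
| 1 (stable elite) | 31/184 | 49.62 | 0.04 | 0.04 |
| 2 (quadratic average) | 100/184 | 41.91 | -0.45 | 0.07 |
| 3 (quadratic low) | 53/184 | 34.22 | -1.04 | 0.12 |

The emulated study does not report within-class variance components, so
they had to be chosen.  They are calibrated once so that the model-implied
classification entropy of the true 3-class model is 0.919, matching the
published entropy of 0.918, and the per-visit within-class spread
(sqrt(1.8^2 + 3.5^2) ~ 3.9 T-points) is consistent with the published
trajectory plots.  The published share percentages (16.8/54.3/28.8) round
from class counts 31/100/53 of 184; the exact count fractions are used so
the probability vector sums to one.

Baseline covariates reproduce the published descriptives (age 52.9 +/- 3.9
truncated at 50, education 13.1 +/- 2.6, WRAT4 reading 93.5 +/- 15.4
correlated 0.51 with education, 82% male, race/ethnicity mix 46/43/9/2%,
PAOFI and BDI-II as overdispersed counts).  Class membership is assigned by
a multinomial logit on (age centred, PAOFI count, latent physiologic-reserve
z, cognitive-reserve z) whose coefficients are the natural logs of the
published per-unit odds ratios; the two free intercepts are calibrated
numerically so the expected class shares equal the configured mixing
proportions.  Covariates are independent of the trajectory residuals given
class, so the 3-step analyses have a known truth (MAR).

Dropout is monotone by default: from visit 1 onward a participant drops
with per-visit hazard `logit^-1(-2.2 - 0.10 (educ - 13.1) + 0.5 date_z)`,
which yields a median of ~6 observed visits, 40-80% coverage at follow-up
visits, and Spearman correlations between missing-visit counts and
education / enrollment date of about -0.15 and +0.3, emulating the
published missingness pattern.  Intermittent (non-monotone) missingness is
available behind a flag.  Visit 0 is always observed.

Raw domain scores are produced by inverting the norming transform: domain
peak-age T-scores scatter around the global score with a centred SD-8
deviation across the seven domains, and raw = (age-25 norm prediction) +
(T-50)/10 x residual-SD + practice gain.  The generating norm regression
uses a -0.10 raw-points/year age slope, so chronological norms are ~2.8
T-points more lenient than peak-age norms at the cohort's mean age.  The
default practice-gain schedule (0, 1.5, 2.0, 2.2, then 2.3 onward, raw
units) emulates a typical retest effect; the no-change retest sample used
to estimate it carries reduced residual noise so the schedule is estimable
with modest samples.  Under these defaults the baseline SuperAger
prevalence lands near 21% (target ~19%), with ~33% cognitively normal and
~45% impaired.

The 39 health items are Bernoulli draws with per-class deficit rates
(0.28/0.29/0.33), giving mean reserve indices near the published 0.72/0.71/
0.67 class gradient.  These items are intentionally distinct from the
latent physiologic-reserve z used in the class logit: the z is the "true"
reserve construct, the items its measured operationalisation.

What the generator does not emulate: site effects, individual test items,
informative (MNAR) dropout, practice effects that differ by test, or
covariate-trajectory dependence within class.  Passing recovery tests
therefore show the estimator is correct under MAR and correct model
specification, not that real cohorts satisfy those assumptions.

## Norming (`trajmix.norming`)

Per-domain norms are linear main-effects regressions of raw score on age,
education, sex, and race/ethnicity, fitted by least squares on a normative
sample; the residual SD defines the T-score unit:

    T = 50 + 10 (raw - prediction) / residual_SD

The peak-age transform substitutes age 25 into the prediction, so T = 40
means one SD below the expectation for a demographically matched
25-year-old.  No T floor or ceiling is applied.  Predicting for a
race/ethnicity level absent from the normative sample raises an error
rather than extrapolating.  Practice effects are corrected as additive
visit-indexed raw-score adjustments estimated from a no-true-change retest
sample; visits beyond the schedule reuse the final gain.  The global score
is the arithmetic mean of the available domain T-scores (domain-mean rather
than test-mean; with equal per-domain weights the two coincide in this
artifact since domains are the generator's atomic unit).

## Baseline classification (`trajmix.classify`)

SuperAger (SA): peak-age global T >= 40 *and* every domain chronological
T >= 40 (both bounds closed; "within normative expectations" is read as the
-1 SD cutoff, and "isolated impairment" as any domain chronological
T < 40).  Non-SA participants are split by the global deficit score: domain
chronological T-scores map to deficit points (>= 40 -> 0, 35-39 -> 1,
30-34 -> 2, 25-29 -> 3, 20-24 -> 4, < 20 -> 5), and a mean of >= 0.5
denotes impairment (CI), else cognitively normal (CN).  The mapping and
cutoff follow the standard deficit-score literature and are
config-overridable.  Status-by-class concordance uses a Pearson chi-square
on the contingency table; degenerate tables return NA with a warning.

## Physiologic reserve (`trajmix.reserve`)

The index is the proportion of available health variables scored normal, a
deficit-accumulation (frailty-complement) construct over 39 items: 23
clinical measurements, 12 comorbidity flags, and 4 HIV-specific indicators.
The criteria live in a versioned rules file (`reserve_criteria.yaml`).
Inequalities are read literally as strict, so boundary values score normal
except the triglyceride rule, which is printed as >= 150 mg/dl.
Hypertension is a deficit if the diagnosis flag is set *or* systolic
pressure exceeds 130 mmHg *or* diastolic exceeds 85 mmHg.  MCHC,
hemoglobin, and HDL dispatch on recorded sex.  The hemoglobin cutoffs are
carried in the source's printed units (umol/l) although g/dl is the
conventional unit for such thresholds; the numeric comparisons are
unaffected.  Missing items are excluded from numerator and denominator
alike; an all-missing profile is an error.

## Growth mixture engine (`trajmix.gmm`)

The model is a K-class mixture of linear mixed models sharing variance
components: y_i | k ~ N(X a_k, Z Psi Z' + Theta), with X the polynomial
mean basis (intercept-only/linear/quadratic/cubic, or a latent basis with
free interior loadings), Z the random-effect columns (intercept and linear
slope by default; a random quadratic and visit-specific residual variances
are config options), Psi and Theta shared across classes.  Missing visits
are handled by full-information maximum likelihood: each participant
contributes the normal density of their observed sub-vector, computed per
missingness pattern with Cholesky factorisations shared within a pattern.

Estimation is EM treating class labels *and* random effects as latent.
This gives closed-form conditional M-steps for every block (mixing
proportions, class means via weighted regression on the residualised
outcomes, Psi from posterior second moments, residual variance from
posterior residuals), rather than a numerical update for (Psi, Theta): the
expectation-conditional-maximisation steps each increase the same Q
function, so the observed-data log-likelihood is monotone by construction
(asserted in tests).  Convergence is absolute log-likelihood change
< 1e-6 or 2000 iterations.  Near-singular Psi receives a logged ridge.

Starts: a k-means initialisation on per-person OLS growth coefficients
(winsorised at the 2nd/98th percentile, since short follow-ups give wild
coefficients) seeds the first start; subsequent starts alternate random
partitions with perturbed k-means solutions.  All starts run an 80-iteration
burn-in; the best few continue to convergence, and the top log-likelihood
must be replicated by a second start or a warning is recorded.  Classes are
reported in descending-intercept order, so "class 1" is always the
highest-performing.

Fit indices: AIC = -2l + 2p, BIC = -2l + p ln n, ssBIC = -2l +
p ln((n+2)/24), and normalized entropy E = 1 - sum(-p_ik ln p_ik)/(n ln K)
(NA for K = 1).  The Lo-Mendell-Rubin comparison of K vs K-1 classes
shrinks 2(l_K - l_{K-1}) by 1 + 1/(q ln n) (q = parameter difference) and
refers it to a chi-square with q degrees of freedom — an approximation to
the LMR weighted chi-square that is calibrated-to-conservative in the null
simulations run by the test suite.  A parametric-bootstrap LRT is provided
as a cross-check.  Class-size adequacy flags mark solutions with a class
under 25 members or under 5% of the sample.

Auxiliary missingness correlates (education, enrollment date) can be
appended as saturated correlates: each auxiliary variable gets a free mean,
a free loading on the growth random effects, and a free residual variance,
all estimable in closed form within the same EM.  With class-invariant
auxiliary means (the default) the auxiliary block cannot define classes;
a by-class-means variant exists but measurably reshapes class formation
when the auxiliaries are class-associated, so it is opt-in.  Even the
invariant form shifts the ML solution slightly in small samples when
auxiliaries correlate with class — an inherent property of
saturated-correlates approximations, worth knowing before enabling
auxiliaries for enumeration.

Standard errors for growth parameters come from the numerically
differentiated observed information matrix (plain ML, not
robust/sandwich).  A secondary fit can drop the baseline indicator
(refitting on visits 1-9 with time codes preserved) and cross-tabulate
modal membership against the primary fit.

## 3-step covariate analysis (`trajmix.posthoc`)

Class membership is fixed by modal posterior assignment (ties break to the
lower class index and are logged) before any covariate enters a model.
Univariable screening uses one-way ANOVA for continuous covariates,
Kruskal-Wallis for variables flagged as skewed counts in the dispatch
config (the source analysis mixes test types without stating its rule),
chi-square for categorical tables, and an exact test when any expected cell
is below 5 — Fisher's exact test for 2x2, otherwise a Monte-Carlo
permutation test (an r x c network-algorithm Fisher test is not available
in the scientific Python stack).  Predictors passing p < 0.10 enter a
multinomial logit (ML, Newton); covariates listed as per-SD (WRAT4,
physiologic reserve, mirroring the source's footnote) are divided by their
sample SD first.  Backward pruning removes, one per pass, the covariate
whose smallest class-contrast p-value is largest and >= 0.10, then refits;
the source's pruning order is unstated, so largest-minimum-p-first is this
package's choice.  Coefficients above |10| trigger a separation warning.
Hard modal assignment (not posterior weighting, and no BCH/Vermunt bias
correction) is used throughout, matching the "assign first, model second"
description of the emulated analysis.

## Pipeline (`trajmix.pipeline`, `trajmix.cli`)

`run_all` chains generate -> norm -> score -> classify -> reserve ->
coverage/missingness diagnostics -> (optional) base-model selection ->
enumeration -> concordance -> baseline-free refit -> 3-step regression,
with per-stage seeds spawned from the run seed, and writes CSV/JSON outputs
plus a manifest recording the seed and SHA-256 of every file; identical
configs reproduce byte-identical bundles.  Model selection defaults to the
smallest K whose (K+1)-class alternative fails the LMR test at 0.05 and
whose classes are adequate, falling back to the adequate ssBIC minimiser;
`force_K` overrides it, because enumeration decisions are judgement-laden
in practice.

## Problem sizes and numerical choices

Recovery analyses run at n = 4000 participants (10 visits, no dropout, 16-40
EM starts) for growth parameters and n = 20000 for odds-ratio recovery;
null-calibration simulations use 200 replicates of n = 120, J = 5 panels.
Tolerances in the test suite are 3 analytic Monte-Carlo SEs (binomial for
shares, OLS-projection variances for growth means, Wald for log-odds).
Integration oracles for the FIML likelihood use finite windows of +/- 15
marginal SDs with quadrature tolerances of 1e-14, giving agreement to
1e-10 on toy panels.

## Known limitations

* The norming and practice models are fitted on synthetic normative/retest
  samples with known generating structure; published normative coefficients
  and practice-correction constants are not reproduced.
* The LMR p-value uses a chi-square reference for the adjusted statistic,
  not the exact weighted chi-square; the bootstrap LRT is the more reliable
  (and slower) alternative.
* Mixture standard errors are plain ML; no robust (sandwich) correction.
* The saturated-correlates auxiliary model is an approximation and can
  shift class formation in small samples (see above).
* Class labels are identified by descending intercept; models whose true
  classes differ mainly in slopes would need a different canonicalisation.
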