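# Methods

## Problem and estimands

The package evaluates how accurately continuous adherence measures,
dichotomized at a cut-off, classify participants by week-48 virological
status.  Orientation is fixed throughout: the *condition positive* state is
a detectable viral load (any quantifiable load, i.e. at or above the assay
threshold of 20 copies/mL; a 1000 copies/mL definition is a matter of how
the binary outcome column was produced upstream and needs no code change),
and the *test positive* state is non-adherence.  Sensitivity is therefore
the percentage of participants with detectable viral load flagged
non-adherent; specificity, PPV and NPV follow the usual 2×2 definitions,
and any zero-denominator cell is reported as an explicit undefined marker
(NaN), never as a number or an exception.

## Adherence scores

All three scores are computed with exact rational arithmetic before the
percent conversion and truncated to [0, 100]:

* self-report, from the reported missed-pill count over the recall window;
* pharmacy refill, from the pill ledger (dispensed at previous visit +
  returned at previous visit − returned at current visit) over prescribed
  pills; an *unknown* current leftover count maps directly to 100%
  (the assume-fully-adherent convention), not to a zero-return imputation —
  the two coincide only when dispensing exactly covers the window;
* electronic monitoring, openings over expected openings.

Truncation at 100% is standard for refill ledgers (supply surplus produces
raw values above 100).  We apply the same cap to the other two channels as
well, because openings can exceed expectations (double openings) and the
downstream cut-off logic assumes scores in [0, 100]; each cap is counted
and surfaced through the module logger.  The self-report recall window is
the actual inter-visit interval when recorded, with a 30-day fallback
(the questionnaire's "past month") otherwise.

## Dichotomization and composites

Non-adherent means *strictly below* the cut-off; equality counts as
adherent, so the 100% cut-off flags exactly the participants who missed
anything.  Composites use the any-measure union rule.  Its continuous
analog is the per-participant minimum of the component scores — the unique
scalar whose thresholding reproduces the union rule at every cut-off
simultaneously (property-tested).  This identity is an inference, since a
composite continuous score is under-determined by a classification rule;
the minimum is the only choice consistent with it at all cut-offs at once.
Two consequences are tested as invariants: at any fixed cut-off the
composite's non-adherent set is the union of the component sets, hence
composite sensitivity ≥ each component's and composite specificity ≤ each
component's.

## ROC, AUC, optimal cut-off

The empirical ROC treats low adherence as high risk and sweeps every
distinct observed score as a cut-off (flagged iff score < c), plus a
terminal cut-off above the maximum; tied scores collapse to a single
vertex.  The trapezoidal area under this curve equals the Mann–Whitney
probability that a random case scores below a random control with half
credit for ties; the equivalence is asserted to 1e-12 against a brute-force
pair-counting oracle, and against scikit-learn's implementation.  The
optimal cut-off is the vertex minimizing Euclidean distance to
(1−specificity, sensitivity) = (0, 1), excluding the two trivial endpoints;
exact distance ties break toward the higher-sensitivity vertex, then the
lower cut-off.  A two-point (no-information) curve has no interior vertex
and yields an undefined marker.  No smoothing, no binormal model, no AUC
confidence intervals: the curve is purely empirical.

## Logistic regression

Each measure × cut-off cell is fitted in its own model — detectable viral
load on the non-adherence indicator, a male indicator and a TLE-regimen
indicator (references: female, non-TLE) — rather than all measures jointly,
matching how single-measure predictive value is reported in this
literature.  Estimation is maximum likelihood (Newton/IRLS, gradient
tolerance 1e-8) via statsmodels; inference is Wald (odds ratios with
symmetric log-scale 95% CIs and two-sided normal p-values), the routine
epidemiological reporting choice.  Quasi-complete separation — expected at
high cut-offs for very specific measures — is detected when any fitted
probability is within 1e-6 of 0 or 1 while some coefficient exceeds 8 in
absolute value, and is *flagged*, not silently repaired: penalization would
change the estimand.  A Firth (Jeffreys-prior) penalized fit is available
behind a flag for users who want finite estimates under separation.
Per-cell failures in the sweep are recorded in the output table and do not
abort the remaining cells.

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
validated.  Per participant:

1. latent adherence propensity from a two-component Beta mixture — an
   adherent component (mean 0.95, concentration 40) with weight 0.7 and a
   struggling component (mean 0.60, concentration 8).  A bimodal law is
   deliberate: a single high-mean distribution leaves no cases below an 80%
   cut-off and makes the grid degenerate.
2. one realized intake stream: Bernoulli(propensity) per dosing moment over
   a 56-day window (two-monthly visits), one dosing moment and one pill per
   day by default.  The recorded `true_adherence` is the realized intake
   fraction, so all three channels observe the same behaviour and agree
   with it exactly when their error mechanisms are off.
3. channel observations: the self-report missed count is shrunk by
   `sr_underreport_factor` (default 0.5) and zeroed outright with
   probability `sr_zero_report_prob` (default 0.5); the refill ledger gains
   surplus supply kept at home uncounted with probability `pr_surplus_prob`
   (0.10) and loses its leftover count with probability
   `pr_unknown_leftover_prob` (0.15); electronic openings lose each intake
   event with probability `rtmm_outage_day_prob` (0.02) and are consolidated
   by a pocket-dosing event with probability `rtmm_pocket_dose_prob` (0.10).
   The self-report defaults encode the over-reporting scenario the package's
   directional-bias checks probe; the refill and pocket-dosing rates are
   scenario parameters chosen once as plausible magnitudes, not estimates —
   no quantitative error rates exist for them in this setting.
4. outcome: detectable viral load ~ Bernoulli(logit⁻¹(2.7 − 4.0·adherence −
   0.7·1[TLE])).  Intercept, slope and regimen effect were chosen once so
   that the analytic prevalence (numeric integration of the inverse-logit
   over the mixture and the binomial intake realization, implemented in
   `expected_detectable_fraction`) is ≈ 0.31 with a 32% TLE share — the
   week-48 composition of the cohort being emulated (233 participants,
   70.4% female, 69% suppressed).

Only the final visit window is simulated — no longitudinal trajectories, no
event timestamps, no reminder-intervention feedback, no visual-analogue
self-report.  Electronic-monitoring observables are generated for everyone
by default (`rtmm_arm_prob = 1`) so that measure comparisons share one
cohort; setting it to ⅓ reproduces a design where only one arm carries the
device, and all monitoring analyses then restrict to that arm.

What passing tests therefore show: the pipeline's arithmetic, orderings and
calibration are correct *under this generative model* — one shared intake
stream, independent error mechanisms, a logistic outcome.  What they do not
show: performance under real-data features the generator omits (correlated
errors across channels, adherence that varies within the window, informative
missingness, pill sharing or dumping, outcome misclassification).

## Numerical and interface choices

* Determinism: a `SimulationConfig` (including its seed) reproduces a
  byte-identical cohort and byte-identical pipeline output files; all
  randomness flows through one `numpy` generator.
* Cohort CSV: fixed header, unknown leftover and absent monitoring encoded
  as empty fields; floats written with `repr` and parsed with pandas'
  round-trip precision so read(write(x)) == x.
* Validation errors name the offending field (configs) or participant and
  row (cohort files).
* Problem sizes in the validation suites — replicate counts of 100–200,
  cohorts of 250 for accuracy orderings, 1000–2000 for regression
  calibration — were chosen so Monte-Carlo bands (3 binomial standard
  errors) are tight enough to detect real miscalibration while the whole
  suite stays interactive.

## Known limitations

* The empirical AUC is reported without a confidence interval; with ~70
  cases, differences of 0.02–0.05 between measures are well within noise.
* Wald inference is poor near separation; the separation flag marks those
  cells and the Firth option provides finite estimates, but no
  profile-likelihood intervals are implemented.
* The generator's error mechanisms are independent across channels given
  the intake stream; real over-reporting plausibly correlates with refill
  manipulation, which would change composite performance.
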