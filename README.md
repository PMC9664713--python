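# adhereval

How well does a medication-adherence measure predict virological failure in
people on antiretroviral therapy (ART)?  Clinics in low-resource settings
routinely assess adherence by **self-report** (how many pills did you miss?),
**pharmacy refill counts** (pills dispensed minus pills returned over the
inter-visit interval) and, increasingly, **real-time medication monitoring
(RTMM)** — a smart pill box that records each opening.  All three are error
prone in characteristic directions: self-report over-states adherence
(social desirability, recall), refill ledgers break when leftover pills go
uncounted, and electronic monitoring undercounts intake through connectivity
outages and "pocket dosing" (several doses removed in one opening).

`adhereval` is a package for epidemiologists and implementation scientists
evaluating such measures.  It provides

* the three standard adherence percentages, each truncated to [0, 100]:

  - self-report: ((days × pills/day − missed) / (days × pills/day)) × 100
  - pharmacy refill: ((dispensed + returned previously − returned now) /
    (days × pills/day)) × 100, with unknown leftovers treated as full
    adherence
  - RTMM: (openings / expected openings) × 100

* dichotomization at a cut-off grid (default 80, 85, 90, 95, 100 %;
  non-adherent iff strictly below the cut-off) and *any-measure composites*
  (non-adherent on the composite iff non-adherent on any component; the
  continuous analog is the per-participant minimum);
* diagnostic accuracy against detectable viral load — sensitivity,
  specificity, PPV, NPV per (measure, cut-off) cell; empirical ROC curves
  with proper tie handling (trapezoidal AUC = Mann–Whitney
  P(case < control) + ½ P(tie)); the optimal cut-off closest to the
  top-left corner of the ROC;
* logistic regression of detectable viral load on non-adherence, adjusted
  for sex and TLE-vs-other regimen (tenofovir + lamivudine + efavirenz),
  with Wald odds ratios and explicit separation flagging;
* a **synthetic cohort generator** that draws a latent adherence propensity
  from a two-component (adherent / struggling) Beta mixture, realizes one
  Bernoulli intake stream per participant, and pushes it through the three
  error channels above, plus a logistic outcome model — so every stage of
  the pipeline is testable without access to trial data.

## Worked example

```python
from adhereval import SimulationConfig, simulate_cohort, AdherenceModel

cohort = simulate_cohort(SimulationConfig(seed=1))   # 233 participants
results = AdherenceModel(cohort).fit()
print(results.summary())
```

prints (abridged):

```
Adherence measure diagnostic evaluation
=======================================================
Participants: 233  (detectable viral load: 72, 30.9%)

Discrimination (empirical ROC):
  measure               AUC   optimal cut-off
  self_report         0.592            100.0%
  pharmacy_refill     0.687             89.3%
  rtmm                0.684             87.5%
  sr_pr               0.687             91.1%
  all_three           0.684             87.5%

Accuracy by cut-off (percent):
  measure            cutoff   sens   spec    ppv    npv
  self_report            80    9.7   98.1   70.0   70.9
  self_report            95   25.0   90.1   52.9   72.9
  rtmm                   95   91.7   25.5   35.5   87.2
  all_three              95   91.7   25.5   35.5   87.2
  ...
```

Reading: of the 72 participants with detectable viral load, only 9.7% are
flagged by self-report at the 80% cut-off (over-reporting hides them) while
98.1% of suppressed participants are correctly left unflagged; combining
measures raises sensitivity (91.7% for the triple at the 95% cut-off) at the
price of specificity.  The self-report ROC dot sits at the 100% cut-off —
only a report of *any* missed pill carries signal.  `results.diagnostics`,
`results.rocs`, `results.optimal_cutoffs` and `results.regressions` expose
the underlying tables; `results.plot_roc()` draws the curves with the
optimal cut-off dots.

The same pipeline runs from the shell:

```sh
adhereval simulate --seed 1 -o cohort.csv
adhereval report cohort.csv -d results/
```

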