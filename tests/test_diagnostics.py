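"""Confusion metrics, empirical ROC/AUC and the optimal cut-off.

Independent oracles: brute-force tallies for confusion counts, case-control
pair counting (half-credit ties) for AUC, exhaustive vertex search for the
optimal cut-off, and scikit-learn's ROC as an external cross-check.
"""

import math

import numpy as np
import pytest

from adhereval import (
    ConfusionCounts,
    auc,
    confusion,
    diagnostic_table,
    metrics,
    optimal_cutoff,
    roc_curve,
    simulate_cohort,
    build_panel,
)
from adhereval.diagnostics import RocCurve

from conftest import config_with


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def pair_counting_auc(scores, outcomes):
    """Mann-Whitney: P(case < control) + 0.5 P(tie) over all case-control pairs."""
    cases = [s for s, o in zip(scores, outcomes) if o]
    controls = [s for s, o in zip(scores, outcomes) if not o]
    total = 0.0
    for c in cases:
        for k in controls:
            total += 1.0 if c < k else (0.5 if c == k else 0.0)
    return total / (len(cases) * len(controls))


def brute_force_confusion(flags, outcomes):
    tp = fp = fn = tn = 0
    for f, o in zip(flags, outcomes):
        if f and o:
            tp += 1
        elif f and not o:
            fp += 1
        elif not f and o:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def _random_cohort(rng, n, tie_heavy=False):
    """Scores with deliberate ties plus a two-class outcome."""
    if tie_heavy:
        scores = rng.choice(np.arange(0, 101, 5.0), size=n)
    else:
        scores = np.round(rng.uniform(0, 100, size=n), 1)
    outcomes = rng.random(n) < 0.35
    if outcomes.all() or not outcomes.any():
        outcomes[0] = ~outcomes[0]
    return scores, outcomes


# ---------------------------------------------------------------------------
# confusion and metrics
# ---------------------------------------------------------------------------

class TestConfusion:
    def test_enumeration(self):
        c = confusion([True, False, True, False], [True, True, False, False])
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 1)

    def test_degenerate_all_negative(self):
        c = confusion([False] * 7, [False] * 7)
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 0, 7)

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(42)
        flags = rng.random(50) < 0.4
        outcomes = rng.random(50) < 0.3
        c = confusion(flags, outcomes)
        assert (c.tp, c.fp, c.fn, c.tn) == brute_force_confusion(flags, outcomes)
        assert c.total == 50

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            confusion([True, False], [True])

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, fn=0, tn=0)


class TestMetrics:
    def test_forced_values(self):
        m = metrics(ConfusionCounts(tp=10, fp=0, fn=5, tn=0))
        assert m["sensitivity"] == pytest.approx(100 * 10 / 15)
        assert m["ppv"] == 100.0

    def test_zero_denominators_are_undefined(self):
        m = metrics(ConfusionCounts(tp=0, fp=3, fn=0, tn=5))
        assert math.isnan(m["sensitivity"])
        assert math.isnan(m["npv"]) is False
        m2 = metrics(ConfusionCounts(tp=0, fp=0, fn=2, tn=5))
        assert math.isnan(m2["ppv"])


class TestDiagnosticTable:
    def test_cardinality(self, panel):
        table = diagnostic_table(panel, ["self_report"], (80, 85, 90, 95, 100))
        assert len(table) == 5

    def test_perfect_separation_cell(self, panel):
        sub = panel.copy()
        sub["sr_adherence"] = np.where(sub["vl_detectable"], 70.0, 95.0)
        row = diagnostic_table(sub, ["self_report"], (90,)).iloc[0]
        assert row["sensitivity"] == 100.0 and row["specificity"] == 100.0

    def test_rtmm_rows_restricted_to_monitored_arm(self):
        cohort = simulate_cohort(config_with(rtmm_arm_prob=0.4, n_participants=300, seed=8))
        panel = build_panel(cohort)
        table = diagnostic_table(panel, ["self_report", "rtmm"], (90,))
        n_rtmm = int(panel["rtmm_adherence"].notna().sum())
        by_measure = table.set_index("measure")["n"]
        assert by_measure["rtmm"] == n_rtmm
        assert by_measure["self_report"] == len(panel)

    def test_absent_measure_rejected(self, panel):
        sub = panel.copy()
        sub["rtmm_adherence"] = np.nan
        with pytest.raises(ValueError, match="rtmm"):
            diagnostic_table(sub, ["rtmm"], (90,))


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

class TestRocCurve:
    def test_perfect_separation(self):
        scores = [0.0, 0.0, 100.0, 100.0, 100.0]
        outcomes = [True, True, False, False, False]
        curve = roc_curve(scores, outcomes)
        assert curve.auc == 1.0
        assert any((f == 0.0 and t == 1.0) for f, t in zip(curve.fpr, curve.tpr))

    def test_all_tied_is_diagonal(self):
        curve = roc_curve([90.0] * 6, [True, False, True, False, False, True])
        assert len(curve.fpr) == 2
        assert curve.auc == 0.5

    def test_hand_enumerated_vertices(self):
        # cases {97, 85}, controls {99, 90}
        scores = [97.0, 85.0, 99.0, 90.0]
        outcomes = [True, True, False, False]
        curve = roc_curve(scores, outcomes)
        expected = {
            (0.0, 0.0): 85.0,   # cut-off at min: nobody flagged
            (0.0, 0.5): 90.0,   # flags 85 only
            (0.5, 0.5): 97.0,   # flags 85, 90
            (0.5, 1.0): 99.0,   # flags 85, 90, 97
            (1.0, 1.0): math.inf,
        }
        got = {(f, t): c for f, t, c in zip(curve.fpr, curve.tpr, curve.thresholds)}
        assert got == expected
        assert curve.auc == pytest.approx(0.75)
        assert auc(scores, outcomes) == pytest.approx(pair_counting_auc(scores, outcomes))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="suppressed"):
            roc_curve([80, 90], [True, True])
        with pytest.raises(ValueError, match="detectable"):
            roc_curve([80, 90], [False, False])

    def test_invariants_enforced_on_construction(self):
        with pytest.raises(ValueError, match="ROC"):
            RocCurve(thresholds=[0, 1], fpr=[0.1, 1.0], tpr=[0.0, 1.0], auc=0.5)

    def test_trapezoid_equals_pair_counting(self):
        """Oracle equivalence on random tie-heavy cohorts."""
        rng = np.random.default_rng(7)
        for i in range(30):
            scores, outcomes = _random_cohort(rng, int(rng.integers(5, 200)), tie_heavy=i % 2)
            assert abs(auc(scores, outcomes) - pair_counting_auc(scores, outcomes)) < 1e-12

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        for _ in range(10):
            scores, outcomes = _random_cohort(rng, 120, tie_heavy=True)
            # low adherence = high risk, so negate for sklearn's orientation
            assert auc(scores, outcomes) == pytest.approx(
                roc_auc_score(outcomes, -scores), abs=1e-12
            )

    def test_relabeling_reflects_auc(self):
        rng = np.random.default_rng(5)
        scores, outcomes = _random_cohort(rng, 90, tie_heavy=True)
        assert auc(scores, outcomes) + auc(scores, ~outcomes) == pytest.approx(1.0)

    def test_constant_shift_invariance(self):
        rng = np.random.default_rng(6)
        scores = np.round(rng.uniform(10, 80, 60), 1)
        outcomes = rng.random(60) < 0.4
        outcomes[0] = True
        outcomes[1] = False
        base = roc_curve(scores, outcomes)
        shifted = roc_curve(scores + 15.0, outcomes)
        np.testing.assert_array_equal(base.fpr, shifted.fpr)
        np.testing.assert_array_equal(base.tpr, shifted.tpr)
        assert base.auc == pytest.approx(shifted.auc, abs=1e-12)


class TestOptimalCutoff:
    def test_perfect_separation_threshold(self):
        curve = roc_curve([60.0, 65.0, 90.0, 95.0], [True, True, False, False])
        # flagging scores < 90 classifies everyone correctly
        assert optimal_cutoff(curve) == 90.0

    def test_tie_breaks_toward_higher_sensitivity(self):
        # two vertices equidistant from (0,1): (0, 0.5) and (0.5, 1)
        curve = RocCurve(
            thresholds=[70.0, 80.0, 90.0, math.inf],
            fpr=[0.0, 0.0, 0.5, 1.0],
            tpr=[0.0, 0.5, 1.0, 1.0],
            auc=0.75,
        )
        assert optimal_cutoff(curve) == 90.0

    def test_degenerate_curve_undefined(self):
        curve = roc_curve([90.0] * 4, [True, False, True, False])
        assert math.isnan(optimal_cutoff(curve))

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(11)
        scores, outcomes = _random_cohort(rng, 20, tie_heavy=True)
        curve = roc_curve(scores, outcomes)
        best = None
        for c, f, t in zip(curve.thresholds, curve.fpr, curve.tpr):
            if (f, t) in ((0.0, 0.0), (1.0, 1.0)):
                continue
            key = (math.hypot(f, 1 - t), -t, c)
            if best is None or key < best[0]:
                best = (key, c)
        assert optimal_cutoff(curve) == best[1]
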