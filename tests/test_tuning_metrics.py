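"""Depth-sign indices, permutation test, and congruency metrics."""

import numpy as np
import pytest
from scipy import stats

from mtdetect import tuning_metrics as tm

GRID = np.arange(-2.0, 2.5, 0.5)


def _curve_from_means(means, sd=2.0, n=8, seed=0):
    """Trials with exactly the requested per-depth means and spread."""
    rng = np.random.default_rng(seed)
    trials = []
    for mu in means:
        x = rng.standard_normal(n)
        x = (x - x.mean()) / x.std(ddof=1)  # exact mean 0, SD 1
        trials.append(mu + sd * x)
    return tm.TuningCurve(cue="BD", depths=GRID, trials=trials)


class TestComputeDsdi:
    def test_step_tuning_value(self):
        # near depths at 10, far at 20, SD 5 -> each pair term 10/15
        means = [10, 10, 10, 10, 15, 20, 20, 20, 20]
        curve = _curve_from_means(means, sd=5.0)
        assert tm.compute_dsdi(curve).dsdi == pytest.approx(10.0 / 15.0, abs=1e-12)

    def test_symmetric_curve_gives_zero(self):
        means = [10, 12, 14, 16, 18, 16, 14, 12, 10]
        curve = _curve_from_means(means)
        assert tm.compute_dsdi(curve).dsdi == pytest.approx(0.0, abs=1e-12)

    def test_bounded_strictly_below_one(self):
        rng = np.random.default_rng(4)
        for seed in range(20):
            means = rng.uniform(0, 50, size=9)
            curve = _curve_from_means(means, sd=rng.uniform(0.5, 5), seed=seed)
            assert abs(tm.compute_dsdi(curve).dsdi) < 1.0

    def test_invariant_to_constant_offset(self):
        means = np.array([10, 12, 9, 14, 15, 16, 19, 12, 20], dtype=float)
        a = tm.compute_dsdi(_curve_from_means(means, seed=5)).dsdi
        b = tm.compute_dsdi(_curve_from_means(means + 37.0, seed=5)).dsdi
        assert a == pytest.approx(b, abs=1e-12)

    def test_reversed_depth_axis_negates(self):
        means = np.array([10, 12, 9, 14, 15, 16, 19, 12, 20], dtype=float)
        a = tm.compute_dsdi(_curve_from_means(means, seed=6)).dsdi
        b = tm.compute_dsdi(_curve_from_means(means[::-1], seed=6)).dsdi
        assert a == pytest.approx(-b, abs=1e-12)

    def test_missing_pair_rejected(self):
        curve = tm.TuningCurve(
            cue="BD",
            depths=np.array([-2.0, -1.0, 1.0]),
            trials=[np.ones(3), np.ones(3), np.ones(3)],
        )
        with pytest.raises(ValueError, match="missing symmetric pair"):
            tm.compute_dsdi(curve)

    def test_zero_denominator_term_contributes_zero(self):
        trials = [np.full(3, 10.0) for _ in GRID]  # flat, zero SD
        curve = tm.TuningCurve(cue="BD", depths=GRID, trials=trials)
        assert tm.compute_dsdi(curve).dsdi == 0.0


class TestComputeDsdiDyn:
    deltas = (-1.53, -0.57, -0.21, 0.21, 0.57, 1.53)

    def test_constant_pair_difference_value(self):
        rng = np.random.default_rng(0)

        def jitter(mu):
            x = rng.standard_normal(10)
            return mu + 2.0 * (x - x.mean()) / x.std(ddof=1)

        resp = {d: jitter(12.0 if d > 0 else 8.0) for d in self.deltas}
        # each pair: (12-8)/(4+2) = 2/3
        assert tm.compute_dsdi_dyn(resp).dsdi == pytest.approx(4.0 / 6.0, abs=1e-12)

    def test_sign_symmetric_responses_give_zero(self):
        rng = np.random.default_rng(1)
        resp = {}
        for mag in (0.21, 0.57, 1.53):
            x = rng.normal(10, 2, size=8)
            resp[mag] = x
            resp[-mag] = x.copy()
        assert tm.compute_dsdi_dyn(resp).dsdi == pytest.approx(0.0, abs=1e-12)

    def test_swapping_signs_negates(self):
        rng = np.random.default_rng(2)
        resp = {d: rng.normal(10 + 3 * d, 2, size=8) for d in self.deltas}
        flipped = {-d: v for d, v in resp.items()}
        a = tm.compute_dsdi_dyn(resp).dsdi
        b = tm.compute_dsdi_dyn(flipped).dsdi
        assert a == pytest.approx(-b, abs=1e-12)


class TestPermutationTest:
    def test_strong_tuning_hits_p_floor(self):
        means = np.linspace(5, 60, 9)
        curve = _curve_from_means(means, sd=1.0)
        res = tm.permutation_test_dsdi(curve, n_perm=1000, seed=0)
        assert res.p_value <= 1.0 / 1000.0

    def test_flat_tuning_p_not_extreme(self):
        curve = _curve_from_means(np.full(9, 20.0), sd=4.0, seed=3)
        res = tm.permutation_test_dsdi(curve, n_perm=500, seed=0)
        assert 0.05 < res.p_value < 0.95

    def test_null_rejection_rate_of_sign_rule(self):
        # the sign rule is one-sided in the observed direction, so its null
        # rejection rate at threshold alpha is ~2*alpha (modest run here; the
        # full-scale calibration lives in the acceptance suite)
        rng = np.random.default_rng(9)
        rejections = 0
        n_neurons = 300
        for i in range(n_neurons):
            trials = [rng.normal(15, 4, size=6) for _ in GRID]
            curve = tm.TuningCurve(cue="MP", depths=GRID, trials=trials)
            res = tm.permutation_test_dsdi(curve, n_perm=200, seed=i)
            rejections += res.p_value < 0.05
        assert abs(rejections / n_neurons - 0.10) < 0.045

    def test_small_n_perm_warns(self):
        curve = _curve_from_means(np.full(9, 20.0), sd=4.0)
        with pytest.warns(UserWarning, match="n_perm"):
            tm.permutation_test_dsdi(curve, n_perm=50, seed=0)


class TestCongruency:
    def test_identical_curves_fully_congruent(self, conditions, session_trials):
        means = np.array([5, 8, 15, 25, 30, 25, 15, 8, 5], dtype=float)
        bd = _curve_from_means(means, seed=1)
        mp = tm.TuningCurve(cue="MP", depths=GRID, trials=bd.trials)
        det = session_trials[session_trials["neuron_id"] == 0]
        res = tm.compute_congruency(bd, mp, det, conditions)
        assert res.r_mp_bd == pytest.approx(1.0)
        assert res.cls == "congruent"

    def test_negated_curve_fully_opposite(self, conditions, session_trials):
        means = np.array([5, 8, 15, 25, 30, 25, 15, 8, 5], dtype=float)
        bd = _curve_from_means(means, seed=2)
        mp = _curve_from_means(2 * means.mean() - means, seed=2)
        det = session_trials[session_trials["neuron_id"] == 0]
        res = tm.compute_congruency(bd, mp, det, conditions)
        assert res.r_mp_bd == pytest.approx(-1.0)
        assert res.cls == "opposite"

    def test_zero_variance_curve_rejected(self, conditions, session_trials):
        flat = tm.TuningCurve(
            cue="BD", depths=GRID, trials=[np.full(3, 10.0) for _ in GRID]
        )
        bumpy = _curve_from_means(np.linspace(5, 30, 9))
        det = session_trials[session_trials["neuron_id"] == 0]
        with pytest.raises(ValueError, match="zero-variance"):
            tm.compute_congruency(flat, bumpy, det, conditions)

    def test_identical_response_sets_give_unit_peak_ratio(self, conditions):
        import pandas as pd

        rng = np.random.default_rng(0)
        rows = []
        rates = rng.normal(20, 3, size=10)
        for cid in conditions["condition_id"]:
            for r in rates:
                rows.append({"condition_id": cid, "rate_hz": r})
        trials = pd.DataFrame(rows)
        assert tm.peak_response_ratio(trials, conditions) == pytest.approx(1.0)

    def test_population_correlations_match_expected_structure(self, neuron_summary):
        # expected selectivity/congruency structure on the default population
        r_pr, p_pr = stats.spearmanr(
            neuron_summary["peak_ratio"], neuron_summary["r_mp_bd"]
        )
        assert r_pr < 0 and p_pr < 0.05
        r_dd, p_dd = stats.spearmanr(
            neuron_summary["dsdi_dyn"], neuron_summary["delta_dsdi"]
        )
        assert r_dd > 0 and p_dd < 0.05
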