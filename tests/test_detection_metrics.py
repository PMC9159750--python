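"""ROC ideal observer, neurometric performance, DP, and time courses."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mtdetect import detection_metrics as dm
from mtdetect import synthpop as sp


def brute_force_auc(preferred, other):
    """Exhaustive pair counting: P(pref > other) + 0.5 P(tie)."""
    wins = ties = 0
    for a, b in itertools.product(preferred, other):
        wins += a > b
        ties += a == b
    return (wins + 0.5 * ties) / (len(preferred) * len(other))


class TestRocArea:
    def test_identical_distributions(self):
        assert dm.roc_area([1, 2, 3], [1, 2, 3]).area == pytest.approx(0.5)

    def test_interleaved_example(self):
        assert dm.roc_area([2, 4], [1, 3]).area == pytest.approx(0.75)

    def test_complete_separation(self):
        assert dm.roc_area([10, 11], [1, 2]).area == 1.0
        assert dm.roc_area([1, 2], [10, 11]).area == 0.0

    def test_complement_under_group_swap(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(1, 1, 7), rng.normal(0, 1, 5)
        assert dm.roc_area(a, b).area == pytest.approx(1 - dm.roc_area(b, a).area)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            dm.roc_area([], [1.0])

    @given(
        a=st.lists(st.integers(0, 6), min_size=1, max_size=8),
        b=st.lists(st.integers(0, 6), min_size=1, max_size=8),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_pair_counting_oracle(self, a, b):
        # small integer rates force heavy ties; rank formula must agree exactly
        assert dm.roc_area(a, b).area == pytest.approx(
            brute_force_auc(a, b), abs=1e-12
        )


class TestNeurometricPerformance:
    def test_condition_independent_rates_near_half(self, conditions):
        rng = np.random.default_rng(1)
        rows = []
        for cid in conditions["condition_id"]:
            for _ in range(40):
                rows.append({"condition_id": cid, "rate_hz": rng.normal(20, 4)})
        res = dm.neurometric_performance(pd.DataFrame(rows), conditions)
        assert res.np_value == pytest.approx(0.5, abs=0.05)
        assert len(res.areas) == 6

    def test_engineered_dynamic_preference(self, conditions):
        # all six nonzero-conflict areas above 0.5, as for a strong opposite cell
        rng = np.random.default_rng(2)
        rows = []
        for _, cond in conditions.iterrows():
            boost = 15.0 if cond["delta_depth_deg"] != 0 else 0.0
            for _ in range(30):
                rows.append(
                    {
                        "condition_id": cond["condition_id"],
                        "rate_hz": rng.normal(20 + boost, 4),
                    }
                )
        res = dm.neurometric_performance(pd.DataFrame(rows), conditions)
        assert res.np_value > 0.5
        assert all(a > 0.5 for a in res.areas.values())

    def test_missing_delta_level_rejected(self, conditions):
        keep = conditions[conditions["delta_depth_deg"] != 1.53]
        rows = [
            {"condition_id": cid, "rate_hz": 20.0}
            for cid in keep["condition_id"]
            for _ in range(3)
        ]
        with pytest.raises(ValueError, match=r"1\.53"):
            dm.neurometric_performance(pd.DataFrame(rows), conditions)


def _ambiguous_trials(rates, choices, conditions):
    amb_id = conditions.loc[
        (conditions["kind"] == "dynamic") & (conditions["delta_depth_deg"] == 0),
        "condition_id",
    ].iloc[0]
    return pd.DataFrame(
        {"condition_id": amb_id, "rate_hz": rates, "choice_in_rf": choices}
    )


class TestDetectionProbability:
    def test_perfect_choice_separation(self, conditions):
        rates = np.concatenate([np.full(10, 30.0), np.full(10, 10.0)])
        choices = np.concatenate([np.ones(10, bool), np.zeros(10, bool)])
        res = dm.detection_probability(
            _ambiguous_trials(rates, choices, conditions), conditions, seed=0
        )
        assert res.dp == 1.0
        assert res.eligible

    def test_choice_independent_rates(self, conditions):
        rng = np.random.default_rng(3)
        rates = rng.normal(20, 4, size=80)
        choices = rng.random(80) < 0.5
        res = dm.detection_probability(
            _ambiguous_trials(rates, choices, conditions), conditions, seed=0
        )
        assert res.dp == pytest.approx(0.5, abs=0.15)
        assert res.p_value > 0.05

    def test_eligibility_threshold(self, conditions):
        rates = np.arange(12.0)
        choices = np.array([True] * 4 + [False] * 8)
        res = dm.detection_probability(
            _ambiguous_trials(rates, choices, conditions), conditions, seed=0
        )
        assert not res.eligible
        assert res.n_in == 4

    def test_uses_only_ambiguous_trials(self, conditions, session_trials):
        # DP must be invariant to every ΔDepth != 0 trial: NP and DP trial
        # sets are disjoint by construction
        det = session_trials[session_trials["neuron_id"] == 0]
        merged = det.merge(
            conditions[["condition_id", "kind", "delta_depth_deg"]], on="condition_id"
        )
        mangled = det.copy()
        nonzero = (merged["delta_depth_deg"] != 0) | (merged["kind"] != "dynamic")
        mangled.loc[nonzero.to_numpy(), "rate_hz"] = 0.0
        a = dm.detection_probability(det, conditions, seed=5)
        b = dm.detection_probability(mangled, conditions, seed=5)
        assert a.dp == b.dp and a.p_value == b.p_value

    def test_no_ambiguous_trials_rejected(self, conditions):
        rows = pd.DataFrame(
            {"condition_id": ["sta+0.00"] * 4, "rate_hz": 20.0, "choice_in_rf": True}
        )
        with pytest.raises(ValueError, match="ambiguous"):
            dm.detection_probability(rows, conditions)

    def test_coupled_population_dp_above_half_for_dynamic_preferring(
        self, neuron_summary
    ):
        # recovery run in the style of the DP-distribution result: neurons
        # preferring dynamic objects carry choice-predictive activity
        dp = neuron_summary["dp"][neuron_summary["np"] > 0.55]
        assert stats.wilcoxon(dp - 0.5, alternative="greater").pvalue < 0.01


class TestChoiceSortedTimecourse:
    def _counts(self, rates, duration=2.0, bin_s=0.01, seed=0):
        return sp.simulate_rasters(rates, duration_s=duration, bin_s=bin_s, seed=seed)

    def test_identical_groups_no_difference(self):
        rng = np.random.default_rng(0)
        counts = self._counts(np.full(40, 20.0))
        phase = np.repeat([0.0, 180.0], 20)
        choice = np.tile([True, False], 20)
        res = dm.choice_sorted_timecourse(counts, 0.01, phase, choice)
        for ph, sig in res.significant.items():
            assert sig.mean() < 0.15  # only alpha-level false positives
        for ph, diff in res.difference.items():
            assert abs(diff.mean()) < 0.5

    def test_constant_rate_is_flat_before_zscoring(self):
        counts = np.full((6, 200), 3.0)
        phase = np.repeat([0.0, 180.0], 3)
        choice = np.array([True, True, False] * 2)
        res = dm.choice_sorted_timecourse(counts, 0.01, phase, choice)
        for trace in res.traces.values():
            assert np.allclose(trace["mean"], trace["mean"][0])

    def test_step_increase_detected_in_time(self):
        rng = np.random.default_rng(7)
        n, bins, bin_s = 30, 210, 0.01
        base = rng.poisson(0.2, size=(2 * n, bins)).astype(float)
        # in-RF-choice trials get a strong step at t = 0.4 s
        base[:n, 40:] += rng.poisson(2.0, size=(n, bins - 40))
        phase = np.zeros(2 * n)
        choice = np.array([True] * n + [False] * n)
        res = dm.choice_sorted_timecourse(base, bin_s, phase, choice)
        sig_times = res.time[res.significant[0.0]]
        onset = sig_times.min()
        assert 0.3 <= onset <= 0.55 + 0.15

    def test_sparse_cell_omitted(self):
        counts = np.ones((5, 100))
        phase = np.array([0.0, 0.0, 0.0, 180.0, 180.0])
        choice = np.array([True, True, False, True, True])
        res = dm.choice_sorted_timecourse(counts, 0.01, phase, choice)
        assert (0.0, False) in res.omitted or (180.0, False) in res.omitted
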