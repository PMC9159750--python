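"""Noise-correlation construction, pseudo-population sampling, LDA readout."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mtdetect import decoder as dec
from mtdetect.stimgeom import standard_condition_table


class TestNoiseCorrelationMatrix:
    def test_equal_np_pair_value(self):
        model = dec.noise_correlation_matrix([0.6, 0.6])
        assert model.correlation[0, 1] == pytest.approx(0.55)

    def test_dissimilar_pair_goes_negative(self):
        model = dec.noise_correlation_matrix([0.78, 0.23])
        assert model.correlation[0, 1] == pytest.approx(-0.055)

    def test_identical_np_population_is_psd_without_repair(self):
        model = dec.noise_correlation_matrix(np.full(20, 0.5))
        expected = 0.55 + 0.45 * np.eye(20)
        np.testing.assert_allclose(model.correlation, expected)
        assert not model.psd_repaired
        assert np.linalg.eigvalsh(model.correlation).min() > 0

    def test_sqrt_reconstructs_correlation(self, moments):
        model = dec.noise_correlation_matrix(moments.np_values)
        np.testing.assert_allclose(
            model.sqrt @ model.sqrt.T, model.correlation, atol=1e-8
        )
        assert np.allclose(np.diag(model.correlation), 1.0)

    def test_repair_path_yields_unit_diagonal_psd(self):
        # widely spread NP values force indefinite raw matrices
        rng = np.random.default_rng(0)
        npv = rng.uniform(0.05, 0.95, size=40)
        model = dec.noise_correlation_matrix(npv)
        evals = np.linalg.eigvalsh(model.correlation)
        assert evals.min() > -1e-10
        np.testing.assert_allclose(np.diag(model.correlation), 1.0, atol=1e-12)

    def test_single_neuron_rejected(self):
        with pytest.raises(ValueError):
            dec.noise_correlation_matrix([0.5])


class TestSimulatePopulationTrials:
    def test_zero_noise_returns_means(self, moments):
        class ZeroRng:
            def __init__(self):
                self._rng = np.random.default_rng(0)

            def integers(self, *a, **k):
                return self._rng.integers(*a, **k)

            def standard_normal(self, shape):
                return np.zeros(shape)

        x, ci = dec.simulate_population_trials(moments, None, 200, ZeroRng())
        np.testing.assert_allclose(x, moments.mu.T[ci])

    def test_empirical_moments_converge(self, moments):
        rng = np.random.default_rng(1)
        noise = dec.noise_correlation_matrix(moments.np_values)
        n = 40_000
        x, ci = dec.simulate_population_trials(moments, noise, n, rng)
        k = ci == 3  # one arbitrary condition
        emp_mean = x[k].mean(axis=0)
        se = moments.sigma[:, 3] / np.sqrt(k.sum())
        frac_within = np.mean(np.abs(emp_mean - moments.mu[:, 3]) < 4 * se)
        assert frac_within > 0.98

    def test_pairwise_correlations_match_target(self):
        # homogeneous sigma isolates the Q r sigma construction
        conds = standard_condition_table()
        npv = np.array([0.3, 0.45, 0.55, 0.6, 0.8])
        mom = dec.PopulationMoments(
            neuron_ids=np.arange(5),
            mu=np.full((5, 16), 20.0),
            sigma=np.full((5, 16), 4.0),
            np_values=npv,
            conditions=conds[["condition_id", "kind", "delta_depth_deg"]].copy(),
        )
        noise = dec.noise_correlation_matrix(npv)
        x, _ = dec.simulate_population_trials(
            mom, noise, 60_000, np.random.default_rng(2)
        )
        emp = np.corrcoef(x.T)
        assert np.abs(emp - noise.correlation).max() < 0.03

    def test_zero_samples_rejected(self, moments):
        with pytest.raises(ValueError):
            dec.simulate_population_trials(moments, None, 0, 0)


class TestTrainLinearDecoder:
    def _moments(self, mu_sep):
        conds = standard_condition_table()
        is_dyn = (conds["kind"] == "dynamic").to_numpy()
        mu = np.full((6, 16), 20.0)
        mu[:, is_dyn] += mu_sep
        return dec.PopulationMoments(
            neuron_ids=np.arange(6),
            mu=mu,
            sigma=np.full((6, 16), 3.0),
            np_values=np.full(6, 0.5),
            conditions=conds[["condition_id", "kind", "delta_depth_deg"]].copy(),
        )

    def test_identical_classes_at_chance(self):
        # 9 stationary vs 6 scored dynamic conditions: with no signal the
        # decoder can only exploit the class prior, so balanced accuracy
        # (mean of the two per-class rates) must sit at chance
        mom = self._moments(0.0)
        rng = np.random.default_rng(3)
        x, ci = dec.simulate_population_trials(mom, None, 20_000, rng)
        res = dec.train_linear_decoder(x, ci, mom, rng=rng)
        dyn_rate = np.mean([res.per_delta[d] for d in (-1.53, -0.57, -0.21, 0.21, 0.57, 1.53)])
        balanced = 0.5 * (dyn_rate + res.per_delta["stationary"])
        assert balanced == pytest.approx(0.5, abs=0.05)
        assert res.accuracy <= 0.65

    def test_separated_classes_near_perfect(self):
        mom = self._moments(40.0)
        rng = np.random.default_rng(4)
        x, ci = dec.simulate_population_trials(mom, None, 20_000, rng)
        res = dec.train_linear_decoder(x, ci, mom, rng=rng)
        assert res.accuracy > 0.99

    def test_accuracy_rises_with_conflict_magnitude(self, moments):
        rng = np.random.default_rng(5)
        noise = dec.noise_correlation_matrix(moments.np_values)
        x, ci = dec.simulate_population_trials(moments, noise, 30_000, rng)
        res = dec.train_linear_decoder(x, ci, moments, rng=rng)
        small = 0.5 * (res.per_delta[0.21] + res.per_delta[-0.21])
        large = 0.5 * (res.per_delta[1.53] + res.per_delta[-1.53])
        assert large > small

    def test_missing_class_rejected(self):
        mom = self._moments(5.0)
        rng = np.random.default_rng(6)
        x = np.random.default_rng(0).normal(20, 3, size=(100, 6))
        ci = np.zeros(100, dtype=int)  # only one (dynamic) condition sampled
        with pytest.raises(ValueError):
            dec.train_linear_decoder(x, ci, mom, rng=rng)


class TestPredictedDp:
    def test_weight_sign_matches_dp_pred_under_independent_noise(self, moments):
        res = dec.predicted_dp(moments, None, n_sim=20, n_samples=15_000, seed=7)
        strong = np.abs(res.weights) > np.quantile(np.abs(res.weights), 0.5)
        agree = np.sign(res.dp_pred - 0.5) == np.sign(res.weights)
        assert agree[strong].mean() > 0.9
        r, p = stats.spearmanr(res.dp_pred, res.weights)
        assert r > 0.6 and p < 1e-6

    def test_near_zero_weight_neuron_near_half(self, moments):
        res = dec.predicted_dp(moments, None, n_sim=15, n_samples=10_000, seed=8)
        idx = np.argmin(np.abs(res.weights))
        assert res.dp_pred[idx] == pytest.approx(0.5, abs=0.1)

    def test_training_never_sees_ambiguous(self, moments, monkeypatch):
        seen = []
        orig = dec.LinearDiscriminantAnalysis.fit

        def spy(self, x, y):
            seen.append(len(y))
            return orig(self, x, y)

        monkeypatch.setattr(dec.LinearDiscriminantAnalysis, "fit", spy)
        rng = np.random.default_rng(9)
        x, ci = dec.simulate_population_trials(moments, None, 8_000, rng)
        res = dec.train_linear_decoder(x, ci, moments, rng=rng)
        n_amb_train = res.n_train  # already excludes ambiguous by contract
        assert seen[0] == n_amb_train
        assert not moments.is_ambiguous[ci].all()


class TestSubgroupDecoding:
    def test_tercile_sizes_match_study_counts(self):
        groups = dec.tercile_split(np.arange(97.0))
        assert [groups[k].size for k in ("lowest", "middle", "highest")] == [33, 32, 32]

    def test_tercile_split_orders_by_statistic(self):
        stat = np.array([5.0, 1.0, 3.0, 2.0, 4.0, 0.0, 6.0, 7.0, 8.0])
        groups = dec.tercile_split(stat)
        assert stat[groups["lowest"]].max() < stat[groups["middle"]].min()
        assert stat[groups["middle"]].max() < stat[groups["highest"]].min()

    def test_homogeneous_population_groups_indistinguishable(self):
        conds = standard_condition_table()
        is_dyn = (conds["kind"] == "dynamic").to_numpy()
        mu = np.tile(np.where(is_dyn, 26.0, 20.0), (12, 1))
        mom = dec.PopulationMoments(
            neuron_ids=np.arange(12),
            mu=mu,
            sigma=np.full((12, 16), 4.0),
            np_values=np.full(12, 0.6),
            conditions=conds[["condition_id", "kind", "delta_depth_deg"]].copy(),
        )
        out = dec.subgroup_decoding(
            mom, np.arange(12.0), n_sims=12, n_samples=4_000, seed=10
        )
        accs = [out[k]["accuracies"] for k in ("lowest", "middle", "highest")]
        assert stats.kruskal(*accs).pvalue > 0.01

    def test_missing_statistic_rejected(self, moments):
        stat = np.full(moments.n_neurons, np.nan)
        with pytest.raises(ValueError, match="missing"):
            dec.subgroup_decoding(moments, stat, n_sims=2, n_samples=500)
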