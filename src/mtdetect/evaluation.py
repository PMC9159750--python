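"""Seeded evaluation battery for the full analysis chain.

Each routine regenerates its inputs from the synthetic-population generator
under the standard study design, runs the relevant analysis, and returns
summary numbers: design arithmetic, ROC-oracle agreement, permutation-test
calibration, the correlated-noise sampling construction, the qualitative
population correlations, the decoding comparisons, and the behavioral
checks.  Problem sizes are arguments with defaults chosen to keep the whole
battery tractable on one CPU (docs/methods.md lists them).
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats

from . import behavior as bh
from . import decoder as dec
from . import detection_metrics as dm
from . import synthpop as sp
from . import tuning_metrics as tm
from .stimgeom import standard_condition_table

__all__ = [
    "design_summary",
    "roc_oracle_agreement",
    "permutation_calibration",
    "eq45_construction",
    "default_dataset",
    "population_structure",
    "noise_mode_comparison",
    "subgroup_analysis",
    "behavior_checks",
]


def design_summary() -> dict:
    """Condition count and dynamic-object depth range of the standard design."""
    table = standard_condition_table()
    dyn = table[table["kind"] == "dynamic"]
    depths = np.concatenate([dyn["d_mp_deg"], dyn["d_bd_deg"]])
    return {
        "n_conditions": int(len(table)),
        "dynamic_depth_min_deg": float(depths.min()),
        "dynamic_depth_max_deg": float(depths.max()),
    }


def _pair_count_auc(a, b) -> float:
    wins = ties = 0
    for x, y in itertools.product(a, b):
        wins += x > y
        ties += x == y
    return (wins + 0.5 * ties) / (len(a) * len(b))


def roc_oracle_agreement(n_instances: int = 1000, max_n: int = 8, seed=0) -> float:
    """Fraction of random small instances where roc_area matches enumeration.

    Integer-valued rates force heavy ties, the hard case for the rank-based
    implementation; agreement is exact (1e-12).
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_instances):
        na, nb = rng.integers(1, max_n + 1, size=2)
        a = rng.integers(0, 6, size=na)
        b = rng.integers(0, 6, size=nb)
        hits += abs(dm.roc_area(a, b).area - _pair_count_auc(a, b)) < 1e-12
    return hits / n_instances


def permutation_calibration(
    n_neurons: int = 2000, n_perm: int = 1000, seed=0, alpha: float = 0.05
) -> dict:
    """Null rejection rates of the DSDI and DP permutation tests.

    Rates are drawn flat across depths (DSDI) and choices are independent of
    rates (DP), so any rejection is a false positive.  The DP test (two-sided)
    is calibrated near alpha; the DSDI sign rule is one-sided in the observed
    direction and rejects at ≈ 2·alpha by construction.
    """
    rng = np.random.default_rng(seed)
    grid = np.array(sp.TUNING_DEPTH_GRID)
    dsdi_rej = 0
    for i in range(n_neurons):
        trials = {float(d): rng.normal(15.0, 4.0, size=6) for d in grid}
        res = tm.permutation_test_dsdi(trials, n_perm=n_perm, seed=rng.integers(2**31))
        dsdi_rej += res.p_value < alpha

    conds = standard_condition_table()
    amb_id = conds.loc[
        (conds["kind"] == "dynamic") & (conds["delta_depth_deg"] == 0), "condition_id"
    ].iloc[0]
    import pandas as pd

    dp_rej = dp_total = 0
    for i in range(n_neurons):
        n_tr = 70
        frame = pd.DataFrame(
            {
                "condition_id": amb_id,
                "rate_hz": rng.normal(20.0, 5.0, size=n_tr),
                "choice_in_rf": rng.random(n_tr) < 0.5,
            }
        )
        res = dm.detection_probability(
            frame, conds, n_perm=n_perm, seed=rng.integers(2**31)
        )
        if res.eligible:
            dp_total += 1
            dp_rej += res.p_value < alpha
    return {
        "dsdi_null_rejection_rate": dsdi_rej / n_neurons,
        "dp_null_rejection_rate": dp_rej / dp_total,
    }


def default_dataset(seed=0) -> dict:
    """One default synthetic dataset: population, session, tuning, metrics."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4)]
    conditions = standard_condition_table()
    population = sp.sample_population(sp.PopulationSpec(n_neurons=100, seed=seeds[0]))
    trials = sp.simulate_session(
        population, conditions, n_reps=35, behavior=sp.BehaviorSpec(), seed=seeds[1]
    )
    tuning = sp.simulate_tuning(population, n_reps=8, seed=seeds[2])
    metric_rng = np.random.default_rng(seeds[3])

    summary = {
        "peak_ratio": [],
        "r_mp_bd": [],
        "dsdi_dyn": [],
        "delta_dsdi": [],
        "dp": [],
        "dp_eligible": [],
        "np": [],
    }
    for neuron in population:
        det = trials[trials["neuron_id"] == neuron.id]
        sub = tuning[tuning["neuron_id"] == neuron.id]
        bd = tm.TuningCurve.from_frame(sub, "BD")
        mp = tm.TuningCurve.from_frame(sub, "MP")
        cong = tm.compute_congruency(bd, mp, det, conditions)
        merged = det.merge(
            conditions[["condition_id", "kind", "delta_depth_deg"]], on="condition_id"
        )
        dyn = merged[merged["kind"] == "dynamic"]
        by_delta = {
            float(d): g["rate_hz"].to_numpy()
            for d, g in dyn.groupby("delta_depth_deg")
            if d != 0
        }
        dp = dm.detection_probability(
            det, conditions, seed=metric_rng.integers(2**31)
        )
        summary["peak_ratio"].append(cong.peak_ratio)
        summary["r_mp_bd"].append(cong.r_mp_bd)
        summary["delta_dsdi"].append(cong.delta_dsdi)
        summary["dsdi_dyn"].append(tm.compute_dsdi_dyn(by_delta).dsdi)
        summary["dp"].append(dp.dp)
        summary["dp_eligible"].append(dp.eligible)
        summary["np"].append(dm.neurometric_performance(det, conditions).np_value)
    return {
        "conditions": conditions,
        "population": population,
        "trials": trials,
        "tuning": tuning,
        "summary": {k: np.asarray(v) for k, v in summary.items()},
    }


def population_structure(dataset: dict) -> dict:
    """Spearman structure of the single-neuron metric relationships."""
    s = dataset["summary"]
    el = s["dp_eligible"]
    r_pr, p_pr = stats.spearmanr(s["peak_ratio"], s["r_mp_bd"])
    r_dd, p_dd = stats.spearmanr(s["dsdi_dyn"], s["delta_dsdi"])
    r_dpnp, p_dpnp = stats.spearmanr(s["dp"][el], s["np"][el])
    return {
        "spearman_peak_ratio_vs_congruency": float(r_pr),
        "p_peak_ratio_vs_congruency": float(p_pr),
        "spearman_dsdi_dyn_vs_delta_dsdi": float(r_dd),
        "p_dsdi_dyn_vs_delta_dsdi": float(p_dd),
        "spearman_dp_vs_np": float(r_dpnp),
        "p_dp_vs_np": float(p_dpnp),
        "mean_dp": float(s["dp"][el].mean()),
        "mean_np": float(s["np"].mean()),
        "n_dp_eligible": int(el.sum()),
    }


def eq45_construction(dataset: dict, n_samples: int = 100_000, seed=0) -> dict:
    """Monte-Carlo check of the µ + Q·r_rand∘σ sampling against its targets.

    Per-condition empirical means are compared with µ at 3σ/√n; empirical
    pairwise correlations are compared with the similarity-rule matrix on a
    homogeneous-σ copy of the moments (so correlations are exactly the
    designed ones).
    """
    moments = dec.moments_from_trials(dataset["trials"], dataset["conditions"])
    noise = dec.noise_correlation_matrix(moments.np_values)
    rng = np.random.default_rng(seed)
    x, ci = dec.simulate_population_trials(moments, noise, n_samples, rng)
    worst_z = 0.0
    within = total = 0
    for k in range(moments.mu.shape[1]):
        sel = ci == k
        n_k = sel.sum()
        emp = x[sel].mean(axis=0)
        se = moments.sigma[:, k] / np.sqrt(n_k)
        z = np.abs(emp - moments.mu[:, k]) / np.where(se > 0, se, np.inf)
        worst_z = max(worst_z, float(z.max()))
        within += int((z < 3.0).sum())
        total += z.size

    homog = dec.PopulationMoments(
        neuron_ids=moments.neuron_ids,
        mu=np.full_like(moments.mu, 20.0),
        sigma=np.full_like(moments.sigma, 4.0),
        np_values=moments.np_values,
        conditions=moments.conditions,
    )
    xh, _ = dec.simulate_population_trials(homog, noise, n_samples, rng)
    emp_corr = np.corrcoef(xh.T)
    max_err = float(np.abs(emp_corr - noise.correlation).max())
    return {
        "mean_within_3se_fraction": within / total,
        "max_mean_z": worst_z,
        "max_correlation_error": max_err,
        "psd_repaired": bool(noise.psd_repaired),
        "n_neurons_decoding": int(moments.n_neurons),
    }


def noise_mode_comparison(
    dataset: dict, n_runs: int = 20, n_sim: int = 5, n_samples: int = 15_000, seed=0
) -> dict:
    """Spearman(DP_pred, NP) under correlated vs. independent noise, per run."""
    moments = dec.moments_from_trials(dataset["trials"], dataset["conditions"])
    noise = dec.noise_correlation_matrix(moments.np_values)
    rng = np.random.default_rng(seed)
    wins = 0
    r_corr, r_ind = [], []
    spread_corr, spread_ind = [], []
    for _ in range(n_runs):
        run_seed = rng.integers(2**31)
        rc = dec.predicted_dp(
            moments, noise, n_sim=n_sim, n_samples=n_samples, seed=run_seed
        )
        ri = dec.predicted_dp(
            moments, None, n_sim=n_sim, n_samples=n_samples, seed=run_seed
        )
        a, _ = stats.spearmanr(rc.dp_pred, moments.np_values)
        b, _ = stats.spearmanr(ri.dp_pred, moments.np_values)
        wins += a > b
        r_corr.append(a)
        r_ind.append(b)
        spread_corr.append(np.nanstd(rc.dp_pred))
        spread_ind.append(np.nanstd(ri.dp_pred))
    return {
        "runs_correlated_stronger": int(wins),
        "n_runs": n_runs,
        "mean_spearman_correlated": float(np.mean(r_corr)),
        "mean_spearman_independent": float(np.mean(r_ind)),
        "mean_dp_pred_spread_correlated": float(np.mean(spread_corr)),
        "mean_dp_pred_spread_independent": float(np.mean(spread_ind)),
    }


def subgroup_analysis(
    dataset: dict, n_sims: int = 100, n_samples: int = 8_000, seed=0
) -> dict:
    """Tercile decoding by peak response ratio with DP_pred summaries."""
    moments = dec.moments_from_trials(dataset["trials"], dataset["conditions"])
    order = {nid: i for i, nid in enumerate(moments.neuron_ids)}
    stat = np.empty(moments.n_neurons)
    ids = [n.id for n in dataset["population"]]
    for nid, pr in zip(ids, dataset["summary"]["peak_ratio"]):
        if nid in order:
            stat[order[nid]] = pr
    out = dec.subgroup_decoding(
        moments, stat, n_sims=n_sims, n_samples=n_samples, seed=seed
    )
    res = {}
    for name, grp in out.items():
        dp = grp["dp_pred_mean"]
        dp = dp[np.isfinite(dp)]
        res[name] = {
            "accuracy_mean": grp["accuracy_mean"],
            "accuracy_ci": grp["accuracy_ci"],
            "median_dp_pred": float(np.median(dp)),
            "signed_rank_p_vs_half": float(stats.wilcoxon(dp - 0.5).pvalue),
        }
    res["p_highest_beats_lowest"] = float(
        stats.mannwhitneyu(
            out["highest"]["accuracies"],
            out["lowest"]["accuracies"],
            alternative="greater",
        ).pvalue
    )
    return res


def behavior_checks(
    seed=0, n_sessions: int = 200, n_trials: int = 500, n_reps: int = 35
) -> dict:
    """Psychometric shape, monocular control, and Eq.-1-style recovery.

    Coverage: simulated multinomial-logit sessions with known utility weights
    are refit; the fraction of 95% Wald CIs containing the implied true
    coefficients (+b for the own-location term, −b for the other location in
    the two-object task) is reported over all sessions and coefficients.
    """
    ss = np.random.SeedSequence(seed)
    s_beh, s_mono, s_cov = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    conditions = standard_condition_table()
    pop = sp.sample_population(sp.PopulationSpec(n_neurons=2, seed=0))
    trials = sp.simulate_session(
        pop, conditions, n_reps=n_reps, behavior=sp.BehaviorSpec(), seed=s_beh
    ).drop_duplicates(subset=["trial_id"])
    curve = bh.psychometric(trials).table.set_index("delta_deg")
    chance_ok = bool(
        curve.loc[0.0, "ci_low"] <= 50.0 <= curve.loc[0.0, "ci_high"]
    )
    mono = sp.simulate_session(
        pop,
        conditions,
        n_reps=n_reps,
        behavior=sp.BehaviorSpec(monocular=True),
        seed=s_mono,
    ).drop_duplicates(subset=["trial_id"])
    # per-level CIs at 99.5% so the 7 simultaneous checks jointly hold ~96%
    mcurve = bh.psychometric(mono, confidence=0.995).table
    mono_ok = bool(((mcurve["ci_low"] <= 50.0) & (mcurve["ci_high"] >= 50.0)).all())

    truth = {"b_bd": 0.3, "b_mp": 0.15, "b_delta": 2.0}
    table = sp.simulate_choice_sessions(
        truth, n_sessions=n_sessions, n_trials=n_trials, seed=s_cov
    )
    covered = total = 0
    valid = 0
    for s in range(n_sessions):
        res = bh.choice_regression(table[table["session_id"] == s], n_objects=2)
        if not res.valid:
            continue
        valid += 1
        for _, row in res.betas.iterrows():
            true_val = truth[f"b_{row['cue']}" if row["cue"] != "delta" else "b_delta"]
            if row["location"] != row["target"]:
                true_val = -true_val
            lo = row["beta"] - 1.96 * row["se"]
            hi = row["beta"] + 1.96 * row["se"]
            covered += lo <= true_val <= hi
            total += 1
    pc = {
        f"percent_correct_delta_{d:+.2f}": float(curve.loc[d, "percent_correct"])
        for d in sorted(curve.index)
    }
    return {
        "psychometric_chance_at_zero": chance_ok,
        "monocular_chance_all_levels": mono_ok,
        "monotone_rise": bool(
            curve.loc[0.21, "percent_correct"] < curve.loc[0.57, "percent_correct"]
            and curve.loc[-0.21, "percent_correct"]
            < curve.loc[-0.57, "percent_correct"]
        ),
        "ci_coverage": covered / total if total else float("nan"),
        "n_valid_sessions": valid,
        **pc,
    }
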