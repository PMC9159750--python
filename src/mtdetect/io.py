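"""Delimited-text interchange, selection criteria, and the seeded pipeline.

All tables travel as UTF-8 CSV with a one-line schema header comment
(``# mtdetect-schema: <table>/<version>``); loaders validate the header, the
column set, and row-level sanity (finite non-negative rates, unique trial
keys, known condition ids) and fail hard with row indices on violation.

Selection mirrors the study's inclusion rules: detection-probability
analyses require at least five choices toward each target on the ambiguous
condition, and population decoding requires responses to every standard
in-RF condition.  ``run_pipeline`` chains the full synthetic analysis
(simulate → tuning metrics → detection metrics → behavior → decoding →
report) deterministically from a single seed and records every derived seed
in a run manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as behavior_mod
from . import decoder as decoder_mod
from . import detection_metrics as det_mod
from . import synthpop
from . import tuning_metrics as tun_mod
from .stimgeom import build_condition_table

__all__ = [
    "SCHEMAS",
    "SelectionCriteria",
    "write_table",
    "load_table",
    "load_trials",
    "load_tuning",
    "load_conditions",
    "apply_selection",
    "default_config",
    "load_config",
    "run_pipeline",
]

SCHEMA_PREFIX = "# mtdetect-schema:"

SCHEMAS = {
    "conditions": {
        "version": 1,
        "columns": [
            "condition_id",
            "kind",
            "d_bd_deg",
            "d_mp_deg",
            "delta_depth_deg",
            "pedestal_deg",
        ],
    },
    "trials": {
        "version": 1,
        "columns": [
            "session_id",
            "neuron_id",
            "trial_id",
            "condition_id",
            "other_condition_id",
            "phase_deg",
            "delta_deg",
            "rate_hz",
            "choice_in_rf",
            "correct",
            "monocular",
        ],
    },
    "tuning": {
        "version": 1,
        "columns": ["neuron_id", "cue", "depth_deg", "rep", "rate_hz"],
    },
}


@dataclass(frozen=True)
class SelectionCriteria:
    """Neuron-inclusion rules for the population analyses."""

    require_standard_delta_set: bool = True
    min_choices_per_side: int = 5  # DP eligibility on ΔDepth = 0 trials
    require_all_stationary_depths: bool = True  # decoding eligibility

    def __post_init__(self) -> None:
        if self.min_choices_per_side < 1:
            raise ValueError("min_choices_per_side must be >= 1")


def write_table(df: pd.DataFrame, path, table: str) -> None:
    """Write a schema-stamped CSV."""
    spec = SCHEMAS[table]
    missing = [c for c in spec["columns"] if c not in df.columns]
    if missing:
        raise ValueError(f"{table}: missing columns {missing}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"{SCHEMA_PREFIX} {table}/{spec['version']}\n")
        df[spec["columns"]].to_csv(fh, index=False)


def load_table(path, table: str) -> pd.DataFrame:
    """Read and validate a schema-stamped CSV."""
    spec = SCHEMAS[table]
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
    expected = f"{SCHEMA_PREFIX} {table}/{spec['version']}"
    if header != expected:
        raise ValueError(f"{path}: schema header {header!r} != {expected!r}")
    df = pd.read_csv(path, comment="#")
    missing = [c for c in spec["columns"] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def _bad_rows(mask: pd.Series, what: str) -> None:
    if mask.any():
        rows = [int(i) for i in np.flatnonzero(mask.to_numpy())[:10]]
        raise ValueError(f"{what} at rows {rows}")


def load_conditions(path) -> pd.DataFrame:
    df = load_table(path, "conditions")
    _bad_rows(df["condition_id"].duplicated(), "duplicate condition ids")
    _bad_rows(~df["kind"].isin(["dynamic", "stationary"]), "unknown condition kind")
    return df


def load_trials(path, conditions: pd.DataFrame | None = None) -> pd.DataFrame:
    df = load_table(path, "trials")
    _bad_rows(~np.isfinite(df["rate_hz"]), "non-finite rate")
    _bad_rows(df["rate_hz"] < 0, "negative rate")
    _bad_rows(
        df.duplicated(subset=["session_id", "neuron_id", "trial_id"]),
        "duplicate trial keys",
    )
    if conditions is not None:
        known = set(conditions["condition_id"])
        _bad_rows(~df["condition_id"].isin(known), "unknown condition id")
        _bad_rows(~df["other_condition_id"].isin(known), "unknown condition id")
    for col in ("choice_in_rf", "correct", "monocular"):
        df[col] = df[col].astype(bool)
    return df


def load_tuning(path) -> pd.DataFrame:
    df = load_table(path, "tuning")
    _bad_rows(~np.isfinite(df["rate_hz"]), "non-finite rate")
    _bad_rows(df["rate_hz"] < 0, "negative rate")
    _bad_rows(~df["cue"].isin(["BD", "MP"]), "unknown cue")
    return df


def apply_selection(
    trials: pd.DataFrame,
    conditions: pd.DataFrame,
    criteria: SelectionCriteria = SelectionCriteria(),
) -> tuple[dict, pd.DataFrame]:
    """Per-neuron eligibility for the DP and decoding analyses.

    Returns ``(eligible, audit)`` where ``eligible`` maps analysis name
    ("dp", "decoding") to arrays of neuron ids and ``audit`` logs one row per
    neuron per analysis with the exclusion reason (empty when included).
    """
    merged = trials.merge(
        conditions[["condition_id", "kind", "delta_depth_deg"]], on="condition_id"
    )
    standard_deltas = set(
        conditions.loc[conditions["kind"] == "dynamic", "delta_depth_deg"]
    )
    all_cond = set(conditions["condition_id"])
    audit_rows = []
    dp_ok, dec_ok = [], []
    for nid, grp in merged.groupby("neuron_id"):
        reasons_dp, reasons_dec = [], []
        if criteria.require_standard_delta_set:
            seen = set(grp.loc[grp["kind"] == "dynamic", "delta_depth_deg"])
            if not standard_deltas <= seen:
                msg = "missing_delta_values"
                reasons_dp.append(msg)
                reasons_dec.append(msg)
        amb = grp[(grp["kind"] == "dynamic") & (grp["delta_depth_deg"] == 0)]
        n_in = int(amb["choice_in_rf"].sum())
        n_out = int((~amb["choice_in_rf"]).sum())
        if min(n_in, n_out) < criteria.min_choices_per_side:
            reasons_dp.append("min_choices")
        if criteria.require_all_stationary_depths:
            if not all_cond <= set(grp["condition_id"]):
                reasons_dec.append("missing_conditions")
        if not reasons_dp:
            dp_ok.append(nid)
        if not reasons_dec:
            dec_ok.append(nid)
        audit_rows.append(
            {
                "neuron_id": nid,
                "dp_eligible": not reasons_dp,
                "dp_reason": ";".join(reasons_dp),
                "decoding_eligible": not reasons_dec,
                "decoding_reason": ";".join(reasons_dec),
            }
        )
    eligible = {"dp": np.array(dp_ok), "decoding": np.array(dec_ok)}
    return eligible, pd.DataFrame(audit_rows)


def default_config() -> dict:
    """Pipeline defaults: the standard design with a paper-scaled population."""
    return {
        "seed": 0,
        "design": {
            "pedestal": -0.45,
            "delta_set": [-1.53, -0.57, -0.21, 0.0, 0.21, 0.57, 1.53],
            "stationary_depths": [round(-1.6 + 0.4 * i, 10) for i in range(9)],
        },
        "population": {"n_neurons": 100, "fraction_opposite": 0.5, "near_bias_mp": 0.75},
        "behavior": {
            "sensitivity": 2.5,
            "lapse": 0.0,
            "choice_coupling": 0.5,
            "monocular": False,
        },
        "session": {"n_reps": 35, "tuning_reps": 8},
        "decode": {
            "mode": "correlated",
            "n_samples": 20000,
            "split": 0.9,
            "n_sim": 50,
            "subgroup_n_sims": 100,
            "subgroup_n_samples": 8000,
            "grouping": "peak_ratio_terciles",
        },
    }


def load_config(path) -> dict:
    """Load a YAML config, overlaying the defaults."""
    with open(path, encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _neuron_metrics(
    neurons, tuning: pd.DataFrame, trials: pd.DataFrame, conditions: pd.DataFrame, seed
) -> pd.DataFrame:
    """Per-neuron DSDI/congruency table (neuron_metrics.csv layout)."""
    rng = np.random.default_rng(seed)
    rows = []
    for neuron in neurons:
        sub = tuning[tuning["neuron_id"] == neuron.id]
        bd = tun_mod.TuningCurve.from_frame(sub, "BD")
        mp = tun_mod.TuningCurve.from_frame(sub, "MP")
        det = trials[trials["neuron_id"] == neuron.id]
        res_bd = tun_mod.permutation_test_dsdi(bd, seed=rng.integers(2**31))
        res_mp = tun_mod.permutation_test_dsdi(mp, seed=rng.integers(2**31))
        merged = det.merge(
            conditions[["condition_id", "kind", "delta_depth_deg"]], on="condition_id"
        )
        dyn = merged[merged["kind"] == "dynamic"]
        by_delta = {
            float(d): g["rate_hz"].to_numpy()
            for d, g in dyn.groupby("delta_depth_deg")
            if d != 0
        }
        dsdi_dyn = tun_mod.compute_dsdi_dyn(by_delta).dsdi
        cong = tun_mod.compute_congruency(bd, mp, det, conditions)
        rows.append(
            {
                "neuron_id": neuron.id,
                "dsdi_bd": res_bd.dsdi,
                "p_bd": res_bd.p_value,
                "dsdi_mp": res_mp.dsdi,
                "p_mp": res_mp.p_value,
                "dsdi_dyn": dsdi_dyn,
                "r_mp_bd": cong.r_mp_bd,
                "p_r": cong.p_value,
                "class": cong.cls,
                "delta_dsdi": cong.delta_dsdi,
                "peak_ratio": cong.peak_ratio,
            }
        )
    return pd.DataFrame(rows)


def _detection_table(
    trials: pd.DataFrame, conditions: pd.DataFrame, criteria: SelectionCriteria, seed
) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    for nid, grp in trials.groupby("neuron_id"):
        nm = det_mod.neurometric_performance(grp, conditions)
        dp = det_mod.detection_probability(
            grp,
            conditions,
            min_choices=criteria.min_choices_per_side,
            seed=rng.integers(2**31),
        )
        row = {"neuron_id": nid, "np": nm.np_value}
        for delta, area in nm.areas.items():
            row[f"roc_{delta:+.2f}"] = area
        row.update(
            {
                "dp": dp.dp,
                "dp_p": dp.p_value,
                "n_in": dp.n_in,
                "n_out": dp.n_out,
                "eligible": dp.eligible,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _behavior_tables(trials: pd.DataFrame, conditions: pd.DataFrame):
    beh = trials.drop_duplicates(subset=["session_id", "trial_id"])
    psy = behavior_mod.psychometric(beh)
    cond_info = conditions.set_index("condition_id")
    loc_rows = []
    for _, row in beh.iterrows():
        for loc, cid in ((0, row["condition_id"]), (1, row["other_condition_id"])):
            info = cond_info.loc[cid]
            loc_rows.append(
                {
                    "session_id": row["session_id"],
                    "trial_id": row["trial_id"],
                    "location": loc,
                    "abs_d_bd": abs(info["d_bd_deg"]),
                    "abs_d_mp": abs(info["d_mp_deg"]),
                    "abs_delta": abs(info["delta_depth_deg"]),
                    "chosen": (loc == 0) == bool(row["choice_in_rf"]),
                }
            )
    loc_table = pd.DataFrame(loc_rows)
    reg = behavior_mod.choice_regression(loc_table, n_objects=2)
    return psy, reg


def _report_figures(out: Path, psy, metrics, detection, subgroups) -> list:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = out / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    panels = []

    def save(fig, name):
        path = figdir / name
        fig.savefig(path, dpi=110)
        plt.close(fig)
        panels.append(str(path.relative_to(out)))

    fig, ax = plt.subplots()
    t = psy.table
    ax.errorbar(
        t["delta_deg"],
        t["percent_correct"],
        yerr=[t["percent_correct"] - t["ci_low"], t["ci_high"] - t["percent_correct"]],
        fmt="o-",
    )
    ax.axhline(50, ls="--", c="gray")
    ax.set(xlabel="ΔDepth (deg)", ylabel="percent correct", title="Psychometric")
    save(fig, "psychometric.png")

    fig, ax = plt.subplots()
    ax.scatter(metrics["dsdi_mp"], metrics["dsdi_bd"], s=14)
    ax.axhline(0, c="gray", lw=0.5)
    ax.axvline(0, c="gray", lw=0.5)
    ax.set(xlabel="DSDI (motion parallax)", ylabel="DSDI (disparity)", title="Depth-sign congruency")
    save(fig, "dsdi_scatter.png")

    fig, ax = plt.subplots()
    el = detection[detection["eligible"]]
    ax.hist(el["dp"], bins=20)
    ax.axvline(0.5, ls="--", c="gray")
    ax.set(xlabel="detection probability", ylabel="neurons", title="DP distribution")
    save(fig, "dp_hist.png")

    fig, ax = plt.subplots()
    ax.scatter(el["np"], el["dp"], s=14)
    ax.axhline(0.5, c="gray", lw=0.5)
    ax.axvline(0.5, c="gray", lw=0.5)
    ax.set(xlabel="neurometric performance", ylabel="detection probability", title="DP vs NP")
    save(fig, "dp_vs_np.png")

    fig, ax = plt.subplots()
    names = list(subgroups)
    means = [subgroups[n]["accuracy_mean"] for n in names]
    err = [
        (
            subgroups[n]["accuracy_mean"] - subgroups[n]["accuracy_ci"][0],
            subgroups[n]["accuracy_ci"][1] - subgroups[n]["accuracy_mean"],
        )
        for n in names
    ]
    ax.bar(names, means, yerr=np.array(err).T, capsize=4)
    ax.set(ylabel="proportion correct", title="Subgroup decoding")
    save(fig, "subgroup_decoding.png")
    return panels


def run_pipeline(config: dict | None = None, out_dir="results/pipeline") -> dict:
    """Run the full seeded synthetic analysis and write its artifacts.

    Returns the manifest (also written to ``manifest.json``), which records
    the seeds of every stochastic stage and the output paths.
    """
    cfg = default_config()
    if config:
        for key, val in config.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key] = {**cfg[key], **val}
            else:
                cfg[key] = val
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg["seed"])
    seeds = {
        name: int(child.generate_state(1)[0] % 2**31)
        for name, child in zip(
            ["tuning", "session", "metrics", "detection", "decode"], ss.spawn(5)
        )
    }

    conditions = build_condition_table(
        cfg["design"]["delta_set"],
        cfg["design"]["stationary_depths"],
        cfg["design"]["pedestal"],
    )
    write_table(conditions, out / "conditions.csv", "conditions")

    pop = synthpop.PopulationSpec(seed=cfg["seed"], **cfg["population"])
    neurons = synthpop.sample_population(pop)
    beh_spec = synthpop.BehaviorSpec(**cfg["behavior"])
    tuning = synthpop.simulate_tuning(
        neurons, n_reps=cfg["session"]["tuning_reps"], seed=seeds["tuning"]
    )
    trials = synthpop.simulate_session(
        neurons,
        conditions,
        n_reps=cfg["session"]["n_reps"],
        behavior=beh_spec,
        seed=seeds["session"],
    )
    write_table(tuning, out / "tuning.csv", "tuning")
    write_table(trials, out / "trials.csv", "trials")

    metrics = _neuron_metrics(neurons, tuning, trials, conditions, seeds["metrics"])
    metrics.to_csv(out / "neuron_metrics.csv", index=False)

    criteria = SelectionCriteria()
    detection = _detection_table(trials, conditions, criteria, seeds["detection"])
    detection.to_csv(out / "detection_metrics.csv", index=False)
    eligible, audit = apply_selection(trials, conditions, criteria)
    audit.to_csv(out / "selection_audit.csv", index=False)

    psy, reg = _behavior_tables(trials, conditions)
    psy.table.to_csv(out / "behavior_summary.csv", index=False)
    reg.betas.to_csv(out / "regression_betas.csv", index=False)

    dec_cfg = cfg["decode"]
    dec_trials = trials[trials["neuron_id"].isin(eligible["decoding"])]
    moments = decoder_mod.moments_from_trials(dec_trials, conditions)
    noise = (
        decoder_mod.noise_correlation_matrix(moments.np_values)
        if dec_cfg["mode"] == "correlated"
        else None
    )
    dp_pred = decoder_mod.predicted_dp(
        moments,
        noise,
        n_sim=dec_cfg["n_sim"],
        n_samples=dec_cfg["n_samples"],
        split=dec_cfg["split"],
        seed=seeds["decode"],
    )
    pd.DataFrame(
        {
            "neuron_id": moments.neuron_ids,
            "dp_pred": dp_pred.dp_pred,
            "ci_low": dp_pred.ci_low,
            "ci_high": dp_pred.ci_high,
            "weight": dp_pred.weights,
        }
    ).to_csv(out / "dp_pred.csv", index=False)

    stat_col = "peak_ratio" if dec_cfg["grouping"] == "peak_ratio_terciles" else "r_mp_bd"
    stat = (
        metrics.set_index("neuron_id")
        .loc[moments.neuron_ids, stat_col]
        .to_numpy(dtype=float)
    )
    subgroups = decoder_mod.subgroup_decoding(
        moments,
        stat,
        n_sims=dec_cfg["subgroup_n_sims"],
        n_samples=dec_cfg["subgroup_n_samples"],
        split=dec_cfg["split"],
        correlated=dec_cfg["mode"] == "correlated",
        seed=seeds["decode"] + 1,
    )
    perf = pd.DataFrame(
        [
            {
                "subgroup": name,
                "accuracy_mean": res["accuracy_mean"],
                "ci_low": res["accuracy_ci"][0],
                "ci_high": res["accuracy_ci"][1],
            }
            for name, res in subgroups.items()
        ]
    )
    perf.to_csv(out / "decode_performance.csv", index=False)

    panels = _report_figures(out, psy, metrics, detection, subgroups)

    manifest = {
        "config": cfg,
        "seeds": seeds,
        "criteria": asdict(criteria),
        "n_neurons": len(neurons),
        "n_dp_eligible": int(eligible["dp"].size),
        "n_decoding_eligible": int(eligible["decoding"].size),
        "decoder_accuracy": dp_pred.accuracy,
        "outputs": sorted(
            str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
        ),
        "panels": panels,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
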