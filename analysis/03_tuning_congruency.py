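#!/usr/bin/env python
"""Depth-sign tuning, cue congruency, and dynamic-object selectivity.

Computes per-neuron DSDI for both cues (with the permutation test), the
cue-congruency correlation R_MP_BD, DSDI_dyn over the ΔDepth responses, and
the peak dynamic:stationary response ratio, then tests the two population
relationships: selectivity for dynamic objects is anti-correlated with cue
congruency, and ΔDepth-sign preference follows the difference in depth-sign
tuning between the cues.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from mtdetect import io as mio
from mtdetect import tuning_metrics as tm

OUT = Path("results/analysis")
SEED = 10

conditions = mio.load_conditions(OUT / "conditions.csv")
trials = mio.load_trials(OUT / "trials.csv", conditions)
tuning = mio.load_tuning(OUT / "tuning.csv")

rng = np.random.default_rng(SEED)
rows = []
for nid in sorted(trials["neuron_id"].unique()):
    det = trials[trials["neuron_id"] == nid]
    sub = tuning[tuning["neuron_id"] == nid]
    bd = tm.TuningCurve.from_frame(sub, "BD")
    mp = tm.TuningCurve.from_frame(sub, "MP")
    res_bd = tm.permutation_test_dsdi(bd, seed=rng.integers(2**31))
    res_mp = tm.permutation_test_dsdi(mp, seed=rng.integers(2**31))
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
    rows.append(
        {
            "neuron_id": nid,
            "dsdi_bd": res_bd.dsdi,
            "p_bd": res_bd.p_value,
            "dsdi_mp": res_mp.dsdi,
            "p_mp": res_mp.p_value,
            "dsdi_dyn": tm.compute_dsdi_dyn(by_delta).dsdi,
            "r_mp_bd": cong.r_mp_bd,
            "p_r": cong.p_value,
            "class": cong.cls,
            "delta_dsdi": cong.delta_dsdi,
            "peak_ratio": cong.peak_ratio,
        }
    )
metrics = pd.DataFrame(rows)
metrics.to_csv(OUT / "neuron_metrics.csv", index=False)

near_mp = (metrics["dsdi_mp"] < 0).mean()
print(f"{len(metrics)} neurons; {100 * near_mp:.0f}% near-preferring by DSDI_MP; "
      f"classes: {metrics['class'].value_counts().to_dict()}")
r1, p1 = stats.spearmanr(metrics["peak_ratio"], metrics["r_mp_bd"])
print(f"peak response ratio vs R_MP_BD: Spearman R = {r1:+.2f} (p = {p1:.2g}) — "
      "incongruent cells respond preferentially to dynamic objects")
r2, p2 = stats.spearmanr(metrics["dsdi_dyn"], metrics["delta_dsdi"])
print(f"DSDI_dyn vs ΔDSDI:              Spearman R = {r2:+.2f} (p = {p2:.2g}) — "
      "ΔDepth preference follows the cue-tuning difference")
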