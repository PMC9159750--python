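"""Shared fixtures: the standard design and one default synthetic dataset.

The expensive objects (session, tuning table, per-neuron metrics) are built
once per test run and reused; tests that need different generator settings
build their own small populations.
"""

import numpy as np
import pytest

from mtdetect import decoder as dec
from mtdetect import detection_metrics as dm
from mtdetect import synthpop as sp
from mtdetect import tuning_metrics as tm
from mtdetect.stimgeom import standard_condition_table


@pytest.fixture(scope="session")
def conditions():
    return standard_condition_table()


@pytest.fixture(scope="session")
def population():
    return sp.sample_population(sp.PopulationSpec(n_neurons=100, seed=0))


@pytest.fixture(scope="session")
def session_trials(population, conditions):
    return sp.simulate_session(
        population, conditions, n_reps=35, behavior=sp.BehaviorSpec(), seed=1
    )


@pytest.fixture(scope="session")
def tuning_table(population):
    return sp.simulate_tuning(population, n_reps=8, seed=2)


@pytest.fixture(scope="session")
def neuron_summary(population, conditions, session_trials, tuning_table):
    """Per-neuron metric arrays over the default synthetic population."""
    rows = {
        "peak_ratio": [],
        "r_mp_bd": [],
        "dsdi_dyn": [],
        "delta_dsdi": [],
        "dp": [],
        "np": [],
        "congruency": [],
    }
    for neuron in population:
        det = session_trials[session_trials["neuron_id"] == neuron.id]
        sub = tuning_table[tuning_table["neuron_id"] == neuron.id]
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
        rows["peak_ratio"].append(cong.peak_ratio)
        rows["r_mp_bd"].append(cong.r_mp_bd)
        rows["delta_dsdi"].append(cong.delta_dsdi)
        rows["dsdi_dyn"].append(tm.compute_dsdi_dyn(by_delta).dsdi)
        rows["dp"].append(dm.detection_probability(det, conditions, seed=3).dp)
        rows["np"].append(dm.neurometric_performance(det, conditions).np_value)
        rows["congruency"].append(neuron.congruency)
    return {k: np.asarray(v) for k, v in rows.items()}


@pytest.fixture(scope="session")
def moments(session_trials, conditions):
    return dec.moments_from_trials(session_trials, conditions)
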