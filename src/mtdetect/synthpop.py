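"""Synthetic MT populations, trial responses, and choices.

The generator emulates the statistical structure that the downstream metrics
assume: Gaussian depth-tuning bumps over equivalent disparity for each cue
(BD, MP); a mixture of congruent and opposite cells (matched vs. mismatched
depth-sign preferences) with a near bias for motion-parallax preferences;
detection-task responses built from a rectified additive combination of the
two cue drives plus a conflict-sensitivity term that grows with the tuning
mismatch between the cues, so opposite cells respond selectively to
cue-conflict (dynamic) stimuli across the ΔDepth range whose sign matches
their preference mismatch; trial rate noise with SD proportional to the
square root of the mean; and choices produced by a logistic observer on
|ΔDepth| whose decision variable shares a latent Gaussian with the neural
noise (weighted by each cell's graded dynamic-preference index), so neurons
preferring dynamic objects acquire detection probabilities above 0.5.

All entry points are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .stimgeom import (
    STANDARD_DELTA_SET,
    STANDARD_STATIONARY_DEPTHS,
    standard_condition_table,
)

__all__ = [
    "CueTuning",
    "NeuronSpec",
    "PopulationSpec",
    "BehaviorSpec",
    "TUNING_DEPTH_GRID",
    "sample_population",
    "tuning_mean",
    "tuning_mismatch",
    "detection_mean",
    "dynamic_preference_index",
    "dynamic_preference_sign",
    "simulate_tuning",
    "simulate_session",
    "simulate_rasters",
    "simulate_choice_sessions",
]

#: Depth grid for tuning measurements: −2 … +2 deg in steps of 0.5.
TUNING_DEPTH_GRID: tuple[float, ...] = tuple(round(-2.0 + 0.5 * i, 10) for i in range(9))


@dataclass(frozen=True)
class CueTuning:
    preferred_depth: float  # deg equivalent disparity
    width: float  # deg
    gain: float  # spikes/s above baseline at the preferred depth

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("tuning width must be positive")
        if self.gain < 0:
            raise ValueError("tuning gain must be non-negative")


@dataclass(frozen=True)
class NeuronSpec:
    id: int
    baseline: float  # spikes/s
    bd: CueTuning
    mp: CueTuning
    congruency: str  # "congruent" or "opposite" (sign relation of preferences)
    trial_noise: float = 1.0  # k in SD = k·sqrt(mean)

    def __post_init__(self) -> None:
        if self.baseline < 0:
            raise ValueError("baseline must be non-negative")
        if self.congruency not in ("congruent", "opposite"):
            raise ValueError(f"unknown congruency {self.congruency!r}")


@dataclass(frozen=True)
class PopulationSpec:
    n_neurons: int = 100
    fraction_opposite: float = 0.5
    near_bias_mp: float = 0.75  # P(MP preferred depth is near)
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.fraction_opposite, self.near_bias_mp):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass(frozen=True)
class BehaviorSpec:
    """Synthetic observer: logistic in |ΔDepth| with shared-noise coupling."""

    sensitivity: float = 2.5  # 1/deg, slope of choice evidence on |ΔDepth|
    lapse: float = 0.0
    choice_coupling: float = 0.5  # weight of the shared latent on rates & choice
    monocular: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse <= 0.5:
            raise ValueError("lapse must lie in [0, 0.5]")
        if self.sensitivity < 0:
            raise ValueError("sensitivity must be non-negative")


def sample_population(spec: PopulationSpec) -> list[NeuronSpec]:
    """Draw a population of neuron specs (deterministic given spec.seed).

    Baselines and gains are log-normal (BD gains larger than MP, as disparity
    responses dominate in MT); preferred-depth magnitudes are uniform on
    0.4–2.0 deg with the MP sign near-biased and the BD sign set by the
    congruency label.
    """
    if spec.n_neurons < 2:
        raise ValueError("need at least 2 neurons")
    rng = np.random.default_rng(spec.seed)
    neurons = []
    for i in range(spec.n_neurons):
        baseline = float(rng.lognormal(math.log(6.0), 0.4))
        opposite = rng.random() < spec.fraction_opposite
        mp_sign = -1.0 if rng.random() < spec.near_bias_mp else 1.0
        mp_pref = mp_sign * rng.uniform(0.4, 2.0)
        bd_sign = -mp_sign if opposite else mp_sign
        bd_pref = bd_sign * rng.uniform(0.4, 2.0)
        mp = CueTuning(
            preferred_depth=float(mp_pref),
            width=float(rng.uniform(0.4, 1.0)),
            gain=float(rng.lognormal(math.log(20.0), 0.4)),
        )
        bd = CueTuning(
            preferred_depth=float(bd_pref),
            width=float(rng.uniform(0.4, 1.0)),
            gain=float(rng.lognormal(math.log(30.0), 0.4)),
        )
        neurons.append(
            NeuronSpec(
                id=i,
                baseline=baseline,
                bd=bd,
                mp=mp,
                congruency="opposite" if opposite else "congruent",
            )
        )
    return neurons


def tuning_mean(neuron: NeuronSpec, cue: str, depth) -> float:
    """Mean rate (spikes/s): baseline + gain·exp(−(d − pref)² / 2w²)."""
    tun = {"BD": neuron.bd, "MP": neuron.mp}[cue]
    d = np.asarray(depth, dtype=float)
    out = neuron.baseline + tun.gain * np.exp(
        -((d - tun.preferred_depth) ** 2) / (2.0 * tun.width**2)
    )
    return out if out.ndim else float(out)


def tuning_mismatch(neuron: NeuronSpec) -> float:
    """Cue-tuning mismatch in [0, 1]: (1 − ρ)/2 with ρ the Pearson correlation
    of the two unit tuning bumps sampled on the 9-point depth grid.

    Matched preferences give ≈0; sign-opposite, well-separated preferences
    approach 1.  This indexes how "opposite" a cell is independent of gains.
    """
    grid = np.array(TUNING_DEPTH_GRID)
    fm = np.exp(-((grid - neuron.mp.preferred_depth) ** 2) / (2 * neuron.mp.width**2))
    fb = np.exp(-((grid - neuron.bd.preferred_depth) ** 2) / (2 * neuron.bd.width**2))
    rho = np.corrcoef(fm, fb)[0, 1]
    return float((1.0 - rho) / 2.0)


def detection_mean(
    neuron: NeuronSpec,
    d_bd,
    d_mp,
    w_bd: float = 0.5,
    w_mp: float = 0.5,
    conflict_gain: float = 0.8,
    conflict_scale: float = 0.6,
):
    """Detection-task mean rate: rectified additive cue combination plus a
    conflict-sensitivity term for cells with mismatched depth tuning.

    The additive part is
    ``baseline + w_BD·[f_BD(d_BD) − baseline] + w_MP·[f_MP(d_MP) − baseline]``.
    Mismatched cells additionally gain a surge for cue conflicts whose sign
    matches their preference mismatch (a near-MP/far-BD cell responds to
    ΔDepth < 0), with amplitude ``conflict_gain · mismatch · mean gain`` and
    saturating growth ``|Δ| / (|Δ| + conflict_scale)``; the whole drive is
    rectified at zero.  The surge vanishes at ΔDepth = 0, so an ambiguous
    dynamic condition equals a stationary condition at the pedestal, and
    ``conflict_gain = 0`` recovers the purely additive model.
    """
    b = neuron.baseline
    drive = (
        b
        + w_bd * (tuning_mean(neuron, "BD", d_bd) - b)
        + w_mp * (tuning_mean(neuron, "MP", d_mp) - b)
    )
    if conflict_gain > 0:
        delta = np.asarray(d_mp, dtype=float) - np.asarray(d_bd, dtype=float)
        pref_gap = neuron.mp.preferred_depth - neuron.bd.preferred_depth
        gate = np.sign(delta) == np.sign(pref_gap)
        amp = (
            conflict_gain
            * tuning_mismatch(neuron)
            * 0.5
            * (neuron.mp.gain + neuron.bd.gain)
        )
        drive = drive + amp * gate * np.abs(delta) / (np.abs(delta) + conflict_scale)
    out = np.maximum(0.0, drive)
    return out if np.ndim(out) else float(out)


def _condition_means(neuron: NeuronSpec, conditions: pd.DataFrame) -> np.ndarray:
    return np.asarray(
        detection_mean(
            neuron,
            conditions["d_bd_deg"].to_numpy(),
            conditions["d_mp_deg"].to_numpy(),
        )
    )


def dynamic_preference_index(
    neuron: NeuronSpec, conditions: pd.DataFrame, scale: float = 8.0
) -> float:
    """Graded dynamic-vs-stationary preference in [−1.5, 1.5].

    A contrast of mean dynamic- vs. stationary-condition responses,
    ``(dyn − sta)/(dyn + sta)``, scaled and clipped; this weights the shared
    choice latent per neuron so choice-related activity grows with a cell's
    selectivity for dynamic objects.
    """
    means = _condition_means(neuron, conditions)
    dyn = means[(conditions["kind"] == "dynamic").to_numpy()].mean()
    sta = means[(conditions["kind"] == "stationary").to_numpy()].mean()
    if dyn + sta <= 0:
        return 0.0
    return float(np.clip(scale * (dyn - sta) / (dyn + sta), -1.5, 1.5))


def dynamic_preference_sign(neuron: NeuronSpec, conditions: pd.DataFrame) -> float:
    """+1 if mean dynamic response exceeds mean stationary response, else −1."""
    means = _condition_means(neuron, conditions)
    dyn = means[(conditions["kind"] == "dynamic").to_numpy()].mean()
    sta = means[(conditions["kind"] == "stationary").to_numpy()].mean()
    return 1.0 if dyn >= sta else -1.0


def simulate_tuning(
    neurons: list[NeuronSpec], n_reps: int = 8, seed=None
) -> pd.DataFrame:
    """Trial-level depth-tuning table for both cues over the 9-point grid.

    Rates are Gaussian about the tuning mean with SD = k·sqrt(mean),
    truncated at zero.  Columns follow the ``tuning.csv`` schema.
    """
    rng = np.random.default_rng(seed)
    depths = np.array(TUNING_DEPTH_GRID)
    rows = []
    for neuron in neurons:
        for cue in ("BD", "MP"):
            mu = np.asarray(tuning_mean(neuron, cue, depths))
            sd = neuron.trial_noise * np.sqrt(mu)
            draws = np.maximum(
                0.0, mu + sd * rng.standard_normal((n_reps, depths.size))
            )
            for rep in range(n_reps):
                for d, r in zip(depths, draws[rep]):
                    rows.append(
                        {
                            "neuron_id": neuron.id,
                            "cue": cue,
                            "depth_deg": d,
                            "rep": rep,
                            "rate_hz": r,
                        }
                    )
    return pd.DataFrame(rows)


def simulate_session(
    neurons: list[NeuronSpec],
    conditions: pd.DataFrame | None = None,
    n_reps: int = 35,
    behavior: BehaviorSpec = BehaviorSpec(),
    seed=None,
    session_id: int = 0,
) -> pd.DataFrame:
    """Simulate one detection session (all neurons as a pseudo-population).

    For each ΔDepth value and each dynamic-object location (in-RF / opposite
    hemifield), ``n_reps`` trials are generated.  The in-RF condition is the
    dynamic condition at that ΔDepth when the dynamic object is in the RF,
    otherwise a stationary condition at a random standard depth; at
    ΔDepth = 0 both objects sit at the pedestal (the ambiguous condition).
    The choice is driven by a decision variable
    ``sensitivity·|ΔDepth|·side + coupling·η + ε`` with a shared standard
    normal latent η that is also added to every neuron's rate (scaled by its
    graded dynamic-preference index and its noise SD), plus a lapse; the
    monocular flag removes the stimulus evidence so performance falls to
    chance.

    Returns one row per neuron × trial with the ``trials.csv`` schema.
    """
    if conditions is None:
        conditions = standard_condition_table()
    if conditions.empty:
        raise ValueError("condition table is empty")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)

    dyn_rows = conditions[conditions["kind"] == "dynamic"]
    sta_rows = conditions[conditions["kind"] == "stationary"]
    deltas = dyn_rows["delta_depth_deg"].to_numpy()
    dyn_ids = dyn_rows["condition_id"].to_numpy()
    sta_ids = sta_rows["condition_id"].to_numpy()

    trial_delta, trial_cond, trial_other, trial_dyn_in_rf = [], [], [], []
    for delta, dyn_id in zip(deltas, dyn_ids):
        for in_rf in (True, False):
            for _ in range(n_reps):
                if delta == 0.0:
                    cond, other = dyn_id, dyn_id
                elif in_rf:
                    cond, other = dyn_id, rng.choice(sta_ids)
                else:
                    cond, other = rng.choice(sta_ids), dyn_id
                trial_delta.append(delta)
                trial_cond.append(cond)
                trial_other.append(other)
                trial_dyn_in_rf.append(in_rf)
    n_trials = len(trial_cond)
    trial_delta = np.array(trial_delta)
    dyn_in_rf = np.array(trial_dyn_in_rf)
    phase = rng.choice([0.0, 180.0], size=n_trials)

    # Decision variable with shared latent η (also injected into rates).
    eta = rng.standard_normal(n_trials)
    side = np.where(dyn_in_rf, 1.0, -1.0)
    evidence = 0.0 if behavior.monocular else behavior.sensitivity * np.abs(trial_delta)
    dv = evidence * side + behavior.choice_coupling * eta + rng.standard_normal(n_trials)
    choice_in_rf = dv > 0
    if behavior.lapse > 0:
        lapse_mask = rng.random(n_trials) < behavior.lapse
        choice_in_rf = np.where(
            lapse_mask, rng.random(n_trials) < 0.5, choice_in_rf
        ).astype(bool)
    correct = choice_in_rf == dyn_in_rf

    cond_index = {cid: k for k, cid in enumerate(conditions["condition_id"])}
    cond_idx = np.array([cond_index[c] for c in trial_cond])

    frames = []
    for neuron in neurons:
        mu_all = _condition_means(neuron, conditions)
        mu = mu_all[cond_idx]
        sd = neuron.trial_noise * np.sqrt(mu)
        g_i = dynamic_preference_index(neuron, conditions)
        noise = rng.standard_normal(n_trials)
        rate = np.maximum(
            0.0, mu + sd * (noise + behavior.choice_coupling * g_i * eta)
        )
        frames.append(
            pd.DataFrame(
                {
                    "session_id": session_id,
                    "neuron_id": neuron.id,
                    "trial_id": np.arange(n_trials),
                    "condition_id": trial_cond,
                    "other_condition_id": trial_other,
                    "phase_deg": phase,
                    "delta_deg": trial_delta,
                    "rate_hz": rate,
                    "choice_in_rf": choice_in_rf,
                    "correct": correct,
                    "monocular": behavior.monocular,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_rasters(
    rates_hz: np.ndarray,
    duration_s: float = 2.1,
    bin_s: float = 0.01,
    seed=None,
) -> np.ndarray:
    """Homogeneous-Poisson spike counts, (n_trials, n_bins), for PSTH work."""
    rng = np.random.default_rng(seed)
    rates = np.asarray(rates_hz, dtype=float)
    n_bins = int(round(duration_s / bin_s))
    return rng.poisson(rates[:, None] * bin_s, size=(rates.size, n_bins))


def simulate_choice_sessions(
    betas: dict,
    n_sessions: int = 1,
    n_trials: int = 500,
    n_objects: int = 2,
    seed=None,
    delta_set=STANDARD_DELTA_SET,
    stationary_depths=STANDARD_STATIONARY_DEPTHS,
    pedestal: float = -0.45,
) -> pd.DataFrame:
    """Simulate a multinomial-logit observer for the choice regression.

    Each trial places the dynamic object (ΔDepth drawn from the nonzero
    values) at a uniformly random location and stationary objects elsewhere.
    Location utilities are ``b_bd·|d_BD| + b_mp·|d_MP| + b_delta·|ΔDepth|``
    plus i.i.d. Gumbel noise (``betas`` keys: ``b_bd``, ``b_mp``,
    ``b_delta``); the chosen location maximizes utility.  Returns a tidy
    location table (one row per trial × location) with columns
    ``session_id, trial_id, location, abs_d_bd, abs_d_mp, abs_delta, chosen``.
    """
    rng = np.random.default_rng(seed)
    nonzero = np.array([d for d in delta_set if d != 0.0])
    sta = np.array(stationary_depths)
    rows = []
    for s in range(n_sessions):
        for t in range(n_trials):
            dyn_loc = rng.integers(n_objects)
            delta = rng.choice(nonzero)
            d_mp = pedestal + delta / 2.0
            d_bd = pedestal - delta / 2.0
            abs_bd = np.abs(rng.choice(sta, size=n_objects))
            abs_mp = abs_bd.copy()
            abs_delta = np.zeros(n_objects)
            abs_bd[dyn_loc] = abs(d_bd)
            abs_mp[dyn_loc] = abs(d_mp)
            abs_delta[dyn_loc] = abs(delta)
            utility = (
                betas["b_bd"] * abs_bd
                + betas["b_mp"] * abs_mp
                + betas["b_delta"] * abs_delta
                + rng.gumbel(size=n_objects)
            )
            chosen = int(np.argmax(utility))
            for loc in range(n_objects):
                rows.append(
                    {
                        "session_id": s,
                        "trial_id": t,
                        "location": loc,
                        "abs_d_bd": abs_bd[loc],
                        "abs_d_mp": abs_mp[loc],
                        "abs_delta": abs_delta[loc],
                        "chosen": loc == chosen,
                    }
                )
    return pd.DataFrame(rows)
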