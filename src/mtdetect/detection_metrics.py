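"""Ideal-observer and choice-related metrics for the detection task.

The ROC area is the probability that a random draw from the preferred group
exceeds one from the other group (ties counted 1/2), computed rank-based.
Neurometric performance (NP) averages, over the six nonzero ΔDepth values,
the ROC area discriminating dynamic-in-RF trials at that ΔDepth from all
stationary-in-RF trials pooled over depth; NP > 0.5 means a preference for
dynamic objects.  Detection probability (DP) applies the same ROC analysis
to the ambiguous (ΔDepth = 0) trials, sorted by the animal's choice, so DP
and NP come from disjoint trial sets by construction.  DP significance is a
two-sided permutation test on choice labels; a neuron is eligible only with
at least five choices toward each target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import uniform_filter1d

__all__ = [
    "RocResult",
    "NeurometricResult",
    "DetectionProbabilityResult",
    "TimecourseResult",
    "roc_area",
    "neurometric_performance",
    "detection_probability",
    "choice_sorted_timecourse",
]


@dataclass
class RocResult:
    area: float
    n_a: int  # preferred-group trials
    n_b: int


@dataclass
class NeurometricResult:
    areas: dict  # signed ΔDepth -> ROC area
    np_value: float  # mean over the nonzero ΔDepth areas


@dataclass
class DetectionProbabilityResult:
    dp: float
    p_value: float
    n_in: int  # choices toward the in-RF target
    n_out: int
    eligible: bool
    n_permutations: int = 0


@dataclass
class TimecourseResult:
    time: np.ndarray
    traces: dict  # (phase, choice_in_rf) -> dict(mean=..., sem=..., n=...)
    difference: dict  # phase -> in-minus-out z-trace
    significant: dict  # phase -> boolean array per timepoint
    omitted: list = field(default_factory=list)  # (phase, choice) cells with <2 trials


def _auc(preferred: np.ndarray, other: np.ndarray) -> float:
    """Rank-based ROC area: P(pref > other) + 0.5·P(tie)."""
    ranks = stats.rankdata(np.concatenate([preferred, other]))
    n_a, n_b = preferred.size, other.size
    r_a = ranks[:n_a].sum()
    return (r_a - n_a * (n_a + 1) / 2.0) / (n_a * n_b)


def roc_area(preferred, other) -> RocResult:
    """ROC area with ``preferred`` as the putatively larger-response group."""
    preferred = np.asarray(preferred, dtype=float)
    other = np.asarray(other, dtype=float)
    if preferred.size == 0 or other.size == 0:
        raise ValueError("both response groups must be non-empty")
    return RocResult(
        area=float(_auc(preferred, other)), n_a=preferred.size, n_b=other.size
    )


def neurometric_performance(
    trials: pd.DataFrame, conditions: pd.DataFrame
) -> NeurometricResult:
    """NP for one neuron from its detection-task trials.

    ``trials`` needs columns ``condition_id`` and ``rate_hz``.  For each
    nonzero ΔDepth, the dynamic-in-RF trials are compared against the pooled
    stationary-in-RF trials (any depth); NP is the unweighted mean of the six
    ROC areas, with the dynamic group as the preferred group.
    """
    merged = trials.merge(
        conditions[["condition_id", "kind", "delta_depth_deg"]], on="condition_id"
    )
    stationary = merged.loc[merged["kind"] == "stationary", "rate_hz"].to_numpy()
    if stationary.size == 0:
        raise ValueError("no stationary-in-RF trials")
    dyn = merged[(merged["kind"] == "dynamic") & (merged["delta_depth_deg"] != 0)]
    expected = sorted(
        conditions.loc[
            (conditions["kind"] == "dynamic") & (conditions["delta_depth_deg"] != 0),
            "delta_depth_deg",
        ]
    )
    missing = [d for d in expected if not (dyn["delta_depth_deg"] == d).any()]
    if missing:
        raise ValueError(f"missing dynamic trials at ΔDepth values: {missing}")
    areas = {}
    for delta in expected:
        rates = dyn.loc[dyn["delta_depth_deg"] == delta, "rate_hz"].to_numpy()
        areas[float(delta)] = float(_auc(rates, stationary))
    return NeurometricResult(areas=areas, np_value=float(np.mean(list(areas.values()))))


def detection_probability(
    trials: pd.DataFrame,
    conditions: pd.DataFrame,
    n_perm: int = 1000,
    min_choices: int = 5,
    seed=None,
) -> DetectionProbabilityResult:
    """DP for one neuron from its ambiguous (ΔDepth = 0) trials.

    Rates are z-scored (both self-motion phases pooled), sorted by the
    choice (``choice_in_rf``), and the ROC area is computed with the
    chose-in-RF group preferred.  The permutation test shuffles choice
    labels; two-sided p = 2·min(tail proportions), clipped to [1/n_perm, 1].
    """
    merged = trials.merge(
        conditions[["condition_id", "kind", "delta_depth_deg"]], on="condition_id"
    )
    amb = merged[(merged["kind"] == "dynamic") & (merged["delta_depth_deg"] == 0)]
    if amb.empty:
        raise ValueError("no ambiguous (ΔDepth = 0) trials")
    rates = amb["rate_hz"].to_numpy(dtype=float)
    choice = amb["choice_in_rf"].to_numpy(dtype=bool)
    sd = rates.std(ddof=1) if rates.size > 1 else 0.0
    z = (rates - rates.mean()) / sd if sd > 0 else rates - rates.mean()
    n_in = int(choice.sum())
    n_out = int((~choice).sum())
    eligible = n_in >= min_choices and n_out >= min_choices
    if n_in == 0 or n_out == 0:
        return DetectionProbabilityResult(np.nan, np.nan, n_in, n_out, False, 0)

    observed = _auc(z[choice], z[~choice])
    # Permutation null: ranks are fixed, only the label partition changes.
    ranks = stats.rankdata(z)
    rng = np.random.default_rng(seed)
    mask = np.tile(choice, (n_perm, 1))
    mask = rng.permuted(mask, axis=1)
    r_in = np.where(mask, ranks, 0.0).sum(axis=1)
    null = (r_in - n_in * (n_in + 1) / 2.0) / (n_in * n_out)
    hi = float(np.mean(null >= observed))
    lo = float(np.mean(null <= observed))
    p = min(1.0, max(1.0 / n_perm, 2.0 * min(hi, lo)))
    return DetectionProbabilityResult(
        dp=float(observed),
        p_value=p,
        n_in=n_in,
        n_out=n_out,
        eligible=eligible,
        n_permutations=n_perm,
    )


def choice_sorted_timecourse(
    counts: np.ndarray,
    bin_s: float,
    phase_deg: np.ndarray,
    choice_in_rf: np.ndarray,
    boxcar_s: float = 0.150,
    alpha: float = 0.05,
) -> TimecourseResult:
    """Choice-sorted, z-scored PSTH time courses for ambiguous trials.

    ``counts`` is (n_trials, n_bins) spike counts aligned to stimulus onset.
    Per-trial rates are smoothed with a ``boxcar_s`` boxcar, z-scored with a
    session-wide mean and SD, sorted by self-motion phase then by choice, and
    the in-RF-minus-out difference is tested per timepoint with a two-sided
    rank-sum test at ``alpha``.  Phase×choice cells with fewer than 2 trials
    are omitted and flagged.
    """
    counts = np.asarray(counts, dtype=float)
    phase_deg = np.asarray(phase_deg)
    choice_in_rf = np.asarray(choice_in_rf, dtype=bool)
    if counts.shape[0] != phase_deg.size or counts.shape[0] != choice_in_rf.size:
        raise ValueError("counts rows must match phase/choice lengths")
    rates = counts / bin_s
    width = max(1, int(round(boxcar_s / bin_s)))
    smooth = uniform_filter1d(rates, size=width, axis=1, mode="nearest")
    mu, sd = smooth.mean(), smooth.std(ddof=1)
    z = (smooth - mu) / sd if sd > 0 else smooth - mu
    time = (np.arange(counts.shape[1]) + 0.5) * bin_s

    traces: dict = {}
    omitted: list = []
    for phase in np.unique(phase_deg):
        for ch in (True, False):
            sel = (phase_deg == phase) & (choice_in_rf == ch)
            if sel.sum() < 2:
                omitted.append((float(phase), ch))
                continue
            grp = z[sel]
            traces[(float(phase), ch)] = {
                "mean": grp.mean(axis=0),
                "sem": grp.std(ddof=1, axis=0) / np.sqrt(sel.sum()),
                "n": int(sel.sum()),
            }

    difference: dict = {}
    significant: dict = {}
    for phase in np.unique(phase_deg):
        key_in, key_out = (float(phase), True), (float(phase), False)
        if key_in not in traces or key_out not in traces:
            continue
        difference[float(phase)] = traces[key_in]["mean"] - traces[key_out]["mean"]
        grp_in = z[(phase_deg == phase) & choice_in_rf]
        grp_out = z[(phase_deg == phase) & ~choice_in_rf]
        sig = np.zeros(counts.shape[1], dtype=bool)
        for t in range(counts.shape[1]):
            sig[t] = stats.mannwhitneyu(grp_in[:, t], grp_out[:, t]).pvalue < alpha
        significant[float(phase)] = sig
    return TimecourseResult(
        time=time,
        traces=traces,
        difference=difference,
        significant=significant,
        omitted=omitted,
    )
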