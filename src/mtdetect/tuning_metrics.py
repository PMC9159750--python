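"""Depth-sign tuning indices and cue-congruency metrics.

A depth tuning curve is the set of trial firing rates at the nine equivalent
disparities −2 … +2 deg (step 0.5), measured separately for the binocular
disparity (BD) and motion parallax (MP) cue.  The depth-sign discrimination
index averages, over the four symmetric depth-magnitude pairs, the signed
response difference normalized by signal plus noise:

    DSDI = (1/4) Σ_i (R_far(i) − R_near(i)) / (|R_far(i) − R_near(i)| + σ_avg(i))

with σ_avg the mean of the two depths' across-trial SDs.  Negative DSDI means
near-preferring.  DSDI_dyn is the same statistic over the three symmetric
ΔDepth pairs of the dynamic-object responses.  Significance comes from a
permutation test that shuffles trial rates across depth labels.

Congruency between the two cues is the Pearson correlation (R_MP_BD) of the
two 9-point mean tuning curves; cells are classed congruent/opposite by the
sign of a significant correlation.  The peak response ratio (max dynamic
mean ÷ max stationary mean from the detection task) indexes preference for
moving over stationary objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TuningCurve",
    "DsdiResult",
    "CongruencyResult",
    "compute_dsdi",
    "compute_dsdi_dyn",
    "permutation_test_dsdi",
    "peak_response_ratio",
    "compute_congruency",
]


@dataclass
class TuningCurve:
    """Per-cue trial responses over a symmetric depth grid.

    ``trials[i]`` holds the trial firing rates (spikes/s) at ``depths[i]``.
    """

    cue: str  # "BD" or "MP"
    depths: np.ndarray
    trials: list  # list of 1-D arrays, one per depth

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.trials = [np.asarray(t, dtype=float) for t in self.trials]
        if self.cue not in ("BD", "MP"):
            raise ValueError(f"cue must be 'BD' or 'MP', got {self.cue!r}")
        if len(self.trials) != self.depths.size:
            raise ValueError("one trial array required per depth")
        if any(t.size < 2 for t in self.trials):
            raise ValueError("need >= 2 trials per depth to estimate SDs")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, cue: str) -> "TuningCurve":
        """Build from a tidy frame with columns depth_deg, rate_hz (one cue)."""
        sub = df[df["cue"] == cue] if "cue" in df.columns else df
        depths = np.sort(sub["depth_deg"].unique())
        trials = [sub.loc[sub["depth_deg"] == d, "rate_hz"].to_numpy() for d in depths]
        return cls(cue=cue, depths=depths, trials=trials)

    @property
    def means(self) -> np.ndarray:
        return np.array([t.mean() for t in self.trials])

    @property
    def sds(self) -> np.ndarray:
        return np.array([t.std(ddof=1) for t in self.trials])


@dataclass
class DsdiResult:
    dsdi: float
    p_value: float = np.nan
    n_permutations: int = 0


@dataclass
class CongruencyResult:
    r_mp_bd: float
    p_value: float
    cls: str  # "congruent", "opposite", or "unclassified"
    delta_dsdi: float  # DSDI_MP − DSDI_BD
    peak_ratio: float  # max dynamic mean / max stationary mean


def _signed_pairs(values: np.ndarray) -> list[tuple[int, int]]:
    """Indices of (positive, negative) symmetric pairs; values must pair up."""
    values = np.asarray(values, dtype=float)
    pairs = []
    for mag in np.unique(np.abs(values[values != 0])):
        pos = np.flatnonzero(np.isclose(values, mag))
        neg = np.flatnonzero(np.isclose(values, -mag))
        if pos.size != 1 or neg.size != 1:
            raise ValueError(f"missing symmetric pair at magnitude {mag}")
        pairs.append((int(pos[0]), int(neg[0])))
    if not pairs:
        raise ValueError("no symmetric nonzero pairs in grid")
    return pairs


def _dsdi_from_moments(means, sds, pairs) -> np.ndarray:
    """Vectorized DSDI over leading axes; means/sds shaped (..., n_levels)."""
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    terms = []
    for pos, neg in pairs:
        diff = means[..., pos] - means[..., neg]
        denom = np.abs(diff) + 0.5 * (sds[..., pos] + sds[..., neg])
        # Indeterminate 0/0 limit (flat, noiseless pair) carries no evidence.
        term = np.divide(diff, denom, out=np.zeros_like(diff), where=denom > 0)
        terms.append(term)
    return np.mean(terms, axis=0)


def compute_dsdi(curve: TuningCurve) -> DsdiResult:
    """DSDI over the four symmetric depth pairs (sign: negative = near).

    The far member of each pair is the positive depth.  Depth 0, if present,
    is ignored.  Requires every symmetric pair to be complete.
    """
    pairs = _signed_pairs(curve.depths)
    return DsdiResult(dsdi=float(_dsdi_from_moments(curve.means, curve.sds, pairs)))


def compute_dsdi_dyn(responses_by_delta: dict) -> DsdiResult:
    """DSDI_dyn over the three symmetric ΔDepth pairs (ΔDepth = 0 excluded).

    ``responses_by_delta`` maps signed ΔDepth (deg) to the array of trial
    rates for the dynamic object at that ΔDepth.
    """
    deltas = np.array(sorted(responses_by_delta), dtype=float)
    trials = [np.asarray(responses_by_delta[d], dtype=float) for d in deltas]
    if any(t.size < 2 for t in trials):
        raise ValueError("need >= 2 trials per ΔDepth to estimate SDs")
    pairs = _signed_pairs(deltas)
    means = np.array([t.mean() for t in trials])
    sds = np.array([t.std(ddof=1) for t in trials])
    return DsdiResult(dsdi=float(_dsdi_from_moments(means, sds, pairs)))


def permutation_test_dsdi(
    curve_or_trials,
    n_perm: int = 1000,
    seed=None,
) -> DsdiResult:
    """One-sided permutation test of DSDI against zero.

    Trial rates are shuffled across depth labels (jointly over all depths,
    preserving per-depth trial counts) ``n_perm`` times.  If the measured
    DSDI is negative, p is the proportion of shuffled DSDIs below it; if
    positive, the proportion above it.

    Note this sign rule is a one-sided test in the observed direction, so
    under a flat-tuning null its p-values are approximately uniform on
    (0, 0.5) and rejection at threshold α occurs at rate ≈ 2α.
    """
    if isinstance(curve_or_trials, TuningCurve):
        depths, trials = curve_or_trials.depths, curve_or_trials.trials
    else:
        depths = np.array(sorted(curve_or_trials), dtype=float)
        trials = [np.asarray(curve_or_trials[d], dtype=float) for d in depths]
    if n_perm < 100:
        import warnings

        warnings.warn(f"n_perm={n_perm} is small; p-values will be coarse")
    pairs = _signed_pairs(depths)
    means = np.array([t.mean() for t in trials])
    sds = np.array([t.std(ddof=1) for t in trials])
    observed = float(_dsdi_from_moments(means, sds, pairs))

    rng = np.random.default_rng(seed)
    pooled = np.concatenate(trials)
    counts = [t.size for t in trials]
    bounds = np.concatenate([[0], np.cumsum(counts)])
    perm = rng.permuted(np.tile(pooled, (n_perm, 1)), axis=1)
    pm = np.empty((n_perm, len(trials)))
    ps = np.empty((n_perm, len(trials)))
    for i in range(len(trials)):
        block = perm[:, bounds[i] : bounds[i + 1]]
        pm[:, i] = block.mean(axis=1)
        ps[:, i] = block.std(ddof=1, axis=1)
    null = _dsdi_from_moments(pm, ps, pairs)
    if observed < 0:
        p = float(np.mean(null < observed))
    else:
        p = float(np.mean(null > observed))
    return DsdiResult(dsdi=observed, p_value=p, n_permutations=n_perm)


def peak_response_ratio(trials: pd.DataFrame, conditions: pd.DataFrame) -> float:
    """Max dynamic-condition mean rate ÷ max stationary-condition mean rate.

    ``trials`` is a detection-task trial table for one neuron with columns
    ``condition_id`` and ``rate_hz``; ``conditions`` the condition table.
    """
    merged = trials.merge(conditions[["condition_id", "kind"]], on="condition_id")
    means = merged.groupby(["kind", "condition_id"])["rate_hz"].mean()
    try:
        dyn = means["dynamic"].max()
        sta = means["stationary"].max()
    except KeyError as err:
        raise ValueError("need both dynamic and stationary conditions") from err
    if sta <= 0:
        raise ValueError("stationary peak response is not positive")
    return float(dyn / sta)


def compute_congruency(
    bd: TuningCurve,
    mp: TuningCurve,
    detection_trials: pd.DataFrame,
    conditions: pd.DataFrame,
    alpha: float = 0.05,
) -> CongruencyResult:
    """Cue congruency (R_MP_BD), ΔDSDI, and peak response ratio for a neuron."""
    if not np.allclose(bd.depths, mp.depths):
        raise ValueError("BD and MP curves must share the same depth grid")
    mb, mm = bd.means, mp.means
    if np.ptp(mb) == 0 or np.ptp(mm) == 0:
        raise ValueError("zero-variance tuning curve: correlation undefined")
    r, p = stats.pearsonr(mm, mb)
    if p < alpha:
        cls = "congruent" if r > 0 else "opposite"
    else:
        cls = "unclassified"
    delta_dsdi = compute_dsdi(mp).dsdi - compute_dsdi(bd).dsdi
    ratio = peak_response_ratio(detection_trials, conditions)
    return CongruencyResult(
        r_mp_bd=float(r),
        p_value=float(p),
        cls=cls,
        delta_dsdi=float(delta_dsdi),
        peak_ratio=ratio,
    )
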