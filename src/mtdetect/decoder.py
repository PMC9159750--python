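"""Correlated-noise pseudo-population simulation and linear decoding.

Each neuron contributes its measured mean µ and SD σ for the 16 standard
in-RF conditions.  Simulated population responses are drawn as

    Response = µ(cond) + Q · r_rand ∘ σ(cond)

with r_rand i.i.d. standard normal and Q the (symmetric principal) square
root of the noise-correlation matrix.  Correlations follow the similarity
rule on neurometric performance,

    r_noise[i, j] = 1.1 · (0.5 − |NP_i − NP_j|),

so neurons with similar NP share stronger noise; the matrix is repaired to
the nearest unit-diagonal PSD form by eigenvalue clipping when needed.  In
independent-noise mode Q is the identity.

A linear-discriminant readout is trained on a 90/10 split to report whether
the in-RF stimulus is a dynamic or stationary object, with the ambiguous
(ΔDepth = 0) condition excluded from training.  Sorting each neuron's
ambiguous test-trial responses by the decoder's output yields a predicted
detection probability (DP_pred) per neuron, and decoding can be repeated for
subgroups of neurons (terciles of a selectivity statistic, or random mixed
subsets).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .detection_metrics import neurometric_performance

__all__ = [
    "PopulationMoments",
    "NoiseModel",
    "DecodeResult",
    "DpPredResult",
    "moments_from_trials",
    "noise_correlation_matrix",
    "simulate_population_trials",
    "train_linear_decoder",
    "predicted_dp",
    "tercile_split",
    "subgroup_decoding",
]


@dataclass
class PopulationMoments:
    """Per-neuron mean/SD response matrices over the standard conditions."""

    neuron_ids: np.ndarray  # (n_neurons,)
    mu: np.ndarray  # (n_neurons, n_conditions) mean rates
    sigma: np.ndarray  # same shape, SDs
    np_values: np.ndarray  # (n_neurons,) neurometric performance
    conditions: pd.DataFrame  # condition_id, kind, delta_depth_deg

    def __post_init__(self) -> None:
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")

    @property
    def n_neurons(self) -> int:
        return self.mu.shape[0]

    @property
    def is_dynamic(self) -> np.ndarray:
        return (self.conditions["kind"] == "dynamic").to_numpy()

    @property
    def is_ambiguous(self) -> np.ndarray:
        return self.is_dynamic & (self.conditions["delta_depth_deg"] == 0).to_numpy()

    def subset(self, idx) -> "PopulationMoments":
        idx = np.asarray(idx)
        return PopulationMoments(
            neuron_ids=self.neuron_ids[idx],
            mu=self.mu[idx],
            sigma=self.sigma[idx],
            np_values=self.np_values[idx],
            conditions=self.conditions,
        )


@dataclass
class NoiseModel:
    correlation: np.ndarray  # R, unit diagonal
    sqrt: np.ndarray  # Q with Q·Qᵀ ≈ R
    psd_repaired: bool = False


@dataclass
class DecodeResult:
    weights: np.ndarray  # per-neuron readout weights
    intercept: float
    accuracy: float  # overall test proportion correct (ambiguous excluded)
    per_delta: dict  # signed ΔDepth -> proportion predicted dynamic; plus
    # "stationary" -> proportion predicted stationary
    n_train: int
    n_test: int
    test_responses: np.ndarray = field(repr=False, default=None)
    test_cond_idx: np.ndarray = field(repr=False, default=None)
    test_pred_dynamic: np.ndarray = field(repr=False, default=None)


@dataclass
class DpPredResult:
    dp_pred: np.ndarray  # (n_neurons,) mean over simulations
    ci_low: np.ndarray
    ci_high: np.ndarray
    per_sim: np.ndarray  # (n_sim, n_neurons), NaN where undefined
    weights: np.ndarray  # mean readout weights over simulations
    accuracy: float  # mean test accuracy over simulations


def moments_from_trials(
    trials: pd.DataFrame, conditions: pd.DataFrame
) -> PopulationMoments:
    """Build population moments from a trial table (all 16 conditions required)."""
    cond_ids = conditions["condition_id"].tolist()
    neuron_ids = np.sort(trials["neuron_id"].unique())
    mu = np.empty((neuron_ids.size, len(cond_ids)))
    sigma = np.empty_like(mu)
    np_values = np.empty(neuron_ids.size)
    grouped = trials.groupby(["neuron_id", "condition_id"])["rate_hz"]
    means, sds = grouped.mean(), grouped.std(ddof=1)
    for i, nid in enumerate(neuron_ids):
        for k, cid in enumerate(cond_ids):
            if (nid, cid) not in means.index:
                raise ValueError(f"neuron {nid} missing condition {cid}")
            mu[i, k] = means[(nid, cid)]
            sigma[i, k] = sds[(nid, cid)]
        np_values[i] = neurometric_performance(
            trials[trials["neuron_id"] == nid], conditions
        ).np_value
    return PopulationMoments(
        neuron_ids=neuron_ids,
        mu=mu,
        sigma=np.nan_to_num(sigma),
        np_values=np_values,
        conditions=conditions[["condition_id", "kind", "delta_depth_deg"]].copy(),
    )


def noise_correlation_matrix(np_values) -> NoiseModel:
    """Eq.-5-style noise-correlation matrix and its symmetric square root."""
    npv = np.asarray(np_values, dtype=float)
    if npv.size < 2:
        raise ValueError("need at least 2 neurons")
    if np.any((npv < 0) | (npv > 1)):
        raise ValueError("NP values must lie in [0, 1]")
    diff = np.abs(npv[:, None] - npv[None, :])
    r = 1.1 * (0.5 - diff)
    np.fill_diagonal(r, 1.0)
    evals, evecs = np.linalg.eigh(r)
    repaired = False
    if evals.min() < -1e-10:
        repaired = True
        evals = np.clip(evals, 0.0, None)
        r = (evecs * evals) @ evecs.T
        d = np.sqrt(np.diag(r))
        r = r / np.outer(d, d)
        np.fill_diagonal(r, 1.0)
        evals, evecs = np.linalg.eigh(r)
        evals = np.clip(evals, 0.0, None)
    q = (evecs * np.sqrt(evals)) @ evecs.T
    return NoiseModel(correlation=r, sqrt=q, psd_repaired=repaired)


def simulate_population_trials(
    moments: PopulationMoments,
    noise: NoiseModel | None,
    n_samples: int,
    rng,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw pseudo-population trials per the µ + Q·r_rand∘σ construction.

    Conditions are drawn uniformly with replacement; ``noise=None`` means
    independent noise (Q = identity).  Rates are not truncated at zero.
    Returns (responses, condition indices).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not hasattr(rng, "standard_normal"):
        rng = np.random.default_rng(rng)
    n_cond = moments.mu.shape[1]
    cond_idx = rng.integers(n_cond, size=n_samples)
    r_rand = rng.standard_normal((n_samples, moments.n_neurons))
    if noise is not None:
        r_rand = r_rand @ noise.sqrt.T
    x = moments.mu.T[cond_idx] + r_rand * moments.sigma.T[cond_idx]
    return x, cond_idx


def train_linear_decoder(
    x: np.ndarray,
    cond_idx: np.ndarray,
    moments: PopulationMoments,
    split: float = 0.9,
    rng=None,
) -> DecodeResult:
    """Train the LDA readout (dynamic vs. stationary in the RF) and test it.

    Trials are split ``split``/(1−split) into training and test sets;
    ambiguous (ΔDepth = 0) trials never enter training.  Test trials landing
    exactly on the decision boundary are broken by a seeded coin flip.
    """
    rng = np.random.default_rng(rng)
    n = x.shape[0]
    order = rng.permutation(n)
    n_train = int(round(split * n))
    train_idx, test_idx = order[:n_train], order[n_train:]

    is_dyn = moments.is_dynamic
    is_amb = moments.is_ambiguous
    train_idx = train_idx[~is_amb[cond_idx[train_idx]]]
    assert not is_amb[cond_idx[train_idx]].any()  # training never sees ΔDepth=0
    y_train = is_dyn[cond_idx[train_idx]]
    if y_train.all() or not y_train.any():
        raise ValueError("both classes must be present in the training split")

    lda = LinearDiscriminantAnalysis(solver="svd")
    lda.fit(x[train_idx], y_train.astype(int))
    weights = lda.coef_.ravel()
    intercept = float(lda.intercept_[0])

    scores = x[test_idx] @ weights + intercept
    ties = scores == 0
    pred_dyn = scores > 0
    if ties.any():
        pred_dyn[ties] = rng.random(int(ties.sum())) < 0.5

    test_cond = cond_idx[test_idx]
    amb_test = is_amb[test_cond]
    y_test = is_dyn[test_cond]
    scored = ~amb_test
    accuracy = float(np.mean(pred_dyn[scored] == y_test[scored])) if scored.any() else np.nan

    deltas = moments.conditions["delta_depth_deg"].to_numpy()
    per_delta: dict = {}
    for k in np.flatnonzero(is_dyn & ~is_amb):
        sel = test_cond == k
        if sel.any():
            per_delta[float(deltas[k])] = float(np.mean(pred_dyn[sel]))
    sel_sta = ~is_dyn[test_cond]
    if sel_sta.any():
        per_delta["stationary"] = float(np.mean(~pred_dyn[sel_sta]))

    return DecodeResult(
        weights=weights,
        intercept=intercept,
        accuracy=accuracy,
        per_delta=per_delta,
        n_train=train_idx.size,
        n_test=test_idx.size,
        test_responses=x[test_idx],
        test_cond_idx=test_cond,
        test_pred_dynamic=pred_dyn,
    )


def _dp_pred_one(result: DecodeResult, moments: PopulationMoments) -> np.ndarray:
    """Per-neuron ROC of ambiguous test responses sorted by decoder output."""
    amb = moments.is_ambiguous[result.test_cond_idx]
    if not amb.any():
        raise ValueError("no ambiguous trials in the test set")
    resp = result.test_responses[amb]
    pred = result.test_pred_dynamic[amb]
    n1, n0 = int(pred.sum()), int((~pred).sum())
    out = np.full(moments.n_neurons, np.nan)
    if n1 == 0 or n0 == 0:
        return out
    ranks = stats.rankdata(resp, axis=0)
    r1 = ranks[pred].sum(axis=0)
    out[:] = (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return out


def predicted_dp(
    moments: PopulationMoments,
    noise: NoiseModel | None,
    n_sim: int = 100,
    n_samples: int = 100_000,
    split: float = 0.9,
    seed=None,
) -> DpPredResult:
    """DP_pred per neuron, aggregated over repeated decoding simulations.

    Each simulation redraws the population trials, retrains the decoder, and
    sorts each neuron's ambiguous test-set responses by the decoder's choice
    (preferred group: "dynamic in RF" predicted).  CIs are 2.5/97.5
    percentiles over simulations.
    """
    rng = np.random.default_rng(seed)
    per_sim = np.full((n_sim, moments.n_neurons), np.nan)
    weights = np.zeros(moments.n_neurons)
    accs = []
    for s in range(n_sim):
        x, cond_idx = simulate_population_trials(moments, noise, n_samples, rng)
        result = train_linear_decoder(x, cond_idx, moments, split=split, rng=rng)
        per_sim[s] = _dp_pred_one(result, moments)
        weights += result.weights
        accs.append(result.accuracy)
    return DpPredResult(
        dp_pred=np.nanmean(per_sim, axis=0),
        ci_low=np.nanpercentile(per_sim, 2.5, axis=0),
        ci_high=np.nanpercentile(per_sim, 97.5, axis=0),
        per_sim=per_sim,
        weights=weights / n_sim,
        accuracy=float(np.nanmean(accs)),
    )


def tercile_split(stat_values) -> dict:
    """Index terciles of a statistic, sizes ⌈n/3⌉ then equal (ties by order)."""
    stat = np.asarray(stat_values, dtype=float)
    n = stat.size
    order = np.argsort(stat, kind="stable")
    n_low = int(np.ceil(n / 3))
    n_rest = (n - n_low) // 2
    return {
        "lowest": order[:n_low],
        "middle": order[n_low : n_low + n_rest],
        "highest": order[n_low + n_rest : n_low + 2 * n_rest],
    }


def subgroup_decoding(
    moments: PopulationMoments,
    stat_values,
    n_sims: int = 500,
    n_samples: int = 100_000,
    split: float = 0.9,
    correlated: bool = True,
    seed=None,
) -> dict:
    """Decode terciles of ``stat_values`` plus size-matched mixed subsets.

    Each subgroup runs ``n_sims`` seeded simulations (fresh noise draws each
    time); the mixed subgroup additionally redraws a random subset (without
    replacement, same size as the upper terciles) per simulation.  Returns,
    per subgroup: the accuracy distribution with mean and 95% CI, and the
    per-neuron mean DP_pred (averaged over the subsamplings that included
    each neuron, for the mixed group).
    """
    stat = np.asarray(stat_values, dtype=float)
    if stat.size != moments.n_neurons:
        raise ValueError("grouping statistic required for every neuron")
    if np.any(~np.isfinite(stat)):
        raise ValueError("grouping statistic missing (non-finite) for some neurons")
    if moments.n_neurons < 9:
        raise ValueError("need at least 9 neurons for tercile decoding")
    rng = np.random.default_rng(seed)
    groups = tercile_split(stat)
    mixed_size = groups["highest"].size

    out: dict = {}
    for name in ("lowest", "middle", "highest", "mixed"):
        accs = np.empty(n_sims)
        dp_sum = np.zeros(moments.n_neurons)
        dp_cnt = np.zeros(moments.n_neurons)
        for s in range(n_sims):
            idx = (
                rng.choice(moments.n_neurons, size=mixed_size, replace=False)
                if name == "mixed"
                else groups[name]
            )
            sub = moments.subset(idx)
            noise = noise_correlation_matrix(sub.np_values) if correlated else None
            x, cond_idx = simulate_population_trials(sub, noise, n_samples, rng)
            result = train_linear_decoder(x, cond_idx, sub, split=split, rng=rng)
            accs[s] = result.accuracy
            dp = _dp_pred_one(result, sub)
            ok = np.isfinite(dp)
            dp_sum[idx[ok]] += dp[ok]
            dp_cnt[idx[ok]] += 1
        member = dp_cnt > 0
        dp_mean = np.full(moments.n_neurons, np.nan)
        dp_mean[member] = dp_sum[member] / dp_cnt[member]
        out[name] = {
            "accuracies": accs,
            "accuracy_mean": float(np.mean(accs)),
            "accuracy_ci": (
                float(np.percentile(accs, 2.5)),
                float(np.percentile(accs, 97.5)),
            ),
            "dp_pred_mean": dp_mean,
            "neuron_ids": moments.neuron_ids[member],
        }
    return out
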