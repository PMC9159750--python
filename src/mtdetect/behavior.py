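"""Behavioral performance curves and the choice logistic regression.

The psychometric curve is percent correct per signed ΔDepth with exact
binomial 95% CIs; the design guarantees chance performance at ΔDepth = 0.

The choice regression asks what the observer weighted.  For each possible
choice location i, a binary logistic model of "location i chosen" is fit on
the per-location absolute depth cues of all N objects:

    log(P_i / (1 − P_i)) = β0 + Σ_j (β_BD,i,j·|d_BD,j| + β_MP,i,j·|d_MP,j|
                                      + β_Δ,i,j·|ΔDepth_j|)

Betas are then averaged over the chosen locations (j = i) and over the
not-chosen locations (j ≠ i), and the fraction of significant betas is
tallied over fits.  Normalized betas (per-SD effects) come from refitting on
z-scored predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import binomtest

__all__ = [
    "PsychometricCurve",
    "ChoiceRegressionResult",
    "psychometric",
    "choice_regression",
    "aggregate_regressions",
]

_CUES = ("bd", "mp", "delta")
_PREDICTORS = {"bd": "abs_d_bd", "mp": "abs_d_mp", "delta": "abs_delta"}


@dataclass
class PsychometricCurve:
    table: pd.DataFrame  # delta_deg, percent_correct, n_trials, ci_low, ci_high


@dataclass
class ChoiceRegressionResult:
    betas: pd.DataFrame  # location, target, cue, beta, beta_norm, se, p_value
    chosen: dict  # cue -> mean beta over chosen-location terms
    not_chosen: dict
    chosen_norm: dict
    not_chosen_norm: dict
    intercepts: np.ndarray
    n_objects: int
    valid: bool  # all per-location fits converged
    failed_locations: list = field(default_factory=list)


def psychometric(trials: pd.DataFrame, confidence: float = 0.95) -> PsychometricCurve:
    """Percent correct per signed ΔDepth with exact binomial CIs.

    ``trials`` needs ``delta_deg`` and ``correct`` columns; one row per
    behavioral trial (deduplicate a multi-neuron table on trial keys first).
    Levels with zero trials are simply absent.
    """
    rows = []
    for delta, grp in trials.groupby("delta_deg"):
        n = len(grp)
        k = int(grp["correct"].sum())
        ci = binomtest(k, n).proportion_ci(confidence_level=confidence, method="exact")
        rows.append(
            {
                "delta_deg": float(delta),
                "percent_correct": 100.0 * k / n,
                "n_trials": n,
                "ci_low": 100.0 * ci.low,
                "ci_high": 100.0 * ci.high,
            }
        )
    return PsychometricCurve(table=pd.DataFrame(rows).sort_values("delta_deg", ignore_index=True))


def _fit_logit(y: np.ndarray, x: np.ndarray):
    model = sm.Logit(y, sm.add_constant(x, has_constant="add"))
    try:
        res = model.fit(disp=0, maxiter=200)
    except Exception:
        return None
    if not res.mle_retvals.get("converged", False):
        return None
    if not np.all(np.isfinite(res.bse)):
        return None
    return res


def choice_regression(
    location_table: pd.DataFrame, n_objects: int = 2
) -> ChoiceRegressionResult:
    """Fit the per-location choice logistic for one session.

    ``location_table`` is tidy: one row per trial × location with columns
    ``trial_id, location, abs_d_bd, abs_d_mp, abs_delta, chosen``.  Each of
    the N per-location fits uses all 3N predictors.  Fits that fail to
    converge (e.g. separation) are flagged and excluded from the averages.
    """
    if n_objects not in (2, 4):
        raise ValueError("n_objects must be 2 or 4")
    locs = sorted(location_table["location"].unique())
    if len(locs) != n_objects:
        raise ValueError(f"expected {n_objects} locations, found {len(locs)}")
    wide = location_table.pivot_table(
        index="trial_id",
        columns="location",
        values=[_PREDICTORS[c] for c in _CUES] + ["chosen"],
    ).sort_index()
    cols = []
    names = []  # (target location j, cue)
    for j in locs:
        for cue in _CUES:
            cols.append(wide[(_PREDICTORS[cue], j)].to_numpy(dtype=float))
            names.append((j, cue))
    x = np.column_stack(cols)
    sd = x.std(axis=0, ddof=1)
    x_norm = np.where(sd > 0, (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0), 0.0)

    rows, intercepts, failed = [], [], []
    for i in locs:
        y = wide[("chosen", i)].to_numpy(dtype=float)
        res = _fit_logit(y, x)
        res_norm = _fit_logit(y, x_norm)
        if res is None or res_norm is None:
            failed.append(i)
            continue
        intercepts.append(res.params[0])
        for k, (j, cue) in enumerate(names):
            rows.append(
                {
                    "location": i,
                    "target": j,
                    "cue": cue,
                    "beta": res.params[k + 1],
                    "beta_norm": res_norm.params[k + 1],
                    "se": res.bse[k + 1],
                    "p_value": res.pvalues[k + 1],
                }
            )
    betas = pd.DataFrame(rows)

    def _avg(frame: pd.DataFrame, col: str, chosen: bool) -> dict:
        if frame.empty:
            return {cue: np.nan for cue in _CUES}
        mask = (frame["location"] == frame["target"]) == chosen
        sel = frame[mask]
        return {cue: float(sel.loc[sel["cue"] == cue, col].mean()) for cue in _CUES}

    return ChoiceRegressionResult(
        betas=betas,
        chosen=_avg(betas, "beta", True),
        not_chosen=_avg(betas, "beta", False),
        chosen_norm=_avg(betas, "beta_norm", True),
        not_chosen_norm=_avg(betas, "beta_norm", False),
        intercepts=np.asarray(intercepts),
        n_objects=n_objects,
        valid=not failed,
        failed_locations=failed,
    )


def aggregate_regressions(
    results: list[ChoiceRegressionResult], alpha: float = 0.05
) -> dict:
    """Population summary across sessions (valid fits only).

    Returns mean chosen/not-chosen betas (raw and normalized) and the
    fraction of significant betas, with the significant count divided by the
    total number of beta values: N·sessions for chosen-location terms and
    N·(N−1)·sessions for not-chosen terms.
    """
    valid = [r for r in results if r.valid]
    if not valid:
        raise ValueError("no valid session fits to aggregate")
    n = valid[0].n_objects
    out: dict = {
        "n_sessions": len(results),
        "n_valid_sessions": len(valid),
        "chosen": {},
        "not_chosen": {},
        "chosen_norm": {},
        "not_chosen_norm": {},
        "sig_fraction_chosen": {},
        "sig_fraction_not_chosen": {},
    }
    all_betas = pd.concat([r.betas for r in valid], ignore_index=True)
    is_chosen = all_betas["location"] == all_betas["target"]
    for cue in _CUES:
        for key in ("chosen", "not_chosen", "chosen_norm", "not_chosen_norm"):
            out[key][cue] = float(np.mean([getattr(r, key)[cue] for r in valid]))
        sel_c = all_betas[is_chosen & (all_betas["cue"] == cue)]
        sel_n = all_betas[~is_chosen & (all_betas["cue"] == cue)]
        out["sig_fraction_chosen"][cue] = float(
            (sel_c["p_value"] < alpha).sum() / (n * len(valid))
        )
        out["sig_fraction_not_chosen"][cue] = float(
            (sel_n["p_value"] < alpha).sum() / (n * (n - 1) * len(valid))
        )
    return out
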