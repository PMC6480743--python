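"""Augmented Dickey-Fuller screening of the log-RT series.

Each person x block series is classified as stationary around zero, around
its mean, around a linear trend, or nonstationary, via a sequential
Dickey-Fuller strategy over three deterministic specifications:

1. constant + trend: unit root rejected and trend coefficient significant
   -> ``stationary_around_trend`` (flagged for detrending);
2. constant: rejected and constant significant -> ``stationary_around_mean``;
3. no deterministic terms: rejected -> ``stationary_around_zero``;
4. otherwise -> ``nonstationary``.

The test regression is built by hand so that missing trials break lag
pairs instead of compressing the time axis; unit-root p-values come from
MacKinnon's response surfaces (statsmodels).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.tsa.adfvalues import mackinnonp

from .preprocessing import CleanSeries

CLASSIFICATIONS = (
    "stationary_around_zero",
    "stationary_around_mean",
    "stationary_around_trend",
    "nonstationary",
)

_REGRESSION_FOR = {
    "stationary_around_zero": "n",
    "stationary_around_mean": "c",
    "stationary_around_trend": "ct",
}


class SeriesTooShortError(ValueError):
    pass


@dataclass
class StationarityVerdict:
    person_id: int
    task: str
    block: int
    classification: str
    test_statistics: dict  # regression spec -> ADF tau statistic
    lag_order: int
    config: dict

    @property
    def needs_detrending(self) -> bool:
        return self.classification == "stationary_around_trend"


def _adf_design(y: np.ndarray, lag: int, regression: str):
    """Rows t of the ADF regression dy_t ~ y_{t-1} + dy_{t-1..lag} (+ det
    terms), keeping only rows whose full lag window is observed (gaps break
    pairs)."""
    T = len(y)
    obs = np.isfinite(y)
    t_idx = np.arange(lag + 1, T)
    # row t needs y_t .. y_{t-lag-1} all observed
    ok = np.ones(len(t_idx), bool)
    for k in range(lag + 2):
        ok &= obs[t_idx - k]
    t_idx = t_idx[ok]
    if len(t_idx) == 0:
        return None
    dy = y[t_idx] - y[t_idx - 1]
    cols = [y[t_idx - 1]]
    for k in range(1, lag + 1):
        cols.append(y[t_idx - k] - y[t_idx - k - 1])
    if regression in ("c", "ct"):
        cols.append(np.ones(len(t_idx)))
    if regression == "ct":
        cols.append(t_idx.astype(float))
    X = np.column_stack(cols)
    return dy, X, t_idx


def _adf_fit(y: np.ndarray, lag: int, regression: str):
    """OLS fit of the ADF regression; returns (tau, nobs, aic, det_pvalues)."""
    design = _adf_design(y, lag, regression)
    if design is None:
        return None
    dy, X, _ = design
    n, p = X.shape
    if n <= p + 1:
        return None
    beta, _, rank, _ = np.linalg.lstsq(X, dy, rcond=None)
    if rank < p:
        return None
    resid = dy - X @ beta
    ssr = float(resid @ resid)
    if ssr <= 0:
        return None
    sigma2 = ssr / (n - p)
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    tau = beta[0] / se[0]
    aic = n * np.log(ssr / n) + 2 * p
    det_p = {}
    dof = n - p
    if regression in ("c", "ct"):
        i_const = lag + 1
        det_p["const"] = 2 * stats.t.sf(abs(beta[i_const] / se[i_const]), dof)
    if regression == "ct":
        i_trend = lag + 2
        det_p["trend"] = 2 * stats.t.sf(abs(beta[i_trend] / se[i_trend]), dof)
    return {"tau": float(tau), "nobs": n, "aic": float(aic), "det_p": det_p}


def _adf_test(y: np.ndarray, regression: str, max_lag: int):
    """AIC lag selection over 0..max_lag, then the ADF tau statistic and its
    MacKinnon p-value at the selected lag."""
    best = None
    best_lag = 0
    for lag in range(max_lag + 1):
        fit = _adf_fit(y, lag, regression)
        if fit is None:
            continue
        if best is None or fit["aic"] < best["aic"]:
            best, best_lag = fit, lag
    if best is None:
        raise SeriesTooShortError("no estimable ADF regression")
    p_unit = float(mackinnonp(best["tau"], regression=regression, N=1))
    return {
        "tau": best["tau"],
        "p_unit_root": p_unit,
        "lag": best_lag,
        "det_p": best["det_p"],
        "nobs": best["nobs"],
    }


def adf_classify(series: CleanSeries, alpha: float = 0.05) -> StationarityVerdict:
    """Classify one series by the sequential Dickey-Fuller rule."""
    y = np.asarray(series.values, float)
    n_obs = int(np.isfinite(y).sum())
    if n_obs < 20:
        raise SeriesTooShortError(f"only {n_obs} observed values (< 20)")
    max_lag = int(np.floor(12 * (len(y) / 100.0) ** 0.25))  # Schwert bound

    stats_out = {}
    lag_out = 0

    ct = _adf_test(y, "ct", max_lag)
    stats_out["ct"] = ct["tau"]
    classification = None
    if ct["p_unit_root"] < alpha and ct["det_p"].get("trend", 1.0) < alpha:
        classification, lag_out = "stationary_around_trend", ct["lag"]
    if classification is None:
        c = _adf_test(y, "c", max_lag)
        stats_out["c"] = c["tau"]
        if c["p_unit_root"] < alpha and c["det_p"].get("const", 1.0) < alpha:
            classification, lag_out = "stationary_around_mean", c["lag"]
    if classification is None:
        nn = _adf_test(y, "n", max_lag)
        stats_out["n"] = nn["tau"]
        if nn["p_unit_root"] < alpha:
            classification, lag_out = "stationary_around_zero", nn["lag"]
        else:
            classification, lag_out = "nonstationary", nn["lag"]

    return StationarityVerdict(
        person_id=series.person_id,
        task=series.task,
        block=series.block,
        classification=classification,
        test_statistics=stats_out,
        lag_order=lag_out,
        config={"alpha": alpha, "max_lag": max_lag, "lag_selection": "aic",
                "rule": "sequential ct -> c -> n", "pvalues": "mackinnon"},
    )


def classify_all(series_list: list[CleanSeries], alpha: float = 0.05) -> list[StationarityVerdict]:
    return [adf_classify(s, alpha=alpha) for s in series_list]


def apply_exclusion(verdicts: list[StationarityVerdict]) -> dict:
    """Paper-style exclusion rule: drop every person having at least one
    zero-stationary series; flag persons with trend verdicts for
    detrending.  Idempotent."""
    persons = sorted({v.person_id for v in verdicts})
    excluded = sorted({v.person_id for v in verdicts if v.classification == "stationary_around_zero"})
    detrend = sorted(
        {
            (v.person_id, v.task, v.block)
            for v in verdicts
            if v.classification == "stationary_around_trend"
        }
    )
    kept = [p for p in persons if p not in set(excluded)]
    return {"kept": kept, "excluded": excluded, "detrend": detrend}


def detrend(values: np.ndarray) -> np.ndarray:
    """Subtract the OLS linear fit over the observed entries (applied before
    model fitting when a trend verdict was raised)."""
    values = np.asarray(values, float).copy()
    obs = np.isfinite(values)
    t = np.arange(len(values), dtype=float)
    if obs.sum() < 3:
        return values
    coef = np.polyfit(t[obs], values[obs], 1)
    values[obs] -= np.polyval(coef, t[obs])
    return values


def verdicts_to_frame(verdicts: list[StationarityVerdict]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "person": v.person_id,
                "task": v.task,
                "block": v.block,
                "classification": v.classification,
                "statistic_ct": v.test_statistics.get("ct", np.nan),
                "statistic_c": v.test_statistics.get("c", np.nan),
                "statistic_n": v.test_statistics.get("n", np.nan),
                "lag": v.lag_order,
            }
            for v in verdicts
        ]
    )


def write_outputs(verdicts, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    verdicts_to_frame(verdicts).to_csv(out / "verdicts.csv", index=False)
    exclusion = apply_exclusion(verdicts)
    exclusion["detrend"] = [list(x) for x in exclusion["detrend"]]
    if verdicts:
        exclusion["config"] = verdicts[0].config
    (out / "exclusions.json").write_text(json.dumps(exclusion, indent=2))
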