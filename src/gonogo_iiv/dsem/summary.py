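"""Posterior summaries, convergence diagnostics and standardization."""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .sampler import PosteriorDraws

_W_COMPONENT = re.compile(r"^(mu|phi|isd)\[(.+)\]$")


def _psr_single(chains: np.ndarray) -> float:
    """Between/within variance ratio PSR = sqrt((W + B) / W) where B is the
    variance of the chain means and W the mean within-chain variance.  Two
    identical chains give exactly 1."""
    chains = np.asarray(chains, float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("PSR needs >= 2 equal-length chains")
    W = chains.var(axis=1, ddof=1).mean()
    B = chains.mean(axis=1).var(ddof=1)
    if W <= 0:
        return 1.0 if B <= 0 else float("inf")
    return float(np.sqrt((W + B) / W))


def compute_psr(draws: PosteriorDraws | np.ndarray, threshold: float = 1.1):
    """PSR per parameter.  Accepts a PosteriorDraws (returns a DataFrame
    with a ``flagged`` column for PSR > threshold) or a raw (chains, draws)
    array (returns a float)."""
    if isinstance(draws, np.ndarray):
        return _psr_single(draws)
    rows = []
    for name, arr in draws.params.items():
        psr = _psr_single(arr)
        rows.append({"parameter": name, "psr": psr, "flagged": psr > threshold})
    return pd.DataFrame(rows)


def _quantiles(x: np.ndarray, q=(2.5, 97.5)) -> tuple[float, float]:
    lo, hi = np.percentile(x, q)
    return float(lo), float(hi)


def summarize(draws: PosteriorDraws, include_aux: bool = False) -> pd.DataFrame:
    """Posterior mean, central 95% interval, CI-exclusion significance flag
    and PSR per parameter."""
    rows = []
    for name, arr in draws.params.items():
        if name.startswith("_") and not include_aux:
            continue
        pooled = np.asarray(arr, float).reshape(-1)
        lo, hi = _quantiles(pooled)
        psr = _psr_single(arr) if arr.shape[0] >= 2 else float("nan")
        rows.append(
            {
                "parameter": name,
                "mean": float(pooled.mean()),
                "ci_low": lo,
                "ci_high": hi,
                "significant": bool(lo > 0 or hi < 0),
                "psr": psr,
            }
        )
    return pd.DataFrame(rows)


def _predictor_sd(draws: PosteriorDraws, token: str) -> np.ndarray | float:
    """Per-draw SD of a regression predictor/outcome: latent components use
    the per-draw across-person SD; other observed variables use their
    constant sample SD."""
    m = _W_COMPONENT.match(token)
    if m:
        return draws.params[f"_sd_{m.group(1)}[{m.group(2)}]"]
    sd = draws.meta.get("obs_sd", {}).get(token)
    if sd is None:
        raise KeyError(f"no sample SD known for predictor {token!r}")
    return sd


def standardize(draws: PosteriorDraws) -> PosteriorDraws:
    """Standardized draws derived per retained draw:

    * level-2 covariances -> correlations (divide by the SD product);
    * regression weights -> weight * SD(predictor) / SD(outcome).

    Intercepts and variance components are not standardized.  Zero-variance
    denominators yield NaN draws (flagged downstream by NaN summaries).
    """
    out: dict[str, np.ndarray] = {}
    p = draws.params
    with np.errstate(invalid="ignore", divide="ignore"):
        for name, arr in p.items():
            m = re.match(r"^cov_(mu|phi|isd)_(mu|phi|isd)\[(.+)\]$", name)
            if m:
                c1, c2, blk = m.groups()
                denom = np.sqrt(p[f"var_{c1}[{blk}]"] * p[f"var_{c2}[{blk}]"])
                out[f"corr_{c1}_{c2}[{blk}]"] = arr / np.where(denom > 0, denom, np.nan)
                continue
            if "~" in name and not name.endswith("~intercept"):
                lhs, rhs = name.split("~", 1)
                sd_pred = _predictor_sd(draws, rhs)
                wm = _W_COMPONENT.match(lhs)
                if wm:
                    sd_out = p[f"_sd_{wm.group(1)}[{wm.group(2)}]"]
                else:
                    sd_out = p[f"_sd_out_{lhs}"]
                sd_out = np.where(np.asarray(sd_out) > 0, sd_out, np.nan)
                out[name] = arr * sd_pred / sd_out
    return PosteriorDraws(params=out, person={}, meta={**draws.meta, "standardized": True})


def summary_tables(draws: PosteriorDraws) -> dict[str, pd.DataFrame]:
    """Raw-scale and standardized summary tables for one fitted model."""
    return {"raw": summarize(draws), "standardized": summarize(standardize(draws))}
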