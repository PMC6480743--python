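"""Descriptive statistics, paired nonparametric block tests and
publication-style output tables."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

N_NOGO_PER_BLOCK = 13
N_PROSPECTIVE_PER_BLOCK = 13


@dataclass
class ErrorSummary:
    task: str
    mean_ce_block1: float
    sd_ce_block1: float
    mean_ce_block2: float
    sd_ce_block2: float
    mean_po_block1: float = np.nan
    sd_po_block1: float = np.nan
    mean_po_block2: float = np.nan
    sd_po_block2: float = np.nan

    @property
    def pooled_ce_rate(self) -> float:
        """Mean commission-error count averaged over blocks, / 13 NoGo trials."""
        return (self.mean_ce_block1 + self.mean_ce_block2) / 2.0 / N_NOGO_PER_BLOCK

    @property
    def pooled_po_rate(self) -> float:
        if np.isnan(self.mean_po_block1):
            return float("nan")
        return (self.mean_po_block1 + self.mean_po_block2) / 2.0 / N_PROSPECTIVE_PER_BLOCK

    @property
    def pm_accuracy(self) -> float:
        return 1.0 - self.pooled_po_rate


def pooled_rate(mean_block1: float, mean_block2: float, n_eligible: int = 13) -> float:
    """Average the per-block mean counts and divide by the eligible-trial
    count; the failure-rate arithmetic used for the pooled percentages."""
    return (mean_block1 + mean_block2) / 2.0 / n_eligible


def error_rate_table(persons: pd.DataFrame) -> list[ErrorSummary]:
    """Per-task error means/SDs and pooled rates from a per-person-per-block
    table with columns (person, task, block, ce[, po])."""
    out = []
    for task, grp in persons.groupby("task", sort=True):
        b1 = grp[grp["block"] == 1]
        b2 = grp[grp["block"] == 2]
        has_po = "po" in grp.columns and grp["po"].notna().any()
        out.append(
            ErrorSummary(
                task=str(task),
                mean_ce_block1=float(b1["ce"].mean()),
                sd_ce_block1=float(b1["ce"].std(ddof=1)),
                mean_ce_block2=float(b2["ce"].mean()),
                sd_ce_block2=float(b2["ce"].std(ddof=1)),
                mean_po_block1=float(b1["po"].mean()) if has_po else np.nan,
                sd_po_block1=float(b1["po"].std(ddof=1)) if has_po else np.nan,
                mean_po_block2=float(b2["po"].mean()) if has_po else np.nan,
                sd_po_block2=float(b2["po"].std(ddof=1)) if has_po else np.nan,
            )
        )
    return out


def wilcoxon_block_test(x, y, n_tests: int = 1) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test with Pratt zero handling and a
    continuity-corrected normal approximation; the two-sided p-value is
    Bonferroni-multiplied by ``n_tests`` and capped at 1.

    Returns (Z, corrected p).  All-zero differences are undefined and
    reported as (0.0, nan).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have the same length")
    d = x - y
    if np.all(d == 0):
        return 0.0, float("nan")
    res = stats.wilcoxon(x, y, zero_method="pratt", correction=True, method="approx")
    z = float(res.zstatistic)
    p = min(1.0, float(res.pvalue) * n_tests)
    return z, p


def backtransform_ms(log_value: float) -> float:
    """Natural-exponential back-transform of a log-ms value, to 2 dp."""
    return round(float(np.exp(log_value)), 2)


def _fmt(est, lo, hi, star):
    flag = " *" if star else ""
    return f"{est:.2f}{flag} ({lo:.2f} to {hi:.2f})"


def significance_star(ci_low: float, ci_high: float) -> bool:
    """Significant iff the 95% CI excludes 0."""
    return ci_low > 0 or ci_high < 0


def render_table1(summaries: list[ErrorSummary]) -> pd.DataFrame:
    cols = {}
    for s in sorted(summaries, key=lambda s: s.task):
        cols[f"{s.task}1"] = [
            f"{s.mean_ce_block1:.2f} ({s.sd_ce_block1:.2f})",
            "na" if np.isnan(s.mean_po_block1) else f"{s.mean_po_block1:.2f} ({s.sd_po_block1:.2f})",
        ]
        cols[f"{s.task}2"] = [
            f"{s.mean_ce_block2:.2f} ({s.sd_ce_block2:.2f})",
            "na" if np.isnan(s.mean_po_block2) else f"{s.mean_po_block2:.2f} ({s.sd_po_block2:.2f})",
        ]
    return pd.DataFrame(cols, index=["commission_errors", "prospective_omissions"])


def render_summary_table(summaries: dict[str, pd.DataFrame], parameters: list[str]) -> pd.DataFrame:
    """Assemble a Table-2/3-style grid: one column per model, one row per
    parameter, entries ``est * (lo to hi)`` with the CI-exclusion star;
    missing parameters render as "na"."""
    out = {}
    for model_name, summ in summaries.items():
        indexed = summ.set_index("parameter")
        col = []
        for p in parameters:
            if p in indexed.index:
                row = indexed.loc[p]
                col.append(
                    _fmt(row["mean"], row["ci_low"], row["ci_high"],
                         significance_star(row["ci_low"], row["ci_high"]))
                )
            else:
                col.append("na")
        out[model_name] = col
    return pd.DataFrame(out, index=parameters)


def descriptives(persons: pd.DataFrame, n_tests: int | None = None) -> dict:
    """Error-rate descriptives plus the block contrasts computed in this run
    (the Bonferroni multiplier defaults to the number of contrasts)."""
    summaries = error_rate_table(persons)
    by_task = {s.task: s for s in summaries}

    def paired(task, col):
        grp = persons[persons["task"] == task]
        b1 = grp[grp["block"] == 1].sort_values("person")[col].to_numpy(float)
        b2 = grp[grp["block"] == 2].sort_values("person")[col].to_numpy(float)
        return b1, b2

    contrasts = []
    if "CGNG" in by_task and "PGNG" in by_task:
        c = persons[persons["task"] == "CGNG"].groupby("person")["ce"].sum()
        p = persons[persons["task"] == "PGNG"].groupby("person")["ce"].sum()
        both = c.index.intersection(p.index)
        contrasts.append(("ce_CGNG_vs_PGNG", c.loc[both].to_numpy(float), p.loc[both].to_numpy(float)))
    for task in by_task:
        contrasts.append((f"ce_{task}1_vs_{task}2", *paired(task, "ce")))
    if "PGNG" in by_task and not np.isnan(by_task["PGNG"].pooled_po_rate):
        contrasts.append(("po_PGNG1_vs_PGNG2", *paired("PGNG", "po")))

    k = n_tests if n_tests is not None else len(contrasts)
    tests = {}
    for name, a, b in contrasts:
        z, p = wilcoxon_block_test(a, b, n_tests=k)
        tests[name] = {"z": z, "p_corrected": p}

    out = {"n_tests": k, "wilcoxon": tests, "tasks": {}}
    for s in summaries:
        out["tasks"][s.task] = {
            "pooled_commission_rate_pct": round(100 * s.pooled_ce_rate, 1),
        }
        if not np.isnan(s.pooled_po_rate):
            out["tasks"][s.task]["pooled_omission_rate_pct"] = round(100 * s.pooled_po_rate, 1)
            out["tasks"][s.task]["pm_accuracy_pct"] = round(100 * s.pm_accuracy)
    return out


def _strip_block(name: str) -> str:
    """Drop block suffixes so single-block summaries from different blocks
    share one row layout: 'gamma_phi[CGNG1]' -> 'gamma_phi'."""
    import re

    return re.sub(r"\[[^]]*\]", "", name)


TABLE2_ROWS = ["gamma_mu", "var_mu", "gamma_phi", "var_phi", "gamma_isd", "var_isd",
               "corr_mu_phi", "corr_mu_isd", "corr_phi_isd"]
TABLE3_ROWS = ["CE~intercept", "CE~mu", "CE~phi", "CE~isd", "r2_CE"]


def write_report(persons: pd.DataFrame, out_dir, summaries: dict | None = None) -> None:
    """``summaries`` maps a model name to its posterior-summary DataFrame
    (raw or standardized); block suffixes are collapsed so the four
    single-block models line up as columns."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table1 = render_table1(error_rate_table(persons))
    table1.to_csv(out / "table1.csv")
    (out / "descriptives.json").write_text(json.dumps(descriptives(persons), indent=2))
    if summaries:
        stripped = {}
        for name, summ in summaries.items():
            s = summ.copy()
            s["parameter"] = s["parameter"].map(_strip_block)
            stripped[name] = s.drop_duplicates("parameter")
        render_summary_table(stripped, TABLE2_ROWS).to_csv(out / "table2.csv")
        render_summary_table(stripped, TABLE3_ROWS).to_csv(out / "table3.csv")
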