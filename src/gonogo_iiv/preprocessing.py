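"""Trial-level RT preprocessing.

Fixed pipeline order per person x block: drop the first trial, mask
incorrect-trial RTs, trim raw RTs outside mean +/- 3 SD (single pass),
natural-log transform, then compute the intraindividual SD (iSD) over the
observed log values.  Trimming before the log transform and the n-1 SD
denominator are deliberate and must not be permuted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class PreprocessingError(ValueError):
    pass


@dataclass
class CleanSeries:
    """Analysis-ready log-RT series for one person x block (length 116)."""

    person_id: int
    task: str
    block: int
    values: np.ndarray  # log-RT, NaN where missing
    n_trimmed: int = 0
    n_missing_design: int = 0  # correct NoGo trials
    index_map: np.ndarray | None = None  # original trial numbers (after first-trial drop)

    @property
    def isd(self) -> float:
        return compute_isd(self)

    @property
    def n_observed(self) -> int:
        return int(np.isfinite(self.values).sum())


def drop_first_trial(block: pd.DataFrame) -> pd.DataFrame:
    """Remove trial 1; relabel remaining trials 1..T-1, keeping the original
    trial number in ``original_trial`` so the time axis round-trips."""
    if len(block) == 0:
        raise PreprocessingError("empty block")
    block = block.sort_values("trial")
    out = block[block["trial"] > block["trial"].min()].copy()
    out["original_trial"] = out["trial"]
    out["trial"] = np.arange(1, len(out) + 1)
    if len(out) == 0:
        warnings.warn("block had a single trial; series is empty after first-trial drop")
    return out


def trim_outliers(rt: np.ndarray) -> tuple[np.ndarray, int]:
    """Replace raw RTs outside mean +/- 3 SD (computed once over observed
    values) with NaN.  Returns (trimmed series, number trimmed)."""
    rt = np.asarray(rt, float).copy()
    obs = np.isfinite(rt)
    if obs.sum() < 2:
        warnings.warn("fewer than 2 observed RTs; skipping trimming")
        return rt, 0
    m = rt[obs].mean()
    s = rt[obs].std(ddof=1)
    if s == 0:
        return rt, 0
    out_of_range = obs & ((rt < m - 3 * s) | (rt > m + 3 * s))
    rt[out_of_range] = np.nan
    return rt, int(out_of_range.sum())


def log_transform(rt: np.ndarray) -> np.ndarray:
    """Natural log, elementwise; missing stays missing."""
    rt = np.asarray(rt, float)
    obs = np.isfinite(rt)
    if np.any(rt[obs] <= 0):
        bad = np.flatnonzero(obs & (rt <= 0))
        raise PreprocessingError(f"nonpositive RT at positions {bad.tolist()}")
    out = np.full(rt.shape, np.nan)
    out[obs] = np.log(rt[obs])
    return out


def compute_isd(clean: CleanSeries | np.ndarray) -> float:
    """Sample SD (denominator n-1) of the observed log-RTs."""
    values = clean.values if isinstance(clean, CleanSeries) else np.asarray(clean, float)
    obs = values[np.isfinite(values)]
    if obs.size < 2:
        warnings.warn("fewer than 2 observed values; iSD undefined")
        return float("nan")
    return float(np.std(obs, ddof=1))


@dataclass
class TrimReport:
    n_total: int = 0
    n_trimmed: int = 0
    per_block: dict = field(default_factory=dict)

    @property
    def fraction(self) -> float:
        return self.n_trimmed / self.n_total if self.n_total else 0.0

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "n_total": self.n_total,
                    "n_trimmed": self.n_trimmed,
                    "fraction": self.fraction,
                    "per_block": {f"{k[0]}{k[1]}": v for k, v in self.per_block.items()},
                },
                indent=2,
            )
        )


def preprocess_block(block: pd.DataFrame) -> CleanSeries:
    """Run the full pipeline for one person x block of raw trial records."""
    person = int(block["person"].iloc[0])
    task = str(block["task"].iloc[0])
    block_no = int(block["block"].iloc[0])
    kept = drop_first_trial(block)

    rt = kept["rt_ms"].to_numpy(float)
    correct = kept["correct"].to_numpy()
    trial_type = kept["trial_type"].to_numpy()
    # only correct-trial RTs are analyzed
    rt = np.where(correct == 1, rt, np.nan)
    n_missing_design = int(((trial_type == "nogo") & (correct == 1)).sum())

    rt, n_trimmed = trim_outliers(rt)
    log_rt = log_transform(rt)
    return CleanSeries(
        person_id=person,
        task=task,
        block=block_no,
        values=log_rt,
        n_trimmed=n_trimmed,
        n_missing_design=n_missing_design,
        index_map=kept["original_trial"].to_numpy(),
    )


def preprocess_dataset(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, TrimReport]:
    """Preprocess a long-format trial table.

    Returns (clean long table with ``log_rt``, per person x block iSD table,
    trim report)."""
    report = TrimReport()
    clean_rows = []
    isd_rows = []
    for (person, task, block_no), grp in trials.groupby(["person", "task", "block"], sort=True):
        cs = preprocess_block(grp)
        report.n_total += len(cs.values)
        report.n_trimmed += cs.n_trimmed
        key = (task, block_no)
        report.per_block.setdefault(key, {"n": 0, "trimmed": 0})
        report.per_block[key]["n"] += len(cs.values)
        report.per_block[key]["trimmed"] += cs.n_trimmed
        clean_rows.append(
            pd.DataFrame(
                {
                    "person": cs.person_id,
                    "task": cs.task,
                    "block": cs.block,
                    "trial": np.arange(1, len(cs.values) + 1),
                    "original_trial": cs.index_map,
                    "log_rt": cs.values,
                }
            )
        )
        isd_rows.append(
            {
                "person": cs.person_id,
                "task": cs.task,
                "block": cs.block,
                "isd": cs.isd,
                "n_observed": cs.n_observed,
                "n_trimmed": cs.n_trimmed,
            }
        )
    clean = pd.concat(clean_rows, ignore_index=True)
    isd_table = pd.DataFrame(isd_rows)
    return clean, isd_table, report


def clean_series_from_frame(clean: pd.DataFrame) -> list[CleanSeries]:
    """Rehydrate CleanSeries objects from the clean long table."""
    out = []
    for (person, task, block_no), grp in clean.groupby(["person", "task", "block"], sort=True):
        grp = grp.sort_values("trial")
        out.append(
            CleanSeries(
                person_id=int(person),
                task=str(task),
                block=int(block_no),
                values=grp["log_rt"].to_numpy(float),
                index_map=grp["original_trial"].to_numpy() if "original_trial" in grp else None,
            )
        )
    return out
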