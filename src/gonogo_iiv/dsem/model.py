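"""Model specification and data assembly for the two-level AR(1) models.

A model is a set of per-block log-RT matrices (persons x trials, NaN =
missing) together with a level-2 structure:

* every block contributes latent person parameters (mu_i, phi_i) and the
  observed fluctuation amplitude isd_i, modeled jointly;
* optional level-2 regressions of error counts on those parameters;
* the two-block variants additionally regress the later block's person
  parameters on the earlier block's, and chain the error regressions
  (CE_later ~ CE_earlier, PO ~ ... + CE_later), with an optional
  working-memory covariate on every error equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COMPONENTS = ("mu", "phi", "isd")

VARIANTS = ("single_block", "single_block_with_errors", "two_block", "two_block_with_covariate")

_SINGLE_BLOCKS = {"m1": "CGNG1", "m2": "CGNG2", "m3": "PGNG1", "m4": "PGNG2",
                  "m5": "CGNG1", "m6": "CGNG2", "m7": "PGNG1", "m8": "PGNG2"}


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of which model variant to fit."""

    name: str
    variant: str
    blocks: tuple[str, ...]
    level2_outcomes: tuple[str, ...] = ()  # outcome keys like "CE[CGNG2]", "PO[PGNG1]"
    covariates: tuple[str, ...] = ()
    #: optional half-block option: (block label, cut trial, "first"|"second")
    split: tuple[str, int, str] | None = None

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant.startswith("two_block") and len(self.blocks) != 2:
            raise ValueError("two-block variants name exactly two blocks")
        if self.variant.startswith("single") and len(self.blocks) != 1:
            raise ValueError("single-block variants name exactly one block")
        for out in self.level2_outcomes:
            if out.startswith("PO[") and not out[3:-1].startswith("P"):
                raise ValueError("PO regression is only defined for a prospective block")


def model_spec(name: str) -> ModelSpec:
    """The named model variants m1..m10."""
    name = name.lower()
    if name in ("m1", "m2", "m3", "m4"):
        return ModelSpec(name=name, variant="single_block", blocks=(_SINGLE_BLOCKS[name],))
    if name in ("m5", "m6", "m7", "m8"):
        b = _SINGLE_BLOCKS[name]
        return ModelSpec(
            name=name, variant="single_block_with_errors", blocks=(b,),
            level2_outcomes=(f"CE[{b}]",),
        )
    if name in ("m9", "m10"):
        variant = "two_block" if name == "m9" else "two_block_with_covariate"
        covs = () if name == "m9" else ("lns",)
        return ModelSpec(
            name=name, variant=variant, blocks=("CGNG2", "PGNG1"),
            level2_outcomes=("CE[CGNG2]", "CE[PGNG1]", "PO[PGNG1]"),
            covariates=covs,
        )
    raise ValueError(f"unknown model name {name!r}")


@dataclass
class RegressionSpec:
    """One level-2 linear regression: outcome ~ columns."""

    name: str  # outcome key, e.g. "CE[CGNG2]"
    cols: list  # [("const",), ("w", block, comp_index), ("obs", key)]


@dataclass
class ModelData:
    """Validated model graph + data, ready for the Gibbs sampler."""

    spec: ModelSpec
    persons: list
    Y: dict  # block -> (N, T_b) float with NaN
    isd: dict  # block -> (N,)
    obs: dict  # observed level-2 vectors: "CE[b]", "PO[b]", "lns", "isd[b]"
    regs: list = field(default_factory=list)

    @property
    def N(self) -> int:
        return len(self.persons)

    @property
    def blocks(self) -> tuple[str, ...]:
        return self.spec.blocks

    @property
    def two_block(self) -> bool:
        return self.spec.variant.startswith("two_block")


def _block_label(task, block_no) -> str:
    return f"{task}{int(block_no)}"


def _pivot_block(clean: pd.DataFrame, label: str, persons: list) -> np.ndarray:
    task, block_no = label[:-1], int(label[-1])
    sub = clean[(clean["task"] == task) & (clean["block"] == block_no)]
    if sub.empty:
        raise ValueError(f"block {label} not present in the clean series table")
    wide = sub.pivot_table(index="person", columns="trial", values="log_rt", dropna=False)
    wide = wide.reindex(index=persons)
    wide = wide[sorted(wide.columns)]
    return wide.to_numpy(float)


def build_model(
    spec: ModelSpec,
    clean: pd.DataFrame,
    persons_table: pd.DataFrame | None = None,
    excluded=(),
) -> ModelData:
    """Assemble matrices and level-2 regressions for ``spec``.

    ``clean`` is the long clean-series table (person, task, block, trial,
    log_rt); ``persons_table`` supplies error counts and the covariate when
    the variant needs them.  Persons in ``excluded`` (stationarity screen)
    are removed; persons with fewer than 2 observed trials in any named
    block are rejected with an explicit list.
    """
    excluded = set(excluded)
    present = None
    for label in spec.blocks:
        task, block_no = label[:-1], int(label[-1])
        sub = clean[(clean["task"] == task) & (clean["block"] == block_no)]
        ids = set(sub["person"].unique())
        present = ids if present is None else (present & ids)
    if not present:
        raise ValueError("no persons present in all named blocks")
    persons = sorted(p.item() if hasattr(p, "item") else p for p in present if p not in excluded)

    if spec.split is not None:
        label, cut, half = spec.split
        if label not in spec.blocks:
            raise ValueError(f"split block {label} not in model blocks")
        if half not in ("first", "second"):
            raise ValueError("split half must be 'first' or 'second'")
        task, block_no = label[:-1], int(label[-1])
        first, second = split_block(clean, task, block_no, cut)
        segment = first if half == "first" else second
        rest = clean[(clean["task"] != task) | (clean["block"] != block_no)]
        clean = pd.concat([rest, segment], ignore_index=True)

    Y, isd = {}, {}
    too_short = []
    for label in spec.blocks:
        mat = _pivot_block(clean, label, persons)
        n_obs = np.isfinite(mat).sum(axis=1)
        too_short += [persons[i] for i in np.flatnonzero(n_obs < 2)]
        Y[label] = mat
        with np.errstate(invalid="ignore"):
            isd[label] = np.array([np.nanstd(row[np.isfinite(row)], ddof=1) if np.isfinite(row).sum() > 1 else np.nan for row in mat])
    if too_short:
        raise ValueError(f"persons with < 2 observed trials: {sorted(set(too_short))}")

    obs = {f"isd[{b}]": isd[b] for b in spec.blocks}
    needs_outcomes = bool(spec.level2_outcomes)
    if needs_outcomes or spec.covariates:
        if persons_table is None:
            raise ValueError("persons_table required for error/covariate models")
        pt = persons_table
        for out in spec.level2_outcomes:
            kind, label = out[:2], out[3:-1]
            task, block_no = label[:-1], int(label[-1])
            col = "ce" if kind == "CE" else "po"
            sub = pt[(pt["task"] == task) & (pt["block"] == block_no)].set_index("person")
            missing = [p for p in persons if p not in sub.index]
            if missing:
                raise ValueError(f"{out}: missing counts for persons {missing}")
            vals = sub.loc[persons, col].to_numpy(float)
            if np.isnan(vals).any():
                raise ValueError(f"{out}: NaN counts")
            obs[out] = vals
        if "lns" in spec.covariates:
            sub = pt.drop_duplicates("person").set_index("person")
            obs["lns"] = sub.loc[persons, "lns"].to_numpy(float)

    regs = _build_regressions(spec)
    return ModelData(spec=spec, persons=persons, Y=Y, isd=isd, obs=obs, regs=regs)


def _build_regressions(spec: ModelSpec) -> list[RegressionSpec]:
    regs = []
    covs = [("obs", c) for c in spec.covariates]

    def w_cols(block):
        return [("w", block, k) for k in range(3)]

    if spec.variant == "single_block_with_errors":
        (b,) = spec.blocks
        for out in spec.level2_outcomes:
            regs.append(RegressionSpec(out, [("const",)] + w_cols(b) + covs))
    elif spec.variant.startswith("two_block"):
        a, b = spec.blocks
        if f"CE[{a}]" in spec.level2_outcomes:
            regs.append(RegressionSpec(f"CE[{a}]", [("const",)] + w_cols(a) + covs))
        if f"CE[{b}]" in spec.level2_outcomes:
            regs.append(
                RegressionSpec(f"CE[{b}]", [("const",)] + w_cols(b) + [("obs", f"CE[{a}]")] + covs)
            )
        if f"PO[{b}]" in spec.level2_outcomes:
            regs.append(
                RegressionSpec(f"PO[{b}]", [("const",)] + w_cols(b) + [("obs", f"CE[{b}]")] + covs)
            )
    return regs


def split_block(
    clean: pd.DataFrame, task: str, block: int, cut: int, min_segment: int = 5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split one block's clean series into two contiguous segments at
    ``cut`` (trials <= cut vs > cut), preserving original trial indices so
    AR lag pairs never cross the cut (the halves are modeled as separate
    series)."""
    sub = clean[(clean["task"] == task) & (clean["block"] == block)]
    if sub.empty:
        raise ValueError(f"block {task}{block} not found")
    tmin, tmax = int(sub["trial"].min()), int(sub["trial"].max())
    if not (tmin + min_segment - 1 <= cut <= tmax - min_segment):
        raise ValueError(f"cut {cut} leaves a segment shorter than {min_segment} trials")
    first = sub[sub["trial"] <= cut].copy()
    second = sub[sub["trial"] > cut].copy()
    return first, second
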