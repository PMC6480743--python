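"""Generation of Go/NoGo task designs and trial-level RT/error datasets.

The generator produces data with exactly the statistical structure the
two-level AR(1) model assumes: per-person log-RT series

    y_it = mu_i + z_it,    z_it = phi_i * z_{i,t-1} + zeta_it,

with person parameters (mu_i, phi_i, isd_i) drawn jointly multivariate
normal, and per-block error counts produced by a linear level-2 regression
on those parameters.  ``isd_i`` is parameterized as the *stationary* SD of
the process, so the innovation SD is ``isd_i * sqrt(1 - phi_i**2)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GO = "go"
NOGO = "nogo"
PROSPECTIVE = "prospective"

#: digit withheld on NoGo trials
NOGO_DIGIT = 3
#: color cueing the prospective response
PROSPECTIVE_COLOR = "blue"

COLORS = ("blue", "pink", "yellow", "light_green", "dark_green", "gray", "brown", "orange")
FONT_SIZES = (63, 81, 99, 117, 135)

#: canonical block labels: task version x block number
DEFAULT_BLOCKS = ("CGNG1", "CGNG2", "PGNG1", "PGNG2")

TRIAL_COLUMNS = ["person", "task", "block", "trial", "trial_type", "digit", "color", "rt_ms", "correct"]


class InfeasibleDesignError(ValueError):
    """No admissible trial ordering exists (or was found) for the design."""


@dataclass(frozen=True)
class BlockDesign:
    """Composition of one 117-trial Go/NoGo block."""

    task_version: str  # "classical" | "prospective"
    n_trials: int = 117
    n_go: int = 104
    n_nogo: int = 13
    n_prospective: int = 0
    nogo_digit: int = NOGO_DIGIT
    prospective_cue: str = PROSPECTIVE_COLOR

    def __post_init__(self):
        if self.n_go + self.n_nogo + self.n_prospective != self.n_trials:
            raise ValueError(
                f"trial counts {self.n_go}+{self.n_nogo}+{self.n_prospective} != {self.n_trials}"
            )
        if min(self.n_go, self.n_nogo, self.n_prospective, self.n_trials) < 0:
            raise ValueError("negative trial count")

    @classmethod
    def classical(cls) -> "BlockDesign":
        return cls(task_version="classical", n_trials=117, n_go=104, n_nogo=13, n_prospective=0)

    @classmethod
    def prospective(cls) -> "BlockDesign":
        return cls(task_version="prospective", n_trials=117, n_go=91, n_nogo=13, n_prospective=13)


@dataclass
class TrialSequence:
    """Ordered trial types and stimulus attributes for one block."""

    block_design: BlockDesign
    trial_types: np.ndarray  # (n_trials,) of {go, nogo, prospective}
    digits: np.ndarray  # (n_trials,) int 1..9
    colors: np.ndarray  # (n_trials,) str
    font_sizes: np.ndarray  # (n_trials,) int

    def __len__(self) -> int:
        return len(self.trial_types)

    def counts(self) -> dict:
        types, n = np.unique(self.trial_types, return_counts=True)
        return dict(zip(types.tolist(), n.tolist()))


def _no_adjacent(flags: np.ndarray) -> bool:
    return not bool(np.any(flags[:-1] & flags[1:]))


def generate_trial_sequence(design: BlockDesign, seed) -> TrialSequence:
    """Pseudo-randomize one block: no consecutive NoGo and no consecutive
    Prospective trials; every digit 1-9 appears exactly 13 times.

    Rejection sampling over uniform permutations, capped at 10,000 attempts.
    """
    rng = np.random.default_rng(seed)
    n = design.n_trials
    if n % 9 != 0:
        raise InfeasibleDesignError("digit balance requires a multiple of 9 trials")
    reps = n // 9
    if design.n_nogo > (n + 1) // 2 or design.n_prospective > (n + 1) // 2:
        raise InfeasibleDesignError("too many special trials to separate")

    base_digits = np.repeat(np.arange(1, 10), reps)
    # NoGo trials are exactly the occurrences of the NoGo digit; designs with
    # fewer NoGo trials than digit repetitions are not representable.
    if design.n_nogo not in (0, reps):
        raise InfeasibleDesignError(
            f"n_nogo must be 0 or {reps} to keep digits balanced, got {design.n_nogo}"
        )

    digits = None
    for _ in range(10_000):
        cand = rng.permutation(base_digits)
        nogo_flags = cand == design.nogo_digit if design.n_nogo else np.zeros(n, bool)
        if design.n_nogo and not _no_adjacent(nogo_flags):
            continue
        digits = cand
        break
    if digits is None:
        raise InfeasibleDesignError("no non-adjacent NoGo arrangement found in 10,000 attempts")

    nogo_flags = (digits == design.nogo_digit) if design.n_nogo else np.zeros(n, bool)
    prospective_flags = np.zeros(n, bool)
    if design.n_prospective:
        eligible = np.flatnonzero(~nogo_flags)  # no blue NoGo digit
        ok = False
        for _ in range(10_000):
            pick = rng.choice(eligible, size=design.n_prospective, replace=False)
            flags = np.zeros(n, bool)
            flags[pick] = True
            if _no_adjacent(flags):
                prospective_flags = flags
                ok = True
                break
        if not ok:
            raise InfeasibleDesignError("no non-adjacent Prospective arrangement found")

    trial_types = np.where(nogo_flags, NOGO, np.where(prospective_flags, PROSPECTIVE, GO))

    colors = rng.choice(COLORS, size=n)
    if design.n_prospective:
        non_blue = [c for c in COLORS if c != design.prospective_cue]
        mask = ~prospective_flags
        colors[mask] = rng.choice(non_blue, size=int(mask.sum()))
        colors[prospective_flags] = design.prospective_cue
    font_sizes = rng.choice(FONT_SIZES, size=n)

    return TrialSequence(design, trial_types, digits, colors, font_sizes)


@dataclass
class PopulationParameters:
    """Level-2 generating parameters.

    ``cov_matrix`` is the 3x3 covariance of (mu_i, phi_i, isd_i); the error
    regressions mirror the level-2 linear model for commission errors (CE)
    and prospective omissions (PO, which additionally loads on CE).
    """

    gamma_mu: float = 6.25
    gamma_phi: float = 0.30
    gamma_isd: float = 0.15
    cov_matrix: np.ndarray = field(
        default_factory=lambda: build_covariance((0.02, 0.01, 0.005), (0.22, 0.11, 0.65))
    )
    # CE regression: CE = beta0 + beta_mu*mu + beta_phi*phi + beta_isd*isd (+ beta_lns*lns) + e
    beta0: float = 19.4
    beta_mu: float = -3.0
    beta_phi: float = -2.0
    beta_isd: float = 18.0
    beta_lns: float = 0.0
    sigma_e: float = 1.2
    # PO regression: PO = po_beta0 + po weights on (mu, phi, isd) + po_beta_ce*CE + e
    po_beta0: float = 0.5
    po_beta_mu: float = 0.0
    po_beta_phi: float = 0.0
    po_beta_isd: float = 0.0
    po_beta_ce: float = 0.25
    po_sigma_e: float = 1.0
    # person covariate (working-memory span score)
    lns_mean: float = 9.41
    lns_sd: float = 2.36

    def __post_init__(self):
        self.cov_matrix = np.asarray(self.cov_matrix, float)
        validate_covariance(self.cov_matrix)

    @property
    def var_mu(self) -> float:
        return float(self.cov_matrix[0, 0])

    @property
    def var_phi(self) -> float:
        return float(self.cov_matrix[1, 1])

    @property
    def var_isd(self) -> float:
        return float(self.cov_matrix[2, 2])

    @classmethod
    def from_table_values(
        cls,
        gamma_mu: float,
        gamma_phi: float,
        gamma_isd: float,
        variances=(0.02, 0.01, 0.005),
        correlations=(0.22, 0.11, 0.65),
        **kwargs,
    ) -> "PopulationParameters":
        """Build from published-style moments (variances and correlations
        r(mu,phi), r(mu,isd), r(phi,isd))."""
        return cls(
            gamma_mu=gamma_mu,
            gamma_phi=gamma_phi,
            gamma_isd=gamma_isd,
            cov_matrix=build_covariance(variances, correlations),
            **kwargs,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cov_matrix"] = self.cov_matrix.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationParameters":
        d = dict(d)
        d["cov_matrix"] = np.asarray(d["cov_matrix"], float)
        return cls(**d)


def build_covariance(variances, correlations) -> np.ndarray:
    """3x3 covariance from variances (v_mu, v_phi, v_isd) and correlations
    (r_mu_phi, r_mu_isd, r_phi_isd)."""
    v = np.asarray(variances, float)
    r01, r02, r12 = correlations
    s = np.sqrt(v)
    cov = np.diag(v).astype(float)
    cov[0, 1] = cov[1, 0] = r01 * s[0] * s[1]
    cov[0, 2] = cov[2, 0] = r02 * s[0] * s[2]
    cov[1, 2] = cov[2, 1] = r12 * s[1] * s[2]
    return cov


def validate_covariance(cov: np.ndarray) -> None:
    cov = np.asarray(cov, float)
    if cov.shape != (3, 3):
        raise ValueError("cov_matrix must be 3x3")
    if not np.allclose(cov, cov.T):
        raise ValueError("cov_matrix must be symmetric")
    eig = np.linalg.eigvalsh(cov)
    if eig.min() < -1e-10 * max(1.0, eig.max()):
        raise ValueError("cov_matrix is not positive semi-definite")


@dataclass
class PersonParameters:
    """Per-person generative (or estimated) parameters and outcomes."""

    person_id: int
    mu_i: float
    phi_i: float
    isd_i: float
    ce_i: int = 0
    po_i: int = 0
    lns: float = np.nan


def sample_person_parameters(
    pop: PopulationParameters,
    n_persons: int,
    seed,
    isd_floor: float = 0.01,
    max_phi_redraws: int = 1000,
) -> list[PersonParameters]:
    """Draw (mu_i, phi_i, isd_i) jointly MVN around the fixed effects.

    phi draws outside (-1, 1) are rejected and redrawn so every generated
    series is stationary; isd is floored at a small positive value.
    """
    validate_covariance(pop.cov_matrix)
    rng = np.random.default_rng(seed)
    mean = np.array([pop.gamma_mu, pop.gamma_phi, pop.gamma_isd])
    draws = rng.multivariate_normal(mean, pop.cov_matrix, size=n_persons, method="svd")
    n_rejected = 0
    bad = np.abs(draws[:, 1]) >= 1.0
    for _ in range(max_phi_redraws):
        if not bad.any():
            break
        n_rejected += int(bad.sum())
        draws[bad] = rng.multivariate_normal(mean, pop.cov_matrix, size=int(bad.sum()), method="svd")
        bad = np.abs(draws[:, 1]) >= 1.0
    else:
        raise RuntimeError("could not draw stationary phi values")
    sample_person_parameters.last_rejection_count = n_rejected

    lns = rng.normal(pop.lns_mean, pop.lns_sd, size=n_persons)
    persons = []
    for i in range(n_persons):
        persons.append(
            PersonParameters(
                person_id=i + 1,
                mu_i=float(draws[i, 0]),
                phi_i=float(draws[i, 1]),
                isd_i=float(max(draws[i, 2], isd_floor)),
                lns=float(lns[i]),
            )
        )
    return persons


sample_person_parameters.last_rejection_count = 0


def simulate_ar1(
    n: int,
    mu: float,
    phi: float,
    stationary_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stationary AR(1) around ``mu`` whose marginal SD equals
    ``stationary_sd``; the initial state is drawn from the stationary
    distribution."""
    if abs(phi) >= 1.0:
        raise ValueError(f"|phi| must be < 1 for a stationary series, got {phi}")
    sigma_innov = stationary_sd * np.sqrt(1.0 - phi**2)
    z = np.empty(n)
    if n == 0:
        return z
    z[0] = rng.normal(0.0, stationary_sd)
    eps = rng.normal(0.0, sigma_innov, size=max(n - 1, 0))
    for t in range(1, n):
        z[t] = phi * z[t - 1] + eps[t - 1]
    return mu + z


def simulate_rt_series(
    person: PersonParameters,
    sequence: TrialSequence,
    seed,
    raw_scale: bool = False,
    prospective_offset: float = 0.0,
    trend_per_trial: float = 0.0,
) -> np.ndarray:
    """Simulate the log-RT series for one block.

    The latent AR(1) process runs over *all* trials (the time axis is never
    compressed); the returned series is NaN on NoGo trials, where a correct
    response withholds the key press.  ``raw_scale=True`` interprets
    (mu_i, isd_i) in milliseconds instead of log-ms (used for illustrative
    raw-RT regimes).  ``trend_per_trial`` injects an explicit deterministic
    trend for nonstationarity experiments.
    """
    rng = np.random.default_rng(seed)
    n = len(sequence)
    y = simulate_ar1(n, person.mu_i, person.phi_i, person.isd_i, rng)
    if trend_per_trial:
        y = y + trend_per_trial * np.arange(n)
    if prospective_offset:
        y = np.where(sequence.trial_types == PROSPECTIVE, y + prospective_offset, y)
    y = np.where(sequence.trial_types == NOGO, np.nan, y)
    if raw_scale:
        return y
    return y


def simulate_errors(person: PersonParameters, pop: PopulationParameters, seed) -> tuple[int, int]:
    """Draw (commission errors, prospective omissions) for one block.

    Linear predictor plus Gaussian residual, rounded to the nearest integer
    and clipped to [0, 13] (clipping introduces a small bias toward the
    interior for extreme predictors).
    """
    rng = np.random.default_rng(seed)
    eta_ce = (
        pop.beta0
        + pop.beta_mu * person.mu_i
        + pop.beta_phi * person.phi_i
        + pop.beta_isd * person.isd_i
        + (pop.beta_lns * person.lns if pop.beta_lns else 0.0)
    )
    ce = int(np.clip(np.rint(eta_ce + rng.normal(0.0, pop.sigma_e)), 0, 13))
    eta_po = (
        pop.po_beta0
        + pop.po_beta_mu * person.mu_i
        + pop.po_beta_phi * person.phi_i
        + pop.po_beta_isd * person.isd_i
        + pop.po_beta_ce * ce
    )
    po = int(np.clip(np.rint(eta_po + rng.normal(0.0, pop.po_sigma_e)), 0, 13))
    return ce, po


@dataclass
class CrossBlockStructure:
    """Optional coupling of later-block person parameters to an earlier
    block: w_B = intercepts + coef_matrix @ w_A + MVN(0, residual_cov)."""

    source: str
    target: str
    intercepts: np.ndarray  # (3,)
    coef_matrix: np.ndarray  # (3,3), rows = (mu, phi, isd) of target
    residual_cov: np.ndarray  # (3,3)


@dataclass
class SimulatedDataset:
    trials: pd.DataFrame
    persons: pd.DataFrame
    truth: dict
    seed: int

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.trials.to_csv(out / "trials.csv", index=False)
        self.persons.to_csv(out / "persons.csv", index=False)
        (out / "truth.json").write_text(json.dumps(self.truth, indent=2))

    @classmethod
    def read(cls, out_dir) -> "SimulatedDataset":
        out = Path(out_dir)
        trials = pd.read_csv(out / "trials.csv")
        persons = pd.read_csv(out / "persons.csv")
        truth = json.loads((out / "truth.json").read_text())
        return cls(trials=trials, persons=persons, truth=truth, seed=truth.get("seed", -1))


def _design_for(block_name: str) -> BlockDesign:
    if block_name.startswith("C"):
        return BlockDesign.classical()
    return BlockDesign.prospective()


def assemble_dataset(
    pop: PopulationParameters | dict,
    n_persons: int,
    seed: int,
    blocks_spec=DEFAULT_BLOCKS,
    cross_block: CrossBlockStructure | None = None,
    go_omission_rate: float = 0.0,
) -> SimulatedDataset:
    """Simulate the full study layout (default: CGNG1, CGNG2, PGNG1, PGNG2).

    ``pop`` may be a single PopulationParameters (shared by all blocks) or a
    mapping block name -> PopulationParameters.  Per-block person parameters
    are drawn independently unless ``cross_block`` couples a target block to
    a source block.  Deterministic under ``seed``.
    """
    blocks_spec = list(blocks_spec)
    pops = {b: (pop[b] if isinstance(pop, dict) else pop) for b in blocks_spec}
    root = np.random.SeedSequence(seed)
    keys = {}
    for b in blocks_spec:
        keys[("seq", b)], keys[("pers", b)], keys[("rt", b)], keys[("err", b)], keys[("rec", b)] = (
            root.spawn(5)
        )
    lns_rng = np.random.default_rng(root.spawn(1)[0])
    pop0 = pops[blocks_spec[0]]
    lns = lns_rng.normal(pop0.lns_mean, pop0.lns_sd, size=n_persons)

    person_params: dict[str, list[PersonParameters]] = {}
    for b in blocks_spec:
        if cross_block is not None and b == cross_block.target:
            src = person_params[cross_block.source]
            rng = np.random.default_rng(keys[("pers", b)])
            persons = []
            for i, sp in enumerate(src):
                w_a = np.array([sp.mu_i, sp.phi_i, sp.isd_i])
                mean = cross_block.intercepts + cross_block.coef_matrix @ w_a
                w_b = rng.multivariate_normal(mean, cross_block.residual_cov, method="svd")
                phi = float(np.clip(w_b[1], -0.99, 0.99))
                persons.append(
                    PersonParameters(i + 1, float(w_b[0]), phi, float(max(w_b[2], 0.01)), lns=lns[i])
                )
            person_params[b] = persons
        else:
            persons = sample_person_parameters(pops[b], n_persons, keys[("pers", b)])
            for i, p in enumerate(persons):
                p.lns = float(lns[i])
            person_params[b] = persons

    trial_rows = []
    person_rows = []
    for b in blocks_spec:
        design = _design_for(b)
        task = "CGNG" if design.task_version == "classical" else "PGNG"
        block_no = int(b[-1])
        seq_seeds = keys[("seq", b)].spawn(n_persons)
        rt_seeds = keys[("rt", b)].spawn(n_persons)
        err_seeds = keys[("err", b)].spawn(n_persons)
        rec_rng = np.random.default_rng(keys[("rec", b)])
        for i, person in enumerate(person_params[b]):
            seq = generate_trial_sequence(design, seq_seeds[i])
            log_rt = simulate_rt_series(person, seq, rt_seeds[i])
            ce, po = simulate_errors(person, pops[b], err_seeds[i])
            person.ce_i, person.po_i = ce, po

            correct = np.ones(len(seq), dtype=int)
            rt_ms = np.exp(log_rt)
            # reconcile generated counts with the realized trial sequence
            nogo_idx = np.flatnonzero(seq.trial_types == NOGO)
            ce_idx = rec_rng.choice(nogo_idx, size=min(ce, len(nogo_idx)), replace=False)
            correct[ce_idx] = 0
            # a commission error is a key press: its RT is observed
            rt_ms[ce_idx] = np.exp(
                simulate_ar1(len(ce_idx), person.mu_i, 0.0, person.isd_i, rec_rng)
            )
            pro_idx = np.flatnonzero(seq.trial_types == PROSPECTIVE)
            if len(pro_idx):
                po_idx = rec_rng.choice(pro_idx, size=min(po, len(pro_idx)), replace=False)
                correct[po_idx] = 0
            if go_omission_rate > 0:
                go_idx = np.flatnonzero(seq.trial_types == GO)
                omit = go_idx[rec_rng.random(len(go_idx)) < go_omission_rate]
                correct[omit] = 0
                rt_ms[omit] = np.nan

            df = pd.DataFrame(
                {
                    "person": person.person_id,
                    "task": task,
                    "block": block_no,
                    "trial": np.arange(1, len(seq) + 1),
                    "trial_type": seq.trial_types,
                    "digit": seq.digits,
                    "color": seq.colors,
                    "rt_ms": np.round(rt_ms, 6),
                    "correct": correct,
                }
            )
            trial_rows.append(df)
            person_rows.append(
                {
                    "person": person.person_id,
                    "task": task,
                    "block": block_no,
                    "mu_i": person.mu_i,
                    "phi_i": person.phi_i,
                    "isd_i": person.isd_i,
                    "ce": ce,
                    "po": po if task == "PGNG" else np.nan,
                    "lns": person.lns,
                }
            )

    trials = pd.concat(trial_rows, ignore_index=True)[TRIAL_COLUMNS]
    persons = pd.DataFrame(person_rows)
    truth = {"seed": int(seed), "blocks": blocks_spec}
    for b in blocks_spec:
        truth[b] = pops[b].to_dict()
    return SimulatedDataset(trials=trials, persons=persons, truth=truth, seed=int(seed))
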