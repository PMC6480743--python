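"""Gibbs sampler with missing-data augmentation for the two-level AR(1)
models.

Each iteration cycles through full-conditional draws of

(a) the latent within-person deviations on missing trials (two-color
    single-site updates, so the time axis is never compressed),
(b) per-person (mu_i, phi_i),
(c) the level-2 mean vector and covariance of (mu, phi, isd) — and, for
    two-block models, the cross-block coefficient matrix and residual
    covariance of the later block,
(d) the innovation variance per block,
(e) the level-2 error-regression coefficients and residual variances.

All conditionals are standard (normal / inverse-gamma / inverse-Wishart),
so no Metropolis steps are needed.  Location parameters carry vague
N(0, 1e10) priors; variances inverse-gamma(0.001, 0.001); the level-2
covariances inverse-Wishart(d+1, s*I).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import invwishart

from .model import COMPONENTS, ModelData


class SamplerDivergedError(RuntimeError):
    pass


@dataclass
class Priors:
    location_prior_variance: float = 1e10
    ig_shape: float = 0.001
    ig_scale: float = 0.001
    #: inverse-Wishart prior scale (df = d + 1).  A fixed identity scale
    #: swamps level-2 variances of log-RT data (~0.01) and is not invariant
    #: to rescaling the series, so by default the scale matrix is
    #: iw_scale * diag(method-of-moments level-2 variances); set
    #: ``iw_empirical=False`` for a fixed iw_scale * I.
    iw_scale: float = 0.1
    iw_empirical: bool = True
    iw_df_offset: float = 1.0  # df = d + offset


@dataclass
class SamplerConfig:
    """``n_iterations`` are post-burn-in iterations; an additional
    ``burn_in_fraction * n_iterations`` iterations are run and discarded
    first.  Retained draws per chain = n_iterations // thinning."""

    n_chains: int = 2
    n_iterations: int = 50_000
    thinning: int = 10
    burn_in_fraction: float = 0.5
    seed: int = 0
    store_person_draws: bool = False
    store_imputations: bool = False


@dataclass
class PosteriorDraws:
    """Retained draws: ``params[name]`` has shape (n_chains, n_draws);
    ``person[name]`` has shape (n_chains, n_draws, N)."""

    params: dict = field(default_factory=dict)
    person: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def names(self):
        return list(self.params)

    def get(self, name: str) -> np.ndarray:
        return self.params[name]

    def sel(self, prefix: str) -> np.ndarray:
        """The unique parameter whose name starts with ``prefix``."""
        hits = [n for n in self.params if n.startswith(prefix)]
        if len(hits) != 1:
            raise KeyError(f"prefix {prefix!r} matches {hits}")
        return self.params[hits[0]]


def _draw_mvn_from_precision(P: np.ndarray, lin: np.ndarray, rng) -> np.ndarray:
    """Draw from N(P^-1 lin, P^-1) via the Cholesky factor of P."""
    P = 0.5 * (P + P.T)
    L = np.linalg.cholesky(P)
    m = np.linalg.solve(P, lin)
    z = rng.standard_normal(len(lin))
    return m + np.linalg.solve(L.T, z)


class _BlockState:
    """Per-block latent state: data, imputed deviations, (mu, phi, s2)."""

    def __init__(self, Y: np.ndarray):
        self.Y = np.asarray(Y, float)
        self.D = np.isfinite(self.Y)
        self.d = self.D.astype(float)
        self.N, self.T = self.Y.shape
        self.any_missing = not self.D.all()

        self.mu = np.nanmean(self.Y, axis=1)
        dev = self.Y - self.mu[:, None]
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            v0 = np.nanvar(dev, axis=1, ddof=1)
        self.v0 = np.where(np.isfinite(v0) & (v0 > 1e-8), v0, 0.05)

        a, b = dev[:, :-1], dev[:, 1:]
        pair = self.D[:, :-1] & self.D[:, 1:]
        num = np.where(pair, a * b, 0.0).sum(axis=1)
        den = np.where(pair, a * a, 0.0).sum(axis=1)
        self.phi = np.clip(np.where(den > 1e-12, num / np.maximum(den, 1e-12), 0.0), -0.95, 0.95)

        resid = np.where(pair, b - self.phi[:, None] * a, 0.0)
        n_pairs = pair.sum()
        self.s2 = float((resid**2).sum() / max(n_pairs, 1)) if n_pairs else 0.05
        self.s2 = max(self.s2, 1e-6)

        # missing cells hold latent deviations; observed cells hold raw data
        self.C = np.where(self.D, self.Y, 0.0)
        cols = np.arange(self.T)
        self._parity_masks = [(~self.D) & ((cols % 2) == p)[None, :] for p in (0, 1)]

    # -- latent deviations ------------------------------------------------
    def deviations(self) -> np.ndarray:
        return self.C - self.d * self.mu[:, None]

    def impute(self, rng: np.random.Generator) -> None:
        if not self.any_missing:
            return
        for mask in self._parity_masks:
            if not mask.any():
                continue
            Z = self.deviations()
            phi = self.phi[:, None]
            prec = np.zeros((self.N, self.T))
            lin = np.zeros((self.N, self.T))
            prec[:, 1:] += 1.0 / self.s2
            lin[:, 1:] += phi * Z[:, :-1] / self.s2
            prec[:, 0] += 1.0 / self.v0  # fixed prior for a missing initial state
            prec[:, :-1] += phi**2 / self.s2
            lin[:, :-1] += phi * Z[:, 1:] / self.s2
            draw = lin / prec + rng.standard_normal((self.N, self.T)) / np.sqrt(prec)
            self.C[mask] = draw[mask]

    # -- person parameters -------------------------------------------------
    def draw_mu(self, prec2, lin2, rng) -> None:
        phi = self.phi[:, None]
        A = self.C[:, 1:] - phi * self.C[:, :-1]
        B = self.d[:, 1:] - phi * self.d[:, :-1]
        prec = (B * B).sum(axis=1) / self.s2 + prec2 + 1e-12
        lin = (A * B).sum(axis=1) / self.s2 + lin2
        self.mu = lin / prec + rng.standard_normal(self.N) / np.sqrt(prec)

    def draw_phi(self, prec2, lin2, rng) -> None:
        Z = self.deviations()
        x, y = Z[:, :-1], Z[:, 1:]
        prec = (x * x).sum(axis=1) / self.s2 + prec2 + 1e-12
        lin = (x * y).sum(axis=1) / self.s2 + lin2
        self.phi = lin / prec + rng.standard_normal(self.N) / np.sqrt(prec)

    def draw_s2(self, priors: Priors, rng) -> None:
        Z = self.deviations()
        r = Z[:, 1:] - self.phi[:, None] * Z[:, :-1]
        ssr = float((r * r).sum())
        n = self.N * (self.T - 1)
        self.s2 = 1.0 / rng.gamma(priors.ig_shape + 0.5 * n, 1.0 / (priors.ig_scale + 0.5 * ssr))
        if not np.isfinite(self.s2) or self.s2 > 1e8:
            raise SamplerDivergedError("innovation variance diverged")


class _Regression:
    def __init__(self, spec, chain):
        self.name = spec.name
        self.cols = list(spec.cols)
        self.y = chain.model.obs[spec.name]
        X = self.design(chain)
        p = X.shape[1]
        beta, *_ = np.linalg.lstsq(X, self.y, rcond=None)
        self.beta = beta
        resid = self.y - X @ beta
        dof = max(len(self.y) - p, 1)
        self.s2_e = max(float(resid @ resid) / dof, 1e-6)

    def design(self, chain) -> np.ndarray:
        cols = []
        for c in self.cols:
            if c[0] == "const":
                cols.append(np.ones(chain.N))
            elif c[0] == "w":
                cols.append(chain.w_matrix(c[1])[:, c[2]])
            else:
                cols.append(chain.model.obs[c[1]])
        return np.column_stack(cols)

    def col_name(self, c) -> str:
        if c[0] == "const":
            return "intercept"
        if c[0] == "w":
            return f"{COMPONENTS[c[2]]}[{c[1]}]"
        return c[1]


class _Chain:
    def __init__(self, model: ModelData, priors: Priors, flat_person_prior: bool):
        self.model = model
        self.priors = priors
        self.flat = flat_person_prior
        self.N = model.N
        self.blocks = {b: _BlockState(model.Y[b]) for b in model.blocks}
        self.block_a = model.blocks[0]
        self.block_b = model.blocks[1] if model.two_block else None
        self.isd = {b: np.asarray(model.isd[b], float) for b in model.blocks}

        d = 3
        self.nu0 = d + priors.iw_df_offset
        W = self.w_matrix(self.block_a)
        self.gamma_a = W.mean(axis=0)
        self.Sigma_a = _regularized_cov(W)
        self.Psi0 = (
            priors.iw_scale * np.diag(np.diag(self.Sigma_a))
            if priors.iw_empirical
            else priors.iw_scale * np.eye(d)
        )
        if model.two_block:
            Wb = self.w_matrix(self.block_b)
            X = np.column_stack([np.ones(self.N), W])
            theta, *_ = np.linalg.lstsq(X, Wb, rcond=None)
            self.theta_int = theta[0].copy()
            self.Gamma = theta[1:].T.copy()  # (3 target, 3 source)
            self.Sigma_b = _regularized_cov(Wb - X @ theta)
            self.Psi0_b = (
                priors.iw_scale * np.diag(np.diag(self.Sigma_b))
                if priors.iw_empirical
                else priors.iw_scale * np.eye(d)
            )
        self.regs = [_Regression(r, self) for r in model.regs]

    def w_matrix(self, block: str) -> np.ndarray:
        st = self.blocks[block]
        return np.column_stack([st.mu, st.phi, self.isd[block]])

    # -- conditional contributions for person-parameter draws ---------------
    def _level2_contrib(self, block: str, k: int):
        prec = np.zeros(self.N)
        lin = np.zeros(self.N)
        W = self.w_matrix(block)
        if not self.flat:
            if block == self.block_b:
                Lam = np.linalg.inv(self.Sigma_b)
                M = self.theta_int + self.w_matrix(self.block_a) @ self.Gamma.T
            else:
                Lam = np.linalg.inv(self.Sigma_a)
                M = np.broadcast_to(self.gamma_a, (self.N, 3))
            R = W - M
            cross = R @ Lam[:, k] - Lam[k, k] * R[:, k]
            prec += Lam[k, k]
            lin += Lam[k, k] * M[:, k] - cross
            if block == self.block_a and self.block_b is not None:
                # predictor role in the cross-block regression
                Lam_b = np.linalg.inv(self.Sigma_b)
                g = self.Gamma[:, k]
                U = self.w_matrix(self.block_b) - self.theta_int - W @ self.Gamma.T
                Rp = U + np.outer(W[:, k], g)
                prec += float(g @ Lam_b @ g)
                lin += Rp @ (Lam_b @ g)
        for reg in self.regs:
            key = ("w", block, k)
            if key not in reg.cols:
                continue
            j = reg.cols.index(key)
            X = reg.design(self)
            bj = reg.beta[j]
            r = self.model.obs[reg.name] - X @ reg.beta + bj * X[:, j]
            prec += bj * bj / reg.s2_e
            lin += bj * r / reg.s2_e
        return prec, lin

    # -- global draws -------------------------------------------------------
    def _draw_level2(self, rng) -> None:
        if self.flat:
            return
        lpv = self.priors.location_prior_variance
        W = self.w_matrix(self.block_a)
        Lam = np.linalg.inv(self.Sigma_a)
        P = self.N * Lam + np.eye(3) / lpv
        self.gamma_a = _draw_mvn_from_precision(P, Lam @ W.sum(axis=0), rng)
        R = W - self.gamma_a
        self.Sigma_a = invwishart.rvs(
            df=self.nu0 + self.N, scale=self.Psi0 + R.T @ R, random_state=rng
        )
        if self.block_b is not None:
            Wb = self.w_matrix(self.block_b)
            X = np.column_stack([np.ones(self.N), W])
            Lam_b = np.linalg.inv(self.Sigma_b)
            P = np.kron(Lam_b, X.T @ X) + np.eye(12) / lpv
            lin = (Lam_b @ (Wb.T @ X)).reshape(-1)
            theta = _draw_mvn_from_precision(P, lin, rng).reshape(3, 4)
            self.theta_int = theta[:, 0]
            self.Gamma = theta[:, 1:]
            U = Wb - X @ np.column_stack([self.theta_int, self.Gamma]).T
            self.Sigma_b = invwishart.rvs(
                df=self.nu0 + self.N, scale=self.Psi0_b + U.T @ U, random_state=rng
            )

    def _draw_regressions(self, rng) -> None:
        lpv = self.priors.location_prior_variance
        for reg in self.regs:
            X = reg.design(self)
            n, p = X.shape
            P = X.T @ X / reg.s2_e + np.eye(p) / lpv
            reg.beta = _draw_mvn_from_precision(P, X.T @ reg.y / reg.s2_e, rng)
            r = reg.y - X @ reg.beta
            reg.s2_e = 1.0 / rng.gamma(
                self.priors.ig_shape + 0.5 * n,
                1.0 / (self.priors.ig_scale + 0.5 * float(r @ r)),
            )
            if not np.isfinite(reg.s2_e) or reg.s2_e > 1e10:
                raise SamplerDivergedError(f"residual variance diverged in {reg.name}")

    def step(self, rng) -> None:
        for b, st in self.blocks.items():
            st.impute(rng)
            prec2, lin2 = self._level2_contrib(b, 0)
            st.draw_mu(prec2, lin2, rng)
            prec2, lin2 = self._level2_contrib(b, 1)
            st.draw_phi(prec2, lin2, rng)
            st.draw_s2(self.priors, rng)
        self._draw_level2(rng)
        self._draw_regressions(rng)

    # -- recording ----------------------------------------------------------
    def record(self, store: dict, person_store: dict, config: SamplerConfig) -> None:
        a, b = self.block_a, self.block_b
        if not self.flat:
            for k, comp in enumerate(COMPONENTS):
                store.setdefault(f"gamma_{comp}[{a}]", []).append(self.gamma_a[k])
                store.setdefault(f"var_{comp}[{a}]", []).append(self.Sigma_a[k, k])
            store.setdefault(f"cov_mu_phi[{a}]", []).append(self.Sigma_a[0, 1])
            store.setdefault(f"cov_mu_isd[{a}]", []).append(self.Sigma_a[0, 2])
            store.setdefault(f"cov_phi_isd[{a}]", []).append(self.Sigma_a[1, 2])
            if b is not None:
                for k, comp in enumerate(COMPONENTS):
                    store.setdefault(f"intercept_{comp}[{b}]", []).append(self.theta_int[k])
                    store.setdefault(f"var_{comp}[{b}]", []).append(self.Sigma_b[k, k])
                    for j, src in enumerate(COMPONENTS):
                        store.setdefault(f"{comp}[{b}]~{src}[{a}]", []).append(self.Gamma[k, j])
                store.setdefault(f"cov_mu_phi[{b}]", []).append(self.Sigma_b[0, 1])
                store.setdefault(f"cov_mu_isd[{b}]", []).append(self.Sigma_b[0, 2])
                store.setdefault(f"cov_phi_isd[{b}]", []).append(self.Sigma_b[1, 2])
        for blk, st in self.blocks.items():
            store.setdefault(f"sigma2_zeta[{blk}]", []).append(st.s2)
            store.setdefault(f"_sd_mu[{blk}]", []).append(st.mu.std(ddof=1) if self.N > 1 else 0.0)
            store.setdefault(f"_sd_phi[{blk}]", []).append(st.phi.std(ddof=1) if self.N > 1 else 0.0)
            store.setdefault(f"_sd_isd[{blk}]", []).append(
                self.isd[blk].std(ddof=1) if self.N > 1 else 0.0
            )
        for reg in self.regs:
            X = reg.design(self)
            eta = X @ reg.beta
            var_eta = eta.var(ddof=1) if self.N > 1 else 0.0
            for j, c in enumerate(reg.cols):
                store.setdefault(f"{reg.name}~{reg.col_name(c)}", []).append(reg.beta[j])
            store.setdefault(f"sigma2_e_{reg.name}", []).append(reg.s2_e)
            store.setdefault(f"r2_{reg.name}", []).append(var_eta / (var_eta + reg.s2_e))
            store.setdefault(f"_sd_out_{reg.name}", []).append(np.sqrt(var_eta + reg.s2_e))
        if config.store_person_draws:
            for blk, st in self.blocks.items():
                person_store.setdefault(f"mu_i[{blk}]", []).append(st.mu.copy())
                person_store.setdefault(f"phi_i[{blk}]", []).append(st.phi.copy())
        if config.store_imputations:
            for blk, st in self.blocks.items():
                if st.any_missing:
                    person_store.setdefault(f"imputed[{blk}]", []).append(st.C[~st.D].copy())


def _regularized_cov(W: np.ndarray) -> np.ndarray:
    if W.shape[0] > 3:
        cov = np.cov(W, rowvar=False)
    else:
        cov = np.zeros((3, 3))
    cov = np.atleast_2d(cov)
    return cov + 1e-4 * np.eye(3)


def gibbs_sample(
    model: ModelData,
    config: SamplerConfig | None = None,
    priors: Priors | None = None,
    flat_person_prior: bool = False,
) -> PosteriorDraws:
    """Run the Gibbs sampler; returns retained, thinned draws per chain.

    ``flat_person_prior=True`` removes the level-2 distribution from the
    (mu_i, phi_i) conditionals (and skips level-2 draws); used for oracle
    comparisons against per-series least-squares estimates.
    """
    config = config or SamplerConfig()
    priors = priors or Priors()
    n_burn = int(round(config.burn_in_fraction * config.n_iterations))
    n_keep = config.n_iterations // config.thinning
    if n_keep < 1:
        raise ValueError("config retains no draws")
    ss = np.random.SeedSequence(config.seed)

    all_stores = []
    all_person = []
    for child in ss.spawn(config.n_chains):
        rng = np.random.default_rng(child)
        chain = _Chain(model, priors, flat_person_prior)
        store: dict = {}
        person_store: dict = {}
        kept = 0
        for it in range(n_burn + config.n_iterations):
            chain.step(rng)
            if it >= n_burn and (it - n_burn) % config.thinning == config.thinning - 1:
                chain.record(store, person_store, config)
                kept += 1
                if kept == n_keep:
                    break
        all_stores.append(store)
        all_person.append(person_store)

    params = {
        name: np.array([s[name] for s in all_stores]) for name in all_stores[0]
    }
    person = {
        name: np.array([s[name] for s in all_person]) for name in all_person[0]
    }
    obs_sd = {}
    for key, vals in model.obs.items():
        vals = np.asarray(vals, float)
        obs_sd[key] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    meta = {
        "model": model.spec.name,
        "variant": model.spec.variant,
        "blocks": list(model.blocks),
        "n_persons": model.N,
        "n_chains": config.n_chains,
        "n_retained_per_chain": n_keep,
        "obs_sd": obs_sd,
        "flat_person_prior": flat_person_prior,
    }
    return PosteriorDraws(params=params, person=person, meta=meta)
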