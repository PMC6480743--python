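"""Sampler correctness: oracle comparisons, null and sign recovery,
calibration, and invariance properties.  Fits are deliberately small to keep
the suite fast; seeds are fixed."""

import numpy as np
import pandas as pd
import pytest

from gonogo_iiv import dsem

from conftest import attach_errors, make_clean_df

SMALL = dict(n_chains=2, n_iterations=1200, thinning=2)


def _fit(clean, persons=None, model="m1", seed=0, excluded=(), flat=False, **cfg_kw):
    spec = dsem.model_spec(model)
    data = dsem.build_model(spec, clean, persons, excluded=excluded)
    cfg = dsem.SamplerConfig(seed=seed, **{**SMALL, **cfg_kw})
    return dsem.gibbs_sample(data, cfg, flat_person_prior=flat)


def _batch_mcse(arr, n_batches=20):
    """Batch-means Monte-Carlo standard error of the pooled posterior mean."""
    means = []
    for chain in arr:
        for batch in np.array_split(chain, n_batches // arr.shape[0]):
            means.append(batch.mean())
    return np.std(means, ddof=1) / np.sqrt(len(means))


class TestOracleEquivalence:
    def test_single_person_matches_conditional_least_squares(self):
        # long complete series so the O(1/T) posterior-mean vs CLS gap is
        # far below Monte-Carlo resolution
        rng = np.random.default_rng(42)
        T, mu, phi, sd = 3000, 6.3, 0.4, 0.15
        z = np.empty(T)
        z[0] = rng.normal(0, sd)
        sig = sd * np.sqrt(1 - phi**2)
        for t in range(1, T):
            z[t] = phi * z[t - 1] + rng.normal(0, sig)
        y = mu + z
        clean = pd.DataFrame({"person": 1, "task": "CGNG", "block": 1,
                              "trial": np.arange(1, T + 1), "log_rt": y})
        draws = _fit(clean, flat=True, seed=3, n_iterations=2000,
                     store_person_draws=True)
        mu_d = draws.person["mu_i[CGNG1]"][:, :, 0]
        phi_d = draws.person["phi_i[CGNG1]"][:, :, 0]
        # conditional least squares oracle: y_t on (1, y_{t-1})
        X = np.column_stack([np.ones(T - 1), y[:-1]])
        b, *_ = np.linalg.lstsq(X, y[1:], rcond=None)
        phi_ols, mu_ols = b[1], b[0] / (1 - b[1])
        assert abs(mu_d.mean() - mu_ols) < max(3 * _batch_mcse(mu_d), 2e-3)
        assert abs(phi_d.mean() - phi_ols) < max(3 * _batch_mcse(phi_d), 3e-3)
        # innovation variance against the OLS residual variance
        resid = y[1:] - X @ b
        s2_ols = resid @ resid / (T - 1)
        s2_d = draws.get("sigma2_zeta[CGNG1]")
        assert abs(s2_d.mean() - s2_ols) < max(3 * _batch_mcse(s2_d), 2e-5)


class TestNullRecovery:
    def test_zero_phi_covered(self):
        clean, _ = make_clean_df(50, 80, gamma_phi=0.0, seed=7)
        draws = _fit(clean, seed=11)
        s = dsem.summarize(draws).set_index("parameter")
        lo, hi = s.loc["gamma_phi[CGNG1]", ["ci_low", "ci_high"]]
        assert lo < 0.0 < hi

    def test_table_values_recovered(self):
        clean, _ = make_clean_df(87, 116, gamma_mu=6.25, gamma_phi=0.30,
                                 gamma_isd=0.15, seed=21)
        draws = _fit(clean, seed=5, n_iterations=2000)
        s = dsem.summarize(draws).set_index("parameter")
        assert s.loc["gamma_phi[CGNG1]", "mean"] == pytest.approx(0.30, abs=0.07)
        assert s.loc["gamma_mu[CGNG1]", "mean"] == pytest.approx(6.25, abs=0.05)
        assert s.loc["gamma_isd[CGNG1]", "mean"] == pytest.approx(0.15, abs=0.02)


class TestSignPattern:
    def test_negative_mu_positive_isd_weights_recovered(self):
        # speed/accuracy pattern: faster (lower mu) and more variable
        # (higher isd) persons make more commission errors.  A moderate
        # phi-isd correlation is used: at 0.65 the shrunken phi_i draws are
        # nearly collinear with observed isd and the two weights cannot be
        # separated in a design where beta_phi is exactly 0.
        from gonogo_iiv.synthetic_data import build_covariance

        cov = build_covariance((0.02, 0.01, 0.005), (0.22, 0.11, 0.3))
        clean, persons = make_clean_df(87, 116, cov=cov, seed=13)
        persons = attach_errors(persons, beta=(25.0, -4.0, 0.0, 25.0), sigma_e=1.0, seed=14)
        draws = _fit(clean, persons, model="m5", seed=15, n_iterations=3000, thinning=3)
        s = dsem.summarize(draws).set_index("parameter")
        assert s.loc["CE[CGNG1]~mu[CGNG1]", "ci_high"] < 0
        assert s.loc["CE[CGNG1]~isd[CGNG1]", "ci_low"] > 0
        std = dsem.summarize(dsem.standardize(draws)).set_index("parameter")
        assert std.loc["CE[CGNG1]~mu[CGNG1]", "mean"] < 0
        assert std.loc["CE[CGNG1]~isd[CGNG1]", "mean"] > 0


class TestDrawValidity:
    @pytest.fixture(scope="class")
    def fitted(self):
        clean, persons = make_clean_df(30, 60, seed=1)
        persons = attach_errors(persons, beta=(15.0, -2.0, -1.0, 15.0), sigma_e=1.2, seed=2)
        return _fit(clean, persons, model="m5", seed=3)

    def test_variance_draws_positive(self, fitted):
        for name in fitted.names():
            if name.startswith(("var_", "sigma2_")):
                assert (fitted.get(name) > 0).all()

    def test_correlations_bounded(self, fitted):
        std = dsem.standardize(fitted)
        for name, arr in std.params.items():
            if name.startswith("corr_"):
                assert np.all(arr >= -1.0) and np.all(arr <= 1.0)

    def test_r2_in_unit_interval(self, fitted):
        r2 = fitted.sel("r2_CE")
        assert np.all(r2 >= 0) and np.all(r2 <= 1)

    def test_psr_close_to_one(self, fitted):
        psr = dsem.compute_psr(fitted)
        fixed = psr[psr["parameter"].str.startswith("gamma_")]
        assert (fixed["psr"] < 1.2).all()


class TestChainSeedIndependence:
    def test_summaries_agree_across_seed_sets(self):
        clean, _ = make_clean_df(40, 80, seed=31)
        d1 = _fit(clean, seed=100)
        d2 = _fit(clean, seed=200)
        g1, g2 = d1.get("gamma_phi[CGNG1]"), d2.get("gamma_phi[CGNG1]")
        tol = 4 * np.hypot(_batch_mcse(g1), _batch_mcse(g2))
        assert abs(g1.mean() - g2.mean()) < max(tol, 5e-3)


class TestMissingness:
    def test_mcar_widens_ci_without_bias(self):
        widths = {}
        means = {}
        for rate in (0.0, 0.35):
            ws, ms = [], []
            for rep in range(3):
                clean, _ = make_clean_df(40, 80, missing_rate=rate, seed=50 + rep)
                draws = _fit(clean, seed=60 + rep)
                s = dsem.summarize(draws).set_index("parameter")
                lo, hi = s.loc["gamma_phi[CGNG1]", ["ci_low", "ci_high"]]
                ws.append(hi - lo)
                ms.append(s.loc["gamma_phi[CGNG1]", "mean"])
            widths[rate] = np.mean(ws)
            means[rate] = np.mean(ms)
        assert widths[0.35] > widths[0.0]
        assert abs(means[0.35] - 0.30) < 0.1  # no gross MCAR bias


class TestStandardizationInvariance:
    def test_invariant_to_affine_rescaling(self):
        clean, persons = make_clean_df(50, 80, seed=71)
        persons = attach_errors(persons, beta=(20.0, -3.0, 0.0, 20.0), sigma_e=1.0, seed=72)
        scaled = clean.copy()
        scaled["log_rt"] = 0.5 * scaled["log_rt"]
        pers_scaled = persons.copy()  # counts unchanged
        d1 = _fit(clean, persons, model="m5", seed=73)
        d2 = _fit(scaled, pers_scaled, model="m5", seed=73)
        s1 = dsem.summarize(dsem.standardize(d1)).set_index("parameter")
        s2 = dsem.summarize(dsem.standardize(d2)).set_index("parameter")
        for par in ("CE[CGNG1]~mu[CGNG1]", "CE[CGNG1]~isd[CGNG1]", "corr_phi_isd[CGNG1]"):
            assert s1.loc[par, "mean"] == pytest.approx(s2.loc[par, "mean"], abs=0.12)


class TestCalibration:
    def test_fixed_effects_covered_in_most_replicates(self):
        hits = {"gamma_mu[CGNG1]": 0, "gamma_phi[CGNG1]": 0, "gamma_isd[CGNG1]": 0}
        truth = {"gamma_mu[CGNG1]": 6.25, "gamma_phi[CGNG1]": 0.30, "gamma_isd[CGNG1]": 0.15}
        # T kept at 116: the conditional-likelihood AR estimate carries an
        # O(1/T) attenuation, so shorter series under-cover the generating phi
        n_rep = 8
        for rep in range(n_rep):
            clean, _ = make_clean_df(40, 116, seed=300 + rep)
            draws = _fit(clean, seed=400 + rep)
            s = dsem.summarize(draws).set_index("parameter")
            for par in hits:
                lo, hi = s.loc[par, ["ci_low", "ci_high"]]
                hits[par] += lo <= truth[par] <= hi
        for par, h in hits.items():
            assert h >= int(0.9 * n_rep), (par, h)


class TestTwoBlockFit:
    @staticmethod
    def _coupled_two_block(N=120, T=116, missing_rate=0.11, seed=0):
        from gonogo_iiv.synthetic_data import build_covariance

        rng = np.random.default_rng(seed)
        covA = build_covariance((0.02, 0.01, 0.005), (0.22, 0.11, 0.65))
        WA = rng.multivariate_normal([6.25, 0.30, 0.15], covA, size=N)
        WA[:, 1] = np.clip(WA[:, 1], -0.9, 0.9)
        WA[:, 2] = np.maximum(WA[:, 2], 0.02)
        Gam = np.diag([0.75, 0.5, 0.6])
        intc = np.array([1.5, 0.05, 0.03])
        WB = intc + WA @ Gam.T + rng.multivariate_normal(
            np.zeros(3), np.diag([0.008, 0.006, 0.002]), size=N
        )
        WB[:, 1] = np.clip(WB[:, 1], -0.9, 0.9)
        WB[:, 2] = np.maximum(WB[:, 2], 0.02)

        def series(W, task, block):
            rows = []
            for i in range(N):
                mu, phi, isd = W[i]
                sig = isd * np.sqrt(1 - phi**2)
                z = np.empty(T)
                z[0] = rng.normal(0, isd)
                for t in range(1, T):
                    z[t] = phi * z[t - 1] + rng.normal(0, sig)
                y = mu + z
                y[rng.random(T) < missing_rate] = np.nan
                rows.append(pd.DataFrame({"person": i + 1, "task": task, "block": block,
                                          "trial": np.arange(1, T + 1), "log_rt": y}))
            return pd.concat(rows, ignore_index=True)

        clean = pd.concat([series(WA, "CGNG", 2), series(WB, "PGNG", 1)], ignore_index=True)
        ids = np.arange(1, N + 1)
        persons = pd.concat(
            [
                pd.DataFrame({"person": ids, "task": "CGNG", "block": 2,
                              "ce": rng.integers(0, 5, N), "po": np.nan,
                              "lns": rng.normal(9.4, 2.4, N)}),
                pd.DataFrame({"person": ids, "task": "PGNG", "block": 1,
                              "ce": rng.integers(0, 6, N), "po": rng.integers(0, 3, N),
                              "lns": np.nan}),
            ],
            ignore_index=True,
        )
        return clean, persons, WA, WB

    def test_m9_recovers_cross_block_link(self):
        clean, persons, WA, WB = self._coupled_two_block()
        model = dsem.build_model(dsem.model_spec("m9"), clean, persons)
        draws = dsem.gibbs_sample(
            model, dsem.SamplerConfig(n_chains=2, n_iterations=1500, thinning=3, seed=1)
        )
        s = dsem.summarize(draws).set_index("parameter")
        # independent oracle: OLS of generating person parameters
        X = np.column_stack([np.ones(len(WA)), WA])
        ols_mu = np.linalg.lstsq(X, WB[:, 0], rcond=None)[0][1]
        lo, hi = s.loc["mu[PGNG1]~mu[CGNG2]", ["ci_low", "ci_high"]]
        assert lo > 0 and lo <= ols_mu <= hi
        lo_p, hi_p = s.loc["phi[PGNG1]~phi[CGNG2]", ["ci_low", "ci_high"]]
        assert lo_p <= 0.5 <= hi_p  # weakly identified but covered
        # outcome regressions present for both blocks
        assert "CE[PGNG1]~CE[CGNG2]" in s.index
        assert "PO[PGNG1]~CE[PGNG1]" in s.index

    def test_m10_pipeline_smoke(self):
        from gonogo_iiv.synthetic_data import PopulationParameters, assemble_dataset
        from gonogo_iiv import preprocessing

        ds = assemble_dataset(PopulationParameters(), n_persons=20, seed=83,
                              blocks_spec=("CGNG2", "PGNG1"))
        clean, _, _ = preprocessing.preprocess_dataset(ds.trials)
        model = dsem.build_model(dsem.model_spec("m10"), clean, ds.persons)
        draws = dsem.gibbs_sample(
            model, dsem.SamplerConfig(n_chains=2, n_iterations=600, thinning=2, seed=84)
        )
        s = dsem.summarize(draws)
        assert {"CE[CGNG2]~lns", "CE[PGNG1]~lns", "PO[PGNG1]~lns"} <= set(s["parameter"])
        assert s["mean"].notna().all()

    def test_split_halves_statistically_indistinguishable(self, small_clean):
        clean, _, _ = small_clean
        clean = clean[(clean["task"] == "CGNG") & (clean["block"] == 1)]
        # homogeneous data: refit on halves, gamma_phi CIs overlap
        big_clean, _ = make_clean_df(45, 116, seed=91)
        out = []
        for half in ("first", "second"):
            spec = dsem.ModelSpec(name=f"m1_{half}", variant="single_block",
                                  blocks=("CGNG1",), split=("CGNG1", 58, half))
            model = dsem.build_model(spec, big_clean)
            draws = dsem.gibbs_sample(
                model, dsem.SamplerConfig(n_chains=2, n_iterations=1200, thinning=2, seed=92)
            )
            s = dsem.summarize(draws).set_index("parameter")
            out.append(s.loc["gamma_phi[CGNG1]"])
        lo = max(out[0]["ci_low"], out[1]["ci_low"])
        hi = min(out[0]["ci_high"], out[1]["ci_high"])
        assert lo < hi  # overlapping credible intervals
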