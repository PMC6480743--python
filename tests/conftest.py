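import numpy as np
import pandas as pd
import pytest

from gonogo_iiv.synthetic_data import PopulationParameters, assemble_dataset
from gonogo_iiv import preprocessing


def make_clean_df(
    n_persons: int,
    n_trials: int,
    gamma_mu: float = 6.25,
    gamma_phi: float = 0.30,
    gamma_isd: float = 0.15,
    cov=None,
    missing_rate: float = 0.11,
    seed: int = 0,
    task: str = "CGNG",
    block: int = 1,
):
    """Model-faithful clean-series table: Gaussian AR(1) log-RT around a
    person mean, with MCAR missingness.  Bypasses the raw-trial pipeline so
    sampler tests see exactly the assumed generative process.

    Returns (clean long DataFrame, person-parameter DataFrame).
    """
    rng = np.random.default_rng(seed)
    if cov is None:
        from gonogo_iiv.synthetic_data import build_covariance

        cov = build_covariance((0.02, 0.01, 0.005), (0.22, 0.11, 0.65))
    mean = np.array([gamma_mu, gamma_phi, gamma_isd])
    W = rng.multivariate_normal(mean, cov, size=n_persons)
    W[:, 1] = np.clip(W[:, 1], -0.95, 0.95)
    W[:, 2] = np.maximum(W[:, 2], 0.01)
    rows = []
    for i in range(n_persons):
        mu, phi, isd = W[i]
        sig = isd * np.sqrt(1 - phi**2)
        z = np.empty(n_trials)
        z[0] = rng.normal(0, isd)
        eps = rng.normal(0, sig, n_trials - 1)
        for t in range(1, n_trials):
            z[t] = phi * z[t - 1] + eps[t - 1]
        y = mu + z
        if missing_rate > 0:
            y[rng.random(n_trials) < missing_rate] = np.nan
        rows.append(
            pd.DataFrame(
                {
                    "person": i + 1,
                    "task": task,
                    "block": block,
                    "trial": np.arange(1, n_trials + 1),
                    "log_rt": y,
                }
            )
        )
    persons = pd.DataFrame(
        {
            "person": np.arange(1, n_persons + 1),
            "task": task,
            "block": block,
            "mu_i": W[:, 0],
            "phi_i": W[:, 1],
            "isd_i": W[:, 2],
        }
    )
    return pd.concat(rows, ignore_index=True), persons


def attach_errors(clean_persons: pd.DataFrame, beta, sigma_e: float, seed: int = 0):
    """Add a 'ce' column from the level-2 linear model with weights
    beta = (b0, b_mu, b_phi, b_isd), on the *observed* iSD of each series."""
    rng = np.random.default_rng(seed)
    b0, bmu, bphi, bisd = beta
    eta = (
        b0
        + bmu * clean_persons["mu_i"]
        + bphi * clean_persons["phi_i"]
        + bisd * clean_persons["isd_i"]
    )
    out = clean_persons.copy()
    out["ce"] = np.clip(np.rint(eta + rng.normal(0, sigma_e, len(eta))), 0, 13)
    out["po"] = 0.0
    return out


@pytest.fixture(scope="session")
def small_dataset():
    return assemble_dataset(PopulationParameters(), n_persons=12, seed=7)


@pytest.fixture(scope="session")
def small_clean(small_dataset):
    clean, isd_table, report = preprocessing.preprocess_dataset(small_dataset.trials)
    return clean, isd_table, report
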