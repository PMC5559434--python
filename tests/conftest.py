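import numpy as np
import pytest

import fecundlmm as f


@pytest.fixture(scope="session")
def ref_params():
    return f.reference_parameters()


def random_panel(rng, n=5, T=4, p=3, equal_lengths=False):
    """Small random panel with random parameters (for oracle checks)."""
    X = rng.normal(size=(n, p))
    lengths = np.full(n, T) if equal_lengths else rng.integers(1, T + 1, size=n)
    Y = np.where(np.arange(T)[None, :] < lengths[:, None],
                 rng.integers(0, 2, size=(n, T)).astype(float), np.nan)
    pi2 = rng.uniform(0.05, 0.95)
    a, b = rng.uniform(0.05, 0.95, size=2)
    params = f.LMParameters(
        pi=np.array([1 - pi2, pi2]),
        Pi=np.array([[1 - a, a], [b, 1 - b]]),
        mu=rng.normal(scale=0.8),
        alpha2=rng.uniform(0.0, 3.0),
        beta=rng.normal(scale=0.5, size=p),
    )
    panel = f.PanelData(X=X, Y=Y, lengths=lengths)
    return panel, params


@pytest.fixture(scope="session")
def medium_fit(ref_params):
    """One medium-sized simulate-and-fit shared across tests (n=2000)."""
    cov = f.simulate_covariates(2000, seed=42)
    sim = f.simulate_lm_sequences(ref_params, cov, T_max=4, seed=43,
                                  absorbing=False)
    panel = f.PanelData.from_simulated(sim)
    fit = f.fit_em(panel, n_random_starts=4, seed=44)
    return panel, sim, fit
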