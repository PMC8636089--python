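import warnings

import numpy as np
import pytest

from lorsen import EQTLDataset, ModelFit, SolverConfig


@pytest.fixture(autouse=True)
def _silence_convergence_warnings():
    # deliberately truncated fits in tests should not spam the log
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


def random_instance(seed, n=8, p=4, q=3, missing=0.0, latent_rank=0):
    """Small random dataset with optional mask and low-rank structure."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    Y = rng.standard_normal((n, q))
    if latent_rank:
        Y = Y + rng.standard_normal((n, latent_rank)) @ rng.standard_normal(
            (latent_rank, q)
        )
    omega = np.ones((n, q))
    if missing:
        omega = (rng.random((n, q)) > missing).astype(float)
        # keep at least 2 observed entries
        if omega.sum() < 2:
            omega.ravel()[:2] = 1.0
    Yna = np.where(omega == 1, Y, np.nan)
    return EQTLDataset(X=X, Y=Yna, omega=omega)


def random_fit(rng, data):
    return ModelFit(
        B=rng.standard_normal((data.p, data.q)),
        L=rng.standard_normal((data.n, data.q)),
        mu=rng.standard_normal(data.q),
    )


@pytest.fixture
def tight_cfg():
    return SolverConfig(tol=1e-12, max_outer_iter=5000)
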