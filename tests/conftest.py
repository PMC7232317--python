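import numpy as np
import pytest

import rsmkin as rk


@pytest.fixture(scope="session")
def ref_study():
    return rk.load_reference_study()


@pytest.fixture(scope="session")
def ref_dataset(ref_study):
    return ref_study[0]


@pytest.fixture(scope="session")
def ref_consts(ref_study):
    return ref_study[1]


@pytest.fixture(scope="session")
def ref_fit(ref_dataset):
    return rk.fit_quadratic(ref_dataset, basis="means")


@pytest.fixture(scope="session")
def ref_anova(ref_fit):
    return rk.anova(ref_fit)


def loo_press(fit):
    """Brute-force leave-one-out PRESS: refit without each run, predict it."""
    press = 0.0
    n = fit.n_obs
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        beta, *_ = np.linalg.lstsq(fit.X[keep], fit.y[keep], rcond=None)
        press += (fit.y[i] - fit.X[i] @ beta) ** 2
    return press
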