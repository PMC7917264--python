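import numpy as np
import pytest

import gclm


@pytest.fixture(scope="session")
def preset():
    return gclm.income_swb_preset()


@pytest.fixture(scope="session")
def preset_spec(preset):
    return preset[0]


@pytest.fixture(scope="session")
def preset_params(preset):
    return preset[1]


@pytest.fixture(scope="session")
def panel500(preset):
    spec, params = preset
    return gclm.simulate_panel(spec, params, gclm.SimulationConfig(N=500, seed=101))


@pytest.fixture(scope="session")
def ml_fit(preset_spec, panel500):
    return gclm.fit_ml(preset_spec, panel500)


@pytest.fixture(scope="session")
def small_draws(preset_spec, panel500):
    """A short but converged diffuse-prior posterior for the preset model."""
    return gclm.sample_posterior(preset_spec, panel500, retained=1000, thin=20,
                                 burnin=3000, seed=202)


@pytest.fixture(scope="session")
def ar1_spec():
    """Univariate AR(1), T=3, no unit effect, no MA: analytic oracle model."""
    return gclm.make_spec(variables=("y",), T=3, ar=1, ma=0, cl=0, clma=0,
                          unit_effects=(False,), loading_mode="fixed_one")


def ar1_params(spec, b=0.6, var=1.0):
    params = gclm.params_template(spec)
    for t in spec.occasions_for("beta", 0, 0, 1):
        params.beta[(0, 0, 1, t)] = b
    for t in range(spec.T):
        params.psi_u[t] = np.array([[var]])
    params.psi_eta = np.zeros((1, 1))
    return params
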