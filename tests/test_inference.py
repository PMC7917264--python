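import numpy as np
import pytest

import gclm
from gclm.inference import granger_specs

from conftest import ar1_params


# -- short-run effects --------------------------------------------------------

def test_short_run_effect_ml_equals_coefficient_sum(ml_fit):
    eff = gclm.short_run_effect(ml_fit, "swb", "income")
    s = ml_fit.summary()
    manual = (s.loc["beta[swb<-income,lag1]", "estimate"]
              + s.loc["delta[swb<-income,lag1]", "estimate"])
    assert eff.estimate == pytest.approx(manual)
    assert eff.sd > 0
    assert eff.lower < eff.estimate < eff.upper


def test_short_run_effect_bayes_matches_draw_sums(small_draws):
    eff = gclm.short_run_effect(small_draws, "swb", "income")
    names, vals = small_draws.structural()
    flat = vals.reshape(-1, vals.shape[2])
    manual = (flat[:, names.index("beta[swb<-income,lag1]")]
              + flat[:, names.index("delta[swb<-income,lag1]")])
    assert eff.estimate == pytest.approx(manual.mean())
    assert eff.draws.shape == manual.shape


def test_short_run_effect_unknown_occasion(ml_fit):
    with pytest.raises(ValueError):
        gclm.short_run_effect(ml_fit, "swb", "income", occasion=99)


# -- Granger ------------------------------------------------------------------

def test_granger_specs_structure(preset_spec):
    specs = granger_specs(preset_spec, "income", "swb")
    assert set(specs) == {"full", "no_x_to_y", "no_y_to_x", "neither"}
    yi, xi = 1, 0
    assert specs["no_x_to_y"].cl_order[yi, xi] == 0
    assert specs["no_x_to_y"].clma_order[yi, xi] == 0
    assert specs["no_x_to_y"].cl_order[xi, yi] == preset_spec.cl_order[xi, yi]
    assert specs["neither"].cl_order.sum() == 0
    assert specs["neither"].clma_order.sum() == 0


def test_granger_specs_rejects_same_variable(preset_spec):
    with pytest.raises(ValueError):
        granger_specs(preset_spec, "income", "income")


def test_granger_suite_ml_detects_direction(preset_spec, panel500):
    gt = gclm.granger_suite(preset_spec, panel500, "income", "swb",
                            method="ml", compute_se=False)
    t = gt.table
    assert len(t) == 4
    # generator: income -> swb real, swb -> income null
    assert t.loc["no_x_to_y", "aic"] > t.loc["full", "aic"]
    assert t.loc["no_y_to_x", "aic"] < t.loc["no_x_to_y", "aic"]
    assert "income" in gt.verdict()


def test_granger_suite_seed_stable(preset_spec, panel500):
    a = gclm.granger_suite(preset_spec, panel500, "income", "swb",
                           method="ml", compute_se=False, seed=3)
    b = gclm.granger_suite(preset_spec, panel500, "income", "swb",
                           method="ml", compute_se=False, seed=3)
    assert np.allclose(a.table["aic"], b.table["aic"])


# -- impulse responses --------------------------------------------------------

def test_irf_ar1_closed_form(ar1_spec):
    b = 0.6
    params = ar1_params(ar1_spec, b=b)
    irf = gclm.impulse_response(ar1_spec, params, "y", t0=1, horizon=2)
    assert np.allclose(irf.responses[:, 0], [1.0, b, b * b])


def test_irf_arma_closed_form():
    spec = gclm.make_spec(variables=("y",), T=4, ar=1, ma=1, cl=0, clma=0,
                          unit_effects=(False,))
    params = gclm.params_template(spec)
    b, d = 0.5, 0.3
    for t in spec.occasions_for("beta", 0, 0, 1):
        params.beta[(0, 0, 1, t)] = b
    for t in spec.occasions_for("delta", 0, 0, 1):
        params.delta[(0, 0, 1, t)] = d
    irf = gclm.impulse_response(spec, params, "y", t0=1, horizon=2)
    assert irf.responses[1, 0] == pytest.approx(b + d)
    assert irf.responses[2, 0] == pytest.approx(b * (b + d))


def test_irf_h1_equals_short_run_effect(ml_fit, preset_spec):
    irf = gclm.impulse_response(preset_spec, ml_fit.estimates, "income",
                                t0=1, horizon=1)
    eff = gclm.short_run_effect(ml_fit, "swb", "income", occasion=2)
    assert irf.responses[1, 1] == pytest.approx(eff.estimate, abs=1e-10)


def test_irf_decays_for_stationary(preset_spec, preset_params):
    with pytest.warns(RuntimeWarning):
        irf = gclm.impulse_response(preset_spec, preset_params, "swb",
                                    t0=1, horizon=60)
    assert abs(irf.responses[60]).max() < 0.05 * abs(irf.responses[1]).max() + 1e-6


def test_irf_warns_past_horizon(preset_spec, preset_params):
    with pytest.warns(RuntimeWarning, match="last observed occasion"):
        gclm.impulse_response(preset_spec, preset_params, "income",
                              t0=4, horizon=5)


def test_irf_bands_ml(ml_fit):
    irf = gclm.impulse_response_bands(ml_fit, "income", horizon=4, n_draws=300)
    assert np.all(irf.lower <= irf.upper)
    # point path inside the bands
    assert np.all(irf.responses >= irf.lower - 1e-8)
    assert np.all(irf.responses <= irf.upper + 1e-8)


def test_irf_bands_bayes_consistent_with_short_run(small_draws):
    irf = gclm.impulse_response_bands(small_draws, "income", t0=1, horizon=2,
                                      n_draws=400)
    eff = gclm.short_run_effect(small_draws, "swb", "income", occasion=2)
    assert irf.responses[1, 1] == pytest.approx(eff.estimate, abs=0.02)
    assert irf.lower[1, 1] < eff.estimate < irf.upper[1, 1]


def test_irf_averaged_mode(preset_spec, preset_params):
    irf = gclm.impulse_response(preset_spec, preset_params, "income",
                                t0=1, horizon=3, occasion_mode="averaged")
    # preset coefficients are time-invariant: averaged == as-is
    ref = gclm.impulse_response(preset_spec, preset_params, "income",
                                t0=1, horizon=3)
    assert np.allclose(irf.responses, ref.responses)
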