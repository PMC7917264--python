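import numpy as np
import pytest

import gclm
from gclm._compile import CompiledModel
from gclm.ml import saturated_loglik


def test_kernel_matches_reference_loglik(preset_spec, preset_params, panel500):
    cm = CompiledModel(preset_spec, panel500)
    theta = cm.theta_of_params(preset_params)
    fast = cm.loglik(theta)
    ref = gclm.marginal_loglik(preset_spec, preset_params, panel500)
    assert fast == pytest.approx(ref, abs=1e-6)


def test_marginal_missing_patterns(preset_spec, preset_params, panel500):
    vals = panel500.values.copy()
    vals[0, 2, 1] = np.nan
    panel = gclm.PanelData(panel500.unit_ids, vals, panel500.variable_names)
    full = gclm.marginal_loglik(preset_spec, preset_params, panel, missing="marginal")
    cc = gclm.marginal_loglik(preset_spec, preset_params, panel, missing="complete")
    # marginal likelihood keeps all units, so it has more terms
    assert full < cc  # one more (partial) unit's negative contribution
    # with no missingness the two agree
    same = gclm.marginal_loglik(preset_spec, preset_params, panel500, missing="marginal")
    assert same == pytest.approx(cc_full := gclm.marginal_loglik(
        preset_spec, preset_params, panel500), abs=1e-8)


def test_saturated_loglik_dominates(preset_spec, preset_params, panel500, ml_fit):
    sat = saturated_loglik(panel500)
    assert sat >= ml_fit.loglik


def test_ml_recovery_within_3se(ml_fit, preset_params, preset_spec):
    s = ml_fit.summary()
    truth = {
        "beta[income<-income,lag1]": 0.97,
        "beta[swb<-swb,lag1]": 0.34,
        "beta[swb<-income,lag1]": 0.24,
        "beta[income<-swb,lag1]": 0.01,
        "delta[swb<-income,lag1]": -0.03,
        "delta[income<-income,lag1]": -0.26,
    }
    for name, v in truth.items():
        est, se = s.loc[name, "estimate"], s.loc[name, "se"]
        assert abs(est - v) < 3.5 * se, f"{name}: {est} vs {v} (se {se})"


def test_ml_result_fields(ml_fit, panel500):
    assert ml_fit.converged
    assert ml_fit.n_units == 500
    assert ml_fit.aic == pytest.approx(-2 * ml_fit.loglik + 2 * ml_fit.n_free)
    assert ml_fit.bic == pytest.approx(-2 * ml_fit.loglik
                                       + ml_fit.n_free * np.log(500))
    assert all(se > 0 for se in ml_fit.standard_errors.values())


def test_identification_error_on_time_varying_spec(panel500):
    tv = gclm.time_varying_income_swb_spec()
    with pytest.raises(gclm.IdentificationError):
        gclm.fit_ml(tv, panel500)


def test_free_loadings_anchored_automatically(preset_spec, panel500):
    spec = preset_spec.replace(loading_mode="free")
    res = gclm.fit_ml(spec, panel500, compute_se=False)
    # first loadings fixed at 1 by the anchoring convention
    names, vals = res.compiled.structural(res.theta)
    assert "lam[income,t1]" not in names   # fixed, not free


def test_compare_ml_ranks(preset_spec, panel500, ml_fit):
    from gclm.inference import granger_specs
    specs = granger_specs(preset_spec, "income", "swb")
    no_xy = gclm.fit_ml(specs["no_x_to_y"], panel500, compute_se=False)
    df = gclm.compare_ml([ml_fit, no_xy])
    # generator has a real income->swb effect: the full model must win
    assert df.loc[0, "rank_aic"] == 1
    assert df.loc[1, "aic"] > df.loc[0, "aic"]


def test_compare_ml_rejects_different_n(preset_spec, preset_params, ml_fit):
    other = gclm.simulate_panel(preset_spec, preset_params,
                                gclm.SimulationConfig(N=120, seed=5))
    fit2 = gclm.fit_ml(preset_spec, other, compute_se=False)
    with pytest.raises(ValueError, match="different N"):
        gclm.compare_ml([ml_fit, fit2])


def test_fixed_parameter_respected(preset_spec, panel500):
    res = gclm.fit_ml(preset_spec, panel500, compute_se=False,
                      fixed={"beta[income<-swb,lag1]": 0.0})
    assert res.estimates.beta[(0, 1, 1, 2)] == 0.0
    assert res.n_free == 41
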