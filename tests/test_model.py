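import numpy as np
import pytest

import gclm
from gclm.model import count_moments, enumerate_slots


# -- counting identities ------------------------------------------------------

def test_time_varying_coefficient_count_worked_example():
    assert gclm.count_time_varying_coeffs(4, 10) == 288


def test_time_varying_coefficient_count_formula():
    for k, T in [(1, 2), (2, 6), (3, 4), (5, 7)]:
        assert gclm.count_time_varying_coeffs(k, T) == (T - 1) * (2 * k + 2 * k * (k - 1))


def test_auto_covariance_count():
    auto, cross = count_moments(1, 6)
    assert auto == 15
    assert cross == 0


def test_cross_covariance_count():
    auto, cross = count_moments(2, 6)
    assert auto == 2 * 6 * 5 // 2
    assert cross == 2 * 1 * 36 // 2


def test_fifty_four_parameter_enumeration():
    spec = gclm.make_spec(variables=("income", "swb"), T=6, ar=(1, 1), ma=(2, 1),
                          cl=1, clma=1,
                          time_varying=gclm.TimeVarying(loadings=True),
                          loading_mode="free")
    c = gclm.count_free_parameters(spec)
    assert c.total == 54
    assert c.items == {"alpha": 12, "loadings": 12, "psi_eta": 3,
                       "psi_u_var": 12, "psi_u_cov": 6, "beta": 4, "delta": 5}


def test_time_varying_spec_underidentification_flagged():
    c = gclm.count_free_parameters(gclm.time_varying_income_swb_spec())
    assert c.warnings  # own-equation parameters exceed auto-covariances


# -- spec construction and validation ----------------------------------------

def test_make_spec_broadcasts_scalars():
    spec = gclm.make_spec(variables=("a", "b", "c"), T=4, ar=2, ma=1, cl=1, clma=0)
    assert spec.ar_order == (2, 2, 2)
    assert spec.ma_order == (1, 1, 1)
    assert spec.cl_order.shape == (3, 3)
    assert np.all(np.diag(spec.cl_order) == 0)
    assert not gclm.validate_spec(spec)


def test_validate_spec_catches_bad_orders():
    spec = gclm.make_spec(variables=("a", "b"), T=3, ar=1)
    bad = spec.replace(ar_order=(5, 1))   # lag order >= T
    assert gclm.validate_spec(bad)


def test_spec_yaml_roundtrip(tmp_path, preset_spec):
    path = tmp_path / "spec.yaml"
    preset_spec.to_yaml(path)
    assert gclm.ModelSpec.from_yaml(path) == preset_spec


def test_spec_equality_differs():
    a = gclm.make_spec(variables=("x", "y"), T=4)
    b = gclm.make_spec(variables=("x", "y"), T=5)
    assert a != b


def test_occasions_for_lag_convention():
    spec = gclm.make_spec(variables=("x",), T=5, ar=2, ma=0, cl=0, clma=0)
    assert spec.occasions_for("beta", 0, 0, 1) == (2, 3, 4, 5)
    assert spec.occasions_for("beta", 0, 0, 2) == (3, 4, 5)


def test_occasion_overrides():
    spec = gclm.make_spec(variables=("x",), T=5, ar=1, ma=0, cl=0, clma=0,
                          occasion_overrides={("beta", 0, 0, 1): (3, 4)})
    assert spec.occasions_for("beta", 0, 0, 1) == (3, 4)


# -- slots and free parameters ------------------------------------------------

def test_slot_theta_consistency(preset_spec):
    slots, thetas = enumerate_slots(preset_spec)
    used = {s.theta for s in slots if s.theta >= 0}
    assert used == set(range(len(thetas)))
    assert len({p.name for p in thetas}) == len(thetas)


def test_tied_coefficients_share_theta():
    spec = gclm.make_spec(variables=("x",), T=4, ar=1, ma=0, cl=0, clma=0,
                          unit_effects=(False,))
    slots, thetas = enumerate_slots(spec)
    ar_slots = [s for s in slots if s.family == "beta"]
    assert len(ar_slots) == 3                      # occasions 2..4
    assert len({s.theta for s in ar_slots}) == 1   # one shared free parameter


def test_fixed_values_remove_thetas(preset_spec):
    base = gclm.count_free_parameters(preset_spec).total
    fixed = gclm.count_free_parameters(
        preset_spec, fixed={"beta[swb<-income,lag1]": 0.0}).total
    assert fixed == base - 1


def test_params_template_validates(preset_spec):
    params = gclm.params_template(preset_spec)
    assert params.validate(preset_spec) == []


def test_params_template_shape_mismatch_reported(preset_spec):
    params = gclm.params_template(preset_spec)
    params.alpha = params.alpha[:-1]
    assert params.validate(preset_spec)
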