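import numpy as np
import pytest

import gclm
from gclm.priors import (DifferencePrior, NormalPrior, build_priors,
                         equivalent_mvn_form, prior_mass_within)


def test_difference_prior_mass_68_within_0p1():
    assert prior_mass_within(DifferencePrior(0.01), 0.1) == pytest.approx(0.6827, abs=5e-4)


def test_normal_prior_masses():
    assert prior_mass_within(NormalPrior(0.0, 0.01), 0.1) == pytest.approx(0.6827, abs=5e-4)
    assert prior_mass_within(NormalPrior(0.0, 0.01), 0.196) == pytest.approx(0.95, abs=1e-3)


def test_equivalent_mvn_form_worked_example():
    cov = equivalent_mvn_form(3, d=1000.0, v=0.1)
    assert cov[0, 0] == 1000.0
    assert cov[0, 1] == pytest.approx(999.95)
    # implied variance of any pairwise difference is v
    for i, j in [(0, 1), (1, 2), (0, 2)]:
        assert cov[i, i] + cov[j, j] - 2 * cov[i, j] == pytest.approx(0.1)
    np.linalg.cholesky(cov)  # positive definite


def test_equivalent_mvn_form_rejects_invalid():
    with pytest.raises(ValueError):
        equivalent_mvn_form(3, d=0.01, v=1.0)


def test_build_priors_difference_groups():
    spec = gclm.time_varying_income_swb_spec()
    cfg = gclm.bayes1_config(spec)
    ps = build_priors(spec, cfg)
    assert len(ps.groups) == 10   # 9 coefficient families + swb loadings
    names = {n for grp, _ in ps.groups for n in grp}
    assert any("beta[swb<-income,lag1" in n for n in names)
    assert any(n.startswith("lam[swb") for n in names)
    # income loadings nulled, not grouped
    assert all(not n.startswith("lam[income") for n in names)
    assert any(n.startswith("lam[income") for n in ps.normal)


def test_bayes2_nulls_income_ma2():
    spec = gclm.time_varying_income_swb_spec()
    ps = build_priors(spec, gclm.bayes2_config(spec))
    ma2 = [n for n in ps.normal if "delta[income<-income,lag2" in n]
    assert len(ma2) == len(spec.occasions_for("delta", 0, 0, 2))
    grouped = {n for grp, _ in ps.groups for n in grp}
    assert not any("delta[income<-income,lag2" in n for n in grouped)


def test_build_priors_unknown_selector_raises():
    spec = gclm.time_varying_income_swb_spec()
    with pytest.raises(KeyError):
        build_priors(spec, {"normal": [{"family": "beta", "target": "income",
                                        "source": "income", "lag": 7}]})


def test_difference_prior_requires_time_varying(preset_spec):
    with pytest.raises(ValueError, match="time-varying"):
        build_priors(preset_spec, {"difference": [
            {"family": "beta", "target": "income", "source": "income", "lag": 1}]})


def test_double_prior_assignment_rejected(panel500):
    from gclm._compile import CompiledModel
    spec = gclm.time_varying_income_swb_spec()
    cfg = {"difference": [
        {"family": "beta", "target": "swb", "source": "income", "lag": 1},
        {"family": "beta", "target": "swb", "source": "income", "lag": 1}]}
    ps = build_priors(spec, cfg)
    with pytest.raises(ValueError, match="more than one prior"):
        ps.compile(CompiledModel(spec, panel500))


def test_describe_covers_every_parameter(preset_spec):
    from gclm.model import enumerate_slots
    _, thetas = enumerate_slots(preset_spec)
    ps = build_priors(preset_spec, None)
    desc = ps.describe([p.name for p in thetas])
    assert set(desc) == {p.name for p in thetas}


def test_conjugate_normal_mean_posterior():
    """One free mean with everything else fixed: MCMC must match the
    analytic normal-normal posterior."""
    spec = gclm.make_spec(variables=("y",), T=2, ar=0, ma=0, cl=0, clma=0,
                          unit_effects=(False,))
    params = gclm.params_template(spec)
    params.alpha[0, 0] = 0.8
    data = gclm.simulate_panel(spec, params, gclm.SimulationConfig(N=200, seed=42))

    m0, v0 = 0.0, 0.25
    fixed = {"alpha[y,t2]": 0.0,
             "psi_u[t1]:logsd[y]": 0.0, "psi_u[t2]:logsd[y]": 0.0}
    cfg = {"normal": [{"family": "alpha", "target": "y", "occasions": [1],
                       "mean": m0, "variance": v0}]}
    draws = gclm.sample_posterior(spec, data, priors=cfg, fixed=fixed,
                                  retained=4000, thin=2, burnin=2000, seed=5)
    assert draws.compiled.n_theta == 1

    y1 = data.values[:, 0, 0]
    n = y1.size
    post_prec = 1 / v0 + n
    post_mean = (m0 / v0 + n * y1.mean()) / post_prec
    post_sd = np.sqrt(1 / post_prec)
    samp = draws.pooled().ravel()
    assert samp.mean() == pytest.approx(post_mean, abs=4 * post_sd / np.sqrt(200))
    assert samp.std() == pytest.approx(post_sd, rel=0.1)
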