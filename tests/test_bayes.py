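import numpy as np
import pytest

import gclm
from gclm.bayes import PosteriorDraws, hpd_interval


def _fake_draws(chains_arrays, names=None):
    arr = np.asarray(chains_arrays)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    names = names or [f"p{i}" for i in range(arr.shape[2])]
    return PosteriorDraws(arr, names, thin=1, seed=0, accept_rates=[])


# -- PSR ----------------------------------------------------------------------

def test_psr_near_one_for_iid_chains():
    rng = np.random.default_rng(0)
    d = _fake_draws(rng.standard_normal((2, 5000)))
    r = gclm.psr(d, scale="theta")
    assert float(r.iloc[0]) < 1.01


def test_psr_large_for_shifted_chains():
    rng = np.random.default_rng(1)
    a = rng.standard_normal(2000)
    b = rng.standard_normal(2000) + 3.0
    r = gclm.psr(_fake_draws(np.stack([a, b])), scale="theta")
    assert float(r.iloc[0]) > 1.05


def test_psr_requires_two_chains():
    with pytest.raises(ValueError):
        gclm.psr(_fake_draws(np.random.default_rng(0).standard_normal((1, 100))),
                 scale="theta")


# -- KS -----------------------------------------------------------------------

def test_ks_passes_for_same_distribution():
    rng = np.random.default_rng(12)
    d = _fake_draws(rng.standard_normal((2, 3000, 3)))
    _, ok = gclm.ks_between_chains(d, scale="theta")
    assert ok


def test_ks_fails_for_different_distributions():
    rng = np.random.default_rng(3)
    a = rng.standard_normal((3000, 1))
    b = rng.standard_normal((3000, 1)) + 1.5
    _, ok = gclm.ks_between_chains(_fake_draws(np.stack([a, b])), scale="theta")
    assert not ok


# -- HPD ----------------------------------------------------------------------

def test_hpd_matches_normal_quantiles():
    rng = np.random.default_rng(4)
    x = rng.standard_normal(200000)
    lo, hi = hpd_interval(x, 0.95)
    assert lo == pytest.approx(-1.96, abs=0.03)
    assert hi == pytest.approx(1.96, abs=0.03)


def test_hpd_is_shortest_for_skewed():
    rng = np.random.default_rng(5)
    x = rng.exponential(size=100000)
    lo, hi = hpd_interval(x, 0.9)
    assert lo == pytest.approx(0.0, abs=0.01)   # mass concentrated at 0
    assert hi < np.quantile(x, 0.95)            # shorter than equal-tail


# -- sampler end-to-end -------------------------------------------------------

def test_sampler_reproducible(preset_spec, panel500):
    kw = dict(retained=50, thin=2, burnin=300, seed=31)
    a = gclm.sample_posterior(preset_spec, panel500, **kw)
    b = gclm.sample_posterior(preset_spec, panel500, **kw)
    assert np.array_equal(a.draws, b.draws)
    c = gclm.sample_posterior(preset_spec, panel500, retained=50, thin=2,
                              burnin=300, seed=32)
    assert not np.array_equal(a.draws, c.draws)


def test_sampler_requires_two_chains(preset_spec, panel500):
    with pytest.raises(ValueError):
        gclm.sample_posterior(preset_spec, panel500, chains=1, retained=10,
                              thin=1, burnin=10)


def test_small_draws_converged(small_draws):
    rep = gclm.convergence_report(small_draws)
    assert rep.max_psr < 1.1
    assert rep.psr.index.size == len(small_draws.structural()[0])


def test_posterior_matches_ml(small_draws, ml_fit):
    """Diffuse-prior posterior means agree with ML point estimates."""
    summ = gclm.summarize(small_draws)
    mls = ml_fit.summary()
    for name in ["beta[income<-income,lag1]", "beta[swb<-income,lag1]",
                 "beta[swb<-swb,lag1]", "delta[swb<-swb,lag1]"]:
        sd = summ.loc[name, "sd"]
        assert abs(summ.loc[name, "mean"] - mls.loc[name, "estimate"]) < 4 * sd


def test_dic_pd_close_to_free_parameter_count(small_draws):
    """Under diffuse priors pD approximates the free-parameter count."""
    fi = gclm.dic(small_draws)
    d = small_draws.compiled.n_theta
    assert 0.6 * d < fi.pd < 1.4 * d
    assert fi.dic == pytest.approx(fi.mean_deviance + fi.pd)


def test_summarize_columns_and_p(small_draws):
    s = gclm.summarize(small_draws)
    assert set(s.columns) == {"mean", "median", "sd", "hpd_lo", "hpd_hi",
                              "p", "p_tail"}
    assert ((s["hpd_lo"] <= s["median"]) & (s["median"] <= s["hpd_hi"])).all()
    # strongly identified positive AR coefficient: p essentially 0
    assert s.loc["beta[income<-income,lag1]", "p"] < 1e-6


def test_ppp_reasonable_for_well_specified(small_draws, panel500):
    p = gclm.ppp(small_draws, panel500, n_draws=150, seed=7)
    assert 0.05 < p < 0.95
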