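"""MCMC posterior sampling for the GCLM with convergence diagnostics and
Bayesian fit indices.

The sampler targets ``f(theta | Y) \\propto f(theta) f(Y | theta)`` with the
same marginal implied-moment MVN likelihood the ML estimator maximizes
(latents integrated out).  The kernel is a Laplace-preconditioned adaptive
random-walk Metropolis: a posterior-mode search supplies the proposal
covariance (inverse observed information), and the global step scale is
adapted to a 0.234 acceptance rate during burn-in, then frozen.  Thinning is
applied before retention.

Diagnostics follow common MCMC practice: the potential scale reduction (PSR,
Gelman-Rubin) with the conventional 1.05 cut-off, two-sample
Kolmogorov-Smirnov tests for between-chain parameter differences with
Bonferroni control at a family-wise 0.05, the posterior predictive p-value
(PPP; 0.5 ideal, > 0.05 acceptable) using a chi-square-style discrepancy
against the saturated moments, and the deviance information criterion
DIC = mean deviance + pD with pD = mean deviance - deviance at the posterior
mean (not an integer in general: informative priors reduce it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import ks_2samp, norm

from ._compile import CompiledModel, numerical_hessian
from .data import PanelData
from .model import ModelSpec
from .priors import PriorSpec, build_priors
from .simulate import SimulationConfig, simulate_panel
from .ml import saturated_loglik

__all__ = ["PosteriorDraws", "ConvergenceReport", "BayesFitIndices",
           "sample_posterior", "psr", "ks_between_chains", "convergence_report",
           "ppp", "dic", "summarize", "hpd_interval"]


@dataclass
class PosteriorDraws:
    """Retained MCMC draws: chains x iterations x free parameters."""

    draws: np.ndarray                # (chains, n_keep, d) on the sampling scale
    theta_names: list
    thin: int
    seed: int
    accept_rates: list
    compiled: CompiledModel = field(repr=False, default=None)
    _structural_cache: tuple = field(repr=False, default=None)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_retained(self) -> int:
        return self.draws.shape[1]

    def pooled(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[2])

    def structural(self):
        """(names, values) with values (chains, n_keep, m) on the natural scale."""
        if self._structural_cache is None:
            C, n, d = self.draws.shape
            names, first = self.compiled.structural(self.draws[0, 0])
            out = np.empty((C, n, len(names)))
            for c in range(C):
                for i in range(n):
                    _, out[c, i] = self.compiled.structural(self.draws[c, i])
            self._structural_cache = (names, out)
        return self._structural_cache

    def posterior_mean_params(self):
        return self.compiled.params_of_theta(self.pooled().mean(axis=0))


@dataclass
class ConvergenceReport:
    psr: pd.Series
    max_psr: float
    ks_p: pd.Series
    psr_pass: bool
    ks_pass: bool
    psr_cutoff: float = 1.05
    ks_alpha: float = 0.05

    @property
    def passed(self) -> bool:
        return self.psr_pass and self.ks_pass


@dataclass
class BayesFitIndices:
    dic: float
    pd: float
    mean_deviance: float
    ppp: float = np.nan


def _laplace_proposal(cm: CompiledModel, theta_map: np.ndarray):
    """Proposal Cholesky from the observed information at the posterior mode."""
    H = numerical_hessian(lambda th: -cm.logpost(th), theta_map)
    H = 0.5 * (H + H.T)
    w, V = np.linalg.eigh(H)
    wmax = max(w.max(), 1.0)
    w = np.clip(w, 1e-8 * wmax, None)   # flat directions get wide proposals
    cov = (V / w) @ V.T
    L = np.linalg.cholesky(0.5 * (cov + cov.T))
    return L * (2.38 / np.sqrt(cm.n_theta))


def sample_posterior(spec: ModelSpec, data: PanelData, priors=None,
                     chains: int = 2, retained: int = 10000, thin: int = 50,
                     burnin: int = 5000, seed: int = 0, fixed=None) -> PosteriorDraws:
    """Draw from the GCLM posterior by preconditioned random-walk Metropolis.

    ``priors`` may be a :class:`~gclm.priors.PriorSpec`, a prior config dict
    (see :func:`~gclm.priors.build_priors`), or None for all-diffuse priors.
    Two chains minimum (diagnostics need them); thinning by ``thin`` is
    applied before retaining ``retained`` draws per chain.  Seeded runs are
    exactly reproducible.
    """
    if chains < 2:
        raise ValueError("need at least 2 chains for convergence diagnostics")
    cm = CompiledModel(spec, data, fixed=fixed)
    if not isinstance(priors, PriorSpec):
        priors = build_priors(spec, priors)
    cm.set_priors(priors.compile(cm))

    res = optimize.minimize(lambda th: -cm.logpost(th), cm.initial_theta(),
                            method="L-BFGS-B",
                            options={"maxiter": 5000, "maxfun": 200000})
    theta_map = res.x
    Lprop = _laplace_proposal(cm, theta_map)

    ss = np.random.SeedSequence(seed)
    chain_seeds = [int(s) % (2 ** 31 - 1) for s in ss.generate_state(chains)]
    rng = np.random.default_rng(ss.spawn(1)[0])

    all_draws = np.empty((chains, retained, cm.n_theta))
    accept = []
    for c in range(chains):
        jitter = Lprop @ rng.standard_normal(cm.n_theta) * 2.0
        theta0 = theta_map + jitter
        if not np.isfinite(cm.logpost(theta0)):
            theta0 = theta_map
        draws, acc, _ = cm.sample_chain(theta0, Lprop, burnin, thin, retained,
                                        chain_seeds[c])
        all_draws[c] = draws
        accept.append(acc)
        if acc < 0.02:
            warnings.warn(f"chain {c}: acceptance rate {acc:.3f} is very low; "
                          "treat results as unconverged", RuntimeWarning)
    return PosteriorDraws(all_draws, list(cm.theta_names), thin, seed, accept,
                          compiled=cm)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def _chains_matrix(draws, scale):
    if scale == "structural":
        names, vals = draws.structural()
    else:
        names, vals = draws.theta_names, draws.draws
    return list(names), np.asarray(vals)


def psr(draws: PosteriorDraws, scale: str = "structural") -> pd.Series:
    """Gelman-Rubin potential scale reduction per parameter.

    Between/within-chain variance ratio; values near 1 indicate convergence
    (1.05 is the conventional cut-off)."""
    names, vals = _chains_matrix(draws, scale)
    C, n, m = vals.shape
    if C < 2:
        raise ValueError("PSR requires at least 2 chains")
    means = vals.mean(axis=1)                     # (C, m)
    W = vals.var(axis=1, ddof=1).mean(axis=0)     # (m,)
    B_over_n = means.var(axis=0, ddof=1)          # (m,)
    W = np.maximum(W, 1e-300)
    var_hat = (n - 1) / n * W + B_over_n
    return pd.Series(np.sqrt(var_hat / W), index=names)


def _independence_spacing(x: np.ndarray, threshold: float = 0.1,
                          max_lag: int = 200) -> int:
    """Smallest lag at which the autocorrelation drops below ``threshold``."""
    x = x - x.mean()
    denom = float(x @ x)
    if denom <= 0:
        return 1
    for lag in range(1, min(max_lag, x.size // 3) + 1):
        if float(x[:-lag] @ x[lag:]) / denom < threshold:
            return lag
    return max_lag


def ks_between_chains(draws: PosteriorDraws, scale: str = "structural",
                      alpha: float = 0.05):
    """Two-sample KS p-values for between-chain parameter differences.

    The KS test assumes independent samples, so each chain is first
    subsampled at the lag where its autocorrelation falls below 0.1.
    Pairwise across chains; family-wise Type-I control at ``alpha`` by
    Bonferroni across all parameter/pair combinations.  Returns
    ``(p_values: Series indexed by parameter, pass: bool)``."""
    names, vals = _chains_matrix(draws, scale)
    C, n, m = vals.shape
    if C < 2:
        raise ValueError("KS diagnostic requires at least 2 chains")
    pvals = np.ones(m)
    n_tests = 0
    for j in range(m):
        step = max(_independence_spacing(vals[c, :, j]) for c in range(C))
        sub = vals[:, ::step, j]
        if sub.shape[1] < 5:
            sub = vals[:, :, j]   # too short to subsample; use as-is
        for a in range(C):
            for b in range(a + 1, C):
                p = ks_2samp(sub[a], sub[b]).pvalue
                pvals[j] = min(pvals[j], p)
                n_tests += 1
    series = pd.Series(pvals, index=names)
    passed = bool((pvals >= alpha / max(n_tests, 1)).all())
    return series, passed


def convergence_report(draws: PosteriorDraws, psr_cutoff: float = 1.05,
                       ks_alpha: float = 0.05) -> ConvergenceReport:
    r = psr(draws)
    ks_p, ks_ok = ks_between_chains(draws, alpha=ks_alpha)
    return ConvergenceReport(psr=r, max_psr=float(r.max()), ks_p=ks_p,
                             psr_pass=bool(r.max() <= psr_cutoff), ks_pass=ks_ok,
                             psr_cutoff=psr_cutoff, ks_alpha=ks_alpha)


# ---------------------------------------------------------------------------
# Fit indices
# ---------------------------------------------------------------------------

def dic(draws: PosteriorDraws) -> BayesFitIndices:
    """DIC and the effective number of parameters pD.

    Deviance is D(theta) = -2 * marginal log-likelihood; pD = mean(D) -
    D(posterior mean); DIC = mean(D) + pD.  Falls back to the posterior
    median with a warning if the mean lands in an invalid region."""
    cm = draws.compiled
    pooled = draws.pooled()
    devs = -2.0 * cm.loglik_many(pooled)
    mean_dev = float(devs.mean())
    center = pooled.mean(axis=0)
    d_at = -2.0 * cm.loglik(center)
    if not np.isfinite(d_at) or d_at > 1e299:
        warnings.warn("posterior mean lies outside the valid parameter region; "
                      "using the posterior median for pD", RuntimeWarning)
        d_at = -2.0 * cm.loglik(np.median(pooled, axis=0))
    p_d = mean_dev - float(d_at)
    return BayesFitIndices(dic=mean_dev + p_d, pd=p_d, mean_deviance=mean_dev)


def ppp(draws: PosteriorDraws, data: PanelData, n_draws: int = 200,
        seed: int = 0) -> float:
    """Posterior predictive p-value with a chi-square-style discrepancy.

    For each sampled parameter draw, a replicate panel of the observed
    (complete-case) size is simulated; the discrepancy is
    -2 [loglik(theta; Y) - saturated loglik(Y)] evaluated for the observed
    and replicate data.  Returns the proportion of draws where the replicate
    discrepancy is at least the observed one (0.5 optimal)."""
    cm = draws.compiled
    pooled = draws.pooled()
    take = np.linspace(0, pooled.shape[0] - 1, min(n_draws, pooled.shape[0])).astype(int)
    obs = data.complete_cases()
    sat_obs = saturated_loglik(obs)
    n_exceed = 0
    n_used = 0
    n_failed = 0
    for i, ix in enumerate(take):
        theta = pooled[ix]
        ll_obs = cm.loglik(theta)
        try:
            params = cm.params_of_theta(theta)
            rep = simulate_panel(cm.spec, params,
                                 SimulationConfig(N=obs.n_units, seed=seed * 100003 + i))
            cm_rep = _suffstats(rep)
            ll_rep = cm.loglik_with_stats(theta, *cm_rep)
            sat_rep = saturated_loglik(rep)
        except (ValueError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        d_obs = -2.0 * (ll_obs - sat_obs)
        d_rep = -2.0 * (ll_rep - sat_rep)
        if d_rep >= d_obs:
            n_exceed += 1
        n_used += 1
    if n_failed:
        warnings.warn(f"PPP: {n_failed} replicate simulations failed and were skipped",
                      RuntimeWarning)
    if n_used == 0:
        raise RuntimeError("PPP: no usable replicates")
    return n_exceed / n_used


def _suffstats(panel: PanelData):
    Y = panel.complete_cases().wide()
    ybar = Y.mean(axis=0)
    dev = Y - ybar
    return np.ascontiguousarray(dev.T @ dev / Y.shape[0]), ybar, Y.shape[0]


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def hpd_interval(samples: np.ndarray, credibility: float = 0.95):
    """Shortest interval containing the stated posterior mass (single interval)."""
    x = np.sort(np.asarray(samples).ravel())
    n = x.size
    m = max(1, int(np.ceil(credibility * n)))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[:n - m]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m])


def summarize(draws: PosteriorDraws, credibility: float = 0.95,
              scale: str = "structural") -> pd.DataFrame:
    """Posterior mean/median/SD, HPD interval and Bayesian p per parameter.

    The two-tailed Bayesian p uses the normal approximation
    ``2 * Phi(-|mean| / SD)``; the empirical alternative
    ``2 * min(Pr(>0), Pr(<0))`` is reported as ``p_tail``."""
    names, vals = _chains_matrix(draws, scale)
    flat = vals.reshape(-1, vals.shape[2])
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0, ddof=1)
    med = np.median(flat, axis=0)
    lo = np.empty_like(mean)
    hi = np.empty_like(mean)
    for j in range(flat.shape[1]):
        lo[j], hi[j] = hpd_interval(flat[:, j], credibility)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, np.abs(mean) / sd, np.inf)
    p = 2 * norm.sf(z)
    p = np.where(sd > 0, p, np.where(mean == 0, 1.0, 0.0))
    pos = (flat > 0).mean(axis=0)
    p_tail = 2 * np.minimum(pos, 1 - pos)
    return pd.DataFrame({"mean": mean, "median": med, "sd": sd,
                         "hpd_lo": lo, "hpd_hi": hi, "p": p, "p_tail": p_tail},
                        index=names)
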