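"""Substantive inference on a fitted GCLM: combined short-run effects,
Granger-style model comparison, and impulse-response functions.

The combined short-run effect of a source on a target at occasion ``t`` is
the sum of the cross-lagged regression and cross-lagged moving-average
coefficients at that occasion (a unit impulse in the source moves the target
next occasion both through the realized source level and through the impulse
itself).  Granger-style comparison fits the full model and the three
restricted models (each direction of cross-effects removed, then both) and
ranks them by information criteria.  Impulse responses iterate the
structural recursion on the fitted coefficients, with uncertainty bands from
posterior draws (Bayes) or from parametric draws of the estimator's
asymptotic normal distribution (ML).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .bayes import PosteriorDraws, dic, hpd_interval, sample_posterior
from .data import PanelData
from .ml import MLResult, fit_ml
from .model import ModelSpec, ParameterSet
from .simulate import _coef_matrix, _max_lags

__all__ = ["ShortRunEffect", "short_run_effect", "granger_specs",
           "granger_suite", "GrangerTable", "IRFResult", "impulse_response",
           "impulse_response_bands"]


# ---------------------------------------------------------------------------
# Combined short-run effects
# ---------------------------------------------------------------------------

@dataclass
class ShortRunEffect:
    """A combined (beta + delta) cross-lagged effect with its uncertainty."""

    estimate: float
    sd: float
    lower: float
    upper: float
    occasion: object          # int or "averaged"
    target: str
    source: str
    lag: int
    method: str               # "ml" or "bayes"
    draws: np.ndarray = field(repr=False, default=None)


def _effect_weights(cm, tgt, src, lag, occasion):
    """Weight vector over theta for the combined short-run effect."""
    w = np.zeros(cm.n_theta)
    for fam in ("beta", "delta"):
        hits = [(i, p) for i, p in enumerate(cm.thetas)
                if p.family == fam and p.target == tgt and p.source == src
                and p.lag == lag]
        if not hits:
            continue
        tied = [i for i, p in hits if p.t == -1]
        if tied:
            for i in tied:
                w[i] += 1.0
        elif occasion == "averaged":
            for i, _ in hits:
                w[i] += 1.0 / len(hits)
        else:
            occ_hits = [i for i, p in hits if p.t == occasion]
            if not occ_hits:
                raise ValueError(
                    f"{fam}[{tgt}<-{src}] has no free coefficient at occasion "
                    f"{occasion}; available: {sorted(p.t for _, p in hits)}")
            for i in occ_hits:
                w[i] += 1.0
    if not w.any():
        raise ValueError("no cross-lagged coefficients match the requested effect")
    return w


def short_run_effect(result, target, source, occasion="averaged", lag: int = 1,
                     credibility: float = 0.95) -> ShortRunEffect:
    """Combined short-run effect of ``source`` on ``target`` (beta + delta).

    ``result`` is an :class:`~gclm.ml.MLResult` (delta-method SE, normal
    interval) or a :class:`~gclm.bayes.PosteriorDraws` (per-draw sums, HPD
    interval).  For time-varying models ``occasion`` picks the occasion or
    averages the per-occasion effects.
    """
    cm = result.compiled
    spec = cm.spec
    if occasion != "averaged" and not 1 <= int(occasion) <= spec.T:
        raise ValueError(f"occasion must be in 1..{spec.T} or 'averaged'")
    tgt, src = spec.var_index(target), spec.var_index(source)
    w = _effect_weights(cm, tgt, src, lag, occasion)
    names = (spec.variable_names[tgt], spec.variable_names[src])

    if isinstance(result, MLResult):
        est = float(w @ result.theta)
        var = float(w @ result.theta_cov @ w)
        sd = float(np.sqrt(max(var, 0.0)))
        z = norm.ppf(0.5 + credibility / 2)
        return ShortRunEffect(est, sd, est - z * sd, est + z * sd, occasion,
                              names[0], names[1], lag, "ml")
    if isinstance(result, PosteriorDraws):
        vals = result.pooled() @ w
        lo, hi = hpd_interval(vals, credibility)
        return ShortRunEffect(float(vals.mean()), float(vals.std(ddof=1)),
                              lo, hi, occasion, names[0], names[1], lag,
                              "bayes", draws=vals)
    raise TypeError(f"unsupported result type: {type(result).__name__}")


# ---------------------------------------------------------------------------
# Granger-style model comparison
# ---------------------------------------------------------------------------

def _drop_direction(spec: ModelSpec, tgt: int, src: int) -> ModelSpec:
    cl = spec.cl_order.copy()
    clma = spec.clma_order.copy()
    cl[tgt, src] = 0
    clma[tgt, src] = 0
    return spec.replace(cl_order=cl, clma_order=clma)


def granger_specs(spec: ModelSpec, x, y) -> dict:
    """The four specs of a bidirectional Granger comparison between x and y.

    Keys: ``full``, ``no_x_to_y`` (x's cross-effects on y removed),
    ``no_y_to_x``, ``neither``.
    """
    xi, yi = spec.var_index(x), spec.var_index(y)
    if xi == yi:
        raise ValueError("x and y must be different variables")
    no_xy = _drop_direction(spec, yi, xi)
    return {
        "full": spec,
        "no_x_to_y": no_xy,
        "no_y_to_x": _drop_direction(spec, xi, yi),
        "neither": _drop_direction(no_xy, xi, yi),
    }


@dataclass
class GrangerTable:
    """Model-comparison table for the four-model Granger suite."""

    table: pd.DataFrame
    fits: dict
    method: str
    x: str
    y: str

    @property
    def best(self) -> str:
        col = "dic" if self.method == "bayes" else "aic"
        return str(self.table[col].idxmin())

    def verdict(self) -> str:
        b = self.best
        msgs = {
            "full": f"evidence for causation in both directions "
                    f"({self.x}<->{self.y})",
            "no_x_to_y": f"no evidence that {self.x} Granger-causes {self.y}; "
                         f"evidence that {self.y} Granger-causes {self.x}",
            "no_y_to_x": f"no evidence that {self.y} Granger-causes {self.x}; "
                         f"evidence that {self.x} Granger-causes {self.y}",
            "neither": f"no evidence of Granger causation between "
                       f"{self.x} and {self.y}",
        }
        return msgs[b]


def granger_suite(spec: ModelSpec, data: PanelData, x, y, method: str = "ml",
                  priors=None, seed: int = 0, **fit_kwargs) -> GrangerTable:
    """Fit the four Granger-comparison models on the same data and settings.

    ``method="ml"`` compares AIC/BIC; ``method="bayes"`` compares DIC (and
    pD).  ``priors`` may be a callable ``spec -> prior config`` so that each
    restricted model receives the analogous prior system, or a single config
    applied to the full model only (restricted models then use diffuse
    priors for the removed paths, which no longer exist).
    """
    specs = granger_specs(spec, x, y)
    fits, rows = {}, []
    for name, sp in specs.items():
        if method == "ml":
            fit = fit_ml(sp, data, seed=seed, **fit_kwargs)
            fits[name] = fit
            rows.append({"model": name, "loglik": fit.loglik, "n_free": fit.n_free,
                         "aic": fit.aic, "bic": fit.bic})
        elif method == "bayes":
            pr = priors(sp) if callable(priors) else (priors if name == "full" else None)
            draws = sample_posterior(sp, data, priors=pr, seed=seed, **fit_kwargs)
            fits[name] = draws
            fi = dic(draws)
            rows.append({"model": name, "mean_deviance": fi.mean_deviance,
                         "pd": fi.pd, "dic": fi.dic})
        else:
            raise ValueError("method must be 'ml' or 'bayes'")
    df = pd.DataFrame(rows).set_index("model")
    crit = "dic" if method == "bayes" else "aic"
    df[f"delta_{crit}"] = df[crit] - df.loc["full", crit]
    df["rank"] = df[crit].rank(method="first").astype(int)
    return GrangerTable(df, fits, method, str(x), str(y))


# ---------------------------------------------------------------------------
# Impulse-response functions
# ---------------------------------------------------------------------------

@dataclass
class IRFResult:
    """Responses of all variables to a single impulse over a horizon."""

    responses: np.ndarray            # (horizon + 1, k)
    horizons: np.ndarray             # 0..horizon
    impulse: str
    t0: int
    size: float
    variable_names: tuple
    lower: np.ndarray = None         # band arrays, same shape as responses
    upper: np.ndarray = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.responses, index=self.horizons,
                          columns=list(self.variable_names))
        df.index.name = "horizon"
        return df


def _averaged(d, k, max_lag):
    A = np.zeros((max_lag, k, k))
    cnt = np.zeros((max_lag, k, k))
    for (j, m, lag, t), v in d.items():
        A[lag - 1, j, m] += v
        cnt[lag - 1, j, m] += 1
    np.divide(A, cnt, out=A, where=cnt > 0)
    return A


def impulse_response(spec: ModelSpec, params: ParameterSet, impulse, t0: int = 1,
                     size: float = 1.0, horizon: int = 10,
                     occasion_mode: str = "as-is") -> IRFResult:
    """Response of every variable to a one-time impulse of ``size`` in
    ``impulse`` at occasion ``t0``.

    Horizon h uses the coefficients of occasion ``t0 + h``; occasions past T
    hold the last occasion's coefficients (with a warning), which is exact
    for time-invariant models.  ``occasion_mode="averaged"`` instead uses
    the across-occasion mean of each coefficient throughout.
    """
    k = spec.k
    j = spec.var_index(impulse)
    if not 1 <= t0 <= spec.T:
        raise ValueError(f"t0 must be in 1..{spec.T}")
    p, q = _max_lags(spec)
    averaged = occasion_mode == "averaged"
    if occasion_mode not in ("as-is", "averaged"):
        raise ValueError("occasion_mode must be 'as-is' or 'averaged'")
    if averaged:
        A_avg = _averaged(params.beta, k, max(p, 1))
        D_avg = _averaged(params.delta, k, max(q, 1))
    elif t0 + horizon > spec.T:
        warnings.warn(
            f"horizon extends past the last observed occasion (T={spec.T}); "
            "holding the last occasion's coefficients", RuntimeWarning)

    def coefs(t):
        if averaged:
            return A_avg, D_avg
        tt = min(t, spec.T)
        return (_coef_matrix(params.beta, k, max(p, 1), tt),
                _coef_matrix(params.delta, k, max(q, 1), tt))

    r = np.zeros((horizon + 1, k))
    r[0, j] = size
    for h in range(1, horizon + 1):
        A, D = coefs(t0 + h)
        acc = np.zeros(k)
        for lag in range(1, min(p, h) + 1):
            acc += A[lag - 1] @ r[h - lag]
        if h <= q:
            acc += D[h - 1, :, j] * size
        r[h] = acc
    return IRFResult(r, np.arange(horizon + 1), spec.variable_names[j], t0,
                     size, spec.variable_names)


def impulse_response_bands(result, impulse, t0: int = 1, size: float = 1.0,
                           horizon: int = 10, credibility: float = 0.95,
                           occasion_mode: str = "as-is", n_draws: int = 1000,
                           seed: int = 0) -> IRFResult:
    """Impulse response with uncertainty bands.

    Bayes: the IRF is computed per posterior draw (subsampled to ``n_draws``)
    and bands are HPD intervals; the point response is the posterior mean.
    ML: parameter draws come from the asymptotic normal N(theta_hat,
    theta_cov) and bands are percentile intervals around the plug-in IRF.
    """
    cm = result.compiled
    spec = cm.spec

    if isinstance(result, PosteriorDraws):
        pooled = result.pooled()
        take = np.linspace(0, pooled.shape[0] - 1,
                           min(n_draws, pooled.shape[0])).astype(int)
        thetas = pooled[take]
        center = None
    elif isinstance(result, MLResult):
        rng = np.random.default_rng(seed)
        L = np.linalg.cholesky(
            result.theta_cov + 1e-12 * np.eye(cm.n_theta))
        thetas = result.theta + rng.standard_normal((n_draws, cm.n_theta)) @ L.T
        center = impulse_response(spec, result.estimates, impulse, t0, size,
                                  horizon, occasion_mode).responses
    else:
        raise TypeError(f"unsupported result type: {type(result).__name__}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        paths = np.empty((thetas.shape[0], horizon + 1, spec.k))
        for i in range(thetas.shape[0]):
            paths[i] = impulse_response(spec, cm.params_of_theta(thetas[i]),
                                        impulse, t0, size, horizon,
                                        occasion_mode).responses

    lower = np.empty((horizon + 1, spec.k))
    upper = np.empty((horizon + 1, spec.k))
    if isinstance(result, PosteriorDraws):
        center = paths.mean(axis=0)
        for h in range(horizon + 1):
            for v in range(spec.k):
                lower[h, v], upper[h, v] = hpd_interval(paths[:, h, v], credibility)
    else:
        a = (1 - credibility) / 2
        lower = np.quantile(paths, a, axis=0)
        upper = np.quantile(paths, 1 - a, axis=0)

    j = spec.var_index(impulse)
    return IRFResult(center, np.arange(horizon + 1), spec.variable_names[j],
                     t0, size, spec.variable_names, lower=lower, upper=upper)
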