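"""Maximum-likelihood estimation of the GCLM.

The objective is the multivariate-normal log-likelihood of the wide observed
vector at the model-implied mean and covariance (latents integrated out).
Standard errors come from the inverse of the numerically evaluated observed
information at the optimum; AIC/BIC use the complete-case N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from ._compile import CompiledModel, numerical_hessian
from .data import PanelData
from .model import ModelSpec, ParameterSet, count_free_parameters
from .sem import build_sem_matrices, implied_moments

__all__ = ["MLResult", "IdentificationError", "marginal_loglik", "fit_ml",
           "compare_ml", "saturated_loglik"]

LOG2PI = 1.8378770664093454


class IdentificationError(ValueError):
    """Raised when a spec has more free parameters than identifying moments."""


def _mvn_loglik(mu, Sigma, Y):
    """Sum of MVN log-densities of rows of Y; raises on non-PD Sigma."""
    n, p = Y.shape
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("implied covariance is not positive definite") from exc
    logdet = 2.0 * np.log(np.diag(L)).sum()
    W = np.linalg.solve(L, (Y - mu).T)
    return -0.5 * (n * (p * LOG2PI + logdet) + (W * W).sum())


def marginal_loglik(spec: ModelSpec, params: ParameterSet, data: PanelData,
                    missing: str = "complete") -> float:
    """Implied-moment MVN log-likelihood of ``data`` under ``params``.

    ``missing="complete"`` drops units with any missing cell;
    ``missing="marginal"`` evaluates each unit's observed sub-vector under
    the corresponding marginal of the implied distribution (one MVN term per
    missingness pattern).
    """
    mu, Sigma = implied_moments(build_sem_matrices(spec, params))
    if missing == "complete":
        Y = data.complete_cases().wide()
        if Y.shape[0] == 0:
            raise ValueError("no complete cases")
        return float(_mvn_loglik(mu, Sigma, Y))
    if missing != "marginal":
        raise ValueError("missing must be 'complete' or 'marginal'")
    Y = data.wide()
    obs = ~np.isnan(Y)
    total = 0.0
    patterns = {}
    for i in range(Y.shape[0]):
        patterns.setdefault(obs[i].tobytes(), []).append(i)
    for key, rows in patterns.items():
        idx = np.flatnonzero(np.frombuffer(key, dtype=bool))
        if idx.size == 0:
            continue
        sub = Y[np.ix_(rows, idx)]
        total += _mvn_loglik(mu[idx], Sigma[np.ix_(idx, idx)], sub)
    return float(total)


def saturated_loglik(data: PanelData) -> float:
    """Complete-case MVN log-likelihood at the sample moments (saturated model)."""
    Y = data.complete_cases().wide()
    n, p = Y.shape
    S = np.cov(Y, rowvar=False, bias=True)
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        raise np.linalg.LinAlgError("sample covariance is singular")
    return float(-0.5 * n * (p * LOG2PI + logdet + p))


@dataclass
class MLResult:
    """Maximum-likelihood fit: estimates, SEs and information criteria."""

    estimates: ParameterSet
    standard_errors: dict            # structural name -> SE
    loglik: float
    aic: float
    bic: float
    n_free: int
    n_units: int
    converged: bool
    gradient_norm: float
    theta: np.ndarray = field(repr=False, default=None)
    theta_cov: np.ndarray = field(repr=False, default=None)
    theta_names: list = field(repr=False, default=None)
    compiled: CompiledModel = field(repr=False, default=None)

    def summary(self) -> pd.DataFrame:
        names, values = self.compiled.structural(self.theta)
        se = [self.standard_errors.get(n, np.nan) for n in names]
        df = pd.DataFrame({"estimate": values, "se": se}, index=names)
        from scipy.stats import norm
        df["z"] = df["estimate"] / df["se"]
        df["p"] = 2 * norm.sf(np.abs(df["z"]))
        return df


def fit_ml(spec: ModelSpec, data: PanelData, fixed=None, anchor_loadings=True,
           allow_underidentified=False, n_starts=1, seed=0, tol=1e-8,
           compute_se=True) -> MLResult:
    """Fit a GCLM by maximum likelihood on the complete cases.

    ``anchor_loadings`` replaces freely-estimated loadings with the
    first-loading-fixed-to-1 convention (free loadings together with free
    unit-effect variances leave the latent scale unidentified under ML).
    Under-identified specs (per :func:`count_free_parameters` warnings) raise
    :class:`IdentificationError` unless ``allow_underidentified``.
    """
    spec_eff = spec
    if anchor_loadings and spec.loading_mode == "free" and any(spec.unit_effects):
        spec_eff = spec.replace(loading_mode="fix_first")

    count = count_free_parameters(spec_eff, fixed=fixed)
    if count.warnings and not allow_underidentified:
        raise IdentificationError(
            "model is under-identified for maximum likelihood:\n  "
            + "\n  ".join(count.warnings)
            + "\n(pass allow_underidentified=True to attempt the fit anyway)")

    cm = CompiledModel(spec_eff, data, fixed=fixed)

    def nll(theta):
        return -cm.loglik(theta)

    rng = np.random.default_rng(seed)
    best = None
    theta0 = cm.initial_theta()
    for start in range(max(1, n_starts)):
        x0 = theta0 if start == 0 else theta0 + 0.2 * rng.standard_normal(cm.n_theta)
        res = optimize.minimize(nll, x0, method="L-BFGS-B",
                                options={"maxiter": 5000, "ftol": tol, "gtol": 1e-7,
                                         "maxfun": 200000})
        if best is None or res.fun < best.fun:
            best = res
    theta_hat = best.x
    loglik = -float(best.fun)
    grad_norm = float(np.max(np.abs(np.atleast_1d(best.jac)))) if best.jac is not None else np.nan
    converged = bool(best.success)

    theta_cov = None
    ses = {}
    if compute_se:
        H = numerical_hessian(nll, theta_hat)
        H = 0.5 * (H + H.T)
        try:
            theta_cov = np.linalg.inv(H)
            if np.any(np.diag(theta_cov) <= 0):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            theta_cov = np.linalg.pinv(H)
            converged = False
        names, vals = cm.structural(theta_hat)
        # delta method through the (mostly linear) structural map
        J = np.empty((cm.n_theta, len(names)))
        h = 1e-5 * (1.0 + np.abs(theta_hat))
        for i in range(cm.n_theta):
            e = np.zeros(cm.n_theta)
            e[i] = h[i]
            _, vp = cm.structural(theta_hat + e)
            _, vm = cm.structural(theta_hat - e)
            J[i] = (vp - vm) / (2 * h[i])
        var = np.einsum("in,ij,jn->n", J, theta_cov, J)
        ses = dict(zip(names, np.sqrt(np.maximum(var, 0.0))))

    n_free = cm.n_theta
    N = cm.N
    return MLResult(
        estimates=cm.params_of_theta(theta_hat),
        standard_errors=ses,
        loglik=loglik,
        aic=-2.0 * loglik + 2.0 * n_free,
        bic=-2.0 * loglik + n_free * np.log(N),
        n_free=n_free,
        n_units=N,
        converged=converged,
        gradient_norm=grad_norm,
        theta=theta_hat,
        theta_cov=theta_cov,
        theta_names=list(cm.theta_names),
        compiled=cm,
    )


def compare_ml(models) -> pd.DataFrame:
    """Rank ML fits by AIC and BIC (smaller better; ties -> fewer parameters).

    All models must have been fit to the same data (same complete-case N).
    """
    models = list(models)
    if not models:
        raise ValueError("no models to compare")
    ns = {m.n_units for m in models}
    if len(ns) != 1:
        raise ValueError(f"models were fit to different N: {sorted(ns)}")
    df = pd.DataFrame({
        "loglik": [m.loglik for m in models],
        "n_free": [m.n_free for m in models],
        "aic": [m.aic for m in models],
        "bic": [m.bic for m in models],
    })
    df["rank_aic"] = np.lexsort((df["n_free"], df["aic"])).argsort() + 1
    df["rank_bic"] = np.lexsort((df["n_free"], df["bic"])).argsort() + 1
    return df
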