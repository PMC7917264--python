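"""Synthetic panel generation from any GCLM parameterization.

The generator follows the structural recursion exactly: unit effects
``eta_i ~ N(0, psi_eta)``, impulses ``u_{i,t} ~ N(0, psi_u[t])``, and

``x_{i,t} = alpha_t + lam_t * eta_i + sum_h beta[.,.,h,t] x_{i,t-h}
            + sum_h delta[.,.,h,t] u_{i,t-h} + u_{i,t}``

with the first occasion predetermined (no lagged terms).  The
``income_swb_preset`` mirrors the structure of the published national
income / subjective well-being panel (k=2, T=6): a strongly persistent
income series, a moderately persistent well-being series, a positive
income->SWB cross-lagged effect, a near-zero reverse effect, and large,
positively correlated unit effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import PanelData
from .model import ModelSpec, ParameterSet, TimeVarying, make_spec, params_template, validate_spec

__all__ = ["SimulationConfig", "simulate_panel", "income_swb_preset",
           "time_varying_income_swb_spec"]


@dataclass
class SimulationConfig:
    """How to generate a panel: size, seed, and initialization.

    init_mode "predetermined-draw" draws the first occasion from its own
    marginal (loading, unit effect, first impulse); "stationary-burnin"
    instead runs ``burnin_length`` extra occasions of the time-invariant
    dynamics and discards them, requiring stationary coefficients and
    occasion-constant impulse covariance.
    """

    N: int
    seed: int = 0
    init_mode: str = "predetermined-draw"
    burnin_length: int = 50

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.burnin_length < 0:
            raise ValueError("burnin_length must be >= 0")
        if self.init_mode not in ("predetermined-draw", "stationary-burnin"):
            raise ValueError(f"unknown init_mode: {self.init_mode}")


def _coef_matrix(params_dict, k, max_lag, t):
    """(max_lag, k, k) coefficient array A[h-1, target, source] at occasion t."""
    A = np.zeros((max_lag, k, k))
    for (j, m, lag, tt), v in params_dict.items():
        if tt == t:
            A[lag - 1, j, m] = v
    return A


def _max_lags(spec: ModelSpec):
    p = max([*spec.ar_order, int(spec.cl_order.max(initial=0)), 0])
    q = max([*spec.ma_order, int(spec.clma_order.max(initial=0)), 0])
    return p, q


def _spectral_radius(spec: ModelSpec, params: ParameterSet) -> float:
    """Spectral radius of the AR/CL companion matrix (time-invariant values)."""
    k = spec.k
    p, _ = _max_lags(spec)
    if p == 0:
        return 0.0
    A = _coef_matrix(params.beta, k, p, spec.T)  # last occasion values
    comp = np.zeros((k * p, k * p))
    for h in range(p):
        comp[:k, h * k:(h + 1) * k] = A[h]
    if p > 1:
        comp[k:, :-k] = np.eye(k * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def _check_time_invariant(params: ParameterSet, label: str):
    for d, name in ((params.beta, "beta"), (params.delta, "delta")):
        by_key = {}
        for (j, m, lag, t), v in d.items():
            by_key.setdefault((j, m, lag), []).append(v)
        for key, vals in by_key.items():
            if np.ptp(vals) > 1e-12:
                raise ValueError(
                    f"{label} requires time-invariant coefficients; {name}{key} varies")


def simulate_panel(spec: ModelSpec, params: ParameterSet, cfg: SimulationConfig) -> PanelData:
    """Generate an N x T x k panel from the structural recursion.

    Identical seeds give bit-identical output.  Raises on non-PSD
    covariances and on ``stationary-burnin`` with non-stationary dynamics.
    """
    bad = validate_spec(spec)
    if bad:
        raise ValueError("invalid spec: " + "; ".join(bad))
    bad = params.validate(spec)
    if bad:
        raise ValueError("parameters do not conform to spec: " + "; ".join(bad))

    k, T, N = spec.k, spec.T, cfg.N
    rng = np.random.default_rng(cfg.seed)
    ue = np.array(spec.unit_effects, dtype=bool)

    try:
        L_eta = np.linalg.cholesky(params.psi_eta[np.ix_(ue, ue)]) if ue.any() else None
    except np.linalg.LinAlgError as exc:
        raise ValueError("psi_eta is not positive definite") from exc
    try:
        L_u = np.stack([np.linalg.cholesky(params.psi_u[t]) for t in range(T)])
    except np.linalg.LinAlgError as exc:
        raise ValueError("psi_u has a non-positive-definite occasion block") from exc

    eta = np.zeros((N, k))
    if ue.any():
        eta[:, ue] = rng.standard_normal((N, int(ue.sum()))) @ L_eta.T

    p, q = _max_lags(spec)

    if cfg.init_mode == "stationary-burnin":
        _check_time_invariant(params, "stationary-burnin")
        if np.ptp(params.psi_u, axis=0).max() > 1e-12:
            raise ValueError("stationary-burnin requires occasion-constant psi_u")
        rho = _spectral_radius(spec, params)
        if rho >= 1.0:
            raise ValueError(
                f"stationary-burnin requires spectral radius < 1, got {rho:.3f}")
        n_extra = cfg.burnin_length
    else:
        n_extra = 0

    n_tot = T + n_extra
    u = np.empty((N, n_tot, k))
    x = np.zeros((N, n_tot, k))
    for s in range(n_tot):
        t = max(s - n_extra, 0)  # burn-in occasions reuse first-occasion scales
        u[:, s] = rng.standard_normal((N, k)) @ L_u[t].T

    # coefficient lookups by simulated occasion
    lam_at = np.empty((n_tot, k))
    alpha_at = np.empty((n_tot, k))
    for s in range(n_tot):
        t = max(s - n_extra, 0)
        lam_at[s] = params.lam[t] * ue
        alpha_at[s] = params.alpha[t]

    stationary = cfg.init_mode == "stationary-burnin"

    def coef_at(d, max_lag, s):
        if stationary:
            # time-invariant by construction: last-occasion values apply
            # throughout, keeping the recursion continuous across the
            # burn-in/observation boundary
            return _coef_matrix(d, k, max_lag, T)
        return _coef_matrix(d, k, max_lag, s + 1)

    for s in range(n_tot):
        acc = alpha_at[s] + lam_at[s] * eta + u[:, s]
        if s > 0:
            A = coef_at(params.beta, p, s) if p else None
            D = coef_at(params.delta, q, s) if q else None
            for h in range(1, min(p, s) + 1 if p else 0):
                acc = acc + x[:, s - h] @ A[h - 1].T
            for h in range(1, min(q, s) + 1 if q else 0):
                acc = acc + u[:, s - h] @ D[h - 1].T
        x[:, s] = acc

    values = x[:, n_extra:]
    unit_ids = tuple(f"u{i + 1}" for i in range(N))
    return PanelData(unit_ids, values.copy(), spec.variable_names)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

# Table-style posterior means for the income/SWB example: AR(1)MA(2) income,
# AR(1)MA(1) SWB, CL(1)/CLMA(1) in both directions.
_PRESET_COEF = {
    ("income", "income", "beta", 1): 0.97,
    ("income", "income", "delta", 1): -0.26,
    ("income", "income", "delta", 2): 0.01,
    ("swb", "swb", "beta", 1): 0.34,
    ("swb", "swb", "delta", 1): 0.16,
    ("swb", "income", "beta", 1): 0.24,
    ("swb", "income", "delta", 1): -0.03,
    ("income", "swb", "beta", 1): 0.01,
    ("income", "swb", "delta", 1): -0.02,
}
# occasion-specific impulse co-movement correlations (t = 1..6)
_PRESET_COMOVE = (0.87, 0.44, 0.05, 0.06, 0.41, 0.15)
_PRESET_ETA_VAR = (0.37, 1.01)   # income, swb unit-effect variances
_PRESET_ETA_CORR = 0.86


def income_swb_preset():
    """(spec, params) mimicking the published income/SWB panel structure.

    Impulse variances are unity (raw scales are not published); co-movement
    correlations, unit-effect variances/correlation, and all dynamic
    coefficients follow the published posterior means.  Loadings are fixed
    at 1 (mean-stationary unit effects), which keeps the preset
    ML-identifiable.
    """
    spec = make_spec(
        variables=("income", "swb"), T=6,
        ar=(1, 1), ma=(2, 1), cl=1, clma=1,
        time_varying=TimeVarying(loadings=False),
        loading_mode="fixed_one",
    )
    params = params_template(spec)
    idx = {n: i for i, n in enumerate(spec.variable_names)}
    for (tgt, src, fam, lag), v in _PRESET_COEF.items():
        d = params.beta if fam == "beta" else params.delta
        for t in spec.occasions_for(fam, idx[tgt], idx[src], lag):
            d[(idx[tgt], idx[src], lag, t)] = v
    for t in range(spec.T):
        rho = _PRESET_COMOVE[t]
        params.psi_u[t] = np.array([[1.0, rho], [rho, 1.0]])
    sd = np.sqrt(_PRESET_ETA_VAR)
    params.psi_eta = np.array([
        [_PRESET_ETA_VAR[0], _PRESET_ETA_CORR * sd[0] * sd[1]],
        [_PRESET_ETA_CORR * sd[0] * sd[1], _PRESET_ETA_VAR[1]],
    ])
    return spec, params


def time_varying_income_swb_spec() -> ModelSpec:
    """The fully time-varying analog of the preset spec.

    Every AR/MA/CL/CLMA coefficient and every loading (after the first,
    which anchors the unit-effect scale) is free at each occasion.  With
    k=2 and T=6 this model is under-identified for maximum likelihood and is
    the showcase for difference (shrinkage) priors.
    """
    return make_spec(
        variables=("income", "swb"), T=6,
        ar=(1, 1), ma=(2, 1), cl=1, clma=1,
        time_varying=TimeVarying(ar=True, ma=True, cl=True, clma=True, loadings=True),
        loading_mode="fix_first",
    )
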