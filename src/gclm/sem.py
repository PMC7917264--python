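"""Assembly of the GCLM as a structural equation model.

The model is cast as ``y_i = Lambda eta_i`` with
``eta_i = alpha + B eta_i + zeta_i``: the latent vector stacks the ``kT``
latent analogs of the observations, the ``kT`` impulses, and one unit effect
per flagged variable.  ``B`` carries the kT unities linking analogs to their
contemporaneous impulses, the unit-effect loadings, and all AR/MA/CL/CLMA
coefficients; ``Psi`` (the covariance of ``zeta``) carries the per-occasion
impulse blocks and the unit-effect block.  The reduced form gives the
implied observed moments ``mu = Lambda (I-B)^{-1} alpha`` and
``Sigma = Lambda (I-B)^{-1} Psi (I-B)^{-T} Lambda^T``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ModelSpec, ParameterSet, validate_spec

__all__ = ["SEMMatrices", "build_sem_matrices", "implied_moments", "sem_to_params"]


@dataclass
class SEMMatrices:
    """Assembled SEM matrices plus the latent layout they were built with."""

    Lambda: np.ndarray    # (kT, n_lat)
    Bmat: np.ndarray      # (n_lat, n_lat)
    alpha_vec: np.ndarray  # (n_lat,)
    Psi: np.ndarray       # (n_lat, n_lat)
    latent_names: tuple = ()

    @property
    def n_observed(self) -> int:
        return self.Lambda.shape[0]


def _layout(spec: ModelSpec):
    """Latent indices: analogs, impulses, unit effects."""
    k, T = spec.k, spec.T
    kT = k * T

    def analog(t, j):
        return (t - 1) * k + j

    def impulse(t, j):
        return kT + (t - 1) * k + j

    unit_vars = [j for j in range(k) if spec.unit_effects[j]]
    unit_of = {j: 2 * kT + i for i, j in enumerate(unit_vars)}
    return kT, analog, impulse, unit_vars, unit_of


def build_sem_matrices(spec: ModelSpec, params: ParameterSet) -> SEMMatrices:
    """Place a ParameterSet into (Lambda, B, alpha, Psi).

    Raises ``ValueError`` on spec violations, parameter/spec dimension
    mismatches, or non-PSD covariance blocks.
    """
    bad = validate_spec(spec)
    if bad:
        raise ValueError("invalid spec: " + "; ".join(bad))
    bad = params.validate(spec)
    if bad:
        raise ValueError("parameters do not conform to spec: " + "; ".join(bad))

    k, T = spec.k, spec.T
    kT, analog, impulse, unit_vars, unit_of = _layout(spec)
    n_lat = 2 * kT + len(unit_vars)
    names = spec.variable_names

    Lambda = np.zeros((kT, n_lat))
    Lambda[:, :kT] = np.eye(kT)
    B = np.zeros((n_lat, n_lat))
    alpha = np.zeros(n_lat)
    Psi = np.zeros((n_lat, n_lat))

    latent_names = (
        [f"y*[{names[j]},t{t}]" for t in range(1, T + 1) for j in range(k)]
        + [f"u[{names[j]},t{t}]" for t in range(1, T + 1) for j in range(k)]
        + [f"eta[{names[j]}]" for j in unit_vars]
    )

    for t in range(1, T + 1):
        for j in range(k):
            row = analog(t, j)
            alpha[row] = params.alpha[t - 1, j]
            B[row, impulse(t, j)] = 1.0
            if spec.unit_effects[j]:
                B[row, unit_of[j]] = params.lam[t - 1, j]
    for (j, m, lag, t), val in params.beta.items():
        B[analog(t, j), analog(t - lag, m)] = val
    for (j, m, lag, t), val in params.delta.items():
        B[analog(t, j), impulse(t - lag, m)] = val

    for t in range(1, T + 1):
        idx = [impulse(t, j) for j in range(k)]
        Psi[np.ix_(idx, idx)] = params.psi_u[t - 1]
    if unit_vars:
        idx = [unit_of[j] for j in unit_vars]
        Psi[np.ix_(idx, idx)] = params.psi_eta[np.ix_(unit_vars, unit_vars)]

    return SEMMatrices(Lambda, B, alpha, Psi, tuple(latent_names))


def implied_moments(sem: SEMMatrices):
    """Model-implied mean and covariance of the observed vector.

    Returns ``(mu, Sigma)`` with ``mu`` of length kT and ``Sigma`` kT x kT.
    Raises ``np.linalg.LinAlgError`` naming non-invertibility when
    ``I - B`` is singular.
    """
    n = sem.Bmat.shape[0]
    A = np.eye(n) - sem.Bmat
    if abs(np.linalg.det(A)) < 1e-300 or not np.isfinite(np.linalg.cond(A)):
        raise np.linalg.LinAlgError("I - B is singular: reduced form does not exist")
    G = np.linalg.solve(A, np.eye(n))
    mu_full = G @ sem.alpha_vec
    Sigma_full = G @ sem.Psi @ G.T
    mu = sem.Lambda @ mu_full
    Sigma = sem.Lambda @ Sigma_full @ sem.Lambda.T
    return mu, 0.5 * (Sigma + Sigma.T)


def sem_to_params(spec: ModelSpec, sem: SEMMatrices) -> ParameterSet:
    """Read a ParameterSet back out of assembled SEM matrices.

    Inverse of :func:`build_sem_matrices` under the same spec (exact)."""
    k, T = spec.k, spec.T
    kT, analog, impulse, unit_vars, unit_of = _layout(spec)
    from .model import params_template

    params = params_template(spec)
    for t in range(1, T + 1):
        for j in range(k):
            row = analog(t, j)
            params.alpha[t - 1, j] = sem.alpha_vec[row]
            if spec.unit_effects[j]:
                params.lam[t - 1, j] = sem.Bmat[row, unit_of[j]]
    for key in params.beta:
        j, m, lag, t = key
        params.beta[key] = sem.Bmat[analog(t, j), analog(t - lag, m)]
    for key in params.delta:
        j, m, lag, t = key
        params.delta[key] = sem.Bmat[analog(t, j), impulse(t - lag, m)]
    for t in range(1, T + 1):
        idx = [impulse(t, j) for j in range(k)]
        params.psi_u[t - 1] = sem.Psi[np.ix_(idx, idx)]
    params.psi_eta[:] = 0.0
    if unit_vars:
        idx = [unit_of[j] for j in unit_vars]
        params.psi_eta[np.ix_(unit_vars, unit_vars)] = sem.Psi[np.ix_(idx, idx)]
    return params
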