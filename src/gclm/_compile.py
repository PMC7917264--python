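"""Compilation of a (spec, data) pair into flat arrays for the fast kernels.

The sampling scale ("phi") holds one value per structural slot, with
covariance blocks in log-Cholesky form; the free-parameter vector ("theta")
holds one value per :class:`~gclm.model.ThetaParam`, feeding tied slots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel
from .model import ModelSpec, ParameterSet, enumerate_slots, params_template

__all__ = ["CompiledModel", "PriorArrays", "params_to_phi", "phi_to_params",
           "numerical_hessian"]

DIFFUSE_VARIANCE = 1e10       # effectively flat normal for coefficients
CHOL_OFFDIAG_VARIANCE = 100.0  # diffuse normal on Cholesky off-diagonals
HALF_NORMAL_SCALE = 10.0       # half-normal scale for Cholesky diagonals

_COEF_FAMILIES = ("alpha", "loading", "beta", "delta")


@dataclass
class PriorArrays:
    """Prior terms in the flat form consumed by the kernels."""

    prior_prec: np.ndarray
    prior_mean: np.ndarray
    logsd_mask: np.ndarray
    hn_scale: float
    grp_ptr: np.ndarray
    grp_idx: np.ndarray
    grp_pptr: np.ndarray
    grp_prec: np.ndarray


def params_to_phi(spec: ModelSpec, slots, params: ParameterSet) -> np.ndarray:
    """Project a ParameterSet onto the sampling scale (log-Cholesky blocks)."""
    ue = [j for j in range(spec.k) if spec.unit_effects[j]]
    chol_u = np.empty((spec.T, spec.k, spec.k))
    for t in range(spec.T):
        chol_u[t] = np.linalg.cholesky(params.psi_u[t])
    chol_eta = (np.linalg.cholesky(params.psi_eta[np.ix_(ue, ue)])
                if ue else np.zeros((0, 0)))
    pos = {j: i for i, j in enumerate(ue)}
    phi = np.empty(len(slots))
    for i, s in enumerate(slots):
        if s.family == "alpha":
            phi[i] = params.alpha[s.t - 1, s.target]
        elif s.family == "loading":
            phi[i] = params.lam[s.t - 1, s.target]
        elif s.family == "beta":
            phi[i] = params.beta[(s.target, s.source, s.lag, s.t)]
        elif s.family == "delta":
            phi[i] = params.delta[(s.target, s.source, s.lag, s.t)]
        elif s.family == "psiu_logsd":
            phi[i] = np.log(chol_u[s.t - 1, s.target, s.target])
        elif s.family == "psiu_chol":
            phi[i] = chol_u[s.t - 1, s.target, s.source]
        elif s.family == "psieta_logsd":
            phi[i] = np.log(chol_eta[pos[s.target], pos[s.target]])
        elif s.family == "psieta_chol":
            phi[i] = chol_eta[pos[s.target], pos[s.source]]
        else:  # pragma: no cover
            raise AssertionError(s.family)
    return phi


def phi_to_params(spec: ModelSpec, slots, phi: np.ndarray) -> ParameterSet:
    """Inverse of :func:`params_to_phi`."""
    ue = [j for j in range(spec.k) if spec.unit_effects[j]]
    pos = {j: i for i, j in enumerate(ue)}
    params = params_template(spec)
    params.lam[:] = 0.0
    chol_u = np.zeros((spec.T, spec.k, spec.k))
    chol_eta = np.zeros((len(ue), len(ue)))
    for i, s in enumerate(slots):
        v = phi[i]
        if s.family == "alpha":
            params.alpha[s.t - 1, s.target] = v
        elif s.family == "loading":
            params.lam[s.t - 1, s.target] = v
        elif s.family == "beta":
            params.beta[(s.target, s.source, s.lag, s.t)] = v
        elif s.family == "delta":
            params.delta[(s.target, s.source, s.lag, s.t)] = v
        elif s.family == "psiu_logsd":
            chol_u[s.t - 1, s.target, s.target] = np.exp(v)
        elif s.family == "psiu_chol":
            chol_u[s.t - 1, s.target, s.source] = v
        elif s.family == "psieta_logsd":
            chol_eta[pos[s.target], pos[s.target]] = np.exp(v)
        elif s.family == "psieta_chol":
            chol_eta[pos[s.target], pos[s.source]] = v
    for t in range(spec.T):
        params.psi_u[t] = chol_u[t] @ chol_u[t].T
    params.psi_eta[:] = 0.0
    if ue:
        params.psi_eta[np.ix_(ue, ue)] = chol_eta @ chol_eta.T
    return params


class CompiledModel:
    """A GCLM spec bound to complete-case sufficient statistics.

    Exposes the fast implied-moment MVN log-likelihood (and log posterior)
    as functions of the free-parameter vector theta.
    """

    def __init__(self, spec: ModelSpec, panel=None, fixed=None):
        self.spec = spec
        self.slots, self.thetas = enumerate_slots(spec, fixed=fixed)
        self.n_phi = len(self.slots)
        self.n_theta = len(self.thetas)
        self.theta_names = [p.name for p in self.thetas]
        self.phi_names = [s.name for s in self.slots]

        k, T = spec.k, spec.T
        kT = k * T
        ue = [j for j in range(k) if spec.unit_effects[j]]
        self.kT = kT
        self.n_lat = 2 * kT + len(ue)
        unit_of = {j: 2 * kT + i for i, j in enumerate(ue)}

        # theta -> phi fill map and baseline of fixed values
        self.phi_base = np.array([s.fixed_value for s in self.slots], dtype=float)
        fill_phi, fill_theta = [], []
        for i, s in enumerate(self.slots):
            if s.theta >= 0:
                fill_phi.append(i)
                fill_theta.append(s.theta)
        self.fill_phi = np.asarray(fill_phi, dtype=np.int64)
        self.fill_theta = np.asarray(fill_theta, dtype=np.int64)

        # B placements
        def analog(t, j):
            return (t - 1) * k + j

        def impulse(t, j):
            return kT + (t - 1) * k + j

        rows, cols, phis = [], [], []
        alpha_phi = np.zeros(kT, dtype=np.int64)
        blocks = {}   # block id -> (offset, size, [(r, c, phi, islog)])
        for t in range(1, T + 1):
            blocks[t - 1] = (kT + (t - 1) * k, k, [])
        if ue:
            blocks[T] = (2 * kT, len(ue), [])
        pos = {j: i for i, j in enumerate(ue)}
        for i, s in enumerate(self.slots):
            if s.family == "alpha":
                alpha_phi[analog(s.t, s.target)] = i
            elif s.family == "loading":
                rows.append(analog(s.t, s.target))
                cols.append(unit_of[s.target])
                phis.append(i)
            elif s.family == "beta":
                rows.append(analog(s.t, s.target))
                cols.append(analog(s.t - s.lag, s.source))
                phis.append(i)
            elif s.family == "delta":
                rows.append(analog(s.t, s.target))
                cols.append(impulse(s.t - s.lag, s.source))
                phis.append(i)
            elif s.family == "psiu_logsd":
                blocks[s.t - 1][2].append((s.target, s.target, i, 1))
            elif s.family == "psiu_chol":
                blocks[s.t - 1][2].append((s.target, s.source, i, 0))
            elif s.family == "psieta_logsd":
                blocks[T][2].append((pos[s.target], pos[s.target], i, 1))
            elif s.family == "psieta_chol":
                blocks[T][2].append((pos[s.target], pos[s.source], i, 0))
        self.b_rows = np.asarray(rows, dtype=np.int64)
        self.b_cols = np.asarray(cols, dtype=np.int64)
        self.b_phi = np.asarray(phis, dtype=np.int64)
        self.alpha_phi = alpha_phi

        blk_ids = sorted(blocks)
        self.blk_off = np.asarray([blocks[b][0] for b in blk_ids], dtype=np.int64)
        self.blk_size = np.asarray([blocks[b][1] for b in blk_ids], dtype=np.int64)
        ch_r, ch_c, ch_phi, ch_log = [], [], [], []
        ch_ptr = [0]
        for b in blk_ids:
            for r, c, p, lg in blocks[b][2]:
                ch_r.append(r)
                ch_c.append(c)
                ch_phi.append(p)
                ch_log.append(lg)
            ch_ptr.append(len(ch_r))
        self.ch_ptr = np.asarray(ch_ptr, dtype=np.int64)
        self.ch_r = np.asarray(ch_r, dtype=np.int64)
        self.ch_c = np.asarray(ch_c, dtype=np.int64)
        self.ch_phi = np.asarray(ch_phi, dtype=np.int64)
        self.ch_log = np.asarray(ch_log, dtype=np.int64)

        # data sufficient statistics (complete cases)
        self.n_dropped = 0
        if panel is not None:
            self.bind_data(panel)
        else:
            self.S = np.eye(kT)
            self.ybar = np.zeros(kT)
            self.N = 0

        self.priors = self.default_priors()

    # -- data -------------------------------------------------------------
    def bind_data(self, panel) -> None:
        keep = panel.complete_rows()
        self.n_dropped = int((~keep).sum())
        Y = panel.wide()[keep]
        if Y.shape[0] < 2:
            raise ValueError("need at least 2 complete cases")
        self.N = Y.shape[0]
        self.ybar = Y.mean(axis=0)
        dev = Y - self.ybar
        self.S = np.ascontiguousarray(dev.T @ dev / self.N)

    def _ll_args(self):
        return (self.kT, self.n_lat, self.b_rows, self.b_cols, self.b_phi,
                self.alpha_phi, self.blk_off, self.blk_size, self.ch_ptr,
                self.ch_r, self.ch_c, self.ch_phi, self.ch_log,
                self.S, self.ybar, self.N)

    # -- priors -----------------------------------------------------------
    def default_priors(self) -> PriorArrays:
        """All-diffuse priors: N(0, 1e10) coefficients, half-normal scales."""
        prec = np.zeros(self.n_theta)
        mean = np.zeros(self.n_theta)
        logsd = np.zeros(self.n_theta, dtype=np.bool_)
        for i, p in enumerate(self.thetas):
            if p.family in _COEF_FAMILIES:
                prec[i] = 1.0 / DIFFUSE_VARIANCE
            elif p.family in ("psiu_chol", "psieta_chol"):
                prec[i] = 1.0 / CHOL_OFFDIAG_VARIANCE
            else:
                logsd[i] = True
        empty = np.zeros(0, dtype=np.int64)
        return PriorArrays(prec, mean, logsd, HALF_NORMAL_SCALE,
                           np.zeros(1, dtype=np.int64), empty,
                           empty, np.zeros(0))

    def set_priors(self, priors: PriorArrays) -> None:
        self.priors = priors

    # -- evaluation -------------------------------------------------------
    def phi_of_theta(self, theta: np.ndarray) -> np.ndarray:
        phi = self.phi_base.copy()
        phi[self.fill_phi] = np.asarray(theta, dtype=float)[self.fill_theta]
        return phi

    def theta_of_params(self, params: ParameterSet) -> np.ndarray:
        phi = params_to_phi(self.spec, self.slots, params)
        theta = np.zeros(self.n_theta)
        seen = np.zeros(self.n_theta, dtype=bool)
        for i, s in enumerate(self.slots):
            if s.theta >= 0 and not seen[s.theta]:
                theta[s.theta] = phi[i]
                seen[s.theta] = True
        return theta

    def params_of_theta(self, theta: np.ndarray) -> ParameterSet:
        return phi_to_params(self.spec, self.slots, self.phi_of_theta(theta))

    def loglik_phi(self, phi: np.ndarray) -> float:
        return float(_kernel.loglik_kernel(np.asarray(phi, dtype=float), *self._ll_args()))

    def loglik(self, theta: np.ndarray) -> float:
        return self.loglik_phi(self.phi_of_theta(theta))

    def loglik_with_stats(self, theta, S, ybar, N) -> float:
        """Log-likelihood of alternative sufficient statistics (same spec)."""
        phi = self.phi_of_theta(theta)
        return float(_kernel.loglik_kernel(
            np.asarray(phi, dtype=float), self.kT, self.n_lat, self.b_rows,
            self.b_cols, self.b_phi, self.alpha_phi, self.blk_off,
            self.blk_size, self.ch_ptr, self.ch_r, self.ch_c, self.ch_phi,
            self.ch_log, np.ascontiguousarray(S, dtype=float),
            np.asarray(ybar, dtype=float), int(N)))

    def loglik_many(self, thetas: np.ndarray) -> np.ndarray:
        out = np.empty(thetas.shape[0])
        for i in range(thetas.shape[0]):
            out[i] = self.loglik(thetas[i])
        return out

    def logpost(self, theta: np.ndarray) -> float:
        pr = self.priors
        return float(_kernel.logpost_kernel(
            np.asarray(theta, dtype=float), self.phi_base, self.fill_phi,
            self.fill_theta, *self._ll_args(),
            pr.prior_prec, pr.prior_mean, pr.logsd_mask, pr.hn_scale,
            pr.grp_ptr, pr.grp_idx, pr.grp_pptr, pr.grp_prec))

    # -- starting values --------------------------------------------------
    def initial_theta(self) -> np.ndarray:
        """Moment-based starting values (requires bound data)."""
        theta = np.zeros(self.n_theta)
        k = self.spec.k
        sd = np.sqrt(np.maximum(np.diag(self.S), 1e-8))
        for i, p in enumerate(self.thetas):
            if p.family == "alpha":
                theta[i] = self.ybar[(p.t - 1) * k + p.target]
            elif p.family == "loading":
                theta[i] = 0.7
            elif p.family == "beta" and p.target == p.source and p.lag == 1:
                theta[i] = 0.3
            elif p.family == "psiu_logsd":
                theta[i] = np.log(0.7 * sd[(p.t - 1) * k + p.target])
            elif p.family == "psieta_logsd":
                theta[i] = np.log(0.5 * sd[p.target])
        return theta

    # -- reporting ----------------------------------------------------------
    def structural(self, theta: np.ndarray):
        """Structural names/values: free coefficients plus covariance entries.

        Coefficient entries are reported per slot (so tied values repeat with
        their per-occasion names suppressed in favour of the theta name);
        covariance blocks are reported as variances and covariances.
        """
        phi = self.phi_of_theta(theta)
        params = phi_to_params(self.spec, self.slots, phi)
        spec = self.spec
        names, values = [], []
        seen = set()
        for i, s in enumerate(self.slots):
            if s.family in ("alpha", "loading", "beta", "delta") and s.theta >= 0:
                nm = self.theta_names[s.theta]
                if nm in seen:
                    continue
                seen.add(nm)
                names.append(nm)
                values.append(phi[i])
        vn = spec.variable_names
        for t in range(spec.T):
            for r in range(spec.k):
                for c in range(r + 1):
                    names.append(f"psi_u[t{t + 1},{vn[r]},{vn[c]}]")
                    values.append(params.psi_u[t, r, c])
        ue = [j for j in range(spec.k) if spec.unit_effects[j]]
        for a, r in enumerate(ue):
            for c in ue[:a + 1]:
                names.append(f"psi_eta[{vn[r]},{vn[c]}]")
                values.append(params.psi_eta[r, c])
        return names, np.asarray(values)

    # -- sampling ---------------------------------------------------------
    def sample_chain(self, theta0, Lprop, n_burn, thin, n_keep, seed, adapt=True):
        pr = self.priors
        draws, acc, log_s = _kernel.metropolis_kernel(
            np.asarray(theta0, dtype=float), np.ascontiguousarray(Lprop, dtype=float),
            int(n_burn), int(thin), int(n_keep), int(seed), bool(adapt),
            self.phi_base, self.fill_phi, self.fill_theta, *self._ll_args(),
            pr.prior_prec, pr.prior_mean, pr.logsd_mask, pr.hn_scale,
            pr.grp_ptr, pr.grp_idx, pr.grp_pptr, pr.grp_prec)
        return draws, float(acc), float(log_s)


def numerical_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Symmetric central-difference Hessian of scalar ``f`` at ``x``."""
    x = np.asarray(x, dtype=float)
    d = x.size
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((d, d))
    f0 = f(x)
    fp = np.empty(d)
    fm = np.empty(d)
    for i in range(d):
        e = np.zeros(d)
        e[i] = h[i]
        fp[i] = f(x + e)
        fm[i] = f(x - e)
        H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h[i] ** 2
    for i in range(d):
        for j in range(i):
            e = np.zeros(d)
            e[i] = h[i]
            e[j] = h[j]
            fpp = f(x + e)
            e[j] = -h[j]
            fpm = f(x + e)
            fmp = f(-e + x)
            e[j] = h[j]
            fmm = f(x - e)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H
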