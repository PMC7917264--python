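"""Structural specification of the general cross-lagged panel model (GCLM).

A GCLM describes ``k`` observed variables measured at occasions ``t = 1..T``
for ``N`` independent units.  Each variable carries a time-invariant latent
unit effect ``eta`` (entering through per-occasion loadings ``lambda_t``), an
occasion effect ``alpha_t``, and an occasion-specific structured residual
("impulse") ``u_t``.  Dynamics come in four families:

- AR:   effect of a variable's own past observation, coefficient ``beta``;
- MA:   effect of a variable's own past impulse, coefficient ``delta``;
- CL:   effect of another variable's past observation (cross-lagged beta);
- CLMA: effect of another variable's past impulse (cross-lagged delta).

This module houses the specification objects (:class:`ModelSpec`,
:class:`ParameterSet`), their validation, the parameter/moment counting
identities, and the slot enumeration that fixes the order of free parameters
shared by the estimation back-ends.

Conventions
-----------
Occasions are 1-based.  The first occasion is predetermined:
``x_{i,1} = alpha_1 + lambda_1 * eta_i + u_{i,1}`` with no lagged terms, and
the impulse covariance at t=1 is free.  A lag-``h`` coefficient exists for
occasions ``t = h + occasion_start .. T`` (default ``occasion_start = 1``,
i.e. whenever the lagged quantity exists).  Coefficients are indexed by
(target variable, source variable, lag, occasion of the *outcome*): the
occasion-``t`` coefficient multiplies the source at ``t - lag``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "TimeVarying",
    "ModelSpec",
    "ParameterSet",
    "make_spec",
    "validate_spec",
    "count_time_varying_coeffs",
    "count_moments",
    "count_free_parameters",
    "ParameterCount",
    "Slot",
    "ThetaParam",
    "enumerate_slots",
    "params_template",
]

LOADING_MODES = ("free", "fix_first", "fixed_one")


@dataclass(frozen=True)
class TimeVarying:
    """Which coefficient families get a free value at every occasion."""

    ar: bool = False
    ma: bool = False
    cl: bool = False
    clma: bool = False
    loadings: bool = True


def _as_order_matrix(value, k: int, names) -> np.ndarray:
    """Normalize a cross-lag order argument to a (k, k) int array.

    Accepts a scalar (applied to every ordered pair), a (k, k) array, or a
    dict keyed ``"target<-source"`` / ``(target, source)`` by name or index.
    The diagonal is always zero (own-variable lags live in ar/ma orders).
    """
    out = np.zeros((k, k), dtype=int)
    if value is None:
        return out
    if np.isscalar(value):
        out[:] = int(value)
    elif isinstance(value, dict):
        idx = {n: i for i, n in enumerate(names)}
        for key, v in value.items():
            if isinstance(key, str):
                tgt, src = (s.strip() for s in key.split("<-"))
                out[idx[tgt], idx[src]] = int(v)
            else:
                out[key[0], key[1]] = int(v)
    else:
        out = np.asarray(value, dtype=int).copy()
    np.fill_diagonal(out, 0)
    return out


@dataclass(eq=False)
class ModelSpec:
    """Structural description of a GCLM.

    Parameters
    ----------
    k, T : int
        Number of observed variables per occasion and number of occasions.
    variable_names : tuple of str
        Unique labels, length ``k``.
    ar_order, ma_order : tuple of int
        Per-variable AR(p) / MA(q) lag orders.
    cl_order, clma_order : (k, k) int arrays
        Per ordered (target, source) pair CL(c) / CLMA(l) lag orders;
        diagonal ignored.
    time_varying : TimeVarying
        Families whose coefficients are free at every occasion.
    unit_effects : tuple of bool
        Whether each variable carries a latent unit effect.
    loading_mode : {"free", "fix_first", "fixed_one"}
        "free": every loading estimated (the convention under which the
        published model counts 54 free parameters; not scale-identified for
        ML together with free unit-effect variances).  "fix_first":
        ``lambda_1 = 1`` anchors the unit-effect scale.  "fixed_one": all
        loadings fixed to 1 (classic random-intercept behaviour).
    occasion_start : int
        Lag-``h`` coefficients exist for ``t = h + occasion_start .. T``.
    occasion_overrides : dict
        Optional explicit occasion sets keyed
        ``(family, target, source, lag)`` with family in {"beta", "delta"},
        overriding the default convention for that coefficient.
    """

    k: int
    T: int
    variable_names: tuple
    ar_order: tuple
    ma_order: tuple
    cl_order: np.ndarray
    clma_order: np.ndarray
    time_varying: TimeVarying = field(default_factory=TimeVarying)
    unit_effects: tuple = None
    loading_mode: str = "free"
    occasion_start: int = 1
    occasion_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        self.variable_names = tuple(self.variable_names)
        self.ar_order = tuple(int(v) for v in np.broadcast_to(self.ar_order, (self.k,)))
        self.ma_order = tuple(int(v) for v in np.broadcast_to(self.ma_order, (self.k,)))
        self.cl_order = _as_order_matrix(self.cl_order, self.k, self.variable_names)
        self.clma_order = _as_order_matrix(self.clma_order, self.k, self.variable_names)
        if self.unit_effects is None:
            self.unit_effects = (True,) * self.k
        self.unit_effects = tuple(bool(v) for v in np.broadcast_to(self.unit_effects, (self.k,)))

    def __eq__(self, other):
        if not isinstance(other, ModelSpec):
            return NotImplemented
        return self.to_dict() == other.to_dict()

    # -- layout helpers -------------------------------------------------
    def var_index(self, name) -> int:
        if isinstance(name, (int, np.integer)):
            return int(name)
        return self.variable_names.index(name)

    def occasions_for(self, family: str, target: int, source: int, lag: int):
        """Occasions at which the (family, target, source, lag) coefficient exists."""
        key = (family, target, source, lag)
        if key in self.occasion_overrides:
            return tuple(self.occasion_overrides[key])
        return tuple(range(lag + self.occasion_start, self.T + 1))

    @property
    def n_unit_effects(self) -> int:
        return sum(self.unit_effects)

    def replace(self, **changes) -> "ModelSpec":
        return dataclasses.replace(self, **changes)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "variables": list(self.variable_names),
            "T": self.T,
            "ar": {n: o for n, o in zip(self.variable_names, self.ar_order)},
            "ma": {n: o for n, o in zip(self.variable_names, self.ma_order)},
            "cl": {
                f"{self.variable_names[i]}<-{self.variable_names[j]}": int(self.cl_order[i, j])
                for i in range(self.k) for j in range(self.k) if i != j
            },
            "clma": {
                f"{self.variable_names[i]}<-{self.variable_names[j]}": int(self.clma_order[i, j])
                for i in range(self.k) for j in range(self.k) if i != j
            },
            "time_varying": dataclasses.asdict(self.time_varying),
            "unit_effects": [n for n, u in zip(self.variable_names, self.unit_effects) if u],
            "loading_mode": self.loading_mode,
            "occasion_start": self.occasion_start,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        names = tuple(d["variables"])
        k = len(names)
        unit = d.get("unit_effects", list(names))
        return make_spec(
            variables=names,
            T=int(d["T"]),
            ar=[d.get("ar", {}).get(n, 0) if isinstance(d.get("ar", {}), dict) else d["ar"] for n in names],
            ma=[d.get("ma", {}).get(n, 0) if isinstance(d.get("ma", {}), dict) else d["ma"] for n in names],
            cl=d.get("cl", 0),
            clma=d.get("clma", 0),
            time_varying=TimeVarying(**d.get("time_varying", {})),
            unit_effects=[n in unit for n in names],
            loading_mode=d.get("loading_mode", "free"),
            occasion_start=int(d.get("occasion_start", 1)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def make_spec(variables, T, ar=1, ma=1, cl=1, clma=1, time_varying=None,
              unit_effects=None, loading_mode="free", occasion_start=1,
              occasion_overrides=None) -> ModelSpec:
    """Convenience constructor with scalar broadcasting for lag orders."""
    names = tuple(variables)
    k = len(names)
    if time_varying is None:
        time_varying = TimeVarying()
    elif isinstance(time_varying, dict):
        time_varying = TimeVarying(**time_varying)
    return ModelSpec(
        k=k, T=int(T), variable_names=names,
        ar_order=ar, ma_order=ma,
        cl_order=_as_order_matrix(cl, k, names),
        clma_order=_as_order_matrix(clma, k, names),
        time_varying=time_varying,
        unit_effects=unit_effects,
        loading_mode=loading_mode,
        occasion_start=occasion_start,
        occasion_overrides=dict(occasion_overrides or {}),
    )


def validate_spec(spec: ModelSpec) -> list:
    """Return a list of human-readable invariant violations (empty if valid)."""
    v = []
    if spec.k < 1:
        v.append("k: must be >= 1")
    if spec.T < 2:
        v.append("T: must be >= 2")
    if len(set(spec.variable_names)) != spec.k:
        v.append("variable_names: must be unique and of length k")
    for name, order, label in (
        (spec.variable_names, spec.ar_order, "ar_order"),
        (spec.variable_names, spec.ma_order, "ma_order"),
    ):
        for n, o in zip(name, order):
            if not 0 <= o < spec.T:
                v.append(f"{label}[{n}]: must satisfy 0 <= order < T, got {o}")
    for mat, label in ((spec.cl_order, "cl_order"), (spec.clma_order, "clma_order")):
        if mat.shape != (spec.k, spec.k):
            v.append(f"{label}: must be (k, k)")
            continue
        for i in range(spec.k):
            for j in range(spec.k):
                if i != j and not 0 <= mat[i, j] < spec.T:
                    v.append(
                        f"{label}[{spec.variable_names[i]}<-{spec.variable_names[j]}]: "
                        f"must satisfy 0 <= order < T, got {mat[i, j]}")
    if spec.loading_mode not in LOADING_MODES:
        v.append(f"loading_mode: must be one of {LOADING_MODES}")
    if spec.occasion_start < 0:
        v.append("occasion_start: must be >= 0")
    for (fam, tgt, src, lag), occs in spec.occasion_overrides.items():
        for t in occs:
            if not (lag + 1) <= t <= spec.T:
                v.append(
                    f"occasion_overrides[{fam},{tgt},{src},{lag}]: occasion {t} "
                    f"outside {lag + 1}..{spec.T}")
    return v


# ---------------------------------------------------------------------------
# Counting identities
# ---------------------------------------------------------------------------

def count_time_varying_coeffs(k: int, T: int) -> int:
    """Total time-varying AR/MA/CL/CLMA coefficients at lag order 1: (T-1)[2k + 2k(k-1)]."""
    if k < 1 or T < 2:
        raise ValueError("require k >= 1 and T >= 2")
    return (T - 1) * (2 * k + 2 * k * (k - 1))


def count_moments(k: int, T: int):
    """(auto, cross) covariance counts available for estimation.

    Auto-covariances: kT(T-1)/2 (within-variable, distinct occasion pairs).
    Cross-covariances: k(k-1)T^2/2 (between-variable, all occasion pairs).
    """
    if k < 1 or T < 2:
        raise ValueError("require k >= 1 and T >= 2")
    return k * T * (T - 1) // 2, k * (k - 1) * T * T // 2


# ---------------------------------------------------------------------------
# Free-parameter enumeration (single source of truth for all back-ends)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Slot:
    """One structural-parameter position (on the sampling scale).

    Covariance blocks are parameterized by their Cholesky factor: families
    ``psiu_logsd`` / ``psieta_logsd`` hold log of the Cholesky diagonal and
    ``psiu_chol`` / ``psieta_chol`` hold raw sub-diagonal entries.
    """

    name: str
    family: str      # alpha | loading | beta | delta | psiu_logsd | psiu_chol | psieta_logsd | psieta_chol
    target: int
    source: int      # -1 when not applicable
    lag: int         # 0 when not applicable
    t: int           # occasion, 0 for psi_eta entries
    theta: int       # index into the free-parameter vector, -1 when fixed
    fixed_value: float = 0.0


@dataclass(frozen=True)
class ThetaParam:
    """One free parameter, possibly feeding several tied slots."""

    name: str
    family: str
    target: int
    source: int
    lag: int
    t: int           # occasion for time-varying entries, -1 for tied/shared


def _coef_name(names, family, target, source, lag, t=None):
    base = f"{family}[{names[target]}<-{names[source]},lag{lag}"
    if t is not None:
        base += f",t{t}"
    return base + "]"


def enumerate_slots(spec: ModelSpec, fixed=None):
    """Enumerate structural slots and the free-parameter (theta) vector.

    Parameters
    ----------
    fixed : dict, optional
        Mapping from slot *or* theta name to a fixed value; matching slots
        are removed from the free vector.

    Returns
    -------
    slots : list of Slot
    thetas : list of ThetaParam
    """
    fixed = dict(fixed or {})
    names = spec.variable_names
    k, T = spec.k, spec.T
    slots: list = []
    thetas: list = []

    consumed = set()

    def new_theta(name, family, target, source=-1, lag=0, t=-1):
        if name in fixed:
            consumed.add(name)
            return -1, float(fixed[name])
        thetas.append(ThetaParam(name, family, target, source, lag, t))
        return len(thetas) - 1, 0.0

    def add_slot(name, family, target, source, lag, t, theta, fixed_value=0.0):
        if name in fixed:
            consumed.add(name)
            theta, fixed_value = -1, float(fixed[name])
        slots.append(Slot(name, family, target, source, lag, t, theta, fixed_value))

    # occasion effects
    for t in range(1, T + 1):
        for j in range(k):
            nm = f"alpha[{names[j]},t{t}]"
            th, fv = new_theta(nm, "alpha", j, t=t)
            add_slot(nm, "alpha", j, -1, 0, t, th, fv)

    # unit-effect loadings
    for j in range(k):
        if not spec.unit_effects[j]:
            continue
        tied = -2
        for t in range(1, T + 1):
            nm = f"lam[{names[j]},t{t}]"
            if spec.loading_mode == "fixed_one" or (spec.loading_mode == "fix_first" and t == 1):
                add_slot(nm, "loading", j, -1, 0, t, -1, 1.0)
            elif spec.time_varying.loadings:
                th, fv = new_theta(nm, "loading", j, t=t)
                add_slot(nm, "loading", j, -1, 0, t, th, fv)
            else:
                if tied == -2:
                    tied, tied_fv = new_theta(f"lam[{names[j]}]", "loading", j)
                add_slot(nm, "loading", j, -1, 0, t, tied, tied_fv if tied == -1 else 0.0)

    # dynamic coefficients
    def add_family(family, target, source, order, tv_flag):
        for lag in range(1, order + 1):
            occs = spec.occasions_for(family, target, source, lag)
            tied = -2
            for t in occs:
                nm = _coef_name(names, family, target, source, lag, t)
                if tv_flag:
                    th, fv = new_theta(nm, family, target, source, lag, t)
                    add_slot(nm, family, target, source, lag, t, th, fv)
                else:
                    if tied == -2:
                        tied, tied_fv = new_theta(
                            _coef_name(names, family, target, source, lag),
                            family, target, source, lag)
                    add_slot(nm, family, target, source, lag, t, tied,
                             tied_fv if tied == -1 else 0.0)

    for j in range(k):
        add_family("beta", j, j, spec.ar_order[j], spec.time_varying.ar)
        for m in range(k):
            if m != j:
                add_family("beta", j, m, int(spec.cl_order[j, m]), spec.time_varying.cl)
        add_family("delta", j, j, spec.ma_order[j], spec.time_varying.ma)
        for m in range(k):
            if m != j:
                add_family("delta", j, m, int(spec.clma_order[j, m]), spec.time_varying.clma)

    # impulse covariance blocks, one per occasion (log-Cholesky)
    for t in range(1, T + 1):
        for j in range(k):
            nm = f"psi_u[t{t}]:logsd[{names[j]}]"
            th, fv = new_theta(nm, "psiu_logsd", j, t=t)
            add_slot(nm, "psiu_logsd", j, -1, 0, t, th, fv)
        for r in range(k):
            for c in range(r):
                nm = f"psi_u[t{t}]:chol[{names[r]},{names[c]}]"
                th, fv = new_theta(nm, "psiu_chol", r, source=c, t=t)
                add_slot(nm, "psiu_chol", r, c, 0, t, th, fv)

    # unit-effect covariance block
    ue = [j for j in range(k) if spec.unit_effects[j]]
    for j in ue:
        nm = f"psi_eta:logsd[{names[j]}]"
        th, fv = new_theta(nm, "psieta_logsd", j)
        add_slot(nm, "psieta_logsd", j, -1, 0, 0, th, fv)
    for a in range(len(ue)):
        for b in range(a):
            nm = f"psi_eta:chol[{names[ue[a]]},{names[ue[b]]}]"
            th, fv = new_theta(nm, "psieta_chol", ue[a], source=ue[b])
            add_slot(nm, "psieta_chol", ue[a], ue[b], 0, 0, th, fv)

    unknown = set(fixed) - consumed
    if unknown:
        raise KeyError(f"fixed values refer to unknown parameters: {sorted(unknown)}")
    return slots, thetas


@dataclass
class ParameterCount:
    """Itemized free-parameter count with identification warnings."""

    items: dict
    total: int
    warnings: list

    def __str__(self):
        lines = [f"{k}: {v}" for k, v in self.items.items()]
        lines.append(f"total: {self.total}")
        lines += [f"warning: {w}" for w in self.warnings]
        return "\n".join(lines)


_COUNT_KEYS = {
    "alpha": "alpha",
    "loading": "loadings",
    "beta": "beta",
    "delta": "delta",
    "psiu_logsd": "psi_u_var",
    "psiu_chol": "psi_u_cov",
    "psieta_logsd": "psi_eta",
    "psieta_chol": "psi_eta",
}


def count_free_parameters(spec: ModelSpec, fixed=None) -> ParameterCount:
    """Itemized count of free parameters under the spec's conventions.

    Emits an identification warning for any variable whose own-equation
    dynamic parameters (loadings, unit-effect variance, own AR and MA terms)
    exceed its available auto-covariances, and a global warning when the
    total exceeds all first and second observed moments.
    """
    bad = validate_spec(spec)
    if bad:
        raise ValueError("invalid spec: " + "; ".join(bad))
    slots, thetas = enumerate_slots(spec, fixed=fixed)
    items = {key: 0 for key in ("alpha", "loadings", "psi_eta", "psi_u_var",
                                "psi_u_cov", "beta", "delta")}
    for p in thetas:
        items[_COUNT_KEYS[p.family]] += 1
    total = len(thetas)

    warnings = []
    auto, cross = count_moments(spec.k, spec.T)
    auto_per_var = spec.T * (spec.T - 1) // 2
    for j, name in enumerate(spec.variable_names):
        own = sum(
            1 for p in thetas
            if (p.family == "loading" and p.target == j)
            or (p.family == "psieta_logsd" and p.target == j)
            or (p.family in ("beta", "delta") and p.target == j and p.source == j)
        )
        if own > auto_per_var:
            warnings.append(
                f"{name}: {own} own-equation dynamic parameters exceed the "
                f"{auto_per_var} available auto-covariances (under-identified for ML)")
    n_moments = spec.k * spec.T + spec.k * spec.T * (spec.k * spec.T + 1) // 2
    if total > n_moments:
        warnings.append(
            f"total free parameters ({total}) exceed observed moments ({n_moments})")
    return ParameterCount(items=items, total=total, warnings=warnings)


# ---------------------------------------------------------------------------
# ParameterSet
# ---------------------------------------------------------------------------

@dataclass
class ParameterSet:
    """All structural coefficients and (co)variances of a GCLM.

    Attributes
    ----------
    alpha, lam : (T, k) arrays
        Occasion effects and unit-effect loadings (lam column is ignored for
        variables without a unit effect).
    beta, delta : dict
        Keyed ``(target, source, lag, t)`` with 1-based occasions; a
        non-time-varying family holds the same value repeated across its
        occasions.
    psi_u : (T, k, k) array
        Impulse covariance per occasion.
    psi_eta : (k, k) array
        Unit-effect covariance (rows/cols of variables without unit effects
        must be zero).
    """

    alpha: np.ndarray
    lam: np.ndarray
    beta: dict
    delta: dict
    psi_u: np.ndarray
    psi_eta: np.ndarray

    def copy(self) -> "ParameterSet":
        return ParameterSet(self.alpha.copy(), self.lam.copy(), dict(self.beta),
                            dict(self.delta), self.psi_u.copy(), self.psi_eta.copy())

    def validate(self, spec: ModelSpec) -> list:
        """Conformance violations of this parameter set against ``spec``."""
        v = []
        T, k = spec.T, spec.k
        if self.alpha.shape != (T, k):
            v.append(f"alpha: expected shape {(T, k)}, got {self.alpha.shape}")
        if self.lam.shape != (T, k):
            v.append(f"lam: expected shape {(T, k)}, got {self.lam.shape}")
        if self.psi_u.shape != (T, k, k):
            v.append(f"psi_u: expected shape {(T, k, k)}, got {self.psi_u.shape}")
        if self.psi_eta.shape != (k, k):
            v.append(f"psi_eta: expected shape {(k, k)}, got {self.psi_eta.shape}")
        if v:
            return v
        expected = set()
        for fam in ("beta", "delta"):
            for j in range(k):
                own = spec.ar_order[j] if fam == "beta" else spec.ma_order[j]
                for lag in range(1, own + 1):
                    for t in spec.occasions_for(fam, j, j, lag):
                        expected.add((fam, (j, j, lag, t)))
                mat = spec.cl_order if fam == "beta" else spec.clma_order
                for m in range(k):
                    if m == j:
                        continue
                    for lag in range(1, int(mat[j, m]) + 1):
                        for t in spec.occasions_for(fam, j, m, lag):
                            expected.add((fam, (j, m, lag, t)))
        for fam, d in (("beta", self.beta), ("delta", self.delta)):
            for key in d:
                if (fam, key) not in expected:
                    v.append(f"{fam}{key}: not part of the spec")
        for fam, key in expected:
            d = self.beta if fam == "beta" else self.delta
            if key not in d:
                v.append(f"{fam}{key}: missing coefficient")
        for t in range(T):
            if not _is_symmetric_psd(self.psi_u[t]):
                v.append(f"psi_u[t{t + 1}]: not symmetric positive semi-definite")
        if not _is_symmetric_psd(self.psi_eta):
            v.append("psi_eta: not symmetric positive semi-definite")
        return v


def _is_symmetric_psd(a: np.ndarray, tol: float = 1e-10) -> bool:
    if not np.allclose(a, a.T, atol=1e-10):
        return False
    w = np.linalg.eigvalsh(0.5 * (a + a.T))
    return bool(w.min() >= -tol * max(1.0, abs(w.max())))


def params_template(spec: ModelSpec) -> ParameterSet:
    """A zero ParameterSet conforming to ``spec`` (identity covariances, unit loadings)."""
    T, k = spec.T, spec.k
    beta, delta = {}, {}
    for fam, d in (("beta", beta), ("delta", delta)):
        for j in range(k):
            own = spec.ar_order[j] if fam == "beta" else spec.ma_order[j]
            for lag in range(1, own + 1):
                for t in spec.occasions_for(fam, j, j, lag):
                    d[(j, j, lag, t)] = 0.0
            mat = spec.cl_order if fam == "beta" else spec.clma_order
            for m in range(k):
                if m == j:
                    continue
                for lag in range(1, int(mat[j, m]) + 1):
                    for t in spec.occasions_for(fam, j, m, lag):
                        d[(j, m, lag, t)] = 0.0
    return ParameterSet(
        alpha=np.zeros((T, k)),
        lam=np.ones((T, k)),
        beta=beta,
        delta=delta,
        psi_u=np.broadcast_to(np.eye(k), (T, k, k)).copy(),
        psi_eta=np.eye(k) * np.array(spec.unit_effects, dtype=float),
    )
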