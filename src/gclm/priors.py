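"""Prior system: diffuse defaults, small-variance ("Minnesota-style") normal
priors, and difference priors on time-varying coefficient groups.

A difference prior shrinks consecutive occasions of a time-varying family
toward *each other* without shrinking them toward zero.  Its joint form is a
zero-mean MVN over the group whose covariance has a diffuse diagonal ``d``
and off-diagonal ``d - v/2``, so that every pairwise difference has prior
variance ``v`` (e.g. d=1000, v=0.1 gives off-diagonal 999.95).  With the
default v=0.01 the prior places roughly 68% mass on parameter differences
within +/-0.1 of zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.stats import norm

from ._compile import CompiledModel, PriorArrays
from .model import ModelSpec, enumerate_slots

__all__ = ["Diffuse", "NormalPrior", "DifferencePrior", "PriorSpec",
           "prior_mass_within", "equivalent_mvn_form", "build_priors",
           "bayes1_config", "bayes2_config", "difference_shrinkage_config"]

_COEF_FAMILIES = ("alpha", "loading", "beta", "delta")


@dataclass(frozen=True)
class Diffuse:
    """The default coefficient prior N(0, 1e10)."""

    variance: float = 1e10


@dataclass(frozen=True)
class NormalPrior:
    mean: float
    variance: float


@dataclass(frozen=True)
class DifferencePrior:
    """Prior on consecutive-occasion differences of a time-varying group."""

    variance: float
    diffuse_variance: float = 1000.0


def prior_mass_within(prior, halfwidth: float) -> float:
    """Prior probability mass inside [-halfwidth, +halfwidth].

    For a :class:`DifferencePrior` the mass refers to the implied
    distribution of each consecutive parameter difference.
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be > 0")
    if isinstance(prior, DifferencePrior):
        mean, var = 0.0, prior.variance
    elif isinstance(prior, (NormalPrior, Diffuse)):
        mean = getattr(prior, "mean", 0.0)
        var = prior.variance
    else:
        raise TypeError(f"unsupported prior type: {type(prior).__name__}")
    sd = np.sqrt(var)
    return float(norm.cdf((halfwidth - mean) / sd) - norm.cdf((-halfwidth - mean) / sd))


def equivalent_mvn_form(n: int, d: float, v: float) -> np.ndarray:
    """The MVN covariance equivalent of a difference prior over ``n`` parameters.

    Diagonal ``d`` (diffuse marginals), off-diagonal ``d - v/2``, so that
    every pairwise difference has prior variance ``v``.  Requires
    ``d > v/2 > 0`` (positive definiteness).
    """
    if not (v > 0 and d > v / 2):
        raise ValueError(f"require d > v/2 > 0, got d={d}, v={v}")
    cov = np.full((n, n), d - v / 2.0)
    np.fill_diagonal(cov, d)
    return cov


@dataclass
class PriorSpec:
    """Resolved priors: per-parameter entries plus difference-prior groups.

    ``normal`` maps free-parameter names to :class:`NormalPrior`;
    ``groups`` lists (ordered name tuple, :class:`DifferencePrior`).
    All unmentioned coefficients are :class:`Diffuse`; covariance-block
    parameters keep the package's weakly-informative scale priors.
    """

    normal: dict = field(default_factory=dict)
    groups: list = field(default_factory=list)

    def describe(self, theta_names) -> dict:
        """Map every free parameter to its prior (exactly one each)."""
        out = {n: Diffuse() for n in theta_names}
        grouped = set()
        for names, dp in self.groups:
            for n in names:
                out[n] = dp
                grouped.add(n)
        for n, pr in self.normal.items():
            out[n] = pr
        return out

    def compile(self, cm: CompiledModel) -> PriorArrays:
        """Lower to the flat arrays consumed by the sampling kernels."""
        arrays = cm.default_priors()
        index = {n: i for i, n in enumerate(cm.theta_names)}
        fams = {n: p.family for n, p in zip(cm.theta_names, cm.thetas)}
        claimed = set()

        def _idx(name):
            if name not in index:
                raise KeyError(f"prior assigned to non-existent parameter: {name}")
            if fams[name] not in _COEF_FAMILIES:
                raise ValueError(f"priors are only supported on coefficients, not {name}")
            if name in claimed:
                raise ValueError(f"parameter has more than one prior: {name}")
            claimed.add(name)
            return index[name]

        grp_ptr, grp_idx, grp_pptr, grp_prec = [0], [], [0], []
        for names, dp in self.groups:
            ids = [_idx(n) for n in names]
            prec = np.linalg.inv(
                equivalent_mvn_form(len(ids), dp.diffuse_variance, dp.variance))
            for i in ids:
                arrays.prior_prec[i] = 0.0   # the group MVN replaces the diffuse term
            grp_idx.extend(ids)
            grp_ptr.append(len(grp_idx))
            grp_prec.extend(prec.ravel().tolist())
            grp_pptr.append(len(grp_prec))
        for name, pr in self.normal.items():
            i = _idx(name)
            arrays.prior_prec[i] = 1.0 / pr.variance
            arrays.prior_mean[i] = pr.mean
        arrays.grp_ptr = np.asarray(grp_ptr, dtype=np.int64)
        arrays.grp_idx = np.asarray(grp_idx, dtype=np.int64)
        arrays.grp_pptr = np.asarray(grp_pptr, dtype=np.int64)
        arrays.grp_prec = np.asarray(grp_prec, dtype=float)
        return arrays


def _theta_catalog(spec: ModelSpec):
    _, thetas = enumerate_slots(spec)
    return thetas


def build_priors(spec: ModelSpec, prior_config=None) -> PriorSpec:
    """Resolve a prior config against a spec.

    Config structure (dict or YAML file content)::

        difference:
          - {family: beta, target: income, source: income, lag: 1, variance: 0.01}
          - {family: loading, target: swb, variance: 0.01}
        normal:
          - {family: delta, target: income, source: income, lag: 2,
             mean: 0, variance: 0.01, occasions: all}
          - {family: loading, target: income, occasions: "t>1",
             mean: 0, variance: 0.01}

    A ``difference`` entry requires the named family to be time-varying (one
    free coefficient per occasion); the matched parameters, ordered by
    occasion, form one difference-prior group.  All other free coefficients
    get the diffuse default.  An empty config gives an all-diffuse PriorSpec.
    """
    if prior_config is None:
        return PriorSpec()
    if isinstance(prior_config, str):
        with open(prior_config) as fh:
            prior_config = yaml.safe_load(fh) or {}
    thetas = _theta_catalog(spec)

    def match(sel, want_group):
        fam = sel["family"]
        tgt = spec.var_index(sel["target"])
        src = spec.var_index(sel["source"]) if "source" in sel else -1
        lag = int(sel.get("lag", 0))
        occ = sel.get("occasions", "all")
        hits = []
        for p in thetas:
            if p.family != fam or p.target != tgt:
                continue
            if fam in ("beta", "delta") and (p.source != src or p.lag != lag):
                continue
            if occ == "t>1" and p.t != -1 and p.t <= 1:
                continue
            if isinstance(occ, (list, tuple)) and p.t not in occ:
                continue
            hits.append(p)
        if not hits:
            raise KeyError(f"prior selector matched no free parameter: {sel}")
        if want_group:
            if any(p.t < 0 for p in hits) or len(hits) < 2:
                raise ValueError(
                    f"difference prior requires a time-varying group: {sel}")
            hits.sort(key=lambda p: p.t)
        return hits

    out = PriorSpec()
    for sel in prior_config.get("difference", []) or []:
        hits = match(sel, want_group=True)
        out.groups.append((
            tuple(p.name for p in hits),
            DifferencePrior(variance=float(sel.get("variance", 0.01)),
                            diffuse_variance=float(sel.get("diffuse_variance", 1000.0))),
        ))
    for sel in prior_config.get("normal", []) or []:
        for p in match(sel, want_group=False):
            out.normal[p.name] = NormalPrior(mean=float(sel.get("mean", 0.0)),
                                             variance=float(sel.get("variance", 0.01)))
    return out


# ---------------------------------------------------------------------------
# Shrinkage presets
# ---------------------------------------------------------------------------

def difference_shrinkage_config(spec: ModelSpec, variance=0.01,
                                mean_stationary_loadings=(), null_loadings=(),
                                null_coefficients=()) -> dict:
    """Config with difference priors N(0, variance) on every time-varying
    AR/MA/CL/CLMA family.

    ``mean_stationary_loadings``: variables whose loading differences get the
    same difference prior (operationalizing mean-stationarity of the unit
    effect).  ``null_loadings``: variables whose post-first loadings get a
    null N(0, variance) prior (betting against unit effects).
    ``null_coefficients``: (family, target, source, lag) tuples whose
    per-occasion coefficients get a null N(0, variance) prior instead of a
    difference prior (lag-order reduction).
    """
    cfg = {"difference": [], "normal": []}
    names = spec.variable_names
    nulls = {(f, spec.var_index(t), spec.var_index(s), lag)
             for f, t, s, lag in null_coefficients}

    def handle(family, tgt, src, order, tv):
        for lag in range(1, order + 1):
            sel = {"family": family, "target": names[tgt], "source": names[src],
                   "lag": lag, "variance": variance}
            if (family, tgt, src, lag) in nulls:
                cfg["normal"].append({**sel, "mean": 0.0})
            elif tv:
                cfg["difference"].append(sel)

    for j in range(spec.k):
        handle("beta", j, j, spec.ar_order[j], spec.time_varying.ar)
        handle("delta", j, j, spec.ma_order[j], spec.time_varying.ma)
        for m in range(spec.k):
            if m != j:
                handle("beta", j, m, int(spec.cl_order[j, m]), spec.time_varying.cl)
                handle("delta", j, m, int(spec.clma_order[j, m]), spec.time_varying.clma)
    for v in mean_stationary_loadings:
        cfg["difference"].append({"family": "loading", "target": v, "variance": variance})
    for v in null_loadings:
        cfg["normal"].append({"family": "loading", "target": v, "mean": 0.0,
                              "variance": variance})
    return cfg


def bayes1_config(spec: ModelSpec, variance=0.01) -> dict:
    """The reference shrinkage system for the income/SWB time-varying model:
    difference priors on all nine time-varying coefficient families, a
    mean-stationarity difference prior on the SWB loadings, and null
    loadings priors for income."""
    return difference_shrinkage_config(
        spec, variance=variance,
        mean_stationary_loadings=("swb",), null_loadings=("income",))


def bayes2_config(spec: ModelSpec, variance=0.01) -> dict:
    """As :func:`bayes1_config` but with the second-order income MA terms
    shrunk toward zero (null prior) rather than toward each other."""
    return difference_shrinkage_config(
        spec, variance=variance,
        mean_stationary_loadings=("swb",), null_loadings=("income",),
        null_coefficients=(("delta", "income", "income", 2),))
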