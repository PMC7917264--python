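"""Result serialization: JSON for fit summaries, CSV for posterior draws,
JSON for parameter sets.

Every results file carries a ``schema_version``, the package version, the
seed used, and a ``kind`` tag so readers can dispatch without guessing.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .bayes import PosteriorDraws, convergence_report, dic, summarize
from .ml import MLResult
from .model import ModelSpec, ParameterSet, params_template

__all__ = ["write_results", "read_results", "write_draws_csv",
           "read_draws_csv", "params_to_dict", "params_from_dict",
           "write_params_json", "read_params_json"]

SCHEMA_VERSION = 1


def _version() -> str:
    from . import __version__
    return __version__


# ---------------------------------------------------------------------------
# Parameter sets
# ---------------------------------------------------------------------------

def params_to_dict(params: ParameterSet) -> dict:
    """JSON-safe dict; beta/delta keys become "target,source,lag,t" strings."""
    return {
        "alpha": params.alpha.tolist(),
        "lam": params.lam.tolist(),
        "beta": {",".join(map(str, k)): float(v) for k, v in params.beta.items()},
        "delta": {",".join(map(str, k)): float(v) for k, v in params.delta.items()},
        "psi_u": params.psi_u.tolist(),
        "psi_eta": params.psi_eta.tolist(),
    }


def params_from_dict(d: dict, spec: ModelSpec) -> ParameterSet:
    params = params_template(spec)
    params.alpha[:] = np.asarray(d["alpha"], dtype=float)
    params.lam[:] = np.asarray(d["lam"], dtype=float)
    params.psi_u[:] = np.asarray(d["psi_u"], dtype=float)
    params.psi_eta[:] = np.asarray(d["psi_eta"], dtype=float)
    for fam, store in (("beta", params.beta), ("delta", params.delta)):
        store.clear()
        for key, v in d.get(fam, {}).items():
            j, m, lag, t = (int(x) for x in key.split(","))
            store[(j, m, lag, t)] = float(v)
    return params


def write_params_json(params: ParameterSet, path) -> None:
    with open(path, "w") as fh:
        json.dump({"schema_version": SCHEMA_VERSION, "kind": "params",
                   "version": _version(), "params": params_to_dict(params)},
                  fh, indent=1)


def read_params_json(path, spec: ModelSpec) -> ParameterSet:
    with open(path) as fh:
        d = json.load(fh)
    if d.get("kind") != "params":
        raise ValueError(f"not a params file: kind={d.get('kind')!r}")
    return params_from_dict(d["params"], spec)


# ---------------------------------------------------------------------------
# Fit results
# ---------------------------------------------------------------------------

def _ml_payload(res: MLResult) -> dict:
    names, values = res.compiled.structural(res.theta)
    return {
        "estimates": dict(zip(names, map(float, values))),
        "standard_errors": {k: float(v) for k, v in res.standard_errors.items()},
        "loglik": res.loglik, "aic": res.aic, "bic": res.bic,
        "n_free": res.n_free, "n_units": res.n_units,
        "converged": res.converged, "gradient_norm": res.gradient_norm,
        "theta": res.theta.tolist(), "theta_names": list(res.theta_names),
    }


def _bayes_payload(draws: PosteriorDraws) -> dict:
    summ = summarize(draws)
    rep = convergence_report(draws)
    fi = dic(draws)
    return {
        "summary": summ.reset_index().rename(columns={"index": "parameter"})
                       .to_dict(orient="records"),
        "psr_max": rep.max_psr, "psr_pass": rep.psr_pass, "ks_pass": rep.ks_pass,
        "dic": fi.dic, "pd": fi.pd, "mean_deviance": fi.mean_deviance,
        "n_chains": draws.n_chains, "n_retained": draws.n_retained,
        "thin": draws.thin, "accept_rates": list(map(float, draws.accept_rates)),
    }


def write_results(result, path, seed=None, extra=None) -> None:
    """Write an MLResult / PosteriorDraws / plain dict as a JSON results file."""
    if isinstance(result, MLResult):
        kind, payload = "ml", _ml_payload(result)
    elif isinstance(result, PosteriorDraws):
        kind, payload = "bayes", _bayes_payload(result)
        seed = result.seed if seed is None else seed
    elif isinstance(result, dict):
        kind, payload = "generic", result
    else:
        raise TypeError(f"unsupported result type: {type(result).__name__}")
    doc = {"schema_version": SCHEMA_VERSION, "kind": kind,
           "version": _version(), "seed": seed, "results": payload}
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, default=float)


def read_results(path) -> dict:
    """Read a results JSON file, validating the schema version."""
    with open(path) as fh:
        doc = json.load(fh)
    sv = doc.get("schema_version")
    if sv != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version {sv!r} "
                         f"(this package reads {SCHEMA_VERSION})")
    return doc


# ---------------------------------------------------------------------------
# Posterior draws
# ---------------------------------------------------------------------------

def write_draws_csv(draws: PosteriorDraws, path) -> None:
    """Store retained draws as CSV with chain and iteration columns."""
    C, n, d = draws.draws.shape
    df = pd.DataFrame(draws.draws.reshape(C * n, d), columns=draws.theta_names)
    df.insert(0, "iteration", np.tile(np.arange(n), C))
    df.insert(0, "chain", np.repeat(np.arange(C), n))
    df.to_csv(path, index=False)


def read_draws_csv(path, compiled=None, thin: int = 0, seed: int = 0) -> PosteriorDraws:
    """Rebuild a PosteriorDraws from CSV (chain structure preserved).

    Pass the matching ``CompiledModel`` as ``compiled`` to re-enable the
    methods that need the likelihood (structural summaries, DIC, PPP).
    """
    df = pd.read_csv(path)
    for col in ("chain", "iteration"):
        if col not in df.columns:
            raise ValueError(f"draws file is missing the '{col}' column")
    names = [c for c in df.columns if c not in ("chain", "iteration")]
    chains = sorted(df["chain"].unique())
    per = [df[df["chain"] == c].sort_values("iteration")[names].to_numpy()
           for c in chains]
    n = min(arr.shape[0] for arr in per)
    arr = np.stack([a[:n] for a in per])
    if compiled is not None and list(compiled.theta_names) != names:
        raise ValueError("draws file parameters do not match the compiled model")
    return PosteriorDraws(arr, names, thin, seed, accept_rates=[],
                          compiled=compiled)
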