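"""First-order variance-based sensitivity indices.

For a scalar model output Y and a parameter X_i with independent uniform
priors on all parameters, the first-order index is

    S_i = Var(E[Y | X_i]) / Var(Y),

estimated by a double Monte-Carlo loop: outer draws fix X_i, inner draws
vary all other parameters; the variance of the inner means over the outer
draws is divided by the total variance from a joint sample.

Priors are uniform and centred on the nominal value; the default spread
rule sets the standard deviation to 10 % of the nominal (half-width
``0.1 * sqrt(3) * |nominal|``), which keeps every support on one side of
zero.  Zero nominals give degenerate (constant) priors.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from math import sqrt
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .bone import remodeling_balance, simulate_fracture
from .cellular import CellularState, simulate_cellular
from .multiscale import CouplingSchedule, quasi_steady_influx
from .parameters import ParameterSet, default_initial_state
from .tissue import simulate_tissue

logger = logging.getLogger(__name__)

__all__ = [
    "Prior",
    "SensitivityResult",
    "first_order_index",
    "lsa_report",
]

_SQRT3 = sqrt(3.0)


@dataclass(frozen=True)
class Prior:
    """Uniform prior for one scalar parameter.

    ``rule`` maps the nominal value to a half-width:

    - ``sd10``: standard deviation 10 % of the nominal (default),
    - ``var10``: variance ``0.1 * |nominal|``,
    - ``halfwidth10``: half-width 10 % of the nominal.
    """

    name: str
    nominal: float
    rule: str = "sd10"

    def half_width(self) -> float:
        a = abs(self.nominal)
        if self.rule == "sd10":
            return 0.1 * a * _SQRT3
        if self.rule == "var10":
            return sqrt(3.0 * 0.1 * a)
        if self.rule == "halfwidth10":
            return 0.1 * a
        raise ValueError(f"unknown prior rule {self.rule!r}")

    def support(self) -> tuple[float, float]:
        hw = self.half_width()
        return self.nominal - hw, self.nominal + hw

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        lo, hi = self.support()
        if lo == hi:
            return np.full(size, self.nominal)
        return rng.uniform(lo, hi, size)

    def variance(self) -> float:
        hw = self.half_width()
        return hw * hw / 3.0


@dataclass(frozen=True)
class SensitivityResult:
    parameter: str
    output: str
    S: float
    se: float
    n_outer: int
    n_inner: int
    seed: int


def first_order_index(
    model_fn: Callable[[dict[str, float]], float],
    target: str,
    priors: Sequence[Prior],
    n_outer: int,
    n_inner: int,
    seed: int,
    output_name: str = "Y",
) -> SensitivityResult:
    """Estimate ``S_target = Var(E[Y | X_target]) / Var(Y)``.

    ``model_fn`` maps a full parameter dictionary to a scalar and must be
    deterministic.  Small negative estimates are clamped to zero (logged);
    the standard error is a delete-one jackknife over the outer draws.
    """
    if n_outer < 2 or n_inner < 2:
        raise ValueError("n_outer and n_inner must both be >= 2")
    priors = list(priors)
    names = [p.name for p in priors]
    if target not in names:
        raise ValueError(f"no prior declared for target parameter {target!r}")
    rng = np.random.default_rng(seed)

    # total variance from a joint sample
    joint = {p.name: p.sample(rng, n_outer * n_inner) for p in priors}
    y_joint = np.array(
        [model_fn({k: v[j] for k, v in joint.items()})
         for j in range(n_outer * n_inner)]
    )
    var_total = float(np.var(y_joint, ddof=1))
    if var_total == 0.0:
        raise ZeroDivisionError("total output variance is zero; index undefined")

    target_prior = priors[names.index(target)]
    outer = target_prior.sample(rng, n_outer)
    cond_means = np.empty(n_outer)
    for i, x in enumerate(outer):
        inner = {p.name: p.sample(rng, n_inner) for p in priors if p.name != target}
        ys = np.empty(n_inner)
        for j in range(n_inner):
            args = {k: v[j] for k, v in inner.items()}
            args[target] = x
            ys[j] = model_fn(args)
        cond_means[i] = ys.mean()
    s = float(np.var(cond_means, ddof=1) / var_total)

    # delete-one jackknife on the outer loop
    jack = np.array(
        [np.var(np.delete(cond_means, i), ddof=1) / var_total
         for i in range(n_outer)]
    )
    se = float(sqrt(max(n_outer - 1, 1) * np.var(jack, ddof=0)))

    if s < 0.0:
        logger.info("clamping negative index %g to 0 for %s", s, target)
        s = 0.0
    return SensitivityResult(
        parameter=target, output=output_name, S=s, se=se,
        n_outer=n_outer, n_inner=n_inner, seed=seed,
    )


# ---------------------------------------------------------------------------
# model-level reports

CELLULAR_PARAMS = ("beta_sM(0)", "R_sM(0)", "r_syn", "r_sgn", "r_pc", "r_b", "r_u")
TISSUE_PARAMS = ("r_a", "r_d", "r_m", "p_Phi")
BONE_PARAMS = ("r_beta", "d_beta", "a_Lng", "a_Oc", "p_RKL", "r_Oc")

#: per-model observation times (cellular horizon [s], tissue [months],
#: bone [days]); configurable through the keyword arguments of lsa_report.
OBSERVATION = {"cellular": 4320.0, "tissue": 24.0, "bone": 200.0}


def _apply_overrides(params: ParameterSet, values: dict[str, float]) -> ParameterSet:
    """Return params with scalar or indexed-vector entries replaced."""
    updates: dict[str, object] = {}
    for key, val in values.items():
        if "(" in key:
            base, idx = key[:-1].split("(")
            vec = list(updates.get(base, getattr(params, base)))
            vec[int(idx)] = val
            updates[base] = tuple(vec)
        else:
            updates[key] = val
    return dataclasses.replace(params, **updates)


def _cellular_outputs(params: ParameterSet, t_obs: float) -> dict[str, float]:
    init = default_initial_state()
    n = int(params.Phi) + 1
    traj = simulate_cellular(
        CellularState.from_initial(init), np.array(init.N_neigh), params,
        np.linspace(0.0, t_obs, 51), rtol=1e-8, atol=1e-8,
    )
    end = traj.y[-1]
    out = {}
    for p in range(n):
        out[f"B_e({p})"] = end[p]
        out[f"R({p})"] = end[n + p]
        out[f"B_i({p})"] = end[2 * n + p]
    out["B_dr"] = end[3 * n]
    return out


def _tissue_outputs(params: ParameterSet, t_obs: float) -> dict[str, float]:
    init = default_initial_state()
    B_in = quasi_steady_influx(np.array(init.N_neigh), params,
                               CouplingSchedule())
    traj = simulate_tissue(np.array(init.N_neigh), B_in, params,
                           np.linspace(0.0, t_obs, 25))
    end = traj.y[-1]
    return {f"N({p})": end[p] for p in range(int(params.Phi) + 1)}


def _bone_outputs(params: ParameterSet, t_obs: float) -> dict[str, float]:
    traj = simulate_fracture(params, horizon_days=t_obs, step=0.05, n_out=101)
    end = traj.y[-1]
    out = dict(zip(traj.columns, end))
    out["balance"] = remodeling_balance(traj)
    return out


_MODEL_OUTPUTS = {
    "cellular": _cellular_outputs,
    "tissue": _tissue_outputs,
    "bone": _bone_outputs,
}

_MODEL_PARAMS = {
    "cellular": CELLULAR_PARAMS,
    "tissue": TISSUE_PARAMS,
    "bone": BONE_PARAMS,
}


def _nominal(params: ParameterSet, key: str) -> float:
    if "(" in key:
        base, idx = key[:-1].split("(")
        return float(getattr(params, base)[int(idx)])
    return float(getattr(params, key))


def lsa_report(
    model: str,
    outputs: Sequence[str],
    n_outer: int,
    n_inner: int,
    seed: int,
    params: ParameterSet | None = None,
    parameters: Sequence[str] | None = None,
    rule: str = "sd10",
    t_obs: float | None = None,
) -> pd.DataFrame:
    """First-order indices for every (parameter, output) pair of one model.

    ``model`` is ``cellular``, ``tissue`` or ``bone``; outputs are state
    names at the model's observation time.  Returns a long-format frame
    with columns (model, output, parameter, S, se).
    """
    if model not in _MODEL_OUTPUTS:
        raise ValueError(f"unknown model {model!r}")
    params = params if params is not None else ParameterSet()
    pnames = tuple(parameters) if parameters is not None else _MODEL_PARAMS[model]
    t_obs = t_obs if t_obs is not None else OBSERVATION[model]
    priors = [Prior(nm, _nominal(params, nm), rule) for nm in pnames]

    cache: dict[tuple, dict[str, float]] = {}

    def evaluate(values: dict[str, float]) -> dict[str, float]:
        key = tuple(sorted(values.items()))
        if key not in cache:
            cache[key] = _MODEL_OUTPUTS[model](_apply_overrides(params, values), t_obs)
        return cache[key]

    rows = []
    for k, output in enumerate(outputs):
        def fn(values: dict[str, float], _o=output) -> float:
            return evaluate(values)[_o]

        for j, prior in enumerate(priors):
            res = first_order_index(
                fn, prior.name, priors, n_outer, n_inner,
                seed + 1000 * j, output_name=output,
            )
            rows.append({"model": model, "output": output,
                         "parameter": prior.name, "S": res.S, "se": res.se})
    return pd.DataFrame(rows)
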