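"""Phenotype-structured population dynamics of the mammary duct.

The average number of cells ``N(phi)`` per neighbour volume evolves under
capacity-limited proliferation and apoptosis, both modulated by the
TGF-beta flux entering the cell through a power-law response factor,
first-order degradation, a stepwise mutation channel (phenotype index only
ever increases) and a direct-to-malignant channel during proliferation.

The response factor ``(gamma * B_in / alpha) ** g`` phenomenologically
encodes a cascade of serial signal-amplification mechanisms: healthy cells
(large positive sensing exponent) are growth-arrested and apoptosis-primed
by TGF-beta, while the malignant phenotype (negative exponent) has the
response inverted - TGF-beta turns from tumor suppressor into tumor
promoter.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .parameters import ParameterSet
from .trajectory import Trajectory

__all__ = [
    "response_factor",
    "tissue_rhs",
    "simulate_tissue",
    "phenotype_fraction",
    "SECONDS_PER_MONTH",
]

SECONDS_PER_DAY = 86400.0
SECONDS_PER_MONTH = 30.4375 * SECONDS_PER_DAY  # mean Gregorian month

#: floor on the dimensionless signal, guarding 0**negative (not biology)
SIGNAL_FLOOR = 1e-12


def response_factor(
    B_in: float | np.ndarray,
    g: float | np.ndarray,
    gamma: float = 1.0,
    alpha: float = 1.0,
    floor: float = SIGNAL_FLOOR,
) -> np.ndarray:
    """Dimensionless modulation ``(gamma * B_in / alpha) ** g``.

    Equals 1 when ``g = 0`` or when the scaled signal is 1; increasing in
    ``B_in`` iff ``g > 0``.  The scaled signal is floored at ``floor`` to
    keep negative exponents finite at zero influx.
    """
    B_in = np.asarray(B_in, dtype=float)
    if np.any(B_in < 0.0):
        raise ValueError("TGF-beta influx must be non-negative")
    x = np.maximum(gamma * B_in / alpha, floor)
    return x ** np.asarray(g, dtype=float)


def tissue_rhs(
    state: np.ndarray,
    B_in: np.ndarray,
    params: ParameterSet,
) -> np.ndarray:
    """Time derivative [cells/s] of the per-phenotype population vector.

    Per phenotype ``f`` (with total ``T = sum(N)`` and Kronecker deltas
    restricting mutation below the malignant ceiling)::

        prolif(f) = r_p(f) * x(f)**(-g_p(f)) * N(f) * (1 - T / C(f))
        death(f)  = (r_a * x(f)**g_a(f) + r_d) * N(f)
        dN(f)/dt  = (1 - p_Phi*(f < Phi)) * prolif(f)
                    + (f == Phi) * p_Phi * sum(prolif(:Phi))
                    - death(f)
                    - r_m * N(f) * (f < Phi) + r_m * N(f-1) * (f > 0)

    where ``x(f)`` is the scaled TGF-beta influx.  A fraction ``p_Phi`` of
    every proliferation term below the ceiling is rerouted directly to the
    malignant class (mutation during division); proliferation with a
    negative net rate reroutes with its sign, keeping the bookkeeping an
    exact redistribution of the proliferation fluxes.
    """
    N = np.maximum(np.asarray(state, dtype=float), 0.0)
    n = int(params.Phi) + 1
    if len(N) != n:
        raise ValueError(f"state must have length Phi+1={n}")
    r_p = np.asarray(params.r_p)
    g_p = np.asarray(params.g_p)
    g_a = np.asarray(params.g_a)
    C = np.asarray(params.C)
    total = N.sum()

    fac_p = response_factor(B_in, -g_p, params.gamma, params.alpha)
    fac_a = response_factor(B_in, g_a, params.gamma, params.alpha)
    prolif = r_p * fac_p * N * (1.0 - total / C)
    death = (params.r_a * fac_a + params.r_d) * N

    below = np.ones(n)
    below[-1] = 0.0  # the malignant ceiling neither mutates nor reroutes
    dN = (1.0 - params.p_Phi * below) * prolif - death
    dN[-1] += params.p_Phi * prolif[:-1].sum()
    dN -= params.r_m * N * below
    dN[1:] += params.r_m * N[:-1]
    return dN


def simulate_tissue(
    init: np.ndarray,
    resp: np.ndarray | Callable[[float], np.ndarray],
    params: ParameterSet,
    t_grid_months: np.ndarray,
    rtol: float = 1e-10,
    atol: float = 1e-18,
) -> Trajectory:
    """Integrate the tissue model; the grid and output times are in months.

    ``resp`` is either a fixed per-phenotype TGF-beta influx vector
    [nmol/s] or a callable of time (seconds) returning one, which is how
    the multi-scale driver feeds re-equilibrated cellular averages.
    Tight absolute tolerance is required because the malignant class is
    seeded through fluxes many orders of magnitude below one cell.
    """
    t_grid_months = np.asarray(t_grid_months, dtype=float)
    if t_grid_months.ndim != 1 or np.any(np.diff(t_grid_months) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    resp_fn = resp if callable(resp) else (lambda t, v=np.asarray(resp, float): v)
    t_sec = t_grid_months * SECONDS_PER_MONTH
    sol = solve_ivp(
        lambda t, y: tissue_rhs(y, resp_fn(t), params),
        (t_sec[0], t_sec[-1]),
        np.asarray(init, dtype=float),
        t_eval=t_sec,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"tissue integration failed at t={sol.t[-1] / SECONDS_PER_MONTH} months:"
            f" {sol.message}"
        )
    y = sol.y.T
    # The malignant-jump term reroutes a *signed* share of net
    # proliferation, so classes whose net seeding flux is still negative
    # carry a transiently negative population of integrator scale
    # (~1e-6 cells).  That signed buffer is part of the mean-field
    # dynamics and is kept in the state; its magnitude is recorded.
    undershoot = float(np.abs(np.minimum(y, 0.0)).max())
    n = int(params.Phi) + 1
    return Trajectory(
        t=t_grid_months,
        y=y,
        columns=[f"N({p})" for p in range(n)],
        units=["1/V_neigh"] * n,
        time_unit="month",
        meta={"model": "tissue", "undershoot": undershoot},
    )


def phenotype_fraction(traj: Trajectory, phi: int, t: float) -> float:
    """Fraction ``N(phi, t) / sum_psi N(psi, t)`` at time ``t`` [months]."""
    state = traj.at(t)
    total = state.sum()
    if total <= 0.0:
        raise ZeroDivisionError("phenotype fraction undefined: total population is zero")
    return float(state[phi] / total)
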