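"""Intracellular Smad pathway: eight-variable mass-action ODE system.

Free TGF-beta ligand binds an inactive membrane receptor; the
ligand-receptor complex phosphorylates cytoplasmic Smad (consuming the
complex, which is how internalized ligand is drained); phosphorylated Smad
translocates to the nucleus, where a constant pool of phosphatase
dephosphorylates it; nuclear phospho-Smad drives target-gene transcription.

Without synthesis or degradation the Smad material
``S_c + pS_c + pS_n + S_n`` is conserved, and the only fixed point
compatible with the ligand-depletion experiments has both the free ligand
and the active receptor at zero, with the nuclear species and the mRNA
converging to initial-condition-dependent stationary values.

The multi-scale model only needs the order-reduced decay rate of
internalized ligand: holding cytoplasmic Smad at a constant ``S_c0``, the
phosphorylation drain collapses to the first-order rate
``r_sgn = k_phos * S_c0`` (:func:`reduce_model`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .trajectory import Trajectory

__all__ = [
    "SmadState",
    "SmadRates",
    "DEFAULT_S_C0",
    "smad_rhs",
    "simulate_smad",
    "reduce_model",
]

STATE_NAMES = ["B", "R_in", "R_act", "S_c", "pS_c", "pS_n", "S_n", "m"]
STATE_UNITS = ["nmol"] * 7 + ["a.u."]

#: cytoplasmic Smad level held constant in the order reduction [nmol].
#: Chosen large relative to the receptor pool, consistent with the
#: abundance argument that justifies freezing S_c.
DEFAULT_S_C0 = 100.0


@dataclass(frozen=True)
class SmadState:
    """Concentrations of the eight pathway species [nmol; mRNA in a.u.]."""

    B: float = 2.0
    R_in: float = 2.0
    R_act: float = 0.0
    S_c: float = DEFAULT_S_C0
    pS_c: float = 0.0
    pS_n: float = 0.0
    S_n: float = 0.0
    m: float = 0.0

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.B, self.R_in, self.R_act, self.S_c,
             self.pS_c, self.pS_n, self.S_n, self.m]
        )


@dataclass(frozen=True)
class SmadRates:
    """Mass-action rate constants of the pathway.

    ``k_phos * S_c0`` reproduces the published reduced signaling rate
    ``r_sgn = 0.003018 1/s`` at the defaults.  The nuclear phosphatase
    level ``P`` is a constant of the run, not a dynamical variable.
    """

    k_act: float = 0.0074      # ligand-receptor activation [1/(nmol s)]
    k_phos: float = 3.018e-5   # Smad phosphorylation by the complex [1/(nmol s)]
    k_t: float = 5.63e-3       # cytoplasm-to-nucleus translocation [1/s]
    k_dephos: float = 6.57e-3  # nuclear dephosphorylation [1/(nmol s)]
    k_transcr: float = 1.0e-4  # transcription by nuclear phospho-Smad [1/s]
    P: float = 1.0             # nuclear phosphatase pool [nmol]

    def __post_init__(self) -> None:
        for name in ("k_act", "k_phos", "k_t", "k_dephos", "k_transcr", "P"):
            if not (getattr(self, name) >= 0.0):
                raise ValueError(f"{name} must be >= 0")


def smad_rhs(state: SmadState | np.ndarray, rates: SmadRates) -> np.ndarray:
    """Time derivatives of the eight species under mass action."""
    y = state.as_vector() if isinstance(state, SmadState) else np.asarray(state, float)
    if np.any(y < 0.0):
        raise ValueError("negative concentrations are outside the model domain")
    B, R_in, R_act, S_c, pS_c, pS_n, S_n, m = y
    bind = rates.k_act * B * R_in
    phos = rates.k_phos * R_act * S_c
    trans = rates.k_t * pS_c
    deph = rates.k_dephos * rates.P * pS_n
    return np.array([
        -bind,                 # B
        -bind,                 # R_in
        bind - phos,           # R_act (consumed handing ligand to Smad)
        -phos,                 # S_c
        phos - trans,          # pS_c
        trans - deph,          # pS_n
        deph,                  # S_n
        rates.k_transcr * pS_n,  # m
    ])


def simulate_smad(
    init: SmadState,
    rates: SmadRates,
    t_grid: np.ndarray,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> Trajectory:
    """Integrate the pathway on a strictly increasing time grid [s]."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    sol = solve_ivp(
        lambda t, y: smad_rhs(np.maximum(y, 0.0), rates),
        (t_grid[0], t_grid[-1]),
        init.as_vector(),
        t_eval=t_grid,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"Smad integration failed at t={sol.t[-1]}: {sol.message}")
    y = np.maximum(sol.y.T, 0.0)
    return Trajectory(
        t=t_grid, y=y, columns=list(STATE_NAMES), units=list(STATE_UNITS),
        time_unit="s", meta={"model": "smad"},
    )


def reduce_model(rates: SmadRates, s_c0: float = DEFAULT_S_C0) -> float:
    """First-order decay rate of internalized ligand with Smad held constant.

    With cytoplasmic Smad frozen at ``s_c0`` the phosphorylation drain on
    the active complex becomes linear, ``dR_act/dt = ... - (k_phos*s_c0) *
    R_act``; the collapsed rate is the cellular model's ``r_sgn``.
    """
    if s_c0 < 0:
        raise ValueError("s_c0 must be >= 0")
    return rates.k_phos * s_c0
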