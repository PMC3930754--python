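"""Per-phenotype TGF-beta production, binding and paracrine exchange.

Each phenotype class ``phi = 0..Phi`` is represented by an average cell
with extracellular ligand ``B_e``, membrane receptors ``R`` and
internalized receptor-ligand complex ``B_i``; a single shared pool ``B_dr``
holds the ligand in the diffusive region through which all neighbour cells
exchange paracrinely.  Healthy cells (``phi = 0``) additionally
ubiquitinate internalized ligand at rate ``r_u``.

The paracrine rate is a Fick's-law discretization over the effective
exchange geometry (:func:`derive_paracrine_rate`); the return flux from the
diffusive region is split equally over all neighbour cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .parameters import ParameterSet
from .trajectory import Trajectory

__all__ = [
    "CellularState",
    "ParacrineGeometry",
    "derive_paracrine_rate",
    "cellular_rhs",
    "simulate_cellular",
    "internalized_summary",
    "monotone_decreasing_flags",
]


@dataclass(frozen=True)
class ParacrineGeometry:
    """Effective geometry of the inter-membrane exchange region."""

    D_eff: float   # effective diffusion coefficient in the ECM [um^2/s]
    S: float       # orthogonal exchange surface [um^2]
    d: float       # inter-membrane distance [um]
    V_dr: float    # diffusive-region volume [um^3]
    V_neigh: float = float("inf")  # neighbour volume [um^3]

    def __post_init__(self) -> None:
        for name in ("D_eff", "S", "d", "V_dr", "V_neigh"):
            if not (getattr(self, name) > 0.0):
                raise ValueError(f"{name} must be strictly positive")
        if not (self.V_dr < self.V_neigh):
            raise ValueError("diffusive region must be smaller than the neighbourhood")


def derive_paracrine_rate(geom: ParacrineGeometry) -> float:
    """Fick's-law paracrine rate ``r_pc = D_eff * S / (d * V_dr)`` [1/s]."""
    return geom.D_eff * geom.S / (geom.d * geom.V_dr)


@dataclass
class CellularState:
    """Per-phenotype cellular species plus the shared diffusive pool."""

    B_e: np.ndarray
    R: np.ndarray
    B_i: np.ndarray
    B_dr: float

    def __post_init__(self) -> None:
        self.B_e = np.asarray(self.B_e, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self.B_i = np.asarray(self.B_i, dtype=float)
        if not (len(self.B_e) == len(self.R) == len(self.B_i)):
            raise ValueError("phenotype vectors must share a length")

    @property
    def n_phenotypes(self) -> int:
        return len(self.B_e)

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.B_e, self.R, self.B_i, [self.B_dr]])

    @classmethod
    def from_vector(cls, y: np.ndarray, n: int) -> "CellularState":
        return cls(B_e=y[:n], R=y[n:2 * n], B_i=y[2 * n:3 * n], B_dr=y[3 * n])

    @classmethod
    def from_initial(cls, init) -> "CellularState":
        return cls(
            B_e=np.array(init.B_e), R=np.array(init.R),
            B_i=np.array(init.B_i), B_dr=init.B_dr,
        )


def state_names(n: int) -> tuple[list[str], list[str]]:
    names = (
        [f"B_e({p})" for p in range(n)]
        + [f"R({p})" for p in range(n)]
        + [f"B_i({p})" for p in range(n)]
        + ["B_dr"]
    )
    return names, ["nmol"] * len(names)


def cellular_rhs(
    state: CellularState | np.ndarray,
    N_neigh: np.ndarray,
    params: ParameterSet,
) -> np.ndarray:
    """Derivative vector ``[dB_e, dR, dB_i, dB_dr]`` at one instant.

    Per phenotype: synthesis sourced by the gene-expression levels, mass-
    action receptor binding, paracrine loss to and equal-share return from
    the diffusive region; internalized ligand drains into Smad signaling at
    ``r_sgn`` and, for healthy cells only, into ubiquitination at ``r_u``.
    """
    n = int(params.Phi) + 1
    if isinstance(state, CellularState):
        y = state.as_vector()
    else:
        y = np.asarray(state, dtype=float)
    if np.any(y < 0.0):
        raise ValueError("negative concentrations are outside the model domain")
    B_e, R, B_i, B_dr = y[:n], y[n:2 * n], y[2 * n:3 * n], y[3 * n]
    N_neigh = np.asarray(N_neigh, dtype=float)
    N_tot = N_neigh.sum()
    if params.r_pc > 0.0 and N_tot <= 0.0:
        raise ValueError("paracrine exchange requires at least one neighbour cell")

    beta_sM = np.asarray(params.beta_sM)
    R_sM = np.asarray(params.R_sM)
    bind = params.r_b * B_e * R
    back = params.r_pc * B_dr / N_tot if N_tot > 0 else 0.0
    ubiq = np.zeros(n)
    ubiq[0] = params.r_u * B_i[0]

    dB_e = params.r_syn * beta_sM - bind - params.r_pc * B_e + back
    dR = params.r_syn * R_sM - bind
    dB_i = bind - params.r_sgn * B_i - ubiq
    dB_dr = params.r_pc * float(N_neigh @ B_e) - params.r_pc * B_dr
    return np.concatenate([dB_e, dR, dB_i, [dB_dr]])


def simulate_cellular(
    init: CellularState,
    N_neigh: np.ndarray,
    params: ParameterSet,
    t_grid: np.ndarray,
    rtol: float = 1e-10,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the cellular model on a strictly increasing grid [s].

    Neighbour counts are held piecewise-constant over the run (quasi-static
    tissue).  The integrator is stiff-safe; the trajectory is clipped at
    zero (clip magnitude recorded in the metadata).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    n = int(params.Phi) + 1
    sol = solve_ivp(
        lambda t, y: cellular_rhs(np.maximum(y, 0.0), N_neigh, params),
        (t_grid[0], t_grid[-1]),
        init.as_vector(),
        t_eval=t_grid,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"cellular integration failed at t={sol.t[-1]}: {sol.message}"
        )
    y = sol.y.T
    clip = float(np.abs(np.minimum(y, 0.0)).max())
    names, units = state_names(n)
    return Trajectory(
        t=t_grid, y=np.maximum(y, 0.0), columns=names, units=units,
        time_unit="s",
        meta={"model": "cellular", "clip_magnitude": clip,
              "N_neigh": list(map(float, N_neigh))},
    )


def internalized_summary(traj: Trajectory, t: float) -> pd.DataFrame:
    """Per-phenotype table of (B_e, R, B_i) at time ``t``, sorted by severity."""
    state = traj.at(t)  # raises on t outside span
    n = (len(traj.columns) - 1) // 3
    return pd.DataFrame(
        {
            "phenotype": np.arange(n),
            "B_e": state[:n],
            "R": state[n:2 * n],
            "B_i": state[2 * n:3 * n],
        }
    )


def monotone_decreasing_flags(summary: pd.DataFrame) -> dict[str, bool]:
    """Whether each species column strictly decreases with phenotype severity.

    A monotone-decreasing receptor column is the signature of an
    anti-tumorigenic isoform: its expression drops as cellular
    aggressiveness rises.
    """
    return {
        col: bool(np.all(np.diff(summary[col].to_numpy()) < 0))
        for col in ("B_e", "R", "B_i")
    }
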