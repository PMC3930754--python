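"""Loose coupling between the cellular and tissue scales.

Cellular kinetics (rates of order 1e-3 to 1e2 per second) relax far faster
than tissue turnover (1e-8 to 1e-6 per second), so the two models are
coupled through averages: at each tissue step the cellular model is run to
quasi-steady state under the current tissue composition, the windowed
average of the Smad-bound influx ``r_sgn * B_i(phi)`` is handed to the
tissue model as its TGF-beta response input, and the tissue advances one
step with that influx frozen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cellular import CellularState, cellular_rhs, simulate_cellular
from .parameters import InitialState, ParameterSet, default_initial_state
from .tissue import SECONDS_PER_MONTH, simulate_tissue
from .trajectory import Trajectory

__all__ = [
    "CouplingSchedule",
    "quasi_steady_influx",
    "run_multiscale",
    "takeover_time",
]

SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class CouplingSchedule:
    """Timing of the cellular-tissue exchange.

    One month of tissue time per cellular re-equilibration by default; the
    cellular horizon of 0.05 day is roughly thirteen relaxation times of
    the internalized-ligand pool (1/r_sgn is about 330 s), and the influx
    is averaged over the last tenth of that horizon.
    """

    tissue_step: float = 30.4375        # [day]
    cellular_horizon: float = 0.05      # [day]
    averaging_window: float = 0.005     # [day]
    rhs_tolerance: float = 1e-3         # relative B_i drift per relaxation time

    def __post_init__(self) -> None:
        for name in ("tissue_step", "cellular_horizon", "averaging_window",
                     "rhs_tolerance"):
            if not (getattr(self, name) > 0.0):
                raise ValueError(f"{name} must be strictly positive")
        if self.averaging_window > self.cellular_horizon:
            raise ValueError("averaging window cannot exceed the cellular horizon")


def quasi_steady_influx(
    tissue_state: np.ndarray,
    params: ParameterSet,
    schedule: CouplingSchedule = CouplingSchedule(),
    init: InitialState | None = None,
) -> np.ndarray:
    """Per-phenotype TGF-beta influx ``r_sgn * <B_i>`` [nmol/s].

    Runs the cellular model under the (continuous, mean-field) neighbour
    counts of the current tissue state and averages the Smad-bound flux
    over the trailing window.  Non-convergence of the internalized pool at
    the horizon raises a warning and returns the last-window average.
    """
    # integrator-scale undershoots from the tissue model are not neighbours
    N_neigh = np.maximum(np.asarray(tissue_state, dtype=float), 0.0)
    if N_neigh.sum() <= 0.0:
        raise ValueError("influx requires a non-empty neighbourhood")
    init = init if init is not None else default_initial_state()
    horizon = schedule.cellular_horizon * SECONDS_PER_DAY
    n_grid = 201
    t_grid = np.linspace(0.0, horizon, n_grid)
    traj = simulate_cellular(
        CellularState.from_initial(init), N_neigh, params, t_grid
    )
    n = int(params.Phi) + 1
    B_i = traj.y[:, 2 * n:3 * n]

    # convergence audit: relative drift of the internalized pool per
    # signaling relaxation time (1/r_sgn) must be below tolerance
    end_rhs = cellular_rhs(traj.y[-1], N_neigh, params)[2 * n:3 * n]
    drift = np.abs(end_rhs) / np.maximum(np.abs(B_i[-1]), 1e-30)
    if params.r_sgn > 0 and np.any(drift / params.r_sgn > schedule.rhs_tolerance):
        warnings.warn(
            "cellular model not converged within the horizon; "
            "using last-window average",
            RuntimeWarning,
            stacklevel=2,
        )
    window = schedule.averaging_window * SECONDS_PER_DAY
    mask = t_grid >= (horizon - window)
    return params.r_sgn * B_i[mask].mean(axis=0)


def run_multiscale(
    params: ParameterSet,
    horizon_months: float,
    schedule: CouplingSchedule = CouplingSchedule(),
    init: InitialState | None = None,
    points_per_step: int = 32,
) -> Trajectory:
    """Advance the coupled tissue model over ``horizon_months``.

    Returns the tissue trajectory (time in months); the per-step influx
    vectors are recorded in ``meta['B_in']`` as (month, vector) pairs.
    Deterministic for fixed parameters and schedule.
    """
    if horizon_months < 0:
        raise ValueError("horizon must be >= 0")
    init = init if init is not None else default_initial_state()
    n = int(params.Phi) + 1
    N = np.array(init.N_neigh, dtype=float)

    step_months = schedule.tissue_step * SECONDS_PER_DAY / SECONDS_PER_MONTH
    t_out = [0.0]
    y_out = [N.copy()]
    b_in_log: list[tuple[float, list[float]]] = []
    t = 0.0
    while t < horizon_months - 1e-12:
        step = min(step_months, horizon_months - t)
        B_in = quasi_steady_influx(N, params, schedule, init)
        b_in_log.append((t, [float(b) for b in B_in]))
        grid = t + np.linspace(0.0, step, points_per_step + 1)
        seg = simulate_tissue(N, B_in, params, grid)
        t_out.extend(seg.t[1:])
        y_out.extend(seg.y[1:])
        N = seg.y[-1].copy()
        t += step
    return Trajectory(
        t=np.array(t_out),
        y=np.array(y_out),
        columns=[f"N({p})" for p in range(n)],
        units=["1/V_neigh"] * n,
        time_unit="month",
        meta={"model": "multiscale", "B_in": b_in_log,
              "tissue_step_day": schedule.tissue_step,
              "cellular_horizon_day": schedule.cellular_horizon},
    )


def takeover_time(traj: Trajectory, phi: int, threshold_fraction: float) -> float:
    """First time [months] the phenotype-``phi`` fraction reaches a threshold.

    Returns ``inf`` if the threshold is never reached within the span.
    """
    if not (0.0 <= threshold_fraction):
        raise ValueError("threshold must be non-negative")
    totals = traj.y.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, traj.y[:, phi] / totals, np.nan)
    above = frac >= threshold_fraction
    if not np.any(above):
        return float("inf")
    i = int(np.argmax(above))
    if i == 0:
        return float(traj.t[0])
    # linear interpolation across the crossing
    f0, f1 = frac[i - 1], frac[i]
    t0, t1 = traj.t[i - 1], traj.t[i]
    if not np.isfinite(f0) or f1 == f0:
        return float(t1)
    return float(t0 + (threshold_fraction - f0) / (f1 - f0) * (t1 - t0))
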