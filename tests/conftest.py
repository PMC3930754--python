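import numpy as np
import pytest

from tgfb_multiscale.parameters import (
    InitialState,
    ParameterSet,
    default_initial_state,
    default_parameters,
)


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    return default_parameters()


@pytest.fixture(scope="session")
def init() -> InitialState:
    return default_initial_state()


@pytest.fixture(scope="session")
def n_phen(params) -> int:
    return int(params.Phi) + 1


def rk4(rhs, y0, t_grid):
    """Independent fixed-step classical Runge-Kutta integrator (oracle)."""
    y = np.asarray(y0, dtype=float).copy()
    out = [y.copy()]
    for t0, t1 in zip(t_grid[:-1], t_grid[1:]):
        h = t1 - t0
        k1 = rhs(t0, y)
        k2 = rhs(t0 + h / 2, y + h / 2 * k1)
        k3 = rhs(t0 + h / 2, y + h / 2 * k2)
        k4 = rhs(t1, y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        out.append(y.copy())
    return np.array(out)
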