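"""Cellular exchange: Fick geometry, mass balance, steady states, summaries."""

import dataclasses

import numpy as np
import pytest
from scipy.optimize import brentq

from conftest import rk4
from tgfb_multiscale.cellular import (
    CellularState,
    ParacrineGeometry,
    cellular_rhs,
    derive_paracrine_rate,
    internalized_summary,
    monotone_decreasing_flags,
    simulate_cellular,
)


class TestParacrineRate:
    def test_unit_inputs(self):
        g = ParacrineGeometry(D_eff=1, S=1, d=1, V_dr=1, V_neigh=2)
        assert derive_paracrine_rate(g) == 1.0

    def test_proportionalities(self):
        base = ParacrineGeometry(D_eff=10.0, S=100.0, d=0.1, V_dr=500.0)
        r = derive_paracrine_rate(base)
        assert derive_paracrine_rate(
            dataclasses.replace(base, d=0.2)) == pytest.approx(r / 2)
        assert derive_paracrine_rate(
            dataclasses.replace(base, D_eff=20.0)) == pytest.approx(2 * r)
        assert derive_paracrine_rate(
            dataclasses.replace(base, V_dr=1000.0)) == pytest.approx(r / 2)

    def test_geometry_reproducing_published_rate(self):
        # effective ECM diffusivity 100 um^2/s across a 10 um^2 contact
        # surface over a 0.1 um membrane gap into a 1000 um^3 region
        g = ParacrineGeometry(D_eff=100.0, S=10.0, d=0.1, V_dr=1000.0)
        assert derive_paracrine_rate(g) == pytest.approx(10.0)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            ParacrineGeometry(D_eff=1, S=1, d=0.0, V_dr=1)
        with pytest.raises(ValueError):
            ParacrineGeometry(D_eff=1, S=1, d=1, V_dr=0.0)


class TestRhs:
    def test_zero_sources_zero_state(self, params):
        p = dataclasses.replace(params, beta_sM=(0.0,) * 4, R_sM=(0.0,) * 4)
        d = cellular_rhs(np.zeros(13), np.array([6.0, 0, 0, 0]), p)
        assert np.all(d == 0.0)

    def test_mass_balance_identity(self, params, init, n_phen):
        """d/dt[sum N(B_e+B_i) + B_dr] must equal synthesis minus the Smad
        and ubiquitination drains exactly (symbolic bookkeeping)."""
        rng = np.random.default_rng(3)
        N = np.array([5.0, 2.0, 1.0, 0.5])
        for _ in range(25):
            y = rng.uniform(0, 10, 3 * n_phen + 1)
            d = cellular_rhs(y, N, params)
            n = n_phen
            lhs = float(N @ (d[:n] + d[2 * n:3 * n]) + d[3 * n])
            B_i = y[2 * n:3 * n]
            rhs_expected = (
                params.r_syn * float(N @ np.array(params.beta_sM))
                - params.r_sgn * float(N @ B_i)
                - params.r_u * N[0] * B_i[0]
            )
            assert lhs == pytest.approx(rhs_expected, rel=1e-10)

    def test_negative_state_rejected(self, params):
        with pytest.raises(ValueError):
            cellular_rhs(-np.ones(13), np.array([6.0, 0, 0, 0]), params)

    def test_healthy_only_steady_state_root(self, params):
        """With one phenotype, no paracrine loss and matched expression
        levels, the stationary point balances binding against synthesis."""
        p = dataclasses.replace(
            params, r_pc=0.0,
            beta_sM=(2.0, 2.0, 2.0, 2.0), R_sM=(2.0, 2.0, 2.0, 2.0),
        )
        N = np.array([6.0, 0.0, 0.0, 0.0])
        syn = p.r_syn * 2.0

        # oracle: at the fixed point B_e = R solves r_b x^2 = syn; B_i follows
        x_star = brentq(lambda x: p.r_b * x * x - syn, 0.0, 1e6)
        b_i_star = syn / (p.r_sgn + p.r_u)
        y = np.zeros(13)
        y[0] = x_star          # B_e(0)
        y[4] = x_star          # R(0)
        y[8] = b_i_star        # B_i(0)
        d = cellular_rhs(y, N, p)
        assert abs(d[0]) < 1e-9 * syn
        assert abs(d[4]) < 1e-9 * syn
        assert abs(d[8]) < 1e-9 * syn


class TestSimulate:
    def test_default_tables_integrate_cleanly(self, params, init):
        traj = simulate_cellular(
            CellularState.from_initial(init), np.array(init.N_neigh),
            params, np.linspace(0, 1000.0, 51),
        )
        assert np.all(traj.y >= 0.0)
        assert traj.meta["clip_magnitude"] < 1e-8

    def test_no_paracrine_decouples_diffusive_region(self, params, init):
        p = dataclasses.replace(params, r_pc=0.0)
        traj = simulate_cellular(
            CellularState.from_initial(init), np.array(init.N_neigh),
            p, np.linspace(0, 500.0, 20),
        )
        assert np.allclose(traj.column("B_dr"), init.B_dr, rtol=1e-9)

    def test_adaptive_matches_fixed_step_oracle(self, params, init):
        """Short-horizon cross-check against an independent RK4 grid."""
        t_grid = np.linspace(0.0, 20.0, 11)
        N = np.array(init.N_neigh)
        traj = simulate_cellular(CellularState.from_initial(init), N, params,
                                 t_grid)
        fine = np.linspace(0.0, 20.0, 40001)
        oracle = rk4(lambda t, y: cellular_rhs(np.maximum(y, 0.0), N, params),
                     CellularState.from_initial(init).as_vector(), fine)
        end = oracle[-1]
        assert np.abs(traj.y[-1] - end).max() / np.abs(end).max() < 1e-6

    def test_homogeneous_phenotypes_stay_identical(self, params, init):
        """Equal expression and equal neighbour counts: paracrine exchanges
        cancel and every phenotype follows the same trajectory."""
        p = dataclasses.replace(
            params, beta_sM=(1.7,) * 4, R_sM=(5.0,) * 4, r_u=0.0)
        N = np.array([2.0, 2.0, 2.0, 2.0])
        traj = simulate_cellular(CellularState.from_initial(init), N, p,
                                 np.linspace(0, 2000.0, 30))
        n = 4
        for block in (slice(0, n), slice(n, 2 * n), slice(2 * n, 3 * n)):
            cols = traj.y[:, block]
            spread = np.abs(cols - cols[:, :1]).max()
            assert spread < 1e-6 * max(np.abs(cols).max(), 1.0)

    def test_stronger_ubiquitination_lowers_healthy_internalized_pool(
            self, params, init):
        N = np.array(init.N_neigh)
        grids = np.linspace(0, 4000.0, 30)

        def b_i_end(r_u):
            p = dataclasses.replace(params, r_u=r_u)
            return simulate_cellular(CellularState.from_initial(init), N, p,
                                     grids).y[-1, 8:12]

        low, high = b_i_end(0.001), b_i_end(0.02)
        assert high[0] < low[0]
        assert np.allclose(high[1:], low[1:], rtol=5e-3)


@pytest.fixture(scope="module")
def traj(params, init):
    return simulate_cellular(
        CellularState.from_initial(init), np.array(init.N_neigh),
        params, np.linspace(0, 4320.0, 100),
    )


class TestSummary:
    def test_initial_time_returns_initial_values(self, traj, init):
        table = internalized_summary(traj, 0.0)
        assert np.allclose(table["B_e"], init.B_e)
        assert np.allclose(table["R"], init.R)
        assert np.allclose(table["B_i"], init.B_i)

    def test_columns_nonnegative_and_sorted_by_severity(self, traj):
        table = internalized_summary(traj, 4000.0)
        assert list(table["phenotype"]) == [0, 1, 2, 3]
        assert (table[["B_e", "R", "B_i"]] >= 0).all().all()

    def test_out_of_span_time_rejected(self, traj):
        with pytest.raises(ValueError):
            internalized_summary(traj, 1e9)

    def test_antitumorigenic_flag_is_monotone_receptor_decline(self):
        import pandas as pd

        decreasing = pd.DataFrame(
            {"phenotype": range(4), "B_e": [4, 3, 2, 1],
             "R": [7, 6, 5, 4], "B_i": [1, 2, 1, 2]})
        flags = monotone_decreasing_flags(decreasing)
        assert flags["R"] and flags["B_e"] and not flags["B_i"]
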