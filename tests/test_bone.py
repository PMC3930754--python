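"""Bone niche DDE: delay law, remodeling cycle, cancer perturbation."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from tgfb_multiscale.bone import (
    BoneState,
    FractureEvent,
    bone_rhs,
    constant_history,
    delay_tau,
    integrate_dde,
    mixed_lesion_index,
    remodeling_balance,
    simulate_fracture,
)


class TestDelayLaw:
    def test_zero_tgfb_gives_base_delay(self, params):
        assert delay_tau(0.0, params) == pytest.approx(6.02)

    def test_saturation_limit(self, params):
        assert delay_tau(1e3, params) == pytest.approx(6.02 + 22.36, rel=1e-6)

    def test_half_saturation(self, params):
        assert delay_tau(params.beta_bar, params) == pytest.approx(
            params.tau_bar + params.Delta / 2.0)

    @settings(max_examples=50, deadline=None)
    @given(beta=st.floats(0.0, 1e6, allow_nan=False))
    def test_bounded_monotone_positive_finite(self, params, beta):
        tau = delay_tau(beta, params)
        assert params.tau_bar <= tau <= params.tau_bar + params.Delta
        assert delay_tau(2 * beta + 1e-9, params) >= tau


class TestRhs:
    def test_healthy_steady_state_is_equilibrium(self, params):
        healthy = BoneState(Ocy=900.0, BMD=100.0)
        no_fracture = FractureEvent(damaged=0.0)
        d = bone_rhs(5.0, healthy.as_vector(), constant_history(healthy),
                     no_fracture, 0.0, params)
        assert np.allclose(d, 0.0, atol=1e-15)

    def test_osteoclasts_decay_without_recruitment_signals(self, params):
        state = BoneState(Ocy=870.0, Oc=3.0, RANKL=0.0, CSF=0.0)
        d = bone_rhs(5.0, state.as_vector(),
                     constant_history(state), FractureEvent(damaged=0.0),
                     0.0, params)
        assert d[1] <= 0.0

    def test_damage_signal_closed_form(self, params):
        fr = FractureEvent(damaged=30.0, duration=1.0)
        # integrates the pulse, then clears exponentially
        assert fr.damage(0.0, params.r_dmg) == 0.0
        mid = fr.damage(0.5, params.r_dmg)
        peak = fr.damage(1.0, params.r_dmg)
        assert 0.0 < mid < peak <= 30.0
        later = fr.damage(50.0, params.r_dmg)
        assert later == pytest.approx(peak * np.exp(-params.r_dmg * 49.0))


class TestIntegrator:
    def test_constant_history_zero_rhs_stays_constant(self, params):
        healthy = BoneState(Ocy=900.0, BMD=100.0)
        traj = integrate_dde(
            bone_rhs, constant_history(healthy), np.linspace(0, 50, 26),
            params, step=0.05, fracture=FractureEvent(damaged=0.0), N_c=0.0,
        )
        assert np.allclose(traj.y, healthy.as_vector(), atol=1e-12)

    def test_frozen_delay_limit_matches_ode_oracle(self, params):
        """With the delayed arguments pinned, the DDE is an ODE; the
        method-of-steps integrator must agree with an adaptive solver.

        The apoptosis pulse lies in the past so the vector field is smooth
        over the compared window (the pulse discontinuity itself is
        exercised by the fracture-cycle tests)."""
        frozen = (0.002, 0.5)
        fr = FractureEvent(onset=-10.0, damaged=30.0)
        start = BoneState(Ocy=880.0, Oc=0.3, Lng=0.6, Ob=0.2,
                          RANKL=500.0, BMP=0.003, CSF=4e-5,
                          BMD=99.5, beta=5e-8)
        t_grid = np.linspace(0.0, 60.0, 61)
        traj = integrate_dde(
            bone_rhs, constant_history(start), t_grid, params,
            step=0.002, fracture=fr, N_c=0.0, frozen_delayed=frozen,
        )
        sol = solve_ivp(
            lambda t, y: bone_rhs(t, y, constant_history(start), fr, 0.0,
                                  params, frozen_delayed=frozen),
            (0.0, 60.0), start.as_vector(), t_eval=t_grid,
            method="LSODA", rtol=1e-12, atol=1e-12,
        )
        scale = np.abs(sol.y.T).max(axis=0)
        err = np.abs(traj.y - sol.y.T) / np.maximum(scale, 1e-30)
        assert err.max() < 1e-6


@pytest.fixture(scope="module")
def control(params):
    return simulate_fracture(params, N_c=0)


@pytest.fixture(scope="module")
def cancer(params):
    return simulate_fracture(params)


class TestFractureCycle:
    def test_control_is_balance_neutral(self, control):
        assert abs(remodeling_balance(control)) < 0.2

    def test_no_clipping_under_defaults(self, control, cancer):
        assert control.meta["clip_count"] == 0
        assert cancer.meta["clip_count"] == 0

    def test_osteocyte_apoptosis_completes_in_about_one_day(self, control):
        ocy = control.column("Ocy")
        t_min = control.t[np.argmin(ocy)]
        assert 0.5 <= t_min <= 1.5
        assert ocy.min() == pytest.approx(870.0, abs=1.0)

    def test_canonical_remodeling_sequence(self, control):
        """Osteocyte drop, RANKL/CSF rise, osteoclast wave, density dip,
        delayed osteoblast wave, density recovery."""
        t = control.t
        t_rankl = t[np.argmax(control.column("RANKL"))]
        t_oc = t[np.argmax(control.column("Oc"))]
        t_ob = t[np.argmax(control.column("Ob"))]
        t_dip = t[np.argmin(control.column("BMD"))]
        assert t_rankl < t_oc < t_ob
        assert t_rankl < t_dip < 200.0
        z = control.column("BMD")
        assert z.min() < 100.0 - 0.05          # resorption dips density
        assert z[-1] > z.min() + 0.05          # formation recovers it
        assert control.column("Ob")[-1] < 1e-3  # the cycle has terminated

    def test_cancer_load_causes_net_bone_loss(self, control, cancer):
        assert remodeling_balance(cancer) < remodeling_balance(control)
        assert abs(remodeling_balance(control)) < abs(remodeling_balance(cancer))

    def test_bmd_loss_monotone_in_cancer_load(self, params):
        balances = [
            remodeling_balance(simulate_fracture(params, N_c=nc, step=0.02))
            for nc in (0, 500, 1000, 2000)
        ]
        assert all(b1 > b2 for b1, b2 in zip(balances, balances[1:]))

    def test_no_damage_is_identical_to_no_fracture(self, params):
        quiet = simulate_fracture(params, N_c=0, horizon_days=50.0,
                                  fracture=FractureEvent(damaged=0.0),
                                  step=0.05, n_out=51)
        healthy = BoneState(Ocy=900.0, BMD=100.0).as_vector()
        assert np.allclose(quiet.y, healthy, atol=1e-12)

    def test_release_rate_sets_the_sign_of_the_balance(self, params):
        """Less TGF-beta released during resorption tips the cycle toward
        net formation; more tips it toward net loss."""
        lo = dataclasses.replace(params, r_beta=params.r_beta / 10.0)
        hi = dataclasses.replace(params, r_beta=params.r_beta * 10.0)
        b_lo = remodeling_balance(simulate_fracture(lo, N_c=0, step=0.02))
        b_hi = remodeling_balance(simulate_fracture(hi, N_c=0, step=0.02))
        assert b_lo > 0.0 > b_hi


class TestMixedLesions:
    def test_degenerate_distribution_gives_zero_index(self, params):
        idx = mixed_lesion_index(params, 3, ("degenerate", {}), seed=1,
                                 horizon_days=120.0, step=0.05)
        assert idx == 0.0

    def test_index_grows_with_release_variability(self, params):
        idx = [
            mixed_lesion_index(params, 6, ("lognormal", {"sigma": s}),
                               seed=11, horizon_days=120.0, step=0.05)
            for s in (0.1, 0.4, 0.8)
        ]
        assert idx[0] < idx[1] < idx[2]

    def test_same_seed_reproduces_index(self, params):
        kw = dict(horizon_days=120.0, step=0.05)
        a = mixed_lesion_index(params, 4, ("lognormal", {"sigma": 0.5}), 7, **kw)
        b = mixed_lesion_index(params, 4, ("lognormal", {"sigma": 0.5}), 7, **kw)
        assert a == b

    def test_invalid_distribution_rejected(self, params):
        with pytest.raises(ValueError):
            mixed_lesion_index(params, 3, ("cauchy", {}), seed=1)
        with pytest.raises(ValueError):
            mixed_lesion_index(params, 1, ("degenerate", {}), seed=1)
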