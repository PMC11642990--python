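"""Calcium-controlled plasticity: gates, short-term dynamics, consolidation."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.integrate import solve_ivp
from scipy.stats import linregress

from epinmm.params import default_params
from epinmm.plasticity import (omega, h_post, stp_field, stp_steady_state,
                               calcium_field, rho_field, consolidation_field)


@pytest.fixture(scope="module")
def pp():
    return default_params().plasticity


class TestGates:
    def test_omega_half_max_at_thresholds(self, pp):
        assert omega(pp.theta_p, "potentiation", pp) == pytest.approx(2.5)
        assert omega(pp.theta_d, "depression", pp) == pytest.approx(0.5)

    def test_omega_negligible_at_zero_calcium(self, pp):
        assert omega(0.0, "potentiation", pp) == pytest.approx(
            pp.gamma_p / (1 + np.exp(pp.beta_p * pp.theta_p)), rel=1e-9)

    def test_omega_rejects_unknown_kind(self, pp):
        with pytest.raises(ValueError):
            omega(0.1, "both", pp)

    def test_h_post_midpoint_saturation_and_example(self, pp):
        assert h_post(pp.V_th, pp) == pytest.approx(0.5)
        assert h_post(-1e4, pp) == pytest.approx(0.0, abs=1e-12)
        assert h_post(10.0, pp) == pytest.approx(1 / (1 + np.exp(-5.0)))
        assert h_post(10.0, pp) == pytest.approx(0.9933, abs=1e-4)


class TestShortTerm:
    def test_silent_steady_state(self, pp):
        r, u = stp_steady_state(0.0, 0.8, pp)
        assert (r, u) == (1.0, 0.8)
        dr, du = stp_field(1.0, 0.8, 0.8, 0.0, pp)
        assert dr == 0.0 and du == 0.0

    def test_closed_forms_at_reference_drive(self, pp):
        r, u = stp_steady_state(5.0, 0.8, pp)
        assert u == pytest.approx(0.8333, abs=1e-4)
        assert r == pytest.approx(0.5455, abs=1e-4)

    @pytest.mark.parametrize("F_pre,Us", [(5.0, 0.8), (2.0, 0.4), (0.7, 0.6)])
    def test_simulation_converges_to_closed_forms(self, pp, F_pre, Us):
        sol = solve_ivp(lambda t, y: stp_field(y[0], y[1], Us, F_pre, pp),
                        (0, 5.0), [1.0, Us], rtol=1e-10, atol=1e-12)
        r_s, u_s = stp_steady_state(F_pre, Us, pp)
        assert sol.y[0, -1] == pytest.approx(r_s, abs=1e-4)
        assert sol.y[1, -1] == pytest.approx(u_s, abs=1e-4)

    def test_monotone_in_drive(self, pp):
        F = np.linspace(0, 5, 50)
        r, u = stp_steady_state(F, 0.8, pp)
        assert np.all(np.diff(r) < 0)
        assert np.all(np.diff(u) > 0)


class TestCalcium:
    def test_decay_without_drive(self, pp):
        assert calcium_field(0.3, 0.0, 0.0, pp, 50.0) == pytest.approx(
            -0.3 / pp.tau_ca)

    def test_fixed_point_matches_slow_regime_formula(self, pp):
        # Ca* = tau_ca * C_NMDA * y_NMDA * h_ca * H(v); drive of 10 -> 0.5
        y_nmda, v = 0.1, 1e3
        drive = 50.0 * y_nmda * pp.h_ca * 1.0
        ca_star = pp.tau_ca * drive
        assert drive == pytest.approx(50.0)
        assert calcium_field(ca_star, y_nmda, v, pp, 50.0) == pytest.approx(
            0.0, abs=1e-9)
        assert calcium_field(0.5, 10.0 / (50.0 * pp.h_ca), 1e3, pp, 50.0
                             ) == pytest.approx(0.0, abs=1e-9)


class TestEfficacy:
    def test_near_equilibria_at_zero_calcium(self, pp):
        for rho in (0.0, 0.5, 1.0):
            assert rho_field(rho, 0.0, pp) == pytest.approx(0.0, abs=1e-4)

    def test_flows_downhill_below_separatrix(self, pp):
        assert rho_field(0.25, 0.0, pp) < 0
        assert rho_field(0.75, 0.0, pp) > 0

    def test_high_calcium_drives_to_a_potentiated_root(self, pp):
        # at Ca = 1 both gates saturate; gamma_p > gamma_d puts the unique
        # root at gamma_p/(gamma_p + gamma_d) ~ 5/6 (cubic perturbation aside)
        assert omega(1.0, "potentiation", pp) == pytest.approx(pp.gamma_p)
        assert omega(1.0, "depression", pp) == pytest.approx(pp.gamma_d)
        for rho in np.linspace(0.0, 0.8, 20):
            assert rho_field(rho, 1.0, pp) > 0
        sol = solve_ivp(lambda t, y: [rho_field(y[0], 1.0, pp)],
                        (0, 2000), [0.1], rtol=1e-9)
        assert sol.y[0, -1] > 0.5

    @pytest.mark.parametrize("rho0,target", [(0.3, 0.0), (0.7, 1.0)])
    def test_bistability_at_zero_calcium(self, pp, rho0, target):
        sol = solve_ivp(lambda t, y: [rho_field(y[0], 0.0, pp)],
                        (0, 2000), [rho0], rtol=1e-9)
        assert sol.y[0, -1] == pytest.approx(target, abs=1e-2)


class TestConsolidation:
    @pytest.mark.parametrize("rho,us_t,ca_t", [
        (1.0, 0.8, 100.0), (0.0, 0.4, 50.0), (0.5, 0.6, 75.0)])
    def test_targets_interpolate_between_bounds(self, pp, rho, us_t, ca_t):
        dUs, dCA = consolidation_field(us_t, ca_t, rho, pp)
        assert dUs == pytest.approx(0.0, abs=1e-12)
        assert dCA == pytest.approx(0.0, abs=1e-12)

    def test_relaxation_is_monotone_when_rho_frozen(self, pp):
        sol = solve_ivp(
            lambda t, y: consolidation_field(y[0], y[1], 1.0, pp),
            (0, 400), [0.4, 50.0], rtol=1e-9)
        assert np.all(np.diff(sol.y[0]) > 0)
        assert np.all(np.diff(sol.y[1]) > 0)
        assert sol.y[0, -1] == pytest.approx(0.8, abs=0.01)


def test_forward_invariance_under_random_drive(pp):
    """All plastic variables stay in their intervals under arbitrary
    nonnegative drives (random firing rate, calcium drive)."""
    rng = np.random.default_rng(42)
    drive_t = np.linspace(0, 60, 601)
    F_samples = rng.uniform(0, 5, size=drive_t.size)
    y_samples = rng.uniform(0, 0.1, size=drive_t.size)

    def rhs(t, y):
        i = min(int(t), drive_t.size - 1)
        F, ynm = F_samples[i], y_samples[i]
        r, u, ca, rho, us, campa = y
        dr, du = stp_field(r, u, us, F, pp)
        dca = calcium_field(ca, ynm, 6.0, pp, 50.0)
        drho = rho_field(rho, ca, pp)
        dus, dcampa = consolidation_field(us, campa, rho, pp)
        return [dr, du, dca, drho, dus, dcampa]

    sol = solve_ivp(rhs, (0, 60), [1.0, 0.4, 0.0, 0.5, 0.4, 50.0],
                    rtol=1e-8, max_step=0.5)
    r, u, ca, rho, us, campa = sol.y
    eps = 1e-9
    assert np.all((r >= -eps) & (r <= 1 + eps))
    assert np.all((u >= -eps) & (u <= 1 + eps))
    assert np.all(ca >= -eps)
    assert np.all((rho >= -eps) & (rho <= 1 + eps))
    assert np.all((us >= 0.4 - eps) & (us <= 0.8 + eps))
    assert np.all((campa >= 50 - eps) & (campa <= 100 + eps))


def test_relaxation_timescales_follow_the_time_constants(pp):
    """Fitted exponential relaxation rates reflect tau_r, tau_ca, tau_rho,
    tau_U orderings within 20%."""
    # r relaxation at F = 0 from 0.5 -> 1: rate 1/tau_r
    t = np.linspace(0, 0.4, 400)
    sol = solve_ivp(lambda t, y: stp_field(y[0], 0.4, 0.4, 0.0, pp)[:1],
                    (0, 0.4), [0.5], t_eval=t, rtol=1e-10)
    rate_r = -linregress(t, np.log(1 - sol.y[0] + 1e-300)).slope
    assert rate_r == pytest.approx(1 / pp.tau_r, rel=0.2)
    # calcium decay rate 1/tau_ca
    sol = solve_ivp(lambda t, y: [calcium_field(y[0], 0.0, 0.0, pp, 50.0)],
                    (0, 0.1), [0.5], t_eval=np.linspace(0, 0.1, 200))
    rate_ca = -linregress(sol.t, np.log(sol.y[0])).slope
    assert rate_ca == pytest.approx(1 / pp.tau_ca, rel=0.2)
    # consolidation rate 1/tau_U
    sol = solve_ivp(lambda t, y: [consolidation_field(y[0], 75.0, 1.0, pp)[0]],
                    (0, 200), [0.4], t_eval=np.linspace(0, 200, 200))
    rate_us = -linregress(sol.t, np.log(0.8 - sol.y[0] + 1e-300)).slope
    assert rate_us == pytest.approx(1 / pp.tau_U, rel=0.2)
    assert rate_r > rate_ca * 0.2          # same order (0.2 s vs 0.05 s)
    assert rate_ca > 100 * rate_us         # calcium far faster than memory
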