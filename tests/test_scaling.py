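import math

import numpy as np
import pytest

from gelcav.bubble_dynamics import SolverConfig, initial_gas_pressure, simulate_bubble
from gelcav.scaling import (
    critical_delta_p,
    critical_initial_radius,
    damped_frequency,
    dimensionless_groups,
    elastic_response_term,
    inertial_pressure_baseline,
    lambda_max_first_order,
    linearized_response,
    radial_velocity_first_integral,
    redimensionalize,
    simulate_nondimensional,
)

T_REF = 0.547e-3


# -------------------------------------------------------------- groups

def test_dimensionless_groups_values(gel):
    m = dimensionless_groups(gel, 9e-6, T_REF)
    assert m.inertia == pytest.approx(1000 * (9e-6 / T_REF) ** 2 / 8000, rel=1e-12)
    assert m.inertia == pytest.approx(3.38e-5, rel=5e-3)
    assert m.surface_tension == pytest.approx(2 * 0.072 / (9e-6 * 8000), rel=1e-12)
    assert m.p_v_tilde == pytest.approx(2339 / 8000, rel=1e-12)

    inviscid = dimensionless_groups(gel.with_(kinematic_viscosity=0.0), 9e-6, T_REF)
    assert inviscid.viscosity == 0.0
    no_surf = dimensionless_groups(gel.with_(surface_tension=0.0), 9e-6, T_REF)
    assert no_surf.surface_tension == 0.0


def test_groups_reject_rigidity_free(water):
    with pytest.raises(ValueError, match="dimensional solver"):
        dimensionless_groups(water, 9e-6, T_REF)


# -------------------------------------------- nondimensional dynamics

def test_stationary_balancing_forcing(gel):
    """Forcing that exactly offsets the vapor term keeps lambda = 1."""
    m = dimensionless_groups(gel, 1e-6, T_REF, r0=50e-6)
    nd = simulate_nondimensional(m, lambda tt: 0.0, (0.0, 2.0))
    assert np.max(np.abs(nd.lam - 1.0)) < 1e-8


def test_dimensional_nondimensional_equivalence(gel, pulse500):
    """The same physics integrated in (r, t) and in (lambda, t~) agree."""
    r0 = 50e-6
    cfg = SolverConfig(rtol=1e-10, atol_radius_factor=1e-11)
    traj = simulate_bubble(gel, pulse500.with_pressure_amplitude(18e3), r0, cfg)
    m = dimensionless_groups(gel, 1e-6, T_REF, r0=r0)
    p_amp_t = 18e3 / gel.shear_modulus
    nd = simulate_nondimensional(
        m,
        lambda tt: -p_amp_t * pulse500.normalized_at(tt * T_REF),
        (0.0, (pulse500.t_end + pulse500.duration) / T_REF),
        cfg,
    )
    t_d, _ = redimensionalize(nd)
    common = t_d <= min(traj.times[-1], t_d[-1])
    lam_dim = np.interp(t_d[common], traj.times, traj.lam)
    assert np.max(np.abs(nd.lam[common] - lam_dim)) < 1e-6


def test_reference_radius_invariance(gel, pulse500):
    """Doubling r_cr with r0 fixed leaves the redimensionalized r(t) unchanged."""
    r0 = 50e-6
    curves = []
    for r_cr in (1e-6, 2e-6):
        m = dimensionless_groups(gel, r_cr, T_REF, r0=r0)
        def forcing(tt, _m=m):
            t = tt * T_REF
            if t >= pulse500.t_end:
                return 0.0
            return -(10e3 / gel.shear_modulus) * pulse500.normalized_at(t)

        nd = simulate_nondimensional(m, forcing, (0.0, 3.0), SolverConfig(rtol=1e-10))
        t_d, r_d = redimensionalize(nd)
        curves.append((t_d, r_d))
    r_b = np.interp(curves[0][0], curves[1][0], curves[1][1])
    assert np.max(np.abs(curves[0][1] - r_b)) < 1e-6 * r0


# ------------------------------------------------------------- Eq. 3/4

def test_damped_frequency_limits(gel):
    r_cr = 50e-6
    clean = gel.with_(kinematic_viscosity=0.0, surface_tension=0.0, vapor_pressure=0.0)
    om = damped_frequency(clean, 1.0, r_cr)
    assert om.omega == pytest.approx(
        math.sqrt(4 * clean.shear_modulus / (clean.density * r_cr ** 2)), rel=1e-12
    )
    # nu = 0: damped equals natural frequency
    inviscid = gel.with_(kinematic_viscosity=0.0)
    assert damped_frequency(inviscid, 1.0, r_cr).omega == pytest.approx(
        math.sqrt(
            (4 - 3 * gel.vapor_pressure / gel.shear_modulus)
            * gel.shear_modulus / (gel.density * r_cr ** 2)
            + 4 * gel.surface_tension / (gel.density * r_cr ** 3)
        ),
        rel=1e-12,
    )
    # heavy viscosity: overdamped flag, not a number
    syrup = gel.with_(kinematic_viscosity=1e-3)
    assert damped_frequency(syrup, 1.0, 5e-6).overdamped


def test_damped_frequency_directional_trends(gel):
    r_cr = 20e-6
    base = damped_frequency(gel, 1.0, r_cr).omega
    assert damped_frequency(gel.with_(kinematic_viscosity=5e-6), 1.0, r_cr).omega < base
    assert damped_frequency(gel.with_(shear_modulus=16e3), 1.0, r_cr).omega > base
    assert damped_frequency(gel.with_(surface_tension=0.144), 1.0, r_cr).omega > base


def test_linearized_response_zero_and_step(gel):
    m = dimensionless_groups(gel, 50e-6, T_REF, r0=50e-6)
    t = np.linspace(0, 2.0, 2000)
    f0 = linearized_response(m, 0.01, lambda tt: 0.0, t)
    assert np.max(np.abs(f0)) == 0.0
    # step forcing: long-time limit is the static balance
    p_t = 0.01
    f = linearized_response(m, p_t, lambda tt: 1.0, np.linspace(0, 40.0, 4000))
    f_inf = -p_t / (2 * m.surface_tension + m.r_tilde * (4 - 3 * m.p_v_tilde))
    assert np.mean(f[-500:]) == pytest.approx(f_inf, rel=1e-3)


def test_linearized_impulse_rings_at_damped_frequency(gel):
    m = dimensionless_groups(gel, 50e-6, T_REF, r0=50e-6)
    t = np.linspace(0, 0.8, 8000)
    f = linearized_response(m, 0.01, lambda tt: math.exp(-((tt - 0.02) / 0.005) ** 2), t)
    sel = t > 0.06
    x, tt = f[sel], t[sel]
    s = np.where(np.diff(np.sign(x)) != 0)[0]
    crossings = tt[s] - x[s] * (tt[s + 1] - tt[s]) / (x[s + 1] - x[s])
    omega_sim = 2 * np.pi / np.mean(2 * np.diff(crossings))
    om = damped_frequency(gel, 1.0, 50e-6, T_REF)
    assert omega_sim == pytest.approx(om.omega, rel=1e-2)


def test_linearized_warns_outside_perturbation_regime(gel):
    m = dimensionless_groups(gel, 50e-6, T_REF)
    with pytest.warns(UserWarning, match="small-forcing"):
        linearized_response(m, 0.2, lambda tt: 1.0, np.linspace(0, 1, 100))


# ------------------------------------------------------------- Eq. 5/6

def test_elastic_term_nonpositive_beyond_unity():
    lam = np.linspace(1.0, 50.0, 2000)
    e = elastic_response_term(lam)
    assert e[0] == pytest.approx(0.0, abs=1e-12)
    assert np.all(e[1:] < 0.0)


def test_first_integral_at_unity_and_imaginary_branch(gel):
    p_g0 = initial_gas_pressure(gel, 5e-6) - gel.ambient_pressure
    at_one = radial_velocity_first_integral(1.0, gel, 1e3, 5e-6, 1e-6, T_REF, p_g0)
    assert at_one.value == pytest.approx(0.0, abs=1e-12)
    assert not at_one.imaginary
    # r0 below gamma/mu at sub-critical tension: negative radicand
    small = radial_velocity_first_integral(
        3.0, gel, 0.5 * critical_delta_p(gel), 2e-6, 1e-6, T_REF,
        initial_gas_pressure(gel, 2e-6) - gel.ambient_pressure,
    )
    assert small.imaginary and math.isnan(small.value)
    with pytest.raises(ValueError):
        radial_velocity_first_integral(0.5, gel, 1e3, 5e-6, 1e-6, T_REF, 0.0)


def test_lambda_max_first_order_examples(gel):
    # bifurcation boundary: numerator vanishes at r0 = gamma/mu
    at_cr = lambda_max_first_order(critical_initial_radius(gel), gel, 3 * 8e3)
    assert at_cr.value == pytest.approx(0.0, abs=1e-12)
    # worked point: r0 = 4.5 um, Delta-p = 3 mu -> (3/2)(4-2)/(0.5) = 6
    est = lambda_max_first_order(4.5e-6, gel, 3 * 8e3)
    assert est.value == pytest.approx(6.0, rel=1e-12)
    assert est.physical and not est.diverged
    # pole: divergence flag, not a number
    pole = lambda_max_first_order(50e-6, gel, critical_delta_p(gel))
    assert pole.diverged and math.isinf(pole.value)


def test_critical_quantities(gel):
    assert critical_delta_p(gel) == pytest.approx(20e3, rel=1e-12)
    assert critical_delta_p(gel.with_(shear_modulus=0.0)) == 0.0
    assert critical_delta_p(gel.with_(shear_modulus=2e3)) == pytest.approx(5e3)
    assert critical_initial_radius(gel) == pytest.approx(9e-6, rel=1e-12)
    assert critical_initial_radius(gel.with_(shear_modulus=2e3)) == pytest.approx(36e-6)
    assert critical_initial_radius(gel.with_(surface_tension=0.0)) == 0.0
    with pytest.raises(ValueError):
        critical_initial_radius(gel.with_(shear_modulus=0.0))


def test_inertial_baseline():
    assert inertial_pressure_baseline(1000, 0.0, 0.1) == 0.0
    assert inertial_pressure_baseline(1000, 500 * 9.81, 36e-3) == pytest.approx(
        176.58e3, rel=1e-3
    )
    # linear in depth, in contrast with the quadratic empirical law
    p1 = inertial_pressure_baseline(1000, 100.0, 0.01)
    assert inertial_pressure_baseline(1000, 100.0, 0.02) == pytest.approx(2 * p1)
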