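"""Nondimensional model, linearized oscillator, and first-order burst theory.

The radius equation is nondimensionalized with lambda = r/r0,
t~ = t / t_ref (t_ref is the input-pulse peak time) and a reference radius
r_cr (the critical radius of pure water by convention; the physics must be
and is invariant to this choice).  Three groups, all normalized by the
shear modulus, control the response:

    A = rho (r_cr / t_ref)^2 / mu     (inertia; Cauchy-like)
    B = 2 nu rho / (mu t_ref)         (viscosity; Deborah-like)
    C = 2 gamma / (r_cr mu)           (surface tension; Weber-like)

Small-forcing perturbations obey a damped linear oscillator

    A r~^3 f'' + 2 B r~ f' + (2C + r~ (4 - 3 p~_v)) f = -p~ q(t~),

whose damped frequency is the printed closed form.  At nu ~ 0 the radius
equation admits an exact first integral for frozen driving tension
Delta-p = p_v - p_a, whose vanishing at the turning point gives, to first
order in 1/lambda, the burst estimate

    lambda_max = (3/2) (2 gamma/(r0 mu) - 2) / (Delta-p/mu - 5/2).

The pole Delta-p = (5/2) mu and the sign change of the numerator at
r0 = gamma/mu are the critical tension and critical initial radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, NamedTuple, Optional
import warnings

import numpy as np
from scipy.integrate import solve_ivp

from .bubble_dynamics import SolverConfig, SolverError
from .materials import MaterialProperties

__all__ = [
    "DimensionlessModel",
    "NondimensionalTrajectory",
    "DampedFrequency",
    "FirstIntegralVelocity",
    "FirstOrderLambdaMax",
    "dimensionless_groups",
    "simulate_nondimensional",
    "redimensionalize",
    "damped_frequency",
    "linearized_response",
    "elastic_response_term",
    "radial_velocity_first_integral",
    "lambda_max_first_order",
    "critical_delta_p",
    "critical_initial_radius",
    "inertial_pressure_baseline",
]


@dataclass(frozen=True)
class DimensionlessModel:
    """Dimensionless groups for one (material, reference-scale) choice."""

    inertia: float          # A
    viscosity: float        # B
    surface_tension: float  # C
    p_v_tilde: float        # p_v / mu
    p_inf_tilde: float      # p_inf / mu (used only in absolute bookkeeping)
    r_tilde: float          # r0 / r_cr
    reference_radius: float  # r_cr, m
    reference_time: float    # t_ref, s

    def __post_init__(self) -> None:
        for name in ("inertia", "viscosity", "surface_tension", "p_v_tilde"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.r_tilde <= 0:
            raise ValueError("r_tilde must be positive")


def dimensionless_groups(
    props: MaterialProperties,
    r_cr: float,
    t_ref: float,
    r0: Optional[float] = None,
) -> DimensionlessModel:
    """Compute A, B, C, p~_v for a material and reference scales.

    ``r0`` sets r~ = r0/r_cr; it defaults to r_cr (r~ = 1).  Rejects
    rigidity-free media: the groups are normalized by the shear modulus,
    so use the dimensional solver for water.
    """
    mu = props.shear_modulus
    if mu <= 0:
        raise ValueError(
            "dimensionless groups are normalized by the shear modulus; "
            "mu = 0 (water) has no such normalization -- use the dimensional solver"
        )
    if r_cr <= 0 or t_ref <= 0:
        raise ValueError("reference scales must be positive")
    rho = props.density
    return DimensionlessModel(
        inertia=rho * (r_cr / t_ref) ** 2 / mu,
        viscosity=2.0 * props.kinematic_viscosity * rho / (mu * t_ref),
        surface_tension=2.0 * props.surface_tension / (r_cr * mu),
        p_v_tilde=props.vapor_pressure / mu,
        p_inf_tilde=props.ambient_pressure / mu,
        r_tilde=(r0 / r_cr) if r0 is not None else 1.0,
        reference_radius=r_cr,
        reference_time=t_ref,
    )


@dataclass
class NondimensionalTrajectory:
    t_tilde: np.ndarray
    lam: np.ndarray
    lam_dot: np.ndarray
    model: DimensionlessModel
    collapsed: bool
    diagnostics: dict

    @property
    def lambda_max(self) -> float:
        return float(np.max(self.lam))


def _nondim_gas_pressure(model: DimensionlessModel, convention: str) -> float:
    # p~_G0 in the chosen bookkeeping; C/r~ = 2 gamma / (r0 mu).
    p = model.surface_tension / model.r_tilde - model.p_v_tilde
    if convention == "absolute":
        p += model.p_inf_tilde
    return p


def simulate_nondimensional(
    model: DimensionlessModel,
    p_a_tilde: Callable[[float], float],
    t_span: tuple[float, float] = (0.0, 3.0),
    config: Optional[SolverConfig] = None,
) -> NondimensionalTrajectory:
    """Integrate the nondimensional radius equation in (lambda, t~).

    ``p_a_tilde`` is the dimensionless far-field pressure history in the
    chosen bookkeeping: for the default reduced convention it is the
    departure from ambient (negative during tensile impact); for absolute
    bookkeeping it includes p~_inf.  Equivalent, after redimensionalization,
    to the dimensional solver run under the same convention (isothermal gas).
    """
    if config is None:
        config = SolverConfig()
    A = model.inertia
    B = model.viscosity
    C = model.surface_tension
    rt = model.r_tilde
    p_v = model.p_v_tilde
    p_g0 = _nondim_gas_pressure(model, config.pressure_convention)
    inert = A * rt * rt  # A r~^3, divided through by r~ lambda in the rhs

    def rhs(tt, y):
        lam, ld = y
        bracket = (
            2.0 * B * ld / lam
            + 0.5 * (5.0 - 4.0 / lam - lam ** -4)
            + (C / rt) / lam
            - p_v
            + p_a_tilde(tt)
            - p_g0 / lam ** 3
        )
        ldd = -1.5 * ld * ld / lam - bracket / (inert * lam)
        return (ld, ldd)

    def collapse_event(tt, y):
        return y[0] - config.lambda_stop

    collapse_event.terminal = True
    collapse_event.direction = -1

    t_eval = np.linspace(t_span[0], t_span[1], config.n_eval)
    sol = solve_ivp(
        rhs,
        t_span,
        [1.0, 0.0],
        method=config.method,
        rtol=config.rtol,
        atol=[1e-12, 1e-12],
        t_eval=t_eval,
        events=(collapse_event,),
    )
    if sol.status == -1:
        raise SolverError(f"nondimensional integration failed: {sol.message}")
    return NondimensionalTrajectory(
        t_tilde=sol.t,
        lam=sol.y[0],
        lam_dot=sol.y[1],
        model=model,
        collapsed=sol.status == 1,
        diagnostics={"nfev": sol.nfev, "message": sol.message},
    )


def redimensionalize(traj: NondimensionalTrajectory) -> tuple[np.ndarray, np.ndarray]:
    """Map (t~, lambda) back to dimensional (t, r)."""
    m = traj.model
    r0 = m.r_tilde * m.reference_radius
    return traj.t_tilde * m.reference_time, traj.lam * r0


class DampedFrequency(NamedTuple):
    omega: float          # rad/s (dimensional) or rad per t~ if t_ref given
    overdamped: bool


def damped_frequency(
    props: MaterialProperties,
    r_tilde: float,
    r_cr: float,
    t_ref: Optional[float] = None,
) -> DampedFrequency:
    """Damped small-oscillation frequency of the linearized bubble.

    Returns the dimensional angular rate (rad/s), or the dimensionless one
    (multiplied by ``t_ref``) when a reference time is given.  A negative
    radicand flags an overdamped bubble instead of returning a number.
    """
    mu = props.shear_modulus
    rho = props.density
    radicand = (
        (4.0 - 3.0 * props.vapor_pressure / mu) * mu / (rho * r_cr ** 2)
        + (4.0 * props.surface_tension / (rho * r_cr ** 3)) / r_tilde
        - (4.0 * props.kinematic_viscosity ** 2 / r_cr ** 4) / r_tilde ** 2
    )
    if radicand < 0:
        return DampedFrequency(math.nan, True)
    omega = math.sqrt(radicand) / r_tilde
    if t_ref is not None:
        omega *= t_ref
    return DampedFrequency(omega, False)


def linearized_response(
    model: DimensionlessModel,
    p_tilde: float,
    q: Callable[[float], float],
    t_grid: np.ndarray,
    r_tilde: Optional[float] = None,
) -> np.ndarray:
    """Solve the small-perturbation oscillator for f(t~), f(0) = f'(0) = 0.

    Warns when |p~ q| exceeds 0.05, outside the perturbation regime.
    """
    rt = model.r_tilde if r_tilde is None else r_tilde
    if abs(p_tilde) > 0.05:
        warnings.warn(
            f"|p_tilde| = {abs(p_tilde):.3g} exceeds the small-forcing regime (0.05)",
            stacklevel=2,
        )
    A = model.inertia * rt ** 3
    Bc = 2.0 * model.viscosity * rt
    K = 2.0 * model.surface_tension + rt * (4.0 - 3.0 * model.p_v_tilde)

    def rhs(tt, y):
        f, fd = y
        return (fd, (-p_tilde * q(tt) - Bc * fd - K * f) / A)

    t_grid = np.asarray(t_grid, float)
    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        [0.0, 0.0],
        method="LSODA",
        rtol=1e-10,
        atol=1e-14,
        t_eval=t_grid,
        max_step=(t_grid[-1] - t_grid[0]) / 200.0,
    )
    if sol.status != 0:
        raise SolverError(f"linearized response integration failed: {sol.message}")
    return sol.y[0]


def elastic_response_term(lam) -> np.ndarray:
    """E*(lambda) = -5 + 6/lambda + 2/lambda^3 - 3/lambda^4 (<= 0 for lambda >= 1)."""
    lam = np.asarray(lam, dtype=float)
    return -5.0 + 6.0 / lam + 2.0 / lam ** 3 - 3.0 / lam ** 4


class FirstIntegralVelocity(NamedTuple):
    value: float       # dlambda/dt~ (NaN on the imaginary branch)
    imaginary: bool    # True when the radicand is negative (bifurcated)


def radial_velocity_first_integral(
    lam: float,
    props: MaterialProperties,
    delta_p: float,
    r0: float,
    r_cr_w: float,
    t_ref: float,
    p_g0: float,
) -> FirstIntegralVelocity:
    """Expansion velocity dlambda/dt~ from the nu ~ 0 first integral.

    ``delta_p`` is the frozen driving tension p_v - p_a and ``p_g0`` the
    initial gas pressure, both in the bookkeeping of the trajectory being
    checked.  A negative radicand is returned as the imaginary-branch flag
    (the bifurcation signature), not an error.
    """
    if lam < 1.0:
        raise ValueError("first integral applies to expansion, lambda >= 1")
    mu = props.shear_modulus
    rho = props.density
    gamma = props.surface_tension
    r_tilde = r0 / r_cr_w
    radicand = (
        (2.0 * delta_p / (3.0 * mu)) * (1.0 - lam ** -3)
        + (2.0 * p_g0 / (mu * lam ** 3)) * math.log(lam)
        - (2.0 * gamma / (mu * r_cr_w)) * (1.0 / (r_tilde * lam)) * (1.0 - lam ** -2)
        + float(elastic_response_term(lam)) / 3.0
    )
    if radicand < 0:
        return FirstIntegralVelocity(math.nan, True)
    prefactor = math.sqrt(mu / rho) * t_ref / (r_tilde * r_cr_w)
    return FirstIntegralVelocity(prefactor * math.sqrt(radicand), False)


class FirstOrderLambdaMax(NamedTuple):
    value: float
    diverged: bool     # at the pole Delta-p/mu = 5/2 (burst signature)
    physical: bool     # value >= 1; False flags the r0 < gamma/mu branch


def lambda_max_first_order(
    r0: float,
    props: MaterialProperties,
    delta_p: float,
    pole_tol: float = 1e-12,
) -> FirstOrderLambdaMax:
    """First-order burst estimate lambda_max = (3/2)(2g/(r0 mu) - 2)/(Dp/mu - 5/2).

    The pole of the denominator is signalled as divergence (burst), not a
    number; estimates below 1 (the r0 < gamma/mu branch) are flagged
    non-physical rather than reinterpreted.
    """
    mu = props.shear_modulus
    if mu <= 0:
        raise ValueError("first-order theory requires mu > 0")
    denom = delta_p / mu - 2.5
    if abs(denom) < pole_tol:
        return FirstOrderLambdaMax(math.inf, True, False)
    value = 1.5 * (2.0 * props.surface_tension / (r0 * mu) - 2.0) / denom
    return FirstOrderLambdaMax(value, False, value >= 1.0)


def critical_delta_p(props: MaterialProperties) -> float:
    """Critical driving tension (5/2) mu at which the burst estimate diverges."""
    if props.shear_modulus < 0:
        raise ValueError("shear modulus must be non-negative")
    return 2.5 * props.shear_modulus


def critical_initial_radius(props: MaterialProperties) -> float:
    """Critical initial radius gamma/mu below which burst is possible."""
    if props.shear_modulus <= 0:
        raise ValueError("critical radius requires mu > 0")
    return props.surface_tension / props.shear_modulus


def inertial_pressure_baseline(rho: float, a: float, h: float) -> float:
    """Conventional hydrostatic-like estimate p = rho * a * h.

    Linear in depth by construction; kept as the comparison baseline the
    quadratic-depth empirical law is contrasted with.
    """
    return rho * a * h
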