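"""Dimensional simulation of a single spherical bubble under impact forcing.

The governing equation is a Rayleigh–Plesset equation extended with a
Kelvin–Voigt / neo-Hookean viscoelastic stress for the surrounding gel:

    r r'' + (3/2) r'^2 =
        (p_v - p_far(t))/rho + (p_G0/rho)(r0/r)^{3k}
        - 4 nu r'/r - 2 gamma/(rho r)
        - (mu/2 rho) [5 - 4 (r0/r) - (r0/r)^4]

with initial conditions r(0) = r0, r'(0) = 0.  The far-field pressure is
driven by a normalized impact pulse: p_far(t) = p_inf - p_amp * a_n(t),
so positive pressure amplitude means impact-induced tension and the rest
state is an exact equilibrium.

Pressure bookkeeping
--------------------
Two conventions are supported through :class:`SolverConfig`:

``"reduced"`` (default)
    Ambient pressure is subtracted from both the far field and the initial
    gas pressure, i.e. the dynamics are driven by departures from
    atmospheric conditions and the trapped gas carries only its
    Laplace/vapor excess, p_G0 - p_inf = 2 gamma/r0 - p_v.  This is the
    bookkeeping under which the first-order burst theory (critical tension
    (5/2) mu, critical radius gamma/mu) emerges, and is used for all
    headline results.

``"absolute"``
    Full atmospheric bookkeeping: the gas starts at
    p_G0 = p_inf - p_v + 2 gamma/r0 and the far field at p_inf.  The rest
    state is likewise an exact equilibrium, but the ~1 atm gas cushion
    stiffens the response and suppresses deep collapse.

Both conventions preserve lambda = 1, dr/dt = 0 as an exact initial
equilibrium; they differ by the term (p_inf/rho)(1 - (r0/r)^{3k}).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, NamedTuple, Optional

import numpy as np
from scipy.integrate import solve_ivp

from .constants import G_STANDARD
from .materials import MaterialProperties

__all__ = [
    "PressurePulse",
    "SolverConfig",
    "BubbleTrajectory",
    "TrajectoryFeatures",
    "SolverError",
    "initial_gas_pressure",
    "far_field_pressure",
    "rp_acceleration",
    "simulate_bubble",
    "integrate_radius_ode",
    "trajectory_features",
]


class SolverError(RuntimeError):
    """Integration failure; carries the last solver state."""

    def __init__(self, message: str, last_state=None):
        super().__init__(message)
        self.last_state = last_state


@dataclass
class PressurePulse:
    """A normalized impact waveform with its amplitude metadata.

    ``normalized_signal`` peaks at exactly 1; ``amplitude`` is the
    acceleration amplitude in m/s^2 (``amplitude_g`` gives the g-multiple);
    ``pressure_amplitude`` is set once the acceleration has been mapped to
    a far-field pressure amplitude (Pa).  ``signal_fn``, when present, is
    an analytic waveform evaluated instead of interpolating the samples.
    """

    times: np.ndarray
    normalized_signal: np.ndarray
    amplitude: float                       # m/s^2
    peak_time: float                       # s, t_max^in
    pressure_amplitude: Optional[float] = None  # Pa
    signal_fn: Optional[Callable[[float], float]] = None
    _warned_outside: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.normalized_signal = np.asarray(self.normalized_signal, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.normalized_signal.shape:
            raise ValueError("times and normalized_signal must be 1-D and equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        peak = np.max(np.abs(self.normalized_signal))
        if abs(peak - 1.0) > 1e-9:
            raise ValueError(f"normalized_signal must peak at 1, got {peak}")
        if abs(self.normalized_signal[0]) > 1e-12:
            raise ValueError("normalized_signal must start at 0")
        i_peak = int(np.argmax(self.normalized_signal))
        dt = np.max(np.diff(self.times))
        if abs(self.times[i_peak] - self.peak_time) > dt:
            raise ValueError("peak_time must coincide with the argmax of the signal")

    @property
    def amplitude_g(self) -> float:
        return self.amplitude / G_STANDARD

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def t_start(self) -> float:
        return float(self.times[0])

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    def normalized_at(self, t: float) -> float:
        """Evaluate a_n(t); clamps to 0 outside the sampled window."""
        if t < self.times[0] or t > self.times[-1]:
            if not self._warned_outside:
                warnings.warn(
                    "pressure pulse evaluated outside its sampled window; "
                    "clamping a_n to 0",
                    stacklevel=2,
                )
                self._warned_outside = True
            return 0.0
        if self.signal_fn is not None:
            return float(self.signal_fn(t))
        return float(np.interp(t, self.times, self.normalized_signal))

    def with_pressure_amplitude(self, p_amp: float) -> "PressurePulse":
        return replace(self, pressure_amplitude=float(p_amp))


@dataclass(frozen=True)
class SolverConfig:
    """Adaptive stiff-integration settings for the radius ODE."""

    rtol: float = 1e-8
    atol_radius_factor: float = 1e-9   # atol on r is r0 * this
    atol_velocity: float = 1e-10       # m/s
    max_step_fraction: float = 1.0 / 50.0  # of the pulse duration
    lambda_stop: float = 0.05          # collapse cutoff on r/r0
    velocity_guard: float = 1e5        # m/s, divergence guard on |r'|
    tail_fraction: float = 1.0         # extra integration time, x pulse duration
    method: str = "LSODA"
    n_eval: int = 1200                 # sample count of the returned record
    pressure_convention: str = "reduced"   # "reduced" | "absolute"
    tension_positive: bool = True      # positive p_amp pulls the far field down

    def __post_init__(self) -> None:
        if self.pressure_convention not in ("reduced", "absolute"):
            raise ValueError("pressure_convention must be 'reduced' or 'absolute'")
        if not 0 < self.lambda_stop < 1:
            raise ValueError("lambda_stop must lie in (0, 1)")


class TrajectoryFeatures(NamedTuple):
    lambda_max: float
    t_max_out: float
    collapsed: bool


@dataclass
class BubbleTrajectory:
    """One simulated bubble: r(t), velocities, and extracted features."""

    times: np.ndarray
    radius: np.ndarray
    radial_velocity: np.ndarray
    initial_radius: float
    gas_pressure_init: float          # convention-adjusted value used in the ODE
    lambda_max: float
    t_max_out: float
    collapsed: bool
    solver_diagnostics: dict = field(default_factory=dict)

    @property
    def lam(self) -> np.ndarray:
        """Normalized radius lambda(t) = r/r0."""
        return self.radius / self.initial_radius

    @property
    def max_radius(self) -> float:
        return self.lambda_max * self.initial_radius

    def features(self) -> TrajectoryFeatures:
        return TrajectoryFeatures(self.lambda_max, self.t_max_out, self.collapsed)


def initial_gas_pressure(props: MaterialProperties, r0: float) -> float:
    """Initial (absolute) gas pressure p_G0 = p_inf - p_v + 2 gamma/r0."""
    if r0 <= 0:
        raise ValueError(f"r0 must be positive, got {r0}")
    p = props.ambient_pressure - props.vapor_pressure + 2.0 * props.surface_tension / r0
    if p <= 0:
        raise ValueError(
            "unphysical parameter combination: non-positive initial gas pressure"
        )
    return p


def far_field_pressure(
    pulse: PressurePulse, t: float, ambient_pressure: float, sign: float = 1.0
) -> float:
    """Absolute far-field pressure p_inf - p_amp * a_n(t).

    Positive pressure amplitude denotes impact-induced tension (the far
    field drops below ambient while the pulse is active); pass
    ``sign=-1`` for the compressive convention.
    """
    if pulse.pressure_amplitude is None:
        raise ValueError("pulse has no pressure_amplitude set")
    return ambient_pressure - sign * pulse.pressure_amplitude * pulse.normalized_at(t)


def rp_acceleration(
    r: float,
    rdot: float,
    t: float,
    props: MaterialProperties,
    pulse: PressurePulse,
    r0: float,
    *,
    pressure_offset: float = 0.0,
    p_g0: Optional[float] = None,
    sign: float = 1.0,
) -> float:
    """Radial acceleration r'' from the viscoelastic Rayleigh–Plesset equation.

    ``pressure_offset`` is subtracted from both the far field and the gas
    pressure (0 for absolute bookkeeping, p_inf for reduced).
    """
    if r <= 0:
        raise ValueError("bubble radius must be positive; stop integration first")
    p_far = far_field_pressure(pulse, t, props.ambient_pressure, sign) - pressure_offset
    if p_g0 is None:
        p_g0 = initial_gas_pressure(props, r0) - pressure_offset
    return _radial_acceleration(
        r, rdot, p_far, p_g0, r0,
        props.density, props.shear_modulus, props.kinematic_viscosity,
        props.surface_tension, props.vapor_pressure, props.polytropic_index,
    )


def _radial_acceleration(r, rdot, p_far, p_g0, r0, rho, mu, nu, gamma, p_v, k):
    x = r0 / r
    gas = (p_g0 / rho) * x ** (3.0 * k)
    elastic = (mu / (2.0 * rho)) * (5.0 - 4.0 * x - x ** 4)
    return (
        (p_v - p_far) / rho
        + gas
        - 1.5 * rdot * rdot
        - 4.0 * nu * rdot / r
        - 2.0 * gamma / (rho * r)
        - elastic
    ) / r


def integrate_radius_ode(
    props: MaterialProperties,
    p_far_fn: Callable[[float], float],
    p_g0: float,
    r0: float,
    t_span: tuple[float, float],
    config: SolverConfig,
    max_step: Optional[float] = None,
) -> BubbleTrajectory:
    """Integrate the radius ODE under an arbitrary (convention-adjusted)
    far-field pressure history.

    This is the low-level driver behind :func:`simulate_bubble`; it is also
    used directly for step/constant-tension numerical experiments.  ``p_far_fn``
    and ``p_g0`` must already be expressed in the same bookkeeping.
    """
    rho = props.density
    mu = props.shear_modulus
    nu = props.kinematic_viscosity
    gamma = props.surface_tension
    p_v = props.vapor_pressure
    k = props.polytropic_index

    def rhs(t, y):
        r, v = y
        return (
            v,
            _radial_acceleration(r, v, p_far_fn(t), p_g0, r0, rho, mu, nu, gamma, p_v, k),
        )

    def collapse_event(t, y):
        return y[0] / r0 - config.lambda_stop

    collapse_event.terminal = True
    collapse_event.direction = -1

    def velocity_guard(t, y):
        return config.velocity_guard - abs(y[1])

    velocity_guard.terminal = True
    velocity_guard.direction = -1

    def peak_event(t, y):
        return y[1]

    peak_event.terminal = False
    peak_event.direction = -1  # r' crossing zero downward: a radius maximum

    t0, t1 = t_span
    t_eval = np.linspace(t0, t1, config.n_eval)
    sol = solve_ivp(
        rhs,
        (t0, t1),
        [r0, 0.0],
        method=config.method,
        rtol=config.rtol,
        atol=[r0 * config.atol_radius_factor, config.atol_velocity],
        max_step=max_step if max_step is not None else np.inf,
        t_eval=t_eval,
        events=(collapse_event, velocity_guard, peak_event),
        dense_output=False,
    )
    if sol.status == -1:
        raise SolverError(f"radius ODE integration failed: {sol.message}",
                          last_state=(sol.t[-1] if sol.t.size else t0,
                                      sol.y[:, -1] if sol.t.size else None))

    times = sol.t
    radius = sol.y[0]
    velocity = sol.y[1]
    collapsed = sol.status == 1 and (
        len(sol.t_events[0]) > 0 or len(sol.t_events[1]) > 0
    )

    # Candidate maxima: sampled record plus exact r'=0 crossings from events.
    lam = radius / r0
    i_best = int(np.argmax(lam)) if lam.size else 0
    lam_max = float(lam[i_best]) if lam.size else 1.0
    t_max = float(times[i_best]) if lam.size else t0
    peak_times = sol.t_events[2]
    peak_states = sol.y_events[2]
    for tp, yp in zip(peak_times, peak_states):
        lp = yp[0] / r0
        if lp > lam_max:
            lam_max = float(lp)
            t_max = float(tp)
    if lam_max <= 1.0 + 1e-12 and lam.size:
        # Quiescent record: the maximum is the initial state.
        lam_max = max(lam_max, 1.0)
        t_max = float(times[0]) if lam_max <= 1.0 else t_max

    diagnostics = {
        "status": sol.status,
        "message": sol.message,
        "nfev": sol.nfev,
        "n_peaks": int(len(peak_times)),
        "t_final": float(times[-1]) if times.size else t0,
    }
    return BubbleTrajectory(
        times=times,
        radius=radius,
        radial_velocity=velocity,
        initial_radius=r0,
        gas_pressure_init=p_g0,
        lambda_max=lam_max,
        t_max_out=t_max,
        collapsed=bool(collapsed),
        solver_diagnostics=diagnostics,
    )


def simulate_bubble(
    props: MaterialProperties,
    pulse: PressurePulse,
    r0: float,
    config: Optional[SolverConfig] = None,
) -> BubbleTrajectory:
    """Simulate one bubble driven by a normalized impact pulse.

    The pulse must carry a ``pressure_amplitude``; integration runs from
    the pulse start through its end plus a configurable tail, stopping
    early (with ``collapsed=True``) if the radius falls below the collapse
    cutoff or the velocity guard trips.
    """
    if config is None:
        config = SolverConfig()
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    offset = props.ambient_pressure if config.pressure_convention == "reduced" else 0.0
    sign = 1.0 if config.tension_positive else -1.0
    p_g0 = initial_gas_pressure(props, r0) - offset

    base = props.ambient_pressure - offset

    def p_far_fn(t: float) -> float:
        # Outside the pulse support the far field is ambient; skip the
        # out-of-window warning that interactive evaluation would raise.
        if t <= pulse.t_start or t >= pulse.t_end:
            return base
        return far_field_pressure(pulse, t, props.ambient_pressure, sign) - offset

    t0 = pulse.t_start
    t1 = pulse.t_end + config.tail_fraction * pulse.duration
    max_step = pulse.duration * config.max_step_fraction
    traj = integrate_radius_ode(
        props, p_far_fn, p_g0, r0, (t0, t1), config, max_step=max_step
    )
    traj.solver_diagnostics["pressure_convention"] = config.pressure_convention
    traj.solver_diagnostics["pressure_amplitude"] = pulse.pressure_amplitude
    return traj


def trajectory_features(traj) -> TrajectoryFeatures:
    """Extract (lambda_max, t_max_out, collapsed) from a trajectory record.

    Accepts a :class:`BubbleTrajectory` or a ``(times, lam)`` pair; for the
    latter the collapse flag applies the default cutoff rule.
    """
    if isinstance(traj, BubbleTrajectory):
        return traj.features()
    times, lam = traj
    times = np.asarray(times, float)
    lam = np.asarray(lam, float)
    if times.size == 0:
        raise ValueError("empty trajectory record")
    i = int(np.argmax(lam))
    collapsed = bool(lam[-1] < SolverConfig().lambda_stop)
    return TrajectoryFeatures(float(lam[i]), float(times[i]), collapsed)
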