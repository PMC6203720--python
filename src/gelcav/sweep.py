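"""Amplitude sweeps, burst detection, and the depth-pressure mapping.

A sweep runs the bubble simulator over an ascending grid of far-field
pressure amplitudes with one fixed pulse shape, recording lambda_max and
t_max^out per point.  Burst is declared when lambda_max jumps by more than
a factor (default 10) between adjacent grid points; the critical amplitude
is then refined by bisection.  The empirical depth law closes the loop
between acceleration, bubble depth and pressure amplitude:

    p_amp = kappa * rho * |a| * h_b^2 / H

with H the sample height carrying the units and kappa a dimensionless
coupling calibrated against the observed lambda_max slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from .bubble_dynamics import (
    PressurePulse,
    SolverConfig,
    SolverError,
    simulate_bubble,
)
from .constants import G_STANDARD
from .materials import MaterialProperties

__all__ = [
    "SweepCurve",
    "ImpactGeometry",
    "BurstDetection",
    "CriticalAcceleration",
    "amplitude_sweep",
    "detect_burst",
    "depth_to_pressure",
    "calibrate_kappa",
    "critical_acceleration",
]


@dataclass(frozen=True)
class ImpactGeometry:
    """Sample geometry: height H, bubble depth h_b, and coupling kappa."""

    sample_height: float           # H, m
    bubble_depth: float            # h_b, m (from the gel's top surface)
    coupling: float = 1.0          # kappa, dimensionless
    drop_height: Optional[float] = None  # metadata only

    def __post_init__(self) -> None:
        if self.sample_height <= 0:
            raise ValueError("sample_height must be positive")
        if not 0.0 <= self.bubble_depth <= self.sample_height:
            raise ValueError("bubble_depth must lie in [0, sample_height]")
        if self.coupling <= 0:
            raise ValueError("coupling must be positive")


@dataclass
class SweepCurve:
    """lambda_max and t_max^out versus pressure amplitude for one r0."""

    r0: float
    p_amp: np.ndarray
    lambda_max: np.ndarray
    t_max_out: np.ndarray
    collapsed: np.ndarray
    props: MaterialProperties
    pulse_shape: PressurePulse
    config: SolverConfig
    burst_detected: bool = False
    p_amp_cn: Optional[float] = None
    lambda_before: Optional[float] = None
    lambda_after: Optional[float] = None
    jump_orders: Optional[float] = None
    _cache: dict = field(default_factory=dict, repr=False)

    def lambda_max_at(self, p: float) -> float:
        """Simulate (with caching) lambda_max at one amplitude."""
        key = float(p)
        if key not in self._cache:
            traj = simulate_bubble(
                self.props, self.pulse_shape.with_pressure_amplitude(key),
                self.r0, self.config,
            )
            self._cache[key] = traj.lambda_max
        return self._cache[key]


def amplitude_sweep(
    props: MaterialProperties,
    r0: float,
    pulse_shape: PressurePulse,
    p_grid,
    config: Optional[SolverConfig] = None,
) -> SweepCurve:
    """Run one simulation per pressure amplitude on an ascending grid."""
    p_grid = np.asarray(p_grid, dtype=float)
    if p_grid.size < 3:
        raise ValueError("p_grid needs at least 3 points")
    if np.any(np.diff(p_grid) <= 0):
        raise ValueError("p_grid must be strictly ascending")
    if config is None:
        config = SolverConfig()
    lam_max = np.empty_like(p_grid)
    t_out = np.empty_like(p_grid)
    collapsed = np.zeros(p_grid.shape, dtype=bool)
    curve = SweepCurve(
        r0=r0, p_amp=p_grid, lambda_max=lam_max, t_max_out=t_out,
        collapsed=collapsed, props=props, pulse_shape=pulse_shape, config=config,
    )
    for i, p in enumerate(p_grid):
        try:
            traj = simulate_bubble(
                props, pulse_shape.with_pressure_amplitude(p), r0, config
            )
        except SolverError as err:
            raise SolverError(
                f"amplitude sweep failed at p_amp = {p:.6g} Pa: {err}",
                last_state=err.last_state,
            ) from err
        lam_max[i] = traj.lambda_max
        t_out[i] = traj.t_max_out
        collapsed[i] = traj.collapsed
        curve._cache[float(p)] = traj.lambda_max
    return curve


class BurstDetection(NamedTuple):
    burst: bool
    p_amp_cn: Optional[float]
    jump_orders: Optional[float]
    lambda_before: Optional[float]
    lambda_after: Optional[float]


def detect_burst(
    curve: SweepCurve,
    jump_factor: float = 10.0,
    refine: bool = True,
    rel_bracket: float = 1e-3,
) -> BurstDetection:
    """Locate a discontinuous lambda_max jump along a sweep curve.

    Burst is declared when adjacent grid values of lambda_max differ by
    more than ``jump_factor``; the transition amplitude is refined by
    bisection until the bracket is narrower than ``rel_bracket`` of the
    amplitude, classifying each midpoint by the geometric mean of the
    bracketing branch values.  A smooth monotone curve returns no burst.
    """
    if curve.p_amp.size < 3:
        raise ValueError("sweep curve needs at least 3 points")
    lam = curve.lambda_max
    ratios = lam[1:] / lam[:-1]
    idx = np.where(ratios > jump_factor)[0]
    if idx.size == 0:
        return BurstDetection(False, None, None, None, None)
    i = int(idx[0])
    p_lo, p_hi = float(curve.p_amp[i]), float(curve.p_amp[i + 1])
    lam_lo, lam_hi = float(lam[i]), float(lam[i + 1])
    if refine:
        while (p_hi - p_lo) > rel_bracket * p_hi:
            p_mid = 0.5 * (p_lo + p_hi)
            lam_mid = curve.lambda_max_at(p_mid)
            if lam_mid > math.sqrt(lam_lo * lam_hi):
                p_hi, lam_hi = p_mid, lam_mid
            else:
                p_lo, lam_lo = p_mid, lam_mid
    p_cn = 0.5 * (p_lo + p_hi)
    jump = math.log10(lam_hi / lam_lo)
    curve.burst_detected = True
    curve.p_amp_cn = p_cn
    curve.lambda_before = lam_lo
    curve.lambda_after = lam_hi
    curve.jump_orders = jump
    return BurstDetection(True, p_cn, jump, lam_lo, lam_hi)


def depth_to_pressure(
    a_amp: float, geom: ImpactGeometry, rho: float
) -> float:
    """Pressure amplitude p_amp = kappa rho |a| h_b^2 / H at a bubble's depth."""
    return geom.coupling * rho * abs(a_amp) * geom.bubble_depth ** 2 / geom.sample_height


def calibrate_kappa(
    empirical_slope_k: float,
    sim_slope: float,
    rho: float,
    sample_height: float,
    g: float = G_STANDARD,
) -> float:
    """Coupling kappa from the empirical per-g slope and the simulated
    dlambda_max/dp_amp, so the two laws agree:

        sim_slope * depth_to_pressure(a, h_b) = k (|a|/g)(h_b/H)^2.
    """
    if empirical_slope_k <= 0 or sim_slope <= 0:
        raise ValueError("both slopes must be positive")
    return empirical_slope_k / (sim_slope * rho * g * sample_height)


class CriticalAcceleration(NamedTuple):
    burst: bool
    a_cr: Optional[float]       # m/s^2
    a_cr_g: Optional[float]
    p_amp_cn: Optional[float]   # Pa


def critical_acceleration(
    props: MaterialProperties,
    r0: float,
    geom: ImpactGeometry,
    pulse_shape: PressurePulse,
    p_grid=None,
    config: Optional[SolverConfig] = None,
    jump_factor: float = 10.0,
) -> CriticalAcceleration:
    """Smallest acceleration amplitude that bursts a bubble at depth h_b.

    Runs a pressure-amplitude pre-sweep, detects/refines the burst
    transition, then inverts the depth law: a_cr = p_cn H / (kappa rho h_b^2).
    Returns an explicit no-burst result when the sweep range shows none.
    """
    if p_grid is None:
        p_grid = np.linspace(2e3, 200e3, 34)
    curve = amplitude_sweep(props, r0, pulse_shape, p_grid, config)
    det = detect_burst(curve, jump_factor=jump_factor)
    if not det.burst:
        return CriticalAcceleration(False, None, None, None)
    a_cr = det.p_amp_cn * geom.sample_height / (
        geom.coupling * props.density * geom.bubble_depth ** 2
    )
    return CriticalAcceleration(True, a_cr, a_cr / G_STANDARD, det.p_amp_cn)
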