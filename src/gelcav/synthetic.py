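"""Synthetic stand-ins for the drop-tower study's raw data.

Every analysis stage can be exercised without downloads: smooth impact
pulses, lambda_max regression datasets drawn from the depth-squared law,
rendered image stacks of dark bubbles with a rigid reference inclusion,
and fully physics-coupled experiments (depth-to-pressure mapping feeding
the bubble simulator).  All stochastic generators require a seed and emit
their ground truth alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .bubble_dynamics import PressurePulse, SolverConfig, simulate_bubble
from .constants import G_STANDARD
from .fits import BubbleObservation
from .imaging import ImageStack
from .materials import MaterialProperties
from .sweep import ImpactGeometry, depth_to_pressure

__all__ = [
    "SyntheticExperimentConfig",
    "MEASURED_AMPLITUDES_G",
    "DEFAULT_SAMPLE_HEIGHT",
    "DEFAULT_BUBBLE_RADIUS",
    "DEFAULT_KAPPA",
    "make_pulse",
    "raised_cosine",
    "make_lambda_dataset",
    "make_image_stack",
    "make_impact_experiment",
]

#: The five measured drop-amplitude levels (g-multiples) for 4-12 cm drops.
MEASURED_AMPLITUDES_G = (228.52, 300.78, 376.95, 448.24, 516.60)

#: Collagen sample height H.
DEFAULT_SAMPLE_HEIGHT = 36e-3  # m

#: Average macro-bubble initial radius.
DEFAULT_BUBBLE_RADIUS = 0.52e-3  # m

#: Default depth-pressure coupling kappa for the physics-coupled
#: experiment.  Chosen so that, for the collagen-like medium and the
#: printed drop amplitudes, the macro bubble stays inside its
#: linear-response regime and acts as a clean pressure gauge (the role
#: macro bubbles play in the study); larger couplings push the deepest
#: bubbles into the softening knee of lambda_max(p_amp).
DEFAULT_KAPPA = 0.12


@dataclass
class SyntheticExperimentConfig:
    """Conditions of the emulated drop-tower experiment."""

    amplitudes_g: Sequence[float] = MEASURED_AMPLITUDES_G
    depths: Sequence[float] = field(
        default_factory=lambda: tuple(np.linspace(4.5e-3, 36e-3, 8))
    )
    sample_height: float = DEFAULT_SAMPLE_HEIGHT
    initial_radius: float = DEFAULT_BUBBLE_RADIUS
    kappa: float = DEFAULT_KAPPA
    pulse_peak_time: float = 0.547e-3
    pulse_duration: float = 1.094e-3
    sigma_lambda: float = 0.01        # additive noise on lambda_max
    illumination_sigma: float = 0.02  # frame-wide multiplicative jitter
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.amplitudes_g):
            raise ValueError("amplitudes must be positive")
        if any(not 0 < h <= self.sample_height for h in self.depths):
            raise ValueError("depths must lie in (0, sample_height]")

    def rng(self) -> np.random.Generator:
        if self.seed is None:
            raise ValueError("a seed is mandatory for stochastic outputs")
        return np.random.default_rng(self.seed)


def raised_cosine(t: float, t_peak: float, duration: float) -> float:
    """Piecewise raised-cosine waveform: 0 at the endpoints, 1 at t_peak, C1."""
    if t <= 0.0 or t >= duration:
        return 0.0
    if t <= t_peak:
        return 0.5 * (1.0 - math.cos(math.pi * t / t_peak))
    return 0.5 * (1.0 + math.cos(math.pi * (t - t_peak) / (duration - t_peak)))


_SHAPES: dict[str, Callable[[float, float, float], float]] = {
    "raised_cosine": raised_cosine,
    "half_sine": lambda t, tp, T: math.sin(math.pi * t / T) if 0 < t < T else 0.0,
}


def make_pulse(
    amplitude_g: float,
    t_peak: float = 0.547e-3,
    duration: float = 1.094e-3,
    shape: str = "raised_cosine",
    dt: float = 2e-6,
) -> PressurePulse:
    """A smooth, compactly supported impact pulse normalized to peak 1.

    The default raised cosine peaks at t_max^in = 0.547 ms over a ~1.1 ms
    support, emulating the measured foam-cushioned acceleration profiles.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not 0 < t_peak < duration:
        raise ValueError("t_peak must lie inside (0, duration)")
    try:
        fn = _SHAPES[shape]
    except KeyError:
        raise ValueError(f"unknown pulse shape {shape!r}; known: {sorted(_SHAPES)}")
    if shape == "half_sine":
        t_peak = duration / 2.0
    times = np.arange(0.0, duration + dt / 2, dt)
    if times[-1] < duration:
        times = np.append(times, duration)
    # Guarantee the peak sample is present so normalization is exact.
    if not np.any(np.isclose(times, t_peak)):
        times = np.sort(np.append(times, t_peak))
    signal = np.array([fn(t, t_peak, duration) for t in times])
    return PressurePulse(
        times=times,
        normalized_signal=signal,
        amplitude=amplitude_g * G_STANDARD,
        peak_time=t_peak,
        signal_fn=lambda t, _fn=fn, _tp=t_peak, _T=duration: _fn(t, _tp, _T),
    )


def make_lambda_dataset(
    k: float,
    c: float,
    config: SyntheticExperimentConfig,
) -> tuple[list[BubbleObservation], dict]:
    """Draw lambda_max observations from the combined law plus Gaussian noise.

    lambda_max = k (|a|/g)(h_b/H)^2 + c + N(0, sigma^2) over the configured
    amplitude x depth grid; one bubble per depth.  Returns the observations
    and a ground-truth record.
    """
    rng = config.rng()
    amps = np.asarray(config.amplitudes_g, dtype=float)
    out = []
    for i, h in enumerate(config.depths):
        x = amps * (h / config.sample_height) ** 2
        lam = k * x + c
        if config.sigma_lambda > 0:
            lam = lam + rng.normal(0.0, config.sigma_lambda, size=lam.shape)
        lam = np.maximum(lam, 1.0)
        out.append(
            BubbleObservation(
                bubble_id=f"bubble_{i + 1}",
                depth=float(h),
                initial_radius=config.initial_radius,
                amplitudes_g=amps.copy(),
                lambda_max=lam,
            )
        )
    truth = {
        "k": k,
        "c": c,
        "sigma": config.sigma_lambda,
        "sample_height": config.sample_height,
        "seed": config.seed,
    }
    return out, truth


def _render_disk(frame, center, radius_px, value, edge_px=0.8):
    rows, cols = frame.shape
    rr = np.arange(rows)[:, None]
    cc = np.arange(cols)[None, :]
    d = np.sqrt((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
    cover = np.clip((radius_px - d) / edge_px + 0.5, 0.0, 1.0)
    frame[:] = frame * (1 - cover) + value * cover


def _reference_mask(shape, anchor):
    """A rigid, deliberately non-circular inclusion: an L-shaped bracket."""
    mask = np.zeros(shape, dtype=bool)
    r0, c0 = anchor
    mask[r0 : r0 + 18, c0 : c0 + 6] = True
    mask[r0 + 12 : r0 + 18, c0 : c0 + 16] = True
    return mask


def make_image_stack(
    radii_px: Sequence[np.ndarray] | Sequence[float],
    centers: Sequence[tuple[float, float]],
    n_frames: int = 60,
    shape: tuple[int, int] = (120, 160),
    frame_rate: float = 25_000.0,
    pixel_size: float = 40e-6,
    impact_frame: int = 10,
    background: float = 0.85,
    foreground: float = 0.15,
    noise_sigma: float = 0.02,
    illumination_sigma: float = 0.0,
    reference_anchor: Optional[tuple[int, int]] = (96, 16),
    edge_px: float = 0.8,
    seed: int = 0,
) -> tuple[ImageStack, dict]:
    """Render a synthetic high-speed stack of dark bubbles on a bright field.

    ``radii_px`` gives, per bubble, either a constant pixel radius or a
    per-frame radius array; bubbles must not overlap at frame 0.  A rigid
    L-shaped reference inclusion is stamped near ``reference_anchor``,
    pixel noise is additive Gaussian, and ``illumination_sigma`` applies a
    frame-wide multiplicative brightness jitter (the dominant real-world
    fluctuation of the rigid reference).  Ground-truth per-frame radii are
    returned alongside the stack.
    """
    rng = np.random.default_rng(seed)
    radii = []
    for r in radii_px:
        arr = np.asarray(r, dtype=float)
        if arr.ndim == 0:
            arr = np.full(n_frames, float(arr))
        if arr.size != n_frames:
            raise ValueError("per-frame radius arrays must have n_frames entries")
        radii.append(arr)
    if len(radii) != len(centers):
        raise ValueError("need one radius law per center")
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            dist = math.dist(centers[i], centers[j])
            if dist <= radii[i][0] + radii[j][0]:
                raise ValueError("bubbles overlap at t = 0")

    frames = np.empty((n_frames,) + shape, dtype=float)
    ref_mask = (
        _reference_mask(shape, reference_anchor) if reference_anchor else None
    )
    for fi in range(n_frames):
        frame = np.full(shape, background)
        for center, rr in zip(centers, radii):
            _render_disk(frame, center, rr[fi], foreground, edge_px=edge_px)
        if ref_mask is not None:
            frame[ref_mask] = foreground
        if illumination_sigma > 0:
            frame *= 1.0 + rng.normal(0.0, illumination_sigma)
        if noise_sigma > 0:
            frame += rng.normal(0.0, noise_sigma, size=shape)
        frames[fi] = np.clip(frame, 0.0, 1.0)

    stack = ImageStack(
        frames=frames,
        frame_rate=frame_rate,
        pixel_size=pixel_size,
        impact_frame=impact_frame,
    )
    truth = {
        "radii_px": [r.copy() for r in radii],
        "centers": list(centers),
        "reference_mask": ref_mask,
        "background": background,
        "foreground": foreground,
        "seed": seed,
    }
    return stack, truth


def make_impact_experiment(
    props: MaterialProperties,
    depths: Sequence[float],
    amplitudes_g: Sequence[float] = MEASURED_AMPLITUDES_G,
    kappa: float = DEFAULT_KAPPA,
    r0: float = DEFAULT_BUBBLE_RADIUS,
    sample_height: float = DEFAULT_SAMPLE_HEIGHT,
    pulse: Optional[PressurePulse] = None,
    config: Optional[SolverConfig] = None,
) -> list[BubbleObservation]:
    """Physics-coupled synthetic experiment closing the empirical loop.

    For every (amplitude, depth) pair the depth law maps acceleration to a
    pressure amplitude, the bubble simulator produces lambda_max, and the
    results are packaged as per-bubble observations.  Deterministic: the
    only inputs are the physics and the geometry.

    The default solver uses absolute pressure bookkeeping: a macro bubble
    in a near-fluid gel is stabilized by the atmosphere, and dropping it
    (the reduced bookkeeping appropriate for stiff gels and submicron
    bubbles) would make the rest state vapor-unstable.
    """
    if pulse is None:
        pulse = make_pulse(max(amplitudes_g))
    if config is None:
        config = SolverConfig(pressure_convention="absolute")
    out = []
    for i, h in enumerate(depths):
        geom = ImpactGeometry(
            sample_height=sample_height, bubble_depth=float(h), coupling=kappa
        )
        lams = []
        for a_g in amplitudes_g:
            p_amp = depth_to_pressure(a_g * G_STANDARD, geom, props.density)
            if p_amp == 0.0:
                lams.append(1.0)
                continue
            traj = simulate_bubble(
                props, pulse.with_pressure_amplitude(p_amp), r0, config
            )
            lams.append(traj.lambda_max)
        out.append(
            BubbleObservation(
                bubble_id=f"bubble_{i + 1}",
                depth=float(h),
                initial_radius=r0,
                amplitudes_g=np.asarray(amplitudes_g, dtype=float),
                lambda_max=np.asarray(lams),
            )
        )
    return out
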