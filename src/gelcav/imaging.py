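"""High-speed image analysis: segmentation, radius tracking, and QC.

Bubbles are segmented per frame by a single global threshold (the same
threshold for every frame of a stack), labelled with 8-connectivity, and
reduced to an equivalent radius r = sqrt(A/pi) from the projected area.
Tracking is nearest-centroid frame to frame; a series is flagged merged
from the first frame where two tracked bubbles map onto one region.  The
pre-impact baseline radius is the mean over a window of frames ending at
the impact frame (default 49), and a rigid reference inclusion bounds the
measurement error via the mean and 95% CI of r_ref/r0 after impact.

Coordinates are (row, col), 0-based, origin at the top-left; depth below
the gel surface follows from the pixel calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from skimage import measure

__all__ = [
    "ImageStack",
    "Region",
    "RadiusSeries",
    "QCResult",
    "segment_frame",
    "equivalent_radius",
    "track_bubbles",
    "baseline_radius",
    "reference_qc",
]


@dataclass
class ImageStack:
    """A grayscale high-speed stack with its acquisition calibration."""

    frames: np.ndarray            # (n_frames, rows, cols)
    frame_rate: float             # frames / s
    pixel_size: float             # m / px
    impact_frame: int = 0         # index of t = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, rows, cols) array")
        if self.frame_rate <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_rate and pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Per-frame times in s; negative before impact."""
        return (np.arange(self.n_frames) - self.impact_frame) / self.frame_rate


class Region(NamedTuple):
    label: int
    area_px: float
    area: Optional[float]          # m^2 when pixel size known
    centroid: tuple[float, float]  # (row, col)


def segment_frame(
    frame: np.ndarray,
    threshold: float,
    dark_objects: bool = True,
    pixel_size: Optional[float] = None,
) -> list[Region]:
    """Threshold a frame and return connected foreground regions.

    ``dark_objects`` selects the polarity: bubbles imaging dark on a
    bright background are foreground where the intensity falls *below*
    the threshold.  An empty mask returns an empty list, not an error.
    """
    frame = np.asarray(frame)
    lo, hi = float(frame.min()), float(frame.max())
    mask = frame < threshold if dark_objects else frame > threshold
    if mask.all():
        # A threshold past the far end of the value range would label the
        # whole frame as one object; that is a setting error, whereas an
        # empty mask (nothing detected) is a legitimate outcome.
        raise ValueError(
            f"threshold {threshold} marks the entire frame as foreground "
            f"(frame range [{lo}, {hi}])"
        )
    labels = measure.label(mask, connectivity=2)
    out = []
    for rp in measure.regionprops(labels):
        area_px = float(rp.area)
        area = area_px * pixel_size ** 2 if pixel_size else None
        out.append(Region(int(rp.label), area_px, area, tuple(rp.centroid)))
    return out


def equivalent_radius(area: float) -> float:
    """Radius of the circle with the same projected area, sqrt(A/pi)."""
    if area < 0:
        raise ValueError("area must be non-negative")
    return math.sqrt(area / math.pi)


@dataclass
class RadiusSeries:
    """Equivalent-radius time series for one tracked object."""

    bubble_id: str
    times: np.ndarray              # s
    radius: np.ndarray             # m
    frames: np.ndarray             # frame indices
    merged: np.ndarray             # per-frame merge flag
    baseline: Optional[float] = None  # r0, m
    is_reference: bool = False
    truncated_reason: Optional[str] = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def lam(self) -> np.ndarray:
        """Normalized radius r/r0 (requires the baseline to be set)."""
        if self.baseline is None:
            raise ValueError("baseline radius not set; run baseline_radius first")
        return self.radius / self.baseline

    @property
    def lambda_max(self) -> float:
        valid = ~self.merged
        if not np.any(valid):
            raise ValueError("no unmerged frames")
        return float(np.max(self.lam[valid]))


def track_bubbles(
    stack: ImageStack,
    seed_positions: Sequence[tuple[float, float]],
    threshold: float,
    dark_objects: bool = True,
    search_radius_px: float = 20.0,
    reference_index: Optional[int] = None,
) -> list[RadiusSeries]:
    """Track seeded bubbles through a stack by nearest-centroid association.

    Each seed (row, col) is matched per frame to the nearest segmented
    region within ``search_radius_px`` of its last known centroid.  When
    two seeds map to the same region the corresponding series are flagged
    merged from that frame on.  A seed with no region in range has its
    series truncated with a reason recorded.
    """
    rows, cols = stack.frames.shape[1:]
    for r, c in seed_positions:
        if not (0 <= r < rows and 0 <= c < cols):
            raise ValueError(f"seed position {(r, c)} outside frame bounds")
    n = len(seed_positions)
    centroids = [np.asarray(p, dtype=float) for p in seed_positions]
    alive = [True] * n
    reasons: list[Optional[str]] = [None] * n
    times_acc: list[list[float]] = [[] for _ in range(n)]
    rad_acc: list[list[float]] = [[] for _ in range(n)]
    frame_acc: list[list[int]] = [[] for _ in range(n)]
    merged_acc: list[list[bool]] = [[] for _ in range(n)]
    merged_state = [False] * n
    times = stack.times

    for fi in range(stack.n_frames):
        regions = segment_frame(
            stack.frames[fi], threshold, dark_objects, stack.pixel_size
        )
        if not regions:
            for b in range(n):
                if alive[b]:
                    alive[b] = False
                    reasons[b] = f"no regions found at frame {fi}"
            break
        reg_centroids = np.array([r.centroid for r in regions])
        assignment: dict[int, list[int]] = {}
        for b in range(n):
            if not alive[b]:
                continue
            d = np.linalg.norm(reg_centroids - centroids[b], axis=1)
            j = int(np.argmin(d))
            if d[j] > search_radius_px:
                alive[b] = False
                reasons[b] = f"lost at frame {fi} (nearest region {d[j]:.1f} px away)"
                continue
            assignment.setdefault(j, []).append(b)
        for j, bubbles in assignment.items():
            if len(bubbles) > 1:
                for b in bubbles:
                    merged_state[b] = True
        for j, bubbles in assignment.items():
            region = regions[j]
            radius = equivalent_radius(region.area)
            for b in bubbles:
                centroids[b] = np.asarray(region.centroid, dtype=float)
                times_acc[b].append(float(times[fi]))
                rad_acc[b].append(radius)
                frame_acc[b].append(fi)
                merged_acc[b].append(merged_state[b])

    out = []
    for b in range(n):
        out.append(
            RadiusSeries(
                bubble_id=f"bubble_{b + 1}",
                times=np.asarray(times_acc[b]),
                radius=np.asarray(rad_acc[b]),
                frames=np.asarray(frame_acc[b], dtype=int),
                merged=np.asarray(merged_acc[b], dtype=bool),
                is_reference=(reference_index == b),
                truncated_reason=reasons[b],
            )
        )
    return out


def baseline_radius(series: RadiusSeries, n_frames: int = 49) -> float:
    """Pre-impact baseline r0: mean radius over the window ending at t = 0.

    Uses the last ``n_frames`` samples with non-positive time; at least one
    pre-impact frame is required.  Sets ``series.baseline``.
    """
    pre = series.times <= 0
    if not np.any(pre):
        raise ValueError("no pre-impact frames in the series")
    radii = series.radius[pre][-n_frames:]
    r0 = float(np.mean(radii))
    series.baseline = r0
    return r0


class QCResult(NamedTuple):
    mean_lambda: float
    ci95_halfwidth: float
    n: int
    passed: Optional[bool]


def reference_qc(
    reference_series: Optional[RadiusSeries],
    observed_excess: Optional[float] = None,
    max_ci_fraction: float = 0.5,
) -> QCResult:
    """Rigid-reference quality control over the post-impact window.

    Returns the mean of r_ref/r0 after impact and its normal-approximation
    95% confidence half-width (1.96 SE).  When the observed bubble
    deformation ``observed_excess`` (= lambda_max - 1) is supplied, the QC
    passes if the half-width is below ``max_ci_fraction`` of it.  A missing
    reference is a QC failure.
    """
    if reference_series is None or reference_series.times.size == 0:
        return QCResult(math.nan, math.nan, 0, False)
    if reference_series.baseline is None:
        baseline_radius(reference_series)
    post = reference_series.times > 0
    lam = reference_series.lam[post]
    if lam.size < 3:
        raise ValueError("need at least 3 post-impact frames for the reference QC")
    mean = float(np.mean(lam))
    se = float(np.std(lam, ddof=1) / math.sqrt(lam.size))
    half = 1.96 * se
    passed = None
    if observed_excess is not None:
        passed = half < max_ci_fraction * observed_excess
    return QCResult(mean, half, int(lam.size), passed)
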