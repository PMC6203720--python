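"""Regression pipeline for the depth-squared pressure-gradient law.

Per-bubble slopes d(lambda_max)/d(|a|/g) are fit by ordinary least
squares, their depth dependence is fit as a power law (with the
constrained quadratic fit reported alongside), and the pooled dataset is
fit to the combined law

    lambda_max = k (|a_amp|/g) (h_b/H)^2 + c

whose coefficient of determination R^2 = 1 - SS_res/SS_tot summarizes the
collapse of all bubbles onto a single line.  Amplitudes are handled in
g-units throughout, matching the per-g slope convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence
import warnings

import numpy as np

__all__ = [
    "BubbleObservation",
    "SlopeFit",
    "DepthScalingFit",
    "FitResult",
    "per_bubble_slope",
    "depth_scaling_fit",
    "combined_law_fit",
]


@dataclass
class BubbleObservation:
    """Per-drop (|a_amp| in g, lambda_max) records for one tracked bubble."""

    bubble_id: str
    depth: float                    # h_b, m
    initial_radius: float           # r0, m
    amplitudes_g: np.ndarray
    lambda_max: np.ndarray
    excluded: bool = False          # e.g. merged with a neighbor upstream

    def __post_init__(self) -> None:
        self.amplitudes_g = np.asarray(self.amplitudes_g, dtype=float)
        self.lambda_max = np.asarray(self.lambda_max, dtype=float)
        if self.amplitudes_g.shape != self.lambda_max.shape:
            raise ValueError("amplitudes_g and lambda_max must have equal length")
        if np.any(self.amplitudes_g < 0):
            raise ValueError("amplitudes must be non-negative")
        if np.any(self.lambda_max < 1.0 - 1e-6):
            raise ValueError("lambda_max below 1 is unphysical for expansion records")


class SlopeFit(NamedTuple):
    slope: float        # per g
    intercept: float
    stderr: float


def per_bubble_slope(records) -> SlopeFit:
    """OLS slope of lambda_max on |a_amp|/g for one bubble.

    ``records`` is a :class:`BubbleObservation` or an ``(amplitudes_g,
    lambda_max)`` pair with at least two distinct amplitudes.
    """
    if isinstance(records, BubbleObservation):
        a, lam = records.amplitudes_g, records.lambda_max
    else:
        a, lam = (np.asarray(x, dtype=float) for x in records)
    if a.size < 2 or np.ptp(a) == 0:
        raise ValueError("need at least 2 distinct amplitudes")
    A = np.column_stack([a, np.ones_like(a)])
    coef, *_ = np.linalg.lstsq(A, lam, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    resid = lam - A @ coef
    dof = max(a.size - 2, 1)
    s2 = float(resid @ resid) / dof
    sxx = float(np.sum((a - a.mean()) ** 2))
    return SlopeFit(slope, intercept, float(np.sqrt(s2 / sxx)))


class DepthScalingFit(NamedTuple):
    beta: float              # free power-law exponent of slope vs depth
    prefactor: float         # alpha in slope = alpha * h^beta
    beta_stderr: float
    quadratic_prefactor: float   # alpha for the constrained beta = 2 fit
    quadratic_residual: float    # RMS log-residual of the constrained fit


def depth_scaling_fit(slopes: Sequence[float], depths: Sequence[float]) -> DepthScalingFit:
    """Power-law fit of per-bubble slopes versus bubble depth.

    Fits log s = log alpha + beta log h by OLS, and also reports the
    constrained beta = 2 fit's prefactor and RMS residual.  Non-positive
    slopes are excluded with a warning (they carry no log).
    """
    s = np.asarray(slopes, dtype=float)
    h = np.asarray(depths, dtype=float)
    if np.any(h <= 0):
        raise ValueError("depths must be positive")
    keep = s > 0
    if not np.all(keep):
        warnings.warn(
            f"excluding {np.count_nonzero(~keep)} non-positive slope(s) "
            "from the power-law fit",
            stacklevel=2,
        )
        s, h = s[keep], h[keep]
    if np.unique(h).size < 3:
        raise ValueError("need at least 3 distinct depths")
    x, y = np.log(h), np.log(s)
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    beta, log_alpha = float(coef[0]), float(coef[1])
    resid = y - A @ coef
    dof = max(x.size - 2, 1)
    sxx = float(np.sum((x - x.mean()) ** 2))
    beta_se = float(np.sqrt((resid @ resid) / dof / sxx))
    # Constrained beta = 2: log alpha2 = mean(log s - 2 log h).
    log_alpha2 = float(np.mean(y - 2.0 * x))
    resid2 = y - (2.0 * x + log_alpha2)
    return DepthScalingFit(
        beta=beta,
        prefactor=float(np.exp(log_alpha)),
        beta_stderr=beta_se,
        quadratic_prefactor=float(np.exp(log_alpha2)),
        quadratic_residual=float(np.sqrt(np.mean(resid2 ** 2))),
    )


@dataclass
class FitResult:
    """Combined-law fit: lambda_max = k (|a|/g)(h_b/H)^2 + c."""

    slope_k: float
    intercept_c: float
    r_squared: float
    n_points: int
    n_bubbles: int
    sample_height: float
    residual_std: float
    per_bubble_slopes: dict = field(default_factory=dict)

    def predict(self, amplitudes_g, depths) -> np.ndarray:
        x = np.asarray(amplitudes_g, float) * (
            np.asarray(depths, float) / self.sample_height
        ) ** 2
        return self.slope_k * x + self.intercept_c

    def to_json(self, path=None) -> str:
        payload = {
            "slope_k": self.slope_k,
            "intercept_c": self.intercept_c,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "n_bubbles": self.n_bubbles,
            "sample_height_m": self.sample_height,
            "residual_std": self.residual_std,
            "per_bubble_slopes": self.per_bubble_slopes,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def combined_law_fit(
    dataset: Sequence[BubbleObservation], sample_height: float
) -> FitResult:
    """Pooled OLS fit of lambda_max on x = (|a|/g)(h_b/H)^2.

    Excluded (e.g. merged) observations are dropped; the design must span
    at least two distinct depths and three points.
    """
    obs = [o for o in dataset if not o.excluded]
    if not obs:
        raise ValueError("no usable observations")
    depths = np.concatenate([np.full(o.amplitudes_g.size, o.depth) for o in obs])
    amps = np.concatenate([o.amplitudes_g for o in obs])
    lam = np.concatenate([o.lambda_max for o in obs])
    if lam.size < 3:
        raise ValueError("need at least 3 points")
    if np.unique(depths).size < 2:
        raise ValueError("need observations spanning at least 2 depths")
    x = amps * (depths / sample_height) ** 2
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the design variable")
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, lam, rcond=None)
    pred = A @ coef
    ss_res = float(np.sum((lam - pred) ** 2))
    ss_tot = float(np.sum((lam - lam.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    slopes = {}
    for o in obs:
        if o.amplitudes_g.size >= 2 and np.ptp(o.amplitudes_g) > 0:
            slopes[o.bubble_id] = per_bubble_slope(o).slope
    return FitResult(
        slope_k=float(coef[0]),
        intercept_c=float(coef[1]),
        r_squared=r2,
        n_points=int(lam.size),
        n_bubbles=len(obs),
        sample_height=sample_height,
        residual_std=float(np.std(lam - pred, ddof=2)) if lam.size > 2 else 0.0,
        per_bubble_slopes=slopes,
    )
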