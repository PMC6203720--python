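"""Readers and writers for the pipeline's on-disk formats.

Acceleration traces and tabular results travel as headered CSV, image
stacks as multi-page TIFF or numbered PNG sequences, and summaries as
JSON sidecars carrying enough metadata (units, seed, configuration) to
re-run the producing stage.  All write-then-read round trips are stable
to 1e-12 relative.
"""

from __future__ import annotations

import glob
import json
import os
from dataclasses import asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .bubble_dynamics import BubbleTrajectory, PressurePulse
from .constants import G_STANDARD
from .fits import BubbleObservation, FitResult
from .imaging import ImageStack, RadiusSeries
from .sweep import SweepCurve

__all__ = [
    "SchemaError",
    "read_acceleration_csv",
    "write_acceleration_csv",
    "write_trajectory",
    "read_trajectory_csv",
    "write_sweep",
    "read_dataset_csv",
    "write_dataset_csv",
    "write_fit_json",
    "write_stack_tiff",
    "read_stack_tiff",
    "read_png_sequence",
    "write_radius_series",
]


class SchemaError(ValueError):
    """A file does not match the expected column schema."""


def _provenance(extra: Optional[dict] = None) -> dict:
    rec = {"package": "gelcav", "version": _version}
    if extra:
        rec.update(extra)
    return rec


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )


def read_acceleration_csv(path) -> PressurePulse:
    """Read a 2-column acceleration trace (time_s, accel_g) into a pulse.

    The g-unit column is converted to m/s^2 with g = 9.81; the waveform is
    normalized to peak 1 and the peak time recorded.  Malformed rows are
    reported with their line numbers.
    """
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as err:
        raise SchemaError(f"{path}: could not parse CSV ({err})") from err
    _require_columns(df, ["time_s", "accel_g"], path)
    bad = df.index[df[["time_s", "accel_g"]].isna().any(axis=1)]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:5]]  # +2: header + 1-based
        raise SchemaError(f"{path}: malformed rows at line(s) {lines}")
    t = df["time_s"].to_numpy(dtype=float)
    a_g = df["accel_g"].to_numpy(dtype=float)
    peak = np.max(np.abs(a_g))
    if peak == 0:
        raise SchemaError(f"{path}: acceleration trace is identically zero")
    signal = a_g / peak
    if abs(signal[0]) > 1e-12:
        # Shift the trace so the pulse starts from rest, preserving shape.
        signal = signal - signal[0]
        signal = signal / np.max(np.abs(signal))
    i_peak = int(np.argmax(np.abs(signal)))
    return PressurePulse(
        times=t,
        normalized_signal=np.abs(signal) if signal[i_peak] < 0 else signal,
        amplitude=peak * G_STANDARD,
        peak_time=float(t[i_peak]),
    )


def write_acceleration_csv(path, pulse: PressurePulse) -> None:
    df = pd.DataFrame(
        {
            "time_s": pulse.times,
            "accel_g": pulse.normalized_signal * pulse.amplitude_g,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def write_trajectory(csv_path, traj: BubbleTrajectory, extra_meta: Optional[dict] = None) -> None:
    """Trajectory CSV (time_s, radius_m, lambda) plus a JSON feature sidecar."""
    pd.DataFrame(
        {"time_s": traj.times, "radius_m": traj.radius, "lambda": traj.lam}
    ).to_csv(csv_path, index=False, float_format="%.17g")
    sidecar = {
        "initial_radius_m": traj.initial_radius,
        "lambda_max": traj.lambda_max,
        "t_max_out_s": traj.t_max_out,
        "collapsed": traj.collapsed,
        "gas_pressure_init_Pa": traj.gas_pressure_init,
        "solver_diagnostics": {
            k: v for k, v in traj.solver_diagnostics.items() if not isinstance(v, np.ndarray)
        },
        "provenance": _provenance(extra_meta),
    }
    with open(os.fspath(csv_path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2, default=float)


def read_trajectory_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["time_s", "radius_m", "lambda"], path)
    return df


def write_sweep(csv_path, curve: SweepCurve, extra_meta: Optional[dict] = None) -> None:
    """Sweep CSV (p_amp_Pa, lambda_max, t_max_out_s) plus JSON summary."""
    pd.DataFrame(
        {
            "p_amp_Pa": curve.p_amp,
            "lambda_max": curve.lambda_max,
            "t_max_out_s": curve.t_max_out,
        }
    ).to_csv(csv_path, index=False, float_format="%.17g")
    summary = {
        "r0_m": curve.r0,
        "burst_detected": curve.burst_detected,
        "p_amp_cn_Pa": curve.p_amp_cn,
        "jump_orders": curve.jump_orders,
        "lambda_before": curve.lambda_before,
        "lambda_after": curve.lambda_after,
        "material": curve.props.label,
        "pressure_convention": curve.config.pressure_convention,
        "provenance": _provenance(extra_meta),
    }
    with open(os.fspath(csv_path) + ".json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)


_DATASET_COLUMNS = ["bubble_id", "h_b_m", "r0_m", "a_amp_g", "lambda_max"]


def write_dataset_csv(path, observations: Sequence[BubbleObservation]) -> None:
    rows = []
    for o in observations:
        for a, lam in zip(o.amplitudes_g, o.lambda_max):
            rows.append((o.bubble_id, o.depth, o.initial_radius, a, lam))
    pd.DataFrame(rows, columns=_DATASET_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_dataset_csv(path) -> list[BubbleObservation]:
    df = pd.read_csv(path)
    _require_columns(df, _DATASET_COLUMNS, path)
    out = []
    for bid, grp in df.groupby("bubble_id", sort=False):
        out.append(
            BubbleObservation(
                bubble_id=str(bid),
                depth=float(grp["h_b_m"].iloc[0]),
                initial_radius=float(grp["r0_m"].iloc[0]),
                amplitudes_g=grp["a_amp_g"].to_numpy(dtype=float),
                lambda_max=grp["lambda_max"].to_numpy(dtype=float),
            )
        )
    return out


def write_fit_json(path, result: FitResult, extra_meta: Optional[dict] = None) -> None:
    payload = json.loads(result.to_json())
    payload["provenance"] = _provenance(extra_meta)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def write_stack_tiff(path, stack: ImageStack) -> None:
    import tifffile

    data = np.clip(stack.frames * 255.0, 0, 255).astype(np.uint8)
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        metadata={
            "frame_rate": stack.frame_rate,
            "pixel_size_m": stack.pixel_size,
            "impact_frame": stack.impact_frame,
        },
    )


def read_stack_tiff(path, frame_rate=None, pixel_size=None, impact_frame=0) -> ImageStack:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    return ImageStack(
        frames=data.astype(float) / 255.0,
        frame_rate=float(frame_rate or meta.get("frame_rate", 25_000.0)),
        pixel_size=float(pixel_size or meta.get("pixel_size_m", 1.0)),
        impact_frame=int(meta.get("impact_frame", impact_frame)),
    )


def read_png_sequence(pattern, frame_rate, pixel_size, impact_frame=0) -> ImageStack:
    """Read a numbered PNG sequence (glob pattern, lexicographic order)."""
    import imageio.v3 as iio

    paths = sorted(glob.glob(str(pattern)))
    if not paths:
        raise FileNotFoundError(f"no files match {pattern!r}")
    frames = np.stack([np.asarray(iio.imread(p), dtype=float) for p in paths])
    if frames.ndim == 4:  # RGB(A): collapse to gray
        frames = frames[..., :3].mean(axis=-1)
    if frames.max() > 1.0:
        frames = frames / 255.0
    return ImageStack(frames, frame_rate, pixel_size, impact_frame)


def write_radius_series(csv_path, series: RadiusSeries, qc: Optional[dict] = None) -> None:
    """Per-bubble CSV (frame, time_s, radius_m, lambda, merged) + QC JSON."""
    lam = series.radius / series.baseline if series.baseline else np.full_like(series.radius, np.nan)
    pd.DataFrame(
        {
            "frame": series.frames,
            "time_s": series.times,
            "radius_m": series.radius,
            "lambda": lam,
            "merged": series.merged.astype(int),
        }
    ).to_csv(csv_path, index=False, float_format="%.17g")
    sidecar = {
        "bubble_id": series.bubble_id,
        "baseline_radius_m": series.baseline,
        "is_reference": series.is_reference,
        "truncated_reason": series.truncated_reason,
        "qc": qc,
        "provenance": _provenance(),
    }
    with open(os.fspath(csv_path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2, default=float)
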