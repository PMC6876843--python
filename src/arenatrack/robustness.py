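"""Tracking-robustness procedures on synthetic ground-truthed video.

Three stressors, each mirroring a published failure mode of long
background-subtraction experiments:

* **Binary pixel noise** injected into the thresholded image, downstream
  of the noise monitor and upstream of segmentation — tracking with a
  poorly calibrated noise correction.
* **Reference shifts**: the stored background displaced a few pixels in a
  random direction on a fixed period — an accidental nudge of the arena —
  with the monitor and automatic reacquisition active.
* **Lossy compression**: the video round-tripped through the delta codec
  at decreasing quality, tracked offline, and compared to traces from the
  uncompressed original.

Every procedure reports measured error statistics against exact ground
truth (or, for compression, against the uncompressed-video traces,
matching how offline tracking is validated in practice).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .synth import binary_noise_hook, make_fixture
from .tracker import TrackerConfig, TrackingResult, run
from .video import encode_video, read_delta_video

__all__ = [
    "fixture_config",
    "tracking_errors",
    "noise_sweep",
    "shift_session",
    "compression_sweep",
]


def fixture_config(fps: float = 30.0) -> TrackerConfig:
    """Tracker settings matched to the synthetic fixture's imaging regime."""
    return TrackerConfig(
        intensity_threshold=25.0,
        min_area=20.0,
        max_area=600.0,
        fps=fps,
    )


def tracking_errors(result: TrackingResult, truth: np.ndarray) -> np.ndarray:
    """Per-(frame, roi) Euclidean error for tracked (non-missing) frames."""
    est = result.positions_array()[:, :, 0, :]  # single animal per ROI
    T = min(est.shape[0], truth.shape[1])
    err = np.linalg.norm(est[:T] - truth[:, :T, :].transpose(1, 0, 2), axis=2)
    return err[np.isfinite(err)]


@dataclass
class SweepPoint:
    level: float
    median_error: float
    mean_error: float
    n_tracked: int


def noise_sweep(
    seed: int,
    probabilities=(0.0, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40),
    duration_s: float = 120.0,
    fps: float = 30.0,
) -> list[SweepPoint]:
    """Median tracking error vs binary-noise injection probability."""
    scene, rois, truth, frames = make_fixture(seed, duration_s, fps)
    cfg = fixture_config(fps)
    frame_list = list(frames())  # render once, track many times
    out = []
    for k, p in enumerate(probabilities):
        hook = binary_noise_hook(p, seed=seed * 1000 + k) if p > 0 else None
        result = run(frame_list, cfg, rois=rois, binary_hook=hook)
        err = tracking_errors(result, truth)
        out.append(
            SweepPoint(
                level=float(p),
                median_error=float(np.median(err)) if err.size else math.inf,
                mean_error=float(np.mean(err)) if err.size else math.inf,
                n_tracked=int(err.size),
            )
        )
    return out


@dataclass
class ShiftSessionResult:
    mean_error: float
    median_error: float
    pearson_r: float
    n_shifts: int
    n_reacquisitions: int
    n_tracked: int


def shift_session(
    seed: int,
    duration_s: float = 300.0,
    fps: float = 30.0,
    shift_px: float = 2.0,
    shift_period_s: float = 2.0,
) -> ShiftSessionResult:
    """Periodic reference displacement with monitor + reacquisition active.

    Every ``shift_period_s`` the stored background (stack and reference)
    is displaced ``shift_px`` in a uniformly random direction, rounded to
    whole pixels.  Reports mean/median centroid error over tracked frames
    and the Pearson correlation between tracked and true coordinates.
    """
    scene, rois, truth, frames = make_fixture(seed, duration_s, fps)
    cfg = fixture_config(fps)
    period = int(round(shift_period_s * fps))
    shift_rng = np.random.default_rng(seed + 7919)
    n_shifts = 0

    def on_frame(frame_idx, state):
        nonlocal n_shifts
        # start shifting once the baseline is in place, as in a session
        # that degrades after clean calibration
        if state.noise is None or frame_idx == 0 or frame_idx % period:
            return
        ang = shift_rng.uniform(0.0, 2.0 * math.pi)
        dx = int(round(shift_px * math.cos(ang)))
        dy = int(round(shift_px * math.sin(ang)))
        if dx == 0 and dy == 0:
            dx = int(math.copysign(shift_px, math.cos(ang)))
        state.model.shift_reference(dx, dy)
        n_shifts += 1

    result = run(frames(), cfg, rois=rois, frame_callback=on_frame)
    err = tracking_errors(result, truth)

    est = result.positions_array()[:, :, 0, :]
    tr = truth.transpose(1, 0, 2)[: est.shape[0]]
    ok = np.isfinite(est).all(axis=2)
    a = np.concatenate([est[ok][:, 0], est[ok][:, 1]])
    b = np.concatenate([tr[ok][:, 0], tr[ok][:, 1]])
    r = float(np.corrcoef(a, b)[0, 1]) if a.size > 1 else math.nan

    return ShiftSessionResult(
        mean_error=float(np.mean(err)),
        median_error=float(np.median(err)),
        pearson_r=r,
        n_shifts=n_shifts,
        n_reacquisitions=len(result.reacquire_frames),
        n_tracked=int(err.size),
    )


@dataclass
class CompressionPoint:
    quant_step: int
    downsample: int
    ratio: float
    median_error: float
    n_compared: int


def compression_sweep(
    seed: int,
    out_dir,
    settings=((8, 1), (32, 2), (64, 2), (32, 4), (48, 4), (64, 4)),
    duration_s: float = 120.0,
    fps: float = 30.0,
) -> list[CompressionPoint]:
    """Track codec round-trips at decreasing quality.

    Reference traces come from tracking the uncompressed frames; each
    setting's traces are compared frame-by-frame to those.  The achieved
    raw-to-encoded size ratio is measured per setting.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scene, rois, truth, frames = make_fixture(seed, duration_s, fps)
    cfg = fixture_config(fps)
    frame_list = list(frames())  # render once
    reference = run(frame_list, cfg, rois=rois).positions_array()[:, :, 0, :]

    out = []
    for step_q, ds in settings:
        path = out_dir / f"fixture_q{step_q}_ds{ds}.adv"
        info = encode_video(frame_list, path, fps=fps, quant_step=step_q,
                            downsample=ds)
        result = run(read_delta_video(path), cfg, rois=rois)
        est = result.positions_array()[:, :, 0, :]
        T = min(len(est), len(reference))
        err = np.linalg.norm(est[:T] - reference[:T], axis=2)
        err = err[np.isfinite(err)]
        out.append(
            CompressionPoint(
                quant_step=int(step_q),
                downsample=int(ds),
                ratio=float(info["ratio"]),
                median_error=float(np.median(err)) if err.size else math.inf,
                n_compared=int(err.size),
            )
        )
        path.unlink()  # keep only the numbers; files are scratch
    return out
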