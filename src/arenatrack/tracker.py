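"""Per-frame tracking loop: segment, assign to ROIs, match to traces.

Each frame passes through three stages.  Image processing computes, per
ROI, the clamped difference against the background reference and
thresholds it to a binary foreground image.  Noise estimation sums the
above-threshold pixels over all ROIs and asks the monitor whether the
frame is trackable; untrackable frames extend every trace with a missing
marker (NaN) and, after enough consecutive failures, force background
reacquisition.  Tracking segments candidate blobs (area-filtered connected
components inside the ROI), and matches them to the ROI's traces by
minimizing total frame-to-frame displacement (exact Hungarian assignment;
spatial segregation makes the per-ROI problems tiny).

Identity across frames is carried by the ROI, not by appearance: traces
never leave their ROI, and within a multi-animal ROI the individual slots
are only displacement-consistent, with no attempt to resolve collisions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .background import BackgroundModel, initialize_background
from .noise import NoiseState, sample_baseline
from .roi import ROISet, detect_rois_auto
from .segment import Blob, segment_binary, threshold_diff

__all__ = [
    "TrackerConfig",
    "Trace",
    "FrameResult",
    "TrackerState",
    "TrackingResult",
    "segment",
    "match",
    "step",
    "heading_series",
    "run",
]

_BIG = 1e9  # cost for traces with no previous position


@dataclass
class TrackerConfig:
    """Tracking parameters (all distances in pixels, areas in px^2)."""

    intensity_threshold: float = 25.0
    min_area: float = 20.0
    max_area: float = 600.0
    n_per_roi: int = 1
    fps: float = 30.0
    px2mm: float | None = None
    invert_polarity: bool = False
    with_orientation: bool = False
    # background model
    bg_stack_size: int = 10
    bg_combine: str = "median"
    d_min: float | None = None  # None -> one body length, estimated
    init_max_frames: int = 300
    # noise monitor
    noise_window: int = 10
    k_flag: float = 5.0
    m_reacquire: int = 10
    baseline_frames: int = 60
    # automatic ROI detection
    roi_quantile: float = 0.9
    roi_min_area: float = 500.0
    roi_max_area: float = 1e7
    # assignment
    greedy_above: int = 32

    def __post_init__(self) -> None:
        if not 0 < self.min_area < self.max_area:
            raise ValueError("need 0 < min_area < max_area")
        if self.fps <= 0:
            raise ValueError("fps must be positive")


@dataclass
class Trace:
    """One individual's per-frame time series (NaN marks missing)."""

    roi_id: int
    individual: int
    positions: np.ndarray  # (T, 2) float32, (x, y)
    areas: np.ndarray  # (T,) float32
    headings: np.ndarray | None = None  # (T,) radians


@dataclass
class FrameResult:
    frame_index: int
    decision: str  # "clean" | "noisy"
    count: int  # above-threshold pixels over all ROIs
    assignments: list[list[tuple[float, float] | None]]  # per ROI, per slot
    reacquired: bool = False


class TrackerState:
    """Everything the per-frame loop mutates."""

    def __init__(
        self,
        rois: ROISet,
        model: BackgroundModel,
        cfg: TrackerConfig,
        binary_hook=None,
        baseline_start: int = 0,
    ):
        self.rois = rois
        self.model = model
        self.cfg = cfg
        self.noise: NoiseState | None = None
        self.binary_hook = binary_hook  # callable(bw, roi_id, frame_idx)
        # frame index from which baseline counts are collected; counts from
        # the warm-up replay (background still settling) are not baseline
        self.baseline_start = baseline_start
        n, m = len(rois), cfg.n_per_roi
        self.frame_index = 0
        self.last_positions = np.full((n, m, 2), np.nan, dtype=np.float64)
        self._xs: list[list[list[float]]] = [
            [[] for _ in range(m)] for _ in range(n)
        ]
        self._ys = [[[] for _ in range(m)] for _ in range(n)]
        self._areas = [[[] for _ in range(m)] for _ in range(n)]
        self.counts: list[int] = []
        self.decisions: list[str] = []
        self.reacquire_frames: list[int] = []
        self._baseline_buffer: list[int] = []
        self._resample_buffer: list[int] | None = None

    def finalize(self) -> "TrackingResult":
        traces = []
        for rid in range(len(self.rois)):
            for ind in range(self.cfg.n_per_roi):
                pos = np.column_stack(
                    [
                        np.asarray(self._xs[rid][ind], dtype=np.float32),
                        np.asarray(self._ys[rid][ind], dtype=np.float32),
                    ]
                )
                traces.append(
                    Trace(
                        roi_id=rid,
                        individual=ind,
                        positions=pos,
                        areas=np.asarray(self._areas[rid][ind], dtype=np.float32),
                    )
                )
        return TrackingResult(
            traces=traces,
            rois=self.rois,
            cfg=self.cfg,
            counts=np.asarray(self.counts),
            decisions=self.decisions,
            reacquire_frames=list(self.reacquire_frames),
        )


@dataclass
class TrackingResult:
    traces: list[Trace]
    rois: ROISet
    cfg: TrackerConfig
    counts: np.ndarray
    decisions: list[str]
    reacquire_frames: list[int]
    container_path: object = None

    @property
    def n_frames(self) -> int:
        return len(self.decisions)

    def positions_array(self) -> np.ndarray:
        """(T, n_rois, n_per_roi, 2) float array of tracked positions."""
        n, m = len(self.rois), self.cfg.n_per_roi
        out = np.full((self.n_frames, n, m, 2), np.nan, dtype=np.float64)
        for tr in self.traces:
            out[:, tr.roi_id, tr.individual, :] = tr.positions
        return out


def segment(diff: np.ndarray, cfg: TrackerConfig) -> list[Blob]:
    """Candidate blobs from a non-negative difference image."""
    if np.any(diff < 0):
        raise ValueError("difference image must be non-negative")
    bw = threshold_diff(diff, cfg.intensity_threshold)
    return segment_binary(bw, cfg.min_area, cfg.max_area, cfg.with_orientation)


def match(
    candidates: np.ndarray,
    last_positions: np.ndarray,
    greedy_above: int = 32,
) -> list[int | None]:
    """Minimum-total-displacement assignment of candidates to traces.

    ``candidates`` is (m, 2), ``last_positions`` is (t, 2) and may contain
    NaN rows (traces with no history take leftover candidates).  Returns,
    per trace, the index of its candidate or None.  Exact Hungarian
    assignment, with a greedy fallback above ``greedy_above`` objects; cost
    ties resolve deterministically (lower candidate index).
    """
    t = len(last_positions)
    m = len(candidates)
    if m == 0:
        return [None] * t
    cand = np.asarray(candidates, dtype=float)
    last = np.asarray(last_positions, dtype=float)
    cost = np.linalg.norm(last[:, None, :] - cand[None, :, :], axis=2)
    cost = np.where(np.isnan(cost), _BIG, cost)
    # deterministic tie-break: epsilon preference for lower candidate index
    cost = cost + np.arange(m)[None, :] * 1e-9
    out: list[int | None] = [None] * t
    if max(t, m) > greedy_above:
        order = np.argsort(cost, axis=None, kind="stable")
        used_t: set[int] = set()
        used_c: set[int] = set()
        for flat in order:
            ti, ci = divmod(int(flat), m)
            if ti in used_t or ci in used_c:
                continue
            out[ti] = ci
            used_t.add(ti)
            used_c.add(ci)
            if len(used_t) == min(t, m):
                break
    else:
        rows, cols = linear_sum_assignment(cost)
        for ti, ci in zip(rows, cols):
            out[ti] = int(ci)
    return out


def step(frame: np.ndarray, state: TrackerState) -> FrameResult:
    """Process one frame: difference, noise decision, segment and match."""
    cfg = state.cfg
    rois = state.rois
    if frame.shape != rois.image_size:
        raise ValueError("frame size does not match the ROI set")
    model = state.model
    fi = state.frame_index

    binaries = []
    total = 0
    for rid in range(len(rois)):
        diff = model.difference(frame, rid)
        bw = threshold_diff(diff, cfg.intensity_threshold)
        total += int(bw.sum())
        binaries.append(bw)

    # ---- noise decision ---------------------------------------------------
    reacquired = False
    if state.noise is None:
        decision = "clean"  # baseline still being sampled
        if fi >= state.baseline_start:
            state._baseline_buffer.append(total)
        if len(state._baseline_buffer) >= max(30, cfg.baseline_frames):
            state.noise = sample_baseline(
                state._baseline_buffer,
                window=cfg.noise_window,
                k_flag=cfg.k_flag,
                m_reacquire=cfg.m_reacquire,
            )
            state._baseline_buffer = []
    else:
        decision = state.noise.evaluate(total)
        if decision == "noisy" and state.noise.should_reacquire():
            last = {
                rid: [
                    _to_crop(state.last_positions[rid, ind], model, rid)
                    for ind in range(cfg.n_per_roi)
                    if np.isfinite(state.last_positions[rid, ind]).all()
                ]
                for rid in range(len(rois))
            }
            model.reacquire(frame, last)
            state.noise.reset_after_reacquire()
            state._resample_buffer = []
            state.reacquire_frames.append(fi)
            reacquired = True
        elif decision == "clean" and state._resample_buffer is not None:
            state._resample_buffer.append(total)
            # wait out the post-reacquisition ramp (animals unveiling from
            # the fresh reference) before trusting the counts again
            if len(state._resample_buffer) >= 60:
                state.noise.rebaseline(state._resample_buffer[-30:])
                state._resample_buffer = None

    state.counts.append(total)
    state.decisions.append(decision)

    assignments: list[list[tuple[float, float] | None]] = []
    if decision == "noisy":
        for rid in range(len(rois)):
            slot: list[tuple[float, float] | None] = [None] * cfg.n_per_roi
            assignments.append(slot)
            for ind in range(cfg.n_per_roi):
                state._xs[rid][ind].append(math.nan)
                state._ys[rid][ind].append(math.nan)
                state._areas[rid][ind].append(math.nan)
    else:
        d_min = model.d_min if model.d_min is not None else 10.0
        for rid in range(len(rois)):
            bw = binaries[rid]
            if state.binary_hook is not None:
                bw = state.binary_hook(bw, rid, fi)
            blobs = segment_binary(
                bw, cfg.min_area, cfg.max_area, cfg.with_orientation
            )
            sy, sx = model._slices[rid]
            cand = np.array(
                [
                    (b.centroid[0] + sx.start, b.centroid[1] + sy.start)
                    for b in blobs
                ]
            ).reshape(-1, 2)
            assign = match(cand, state.last_positions[rid], cfg.greedy_above)
            slot = []
            cents_crop = []
            for ind, ci in enumerate(assign):
                if ci is None:
                    slot.append(None)
                    state._xs[rid][ind].append(math.nan)
                    state._ys[rid][ind].append(math.nan)
                    state._areas[rid][ind].append(math.nan)
                else:
                    x, y = cand[ci]
                    slot.append((float(x), float(y)))
                    state._xs[rid][ind].append(float(x))
                    state._ys[rid][ind].append(float(y))
                    state._areas[rid][ind].append(float(blobs[ci].area))
                    state.last_positions[rid, ind] = (x, y)
                    cents_crop.append((x - sx.start, y - sy.start))
            assignments.append(slot)
            # gated piece-meal background update: only when every expected
            # animal in the ROI is accounted for this frame
            if len(cents_crop) == cfg.n_per_roi:
                model.maybe_add_sample(frame, rid, cents_crop, d_min)

    state.frame_index += 1
    return FrameResult(fi, decision, total, assignments, reacquired)


def _to_crop(pos: np.ndarray, model: BackgroundModel, rid: int):
    sy, sx = model._slices[rid]
    return (float(pos[0]) - sx.start, float(pos[1]) - sy.start)


def heading_series(
    positions: np.ndarray, fps: float, speed_threshold: float
) -> np.ndarray:
    """Per-frame heading (radians) from displacement vectors.

    Heading at frame ``i`` is the angle of the displacement from frame
    ``i-1`` when the frame-to-frame speed is at least ``speed_threshold``
    (px/s); below it the last moving heading is carried forward.  Frames
    before the first movement (and frame 0) are NaN.  Displacement is used
    rather than ellipse orientation because its sign is unambiguous.
    """
    pos = np.asarray(positions, dtype=float)
    T = len(pos)
    out = np.full(T, np.nan)
    current = np.nan
    for i in range(1, T):
        d = pos[i] - pos[i - 1]
        if np.isfinite(d).all():
            speed = math.hypot(d[0], d[1]) * fps
            if speed >= speed_threshold:
                current = math.atan2(d[1], d[0])
        out[i] = current
    return out


def run(
    source,
    cfg: TrackerConfig,
    rois: ROISet | None = None,
    container_path=None,
    binary_hook=None,
    frame_callback=None,
) -> TrackingResult:
    """Full pipeline over a frame stream.

    ``source`` is an iterable of 2-D uint8 frames (lists allow two passes
    without buffering; generators are buffered during initialization so
    every frame is also tracked).  Optional hooks: ``binary_hook(bw,
    roi_id, frame_idx)`` perturbs the thresholded image downstream of the
    noise monitor; ``frame_callback(frame_idx, state)`` runs before each
    step (used e.g. to displace the background reference on a schedule).
    Results stream to ``container_path`` when given.
    """
    frames = iter(source)
    try:
        first = next(frames)
    except StopIteration:
        raise ValueError("empty frame source") from None
    buffered: list[np.ndarray] = [first]

    def tee():
        yield first
        for f in frames:
            buffered.append(f)
            yield f

    if rois is None:
        rois = detect_rois_auto(
            first, cfg.roi_min_area, cfg.roi_max_area, cfg.roi_quantile
        )
    model, n_init = initialize_background(
        tee(),
        rois,
        stack_size=cfg.bg_stack_size,
        combine=cfg.bg_combine,
        d_min=cfg.d_min,
        intensity_threshold=cfg.intensity_threshold,
        min_area=cfg.min_area,
        max_area=cfg.max_area,
        invert_polarity=cfg.invert_polarity,
        max_frames=cfg.init_max_frames,
    )
    # buffered now holds every frame the initializer consumed; track those
    # first so the output covers the stream from frame 0.
    state = TrackerState(rois, model, cfg, binary_hook=binary_hook,
                         baseline_start=n_init)

    writer = None
    if container_path is not None:
        from .container import TraceContainerWriter

        writer = TraceContainerWriter(
            container_path,
            n_rois=len(rois),
            n_per_roi=cfg.n_per_roi,
            fps=cfg.fps,
            px2mm=cfg.px2mm,
        )
    try:
        for frame in itertools.chain(buffered, frames):
            if frame_callback is not None:
                frame_callback(state.frame_index, state)
            res = step(frame, state)
            if writer is not None:
                writer.append_frame_result(res, state)
    finally:
        if writer is not None:
            writer.close()
    result = state.finalize()
    result.container_path = container_path
    return result
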