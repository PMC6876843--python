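"""Ground-truthed synthetic video: the test bed for every other module.

The generator emulates the canonical imaging regime for multi-arena
insect tracking: a grid of bright, back-lit circular arenas on a dark
surround, each holding one (or more) dark elliptical animals, imaged with
mild illumination non-uniformity and Gaussian pixel noise.  Animals follow
a two-state (pause/move) Markov walk with lognormally distributed bout
speeds, so the resulting log-speed distribution is bimodal: a low mode of
apparent centroid jitter and a high mode of genuine locomotion.

Everything is seeded and deterministic, and the trajectory used to render
each frame is returned alongside the frames, so tracking output can be
scored against exact ground truth without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .roi import ROI, ROISet

__all__ = [
    "WalkerModel",
    "SceneSpec",
    "simulate_walkers",
    "render_frame",
    "render_stream",
    "make_scene",
    "make_fixture",
    "ground_truth_frame",
    "binary_noise_hook",
    "scripted_ymaze_positions",
]


@dataclass
class WalkerModel:
    """Two-state bout-structured random walk (units: px, s)."""

    mean_move_s: float = 2.0  # mean dwell in the move state
    mean_pause_s: float = 4.0  # mean dwell in the pause state
    # median bout speed ~30 px/s: a ~10 mm/s walk at the ~3 px/mm scale
    # implied by the default 12 x 8 px blob (a ~4 mm animal)
    speed_log_mean: float = math.log(30.0)
    speed_log_sd: float = 0.4
    frame_speed_jitter: float = 0.15  # multiplicative lognormal sd per frame
    turn_sd: float = 0.25  # heading diffusion, rad per frame
    pause_jitter_px: float = 0.12  # apparent centroid noise while paused
    wall_margin: float = 8.0  # keep this far inside the arena wall
    p_move_init: float | None = None  # None -> stationary occupancy


def simulate_walkers(
    model: WalkerModel,
    n: int,
    duration_s: float,
    fps: float,
    rng: np.random.Generator,
    arena_radius: float,
    centers: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``n`` confined walkers.

    Returns ``positions`` (n, T, 2) in arena coordinates (centered on each
    arena center if ``centers`` given, else on the origin) and ``moving``
    (n, T) boolean state labels.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    T = int(round(duration_s * fps))
    dt = 1.0 / fps
    p_stop = min(1.0, dt / model.mean_move_s) if model.mean_move_s > 0 else 1.0
    p_go = min(1.0, dt / model.mean_pause_s) if model.mean_pause_s > 0 else 1.0
    if model.mean_pause_s == 0:
        p_go = 1.0
    occ = model.p_move_init
    if occ is None:
        tot = model.mean_move_s + model.mean_pause_s
        occ = model.mean_move_s / tot if tot > 0 else 0.0

    r_max = arena_radius - model.wall_margin
    pos = np.zeros((n, T, 2))
    moving = np.zeros((n, T), dtype=bool)
    for i in range(n):
        # start at a uniform point well inside the arena
        rr = r_max * 0.8 * math.sqrt(rng.uniform())
        ang = rng.uniform(0, 2 * math.pi)
        p = np.array([rr * math.cos(ang), rr * math.sin(ang)])
        heading = rng.uniform(0, 2 * math.pi)
        state = rng.uniform() < occ
        anchor = p.copy()
        bout_speed = float(np.exp(rng.normal(model.speed_log_mean, model.speed_log_sd)))
        for t in range(T):
            if state:
                if rng.uniform() < p_stop:
                    state = False
                    anchor = p.copy()
            else:
                if rng.uniform() < p_go:
                    state = True
                    heading = rng.uniform(0, 2 * math.pi)
                    bout_speed = float(
                        np.exp(rng.normal(model.speed_log_mean, model.speed_log_sd))
                    )
            if state:
                heading += rng.normal(0.0, model.turn_sd)
                spd = bout_speed * float(
                    np.exp(rng.normal(0.0, model.frame_speed_jitter))
                )
                step = spd * dt
                cand = p + step * np.array([math.cos(heading), math.sin(heading)])
                if np.hypot(*cand) > r_max:
                    # steer back toward the arena center with some scatter
                    heading = math.atan2(-p[1], -p[0]) + rng.normal(0.0, 0.4)
                    cand = p + step * np.array(
                        [math.cos(heading), math.sin(heading)]
                    )
                    if np.hypot(*cand) > r_max:
                        cand = p
                p = cand
            else:
                p = anchor + rng.normal(0.0, model.pause_jitter_px, size=2)
                d = np.hypot(*p)
                if d > r_max:
                    p = p * (r_max / d)
            pos[i, t] = p
            moving[i, t] = state
    if centers is not None:
        pos = pos + np.asarray(centers, dtype=float)[:, None, :]
    return pos, moving


# ---------------------------------------------------------------------------
# scene rendering
# ---------------------------------------------------------------------------

@dataclass
class SceneSpec:
    """Imaging model for the synthetic arenas.

    Blob sizes below ~3 px diameter are outside the supported regime
    (tracking needs on the order of ten pixels per animal); the default
    ellipse is 6 x 4 px half-axes, about 75 px^2.
    """

    image_size: tuple[int, int]  # (height, width)
    arena_centers: np.ndarray  # (n, 2) in px
    arena_radius: float
    arena_intensity: float = 200.0
    surround_intensity: float = 40.0
    gradient_amplitude: float = 10.0  # linear illumination tilt, levels
    blob_depth: float = 90.0  # intensity dip of the animal
    blob_radii: tuple[float, float] = (6.0, 4.0)  # ellipse half-axes px
    noise_sigma: float = 2.0  # Gaussian pixel noise, levels
    drift_per_min: float = 0.0  # slow background drift, levels/min
    fps: float = 30.0
    # tracked ROIs extend this far beyond the bright disc, so the
    # high-contrast arena wall lies inside the ROI (as drawn in practice)
    roi_margin: float = 4.0

    def __post_init__(self) -> None:
        if min(self.blob_radii) * 2.0 < 3.0:
            raise ValueError("blob diameter must be >= 3 px for stable tracking")


def make_scene(
    n_rows: int = 4,
    n_cols: int = 3,
    arena_radius: float = 50.0,
    pitch: float = 110.0,
    fps: float = 30.0,
    **kwargs,
) -> SceneSpec:
    """A grid scene in the default imaging regime (dimensions in px)."""
    margin = pitch / 2.0
    centers = np.array(
        [
            (margin + c * pitch, margin + r * pitch)
            for r in range(n_rows)
            for c in range(n_cols)
        ],
        dtype=float,
    )
    h = int(round(2 * margin + (n_rows - 1) * pitch))
    w = int(round(2 * margin + (n_cols - 1) * pitch))
    return SceneSpec(
        image_size=(h, w),
        arena_centers=centers,
        arena_radius=arena_radius,
        fps=fps,
        **kwargs,
    )


def _soft_disc(xx, yy, cx, cy, r, edge=1.0):
    d = np.hypot(xx - cx, yy - cy)
    return np.clip((r - d) / edge + 0.5, 0.0, 1.0)


def scene_background(scene: SceneSpec) -> np.ndarray:
    """Animal-free scene (float), bright arenas on a dark surround."""
    h, w = scene.image_size
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    img = np.full((h, w), scene.surround_intensity, dtype=float)
    for cx, cy in scene.arena_centers:
        cov = _soft_disc(xx, yy, cx, cy, scene.arena_radius)
        img += cov * (scene.arena_intensity - scene.surround_intensity)
    if scene.gradient_amplitude:
        img += scene.gradient_amplitude * (xx / max(w - 1, 1) - 0.5)
    return img


def _blob_patch(shape, x0, y0, cx, cy, a, b, heading):
    """Anti-aliased elliptical coverage patch (local coords)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    xr = xx + x0 - cx
    yr = yy + y0 - cy
    ca, sa = math.cos(heading), math.sin(heading)
    u = ca * xr + sa * yr
    v = -sa * xr + ca * yr
    d = np.hypot(u / a, v / b)
    edge = 1.0 / min(a, b)  # ~1 px soft edge in real units
    return np.clip((1.0 - d) / edge + 0.5, 0.0, 1.0)


def render_frame(
    background: np.ndarray,
    scene: SceneSpec,
    positions: np.ndarray,
    headings: np.ndarray | None,
    rng: np.random.Generator | None,
    frame_index: int = 0,
) -> np.ndarray:
    """One uint8 frame: background minus animal dips, plus noise/drift."""
    img = background.copy()
    h, w = img.shape
    a, b = scene.blob_radii
    pad = int(math.ceil(max(a, b) + 2))
    for k, (x, y) in enumerate(np.atleast_2d(positions)):
        hd = 0.0 if headings is None else float(np.atleast_1d(headings)[k])
        x0, x1 = int(x) - pad, int(x) + pad + 1
        y0, y1 = int(y) - pad, int(y) + pad + 1
        x0c, x1c = max(x0, 0), min(x1, w)
        y0c, y1c = max(y0, 0), min(y1, h)
        if x0c >= x1c or y0c >= y1c:
            continue
        cov = _blob_patch(
            (y1c - y0c, x1c - x0c), x0c, y0c, x, y, a, b, hd
        )
        img[y0c:y1c, x0c:x1c] -= scene.blob_depth * cov
    if scene.drift_per_min:
        img += scene.drift_per_min * frame_index / (scene.fps * 60.0)
    if rng is not None and scene.noise_sigma > 0:
        img = img + rng.normal(0.0, scene.noise_sigma, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def render_stream(
    trajectories: np.ndarray,
    scene: SceneSpec,
    seed: int | np.random.Generator | None = 0,
    headings: np.ndarray | None = None,
):
    """Yield uint8 frames for (n_animals, T, 2) trajectories.

    Raises if any trajectory leaves its arena.  Noise is drawn from a
    generator seeded once, so the stream is deterministic per seed.
    """
    traj = np.asarray(trajectories, dtype=float)
    n, T, _ = traj.shape
    centers = np.asarray(scene.arena_centers, dtype=float)
    d = np.hypot(*(traj - centers[:, None, :]).transpose(2, 0, 1))
    if np.any(d > scene.arena_radius):
        raise ValueError("trajectory exits its arena")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else (None if seed is None else np.random.default_rng(seed))
    )
    bg = scene_background(scene)
    for t in range(T):
        hd = None if headings is None else headings[:, t]
        yield render_frame(bg, scene, traj[:, t, :], hd, rng, frame_index=t)


def ground_truth_frame(trajectories: np.ndarray) -> pd.DataFrame:
    """Tidy ground truth: one row per (frame, roi)."""
    traj = np.asarray(trajectories, dtype=float)
    n, T, _ = traj.shape
    return pd.DataFrame(
        {
            "frame": np.repeat(np.arange(T), n),
            "roi": np.tile(np.arange(n), T),
            "x": traj[:, :, 0].T.ravel(),
            "y": traj[:, :, 1].T.ravel(),
        }
    )


def rois_for_scene(scene: SceneSpec) -> ROISet:
    r = float(scene.arena_radius + scene.roi_margin)
    rois = [
        ROI(i, "circle", (float(cx), float(cy)), r)
        for i, (cx, cy) in enumerate(scene.arena_centers)
    ]
    return ROISet(rois, scene.image_size)


def make_fixture(
    seed: int,
    duration_s: float = 120.0,
    fps: float = 30.0,
    n_rows: int = 4,
    n_cols: int = 3,
    walker: WalkerModel | None = None,
    scene_kwargs: dict | None = None,
):
    """The canonical 12-arena single-animal fixture.

    Returns ``(scene, rois, truth, frames)`` where ``truth`` is the
    (n, T, 2) ground-truth trajectory array and ``frames`` is a function
    returning a fresh frame iterator (frames are identical on every call
    for a given seed).
    """
    scene = make_scene(n_rows=n_rows, n_cols=n_cols, fps=fps,
                       **(scene_kwargs or {}))
    walker = walker if walker is not None else WalkerModel()
    ss = np.random.SeedSequence(seed)
    walk_seed, noise_seed = ss.spawn(2)
    rng = np.random.default_rng(walk_seed)
    truth, moving = simulate_walkers(
        walker,
        n=len(scene.arena_centers),
        duration_s=duration_s,
        fps=fps,
        rng=rng,
        arena_radius=scene.arena_radius,
        centers=scene.arena_centers,
    )
    def frames():
        # a fresh generator from the same SeedSequence gives an identical
        # noise stream, so every call replays the same video
        return render_stream(truth, scene,
                             seed=np.random.default_rng(noise_seed))

    return scene, rois_for_scene(scene), truth, frames


def binary_noise_hook(p: float, seed: int):
    """Hook flipping each thresholded pixel to foreground with prob ``p``.

    Applied downstream of the noise monitor and upstream of segmentation,
    emulating tracking with a poorly calibrated noise correction.
    """
    rng = np.random.default_rng(seed)

    def hook(bw: np.ndarray, roi_id: int, frame_idx: int) -> np.ndarray:
        if p <= 0:
            return bw
        return bw | (rng.random(bw.shape) < p)

    return hook


# ---------------------------------------------------------------------------
# scripted Y-maze trajectories (controller / scoring tests)
# ---------------------------------------------------------------------------

def scripted_ymaze_positions(
    roi: ROI,
    arm_order: list[str],
    frames_per_leg: int = 5,
    arm_fraction: float = 0.7,
) -> np.ndarray:
    """Deterministic trajectory visiting arms via the center in order.

    For each listed arm the animal sits ``frames_per_leg`` frames deep in
    the arm, then ``frames_per_leg`` frames at the center.  Useful for
    exercising choice scoring and the LED controller against a known
    script.
    """
    from .metrics import ARMS

    cx, cy = roi.center
    r = float(roi.bounds)
    tip = {}
    for k, name in enumerate(ARMS):
        ang = math.radians(90.0 + 120.0 * k)  # visual angle of arm axis
        tip[name] = (
            cx + arm_fraction * r * math.cos(ang),
            cy - arm_fraction * r * math.sin(ang),
        )
    pts = []
    for arm in arm_order:
        pts.extend([tip[arm]] * frames_per_leg)
        pts.extend([(cx, cy)] * frames_per_leg)
    return np.asarray(pts, dtype=float)
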