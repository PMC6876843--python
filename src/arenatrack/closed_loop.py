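"""Frame-synchronous closed-loop stimulus controllers.

Three assays share one architecture: per frame, the controller receives
the current tracked state of each arena and emits hardware-agnostic
command records.  Commands at frame ``t`` depend only on positions at
frames ``<= t`` (one-frame closed-loop latency), every arena has at most
one active stimulus, and each arena draws from its own seeded RNG stream
so randomization is reproducible regardless of processing order.

Controllers:

* LED Y-maze — an LED is lit in one of the two arms the animal does not
  occupy; when the animal turns into a new arm all LEDs switch off, the
  trial is scored (toward/away from the light), and a new LED lights in
  one of the now-unoccupied arms, chosen uniformly.
* Optomotor — a rotating pinwheel centered on the animal (via the
  camera-to-projector registration) starts only when the animal is
  moving, a minimum inter-trial interval has elapsed, and it is far
  enough from the arena edge; the stimulus is removed after a fixed
  duration.
* Speed-contingent optogenetics — alternating baseline/reinforcement
  periods; during reinforcement the light is on when speed is above
  (lit-when-fast) or at-or-below (lit-when-slow) a threshold.

Hardware is an interface: a null sink for tests and a serial-line sink
emitting 3-byte (address, command, value) packets for LED-panel drivers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .metrics import ARMS

__all__ = [
    "RegistrationMap",
    "fit_registration",
    "StimulusCommand",
    "CommandLog",
    "TrialRecord",
    "YMazeController",
    "OptomotorConfig",
    "OptomotorController",
    "SpeedContingentController",
    "render_pinwheel",
    "NullSink",
    "SerialLineSink",
]


# ---------------------------------------------------------------------------
# camera -> projector registration
# ---------------------------------------------------------------------------

@dataclass
class RegistrationMap:
    """3x3 projective transform from camera pixels to projector pixels."""

    matrix: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        homo = np.column_stack([pts, np.ones(len(pts))])
        out = homo @ self.matrix.T
        out = out[:, :2] / out[:, 2:3]
        return out[0] if np.asarray(points).ndim == 1 else out

    def inverse(self) -> "RegistrationMap":
        return RegistrationMap(np.linalg.inv(self.matrix))

    def residuals(self, camera_points, projector_points) -> np.ndarray:
        pred = self.apply(np.asarray(camera_points, dtype=float))
        return np.linalg.norm(pred - np.asarray(projector_points, float), axis=1)


def _normalize(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # similarity normalization: zero mean, mean distance sqrt(2)
    c = pts.mean(axis=0)
    d = np.linalg.norm(pts - c, axis=1).mean()
    s = math.sqrt(2.0) / d if d > 0 else 1.0
    T = np.array([[s, 0, -s * c[0]], [0, s, -s * c[1]], [0, 0, 1.0]])
    homo = np.column_stack([pts, np.ones(len(pts))]) @ T.T
    return homo, T


def fit_registration(camera_points, projector_points) -> RegistrationMap:
    """Least-squares projective fit (normalized DLT).

    Needs at least 4 non-degenerate correspondences; raises on rank
    deficiency (e.g. collinear points).
    """
    cam = np.asarray(camera_points, dtype=float)
    prj = np.asarray(projector_points, dtype=float)
    if cam.shape != prj.shape or cam.ndim != 2 or cam.shape[1] != 2:
        raise ValueError("point lists must be matching (n, 2) arrays")
    n = len(cam)
    if n < 4:
        raise ValueError("projective fit needs at least 4 correspondences")
    x, Tc = _normalize(cam)
    y, Tp = _normalize(prj)
    A = np.zeros((2 * n, 9))
    for i in range(n):
        X = x[i]
        u, v, w = y[i]
        A[2 * i, 3:6] = -w * X
        A[2 * i, 6:9] = v * X
        A[2 * i + 1, 0:3] = w * X
        A[2 * i + 1, 6:9] = -u * X
    _, s, vt = np.linalg.svd(A)
    if s[7] < 1e-10 * s[0]:
        raise ValueError("degenerate correspondences (rank deficient)")
    Hn = vt[-1].reshape(3, 3)
    H = np.linalg.inv(Tp) @ Hn @ Tc
    H = H / H[2, 2]
    return RegistrationMap(H)


# ---------------------------------------------------------------------------
# command plumbing
# ---------------------------------------------------------------------------

@dataclass
class StimulusCommand:
    frame: int
    roi_id: int
    kind: str  # led_on | led_off | pinwheel | light_on | light_off
    payload: dict = field(default_factory=dict)


class CommandLog:
    """Append-only, reproducible command record."""

    def __init__(self, sink=None):
        self.commands: list[StimulusCommand] = []
        self.sink = sink

    def emit(self, cmd: StimulusCommand) -> None:
        self.commands.append(cmd)
        if self.sink is not None:
            self.sink.send(cmd)

    def __len__(self):
        return len(self.commands)

    def __iter__(self):
        return iter(self.commands)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("frame,roi,kind,payload\n")
            for c in self.commands:
                payload = json.dumps(c.payload, sort_keys=True)
                fh.write(f'{c.frame},{c.roi_id},{c.kind},"{payload}"\n')

    def to_bytes(self) -> bytes:
        """Canonical serialization (used for bit-identity checks)."""
        return "\n".join(
            f"{c.frame}|{c.roi_id}|{c.kind}|{json.dumps(c.payload, sort_keys=True)}"
            for c in self.commands
        ).encode()


@dataclass
class TrialRecord:
    assay: str
    roi_id: int
    onset: int
    offset: int | None
    stimulus: dict
    outcome: dict = field(default_factory=dict)


class NullSink:
    """Swallows commands (tests, dry runs)."""

    def send(self, cmd: StimulusCommand) -> None:
        pass


class SerialLineSink:
    """3-byte packets for microcontroller LED drivers.

    Packet: address byte (ROI id mod 256), command byte (an index into the
    command kinds below), value byte (arm index, intensity, or 0).
    """

    KINDS = {"led_on": 1, "led_off": 2, "pinwheel": 3, "light_on": 4, "light_off": 5}

    def __init__(self, stream):
        self.stream = stream  # binary file-like

    def send(self, cmd: StimulusCommand) -> None:
        value = 0
        if "arm" in cmd.payload and cmd.payload["arm"] is not None:
            value = ARMS.index(cmd.payload["arm"])
        elif "intensity" in cmd.payload:
            value = int(cmd.payload["intensity"]) & 0xFF
        self.stream.write(
            bytes([cmd.roi_id & 0xFF, self.KINDS[cmd.kind], value & 0xFF])
        )


def _per_roi_rngs(n_rois: int, seed: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_rois)]


# ---------------------------------------------------------------------------
# LED Y-maze
# ---------------------------------------------------------------------------

class YMazeController:
    """Per-frame LED Y-maze trial logic for many arenas in parallel.

    Input per frame: the subregion label of each animal (arm_A/arm_B/
    arm_C/center or None).  Missing positions freeze that arena's state.
    """

    def __init__(self, n_rois: int, seed: int = 0, log: CommandLog | None = None):
        self.n_rois = n_rois
        self.log = log if log is not None else CommandLog()
        self.rngs = _per_roi_rngs(n_rois, seed)
        self.lit_arm: list[str | None] = [None] * n_rois
        self.last_arm: list[str | None] = [None] * n_rois
        self._passed_center = [False] * n_rois
        self.trials: list[TrialRecord] = []

    def _light_new(self, frame: int, rid: int, occupied: str) -> None:
        options = [a for a in ARMS if a != occupied]
        arm = options[int(self.rngs[rid].integers(len(options)))]
        self.lit_arm[rid] = arm
        self.log.emit(StimulusCommand(frame, rid, "led_on", {"arm": arm}))

    def step(self, frame: int, labels: list[str | None]) -> list[TrialRecord]:
        """Advance one frame; returns trials completed at this frame."""
        done: list[TrialRecord] = []
        for rid in range(self.n_rois):
            lab = labels[rid]
            if lab is None:
                continue  # state frozen while the position is missing
            if lab == "center":
                self._passed_center[rid] = True
                continue
            if lab not in ARMS:
                continue
            if self.last_arm[rid] is None:
                # first localized arm: start the first trial
                self.last_arm[rid] = lab
                self._light_new(frame, rid, lab)
                continue
            if lab != self.last_arm[rid] and self._passed_center[rid]:
                lit = self.lit_arm[rid]
                self.log.emit(
                    StimulusCommand(frame, rid, "led_off", {"arm": lit})
                )
                rec = TrialRecord(
                    assay="ymaze",
                    roi_id=rid,
                    onset=frame,
                    offset=frame,
                    stimulus={"lit_arm": lit},
                    outcome={
                        "from_arm": self.last_arm[rid],
                        "to_arm": lab,
                        "photo_choice": "toward_lit" if lab == lit else "away",
                    },
                )
                self.trials.append(rec)
                done.append(rec)
                self.last_arm[rid] = lab
                self._passed_center[rid] = False
                self._light_new(frame, rid, lab)
            elif lab != self.last_arm[rid] or self._passed_center[rid]:
                self.last_arm[rid] = lab
                self._passed_center[rid] = False
        return done


# ---------------------------------------------------------------------------
# optomotor pinwheel
# ---------------------------------------------------------------------------

@dataclass
class OptomotorConfig:
    duration_s: float = 2.0
    min_iti_s: float = 2.0
    min_edge_distance: float | None = None  # default 0.25 * arena radius
    refresh_hz: float = 60.0
    speed_threshold: float = 1.0  # "moving" gate, same units as speed input
    contrast_choices: tuple[float, ...] = (1.0,)
    num_cycles_choices: tuple[int, ...] = (6,)
    angular_speed_choices: tuple[float, ...] = (360.0,)  # deg/s


class OptomotorController:
    """Gated pinwheel trials, one independent state machine per arena."""

    def __init__(
        self,
        arenas,  # list of (center (x, y), radius) in camera px
        cfg: OptomotorConfig | None = None,
        registration: RegistrationMap | None = None,
        seed: int = 0,
        log: CommandLog | None = None,
    ):
        self.arenas = list(arenas)
        self.cfg = cfg if cfg is not None else OptomotorConfig()
        self.registration = registration
        self.log = log if log is not None else CommandLog()
        n = len(self.arenas)
        self.rngs = _per_roi_rngs(n, seed)
        self.phase = ["idle"] * n
        self.onset = [-(10**9)] * n  # frames
        self.offset = [-(10**9)] * n
        self.params: list[dict | None] = [None] * n
        self.last_pos: list[tuple[float, float] | None] = [None] * n
        self.trials: list[TrialRecord] = []

    def _edge_ok(self, rid: int, pos) -> bool:
        (cx, cy), radius = self.arenas[rid]
        d_edge = radius - math.dist(pos, (cx, cy))
        min_d = self.cfg.min_edge_distance
        if min_d is None:
            min_d = 0.25 * radius
        return d_edge >= min_d

    def _project(self, pos):
        if self.registration is None:
            return tuple(pos)
        return tuple(self.registration.apply(np.asarray(pos, dtype=float)))

    def step(self, frame: int, positions, speeds) -> list[TrialRecord]:
        """Advance one frame given per-arena positions and speeds."""
        cfg = self.cfg
        fps = cfg.refresh_hz
        dur = int(round(cfg.duration_s * fps))
        iti = int(round(cfg.min_iti_s * fps))
        done: list[TrialRecord] = []
        for rid in range(len(self.arenas)):
            pos = positions[rid]
            spd = speeds[rid]
            if pos is not None:
                self.last_pos[rid] = tuple(pos)
            if self.phase[rid] == "stimulus":
                if frame - self.onset[rid] >= dur:
                    self.phase[rid] = "refractory"
                    self.offset[rid] = frame
                    rec = TrialRecord(
                        assay="optomotor",
                        roi_id=rid,
                        onset=self.onset[rid],
                        offset=frame,
                        stimulus=dict(self.params[rid]),
                    )
                    self.trials.append(rec)
                    done.append(rec)
                    self.log.emit(StimulusCommand(frame, rid, "pinwheel",
                                                  {"state": "off"}))
                else:
                    # track the animal; hold last known position when missing
                    center = self.last_pos[rid]
                    if center is not None:
                        p = self.params[rid]
                        phase = (
                            (frame - self.onset[rid])
                            * math.radians(p["angular_speed"])
                            / fps
                            * p["direction"]
                        )
                        self.log.emit(
                            StimulusCommand(
                                frame,
                                rid,
                                "pinwheel",
                                {
                                    "state": "on",
                                    "center": [round(v, 3) for v in
                                               self._project(center)],
                                    "phase": round(phase, 6),
                                    **{k: p[k] for k in
                                       ("direction", "contrast", "num_cycles",
                                        "angular_speed")},
                                },
                            )
                        )
                continue
            if self.phase[rid] == "refractory":
                if frame - self.offset[rid] >= iti:
                    self.phase[rid] = "idle"
                else:
                    continue
            # idle: all three gates must pass
            if pos is None or spd is None or not np.isfinite(spd):
                continue
            if spd < cfg.speed_threshold:
                continue  # gate 1: moving
            if not self._edge_ok(rid, pos):
                continue  # gate 3: away from the edge
            rng = self.rngs[rid]
            p = {
                "direction": int(rng.choice([-1, 1])),
                "contrast": float(rng.choice(cfg.contrast_choices)),
                "num_cycles": int(rng.choice(cfg.num_cycles_choices)),
                "angular_speed": float(rng.choice(cfg.angular_speed_choices)),
            }
            self.params[rid] = p
            self.phase[rid] = "stimulus"
            self.onset[rid] = frame
            self.log.emit(
                StimulusCommand(
                    frame,
                    rid,
                    "pinwheel",
                    {"state": "on", "center": [round(v, 3) for v in
                                               self._project(pos)],
                     "phase": 0.0, **p},
                )
            )
        return done


# ---------------------------------------------------------------------------
# speed-contingent optogenetic stimulation
# ---------------------------------------------------------------------------

class SpeedContingentController:
    """Alternating baseline/reinforcement schedule with a speed threshold.

    Default schedule is 8 periods of 8 minutes alternating baseline and
    reinforcement; the default threshold is 6.8 mm/s.  Missing speed is
    fail-safe: light off.  Commands are emitted on state change only (the
    log is idempotent per frame).
    """

    def __init__(
        self,
        n_rois: int,
        schedule: list[tuple[str, int]] | None = None,
        threshold: float = 6.8,
        reinforcement_mode: str = "lit_when_slow",
        fps: float = 30.0,
        period_s: float = 8 * 60.0,
        n_periods: int = 8,
        log: CommandLog | None = None,
    ):
        if schedule is None:
            frames = int(round(period_s * fps))
            schedule = [
                ("baseline" if k % 2 == 0 else reinforcement_mode, frames)
                for k in range(n_periods)
            ]
        for mode, _ in schedule:
            if mode not in ("baseline", "lit_when_fast", "lit_when_slow"):
                raise ValueError(f"unknown schedule mode {mode!r}")
        self.schedule = schedule
        self.threshold = float(threshold)
        self.n_rois = n_rois
        self.log = log if log is not None else CommandLog()
        self._edges = np.cumsum([n for _, n in schedule])
        self.lit = [False] * n_rois

    def mode_at(self, frame: int) -> str:
        k = int(np.searchsorted(self._edges, frame, side="right"))
        if k >= len(self.schedule):
            return "baseline"
        return self.schedule[k][0]

    def step(self, frame: int, speeds) -> None:
        mode = self.mode_at(frame)
        for rid in range(self.n_rois):
            spd = speeds[rid]
            if mode == "baseline" or spd is None or not np.isfinite(spd):
                want = False
            elif mode == "lit_when_fast":
                want = spd > self.threshold
            else:  # lit_when_slow
                want = spd <= self.threshold
            if want != self.lit[rid]:
                self.lit[rid] = want
                kind = "light_on" if want else "light_off"
                self.log.emit(StimulusCommand(frame, rid, kind,
                                              {"mode": mode}))


# ---------------------------------------------------------------------------
# pinwheel raster (test-only rendering; no display code)
# ---------------------------------------------------------------------------

def render_pinwheel(
    size: tuple[int, int],
    center: tuple[float, float],
    phase: float,
    contrast: float,
    num_cycles: int,
) -> np.ndarray:
    """Angular square-wave grating about ``center``, values in [0, 1].

    ``num_cycles`` dark/bright pairs around the full turn; ``phase`` in
    radians rotates the pattern.  Contrast 0 gives a uniform 0.5 patch.
    A stimulus rotating at ``angular_speed`` deg/s on a display refreshing
    at ``refresh`` Hz advances ``phase`` by
    ``radians(angular_speed) / refresh`` per frame.
    """
    if not 0.0 <= contrast <= 1.0:
        raise ValueError("contrast must be in [0, 1]")
    h, w = size
    yy, xx = np.mgrid[0:h, 0:w]
    theta = np.arctan2(yy - center[1], xx - center[0])
    wave = np.sin(num_cycles * theta + phase)
    square = np.where(wave >= 0, 1.0, -1.0)
    return 0.5 + 0.5 * contrast * square
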