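"""Behavioral statistics derived from centroid traces.

Speed, a data-driven movement threshold (log-speed distributions of
walking insects are bimodal: a low mode of frame-to-frame tracking noise
and a high mode of genuine locomotion), movement bouts, Y-maze choice
scoring (handedness and phototaxis), optomotor indices, and occupancy /
entry rates for place-contingent stimulation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .roi import ROI, ROISet

logger = logging.getLogger(__name__)

__all__ = [
    "SpeedSeries",
    "BoutSet",
    "Choice",
    "ChoiceSequence",
    "speed",
    "movement_threshold",
    "bouts",
    "arm_sequence",
    "score_ymaze",
    "biases",
    "optomotor_index",
    "occupancy_entries",
    "wrap_angle",
]

ARMS = ("arm_A", "arm_B", "arm_C")


@dataclass
class SpeedSeries:
    """Per-frame scalar speed; mm/s when a pixel scale is known, else px/s."""

    values: np.ndarray
    fps: float
    units: str = "px/s"


@dataclass
class BoutSet:
    """Disjoint, ordered movement bouts: (start, end) inclusive frames."""

    bouts: list[tuple[int, int, float]]  # start, end, mean speed
    threshold: float

    def __len__(self):
        return len(self.bouts)

    def durations(self, fps: float) -> np.ndarray:
        return np.array([(e - s + 1) / fps for s, e, _ in self.bouts])


@dataclass
class Choice:
    frame: int
    from_arm: str
    to_arm: str
    lit_arm: str | None
    turn_direction: str  # "L" | "R"
    photo_choice: str | None  # "toward_lit" | "away"


@dataclass
class ChoiceSequence:
    choices: list[Choice] = field(default_factory=list)

    def __len__(self):
        return len(self.choices)

    def __iter__(self):
        return iter(self.choices)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([c.__dict__ for c in self.choices])


def speed(positions: np.ndarray, fps: float, px2mm: float | None = None) -> SpeedSeries:
    """Frame-to-frame speed; missing at both intervals adjoining a gap.

    ``values[i]`` is the speed over the interval (i-1, i); frame 0 is NaN.
    """
    pos = np.asarray(positions, dtype=float)
    if fps <= 0:
        raise ValueError("fps must be positive")
    d = np.diff(pos, axis=0)
    v = np.hypot(d[:, 0], d[:, 1]) * fps
    out = np.concatenate([[np.nan], v])
    units = "px/s"
    if px2mm is not None:
        out = out * px2mm
        units = "mm/s"
    return SpeedSeries(out, fps, units)


def movement_threshold(speeds: SpeedSeries, grid_points: int = 512) -> float:
    """Movement threshold from the bimodal log-speed distribution.

    Kernel density estimate (Gaussian kernel, Silverman bandwidth) of the
    log of nonzero speeds; the threshold is the density minimum between
    the two largest local maxima, mapped back to speed units.  Raises
    ``ValueError("unimodal")`` when no interior minimum exists.
    """
    v = np.asarray(speeds.values, dtype=float)
    v = v[np.isfinite(v) & (v > 0)]
    if v.size < 1000:
        raise ValueError("need at least 1000 finite nonzero speed samples")
    logv = np.log(v)
    kde = gaussian_kde(logv, bw_method="silverman")
    grid = np.linspace(logv.min(), logv.max(), grid_points)
    dens = kde(grid)
    interior = np.arange(1, grid_points - 1)
    is_max = (dens[interior] >= dens[interior - 1]) & (dens[interior] > dens[interior + 1])
    peaks = interior[is_max]
    # ignore negligible wiggles in the tails
    peaks = peaks[dens[peaks] >= 0.05 * dens.max()]
    if len(peaks) < 2:
        raise ValueError("unimodal")
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    lo, hi = sorted(top2)
    valley = lo + int(np.argmin(dens[lo : hi + 1]))
    # the minimum must genuinely separate the modes
    if valley in (lo, hi) or dens[valley] > 0.9 * min(dens[lo], dens[hi]):
        raise ValueError("unimodal")
    return float(np.exp(grid[valley]))


def bouts(speeds: SpeedSeries, threshold: float) -> BoutSet:
    """Maximal runs of consecutive frames with speed >= threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    v = np.asarray(speeds.values, dtype=float)
    moving = np.isfinite(v) & (v >= threshold)
    out = []
    start = None
    for i, m in enumerate(moving):
        if m and start is None:
            start = i
        elif not m and start is not None:
            out.append((start, i - 1, float(np.mean(v[start:i]))))
            start = None
    if start is not None:
        out.append((start, len(v) - 1, float(np.mean(v[start:]))))
    return BoutSet(out, threshold)


# ---------------------------------------------------------------------------
# Y-maze scoring
# ---------------------------------------------------------------------------

def arm_sequence(positions: np.ndarray, roi: ROI, rois: ROISet) -> list[str | None]:
    """Per-frame subregion label (arm_A/arm_B/arm_C/center or None)."""
    labels: list[str | None] = []
    for x, y in np.asarray(positions, dtype=float):
        if not (math.isfinite(x) and math.isfinite(y)):
            labels.append(None)
            continue
        labels.append(roi.subregion_at((x, y), rois.image_size))
    return labels


def _ccw_neighbor(arm: str) -> str:
    return ARMS[(ARMS.index(arm) + 1) % 3]


def turn_direction(from_arm: str, to_arm: str) -> str:
    """Left when turning into the counterclockwise neighbor (on screen)."""
    return "L" if to_arm == _ccw_neighbor(from_arm) else "R"


def score_ymaze(
    positions: np.ndarray,
    roi: ROI,
    rois: ROISet,
    lit_arm_by_frame,
) -> ChoiceSequence:
    """Score arm-entry choices for handedness and phototaxis.

    A choice is the first frame in a new arm after the animal has passed
    through the center; re-entering the same arm is not a choice.
    ``lit_arm_by_frame`` maps frame index to the lit arm name (or None).
    Events with unknown lit-arm state are kept for handedness but carry no
    phototactic score when the lit arm is undefined; events whose lit-arm
    state is missing are dropped with a log entry.
    """
    if not roi.subregions:
        raise ValueError("ROI has no Y-maze subregions")
    labels = arm_sequence(positions, roi, rois)
    seq = ChoiceSequence()
    last_arm: str | None = None
    passed_center = False
    for i, lab in enumerate(labels):
        if lab == "center":
            passed_center = True
            continue
        if lab not in ARMS:
            continue
        if last_arm is None:
            last_arm = lab
            passed_center = False
            continue
        if lab != last_arm and passed_center:
            lit = lit_arm_by_frame[i] if lit_arm_by_frame is not None else None
            if lit_arm_by_frame is not None and lit is None:
                logger.info("dropping choice at frame %d: lit-arm state missing", i)
            else:
                photo = None
                if lit is not None:
                    photo = "toward_lit" if lab == lit else "away"
                seq.choices.append(
                    Choice(i, last_arm, lab, lit, turn_direction(last_arm, lab), photo)
                )
        if lab != last_arm or passed_center:
            last_arm = lab
            passed_center = False
    return seq


def biases(choices: ChoiceSequence) -> dict:
    """Turn and phototactic biases, overall and split by lit-arm side.

    ``turn_bias`` is the fraction of right turns (0 = all left, 1 = all
    right); ``photo_bias`` the fraction of choices toward the lit arm.
    The conditional entries split trials by whether the lit arm was the
    clockwise (right) or counterclockwise (left) neighbor of the origin
    arm.
    """
    if len(choices) == 0:
        raise ValueError("empty choice sequence")
    turns = np.array([c.turn_direction == "R" for c in choices.choices])
    out = {"n_choices": len(choices), "turn_bias": float(turns.mean())}
    photo = [c.photo_choice == "toward_lit" for c in choices.choices
             if c.photo_choice is not None]
    out["photo_bias"] = float(np.mean(photo)) if photo else np.nan
    for side in ("L", "R"):
        sel = [
            c
            for c in choices.choices
            if c.lit_arm is not None
            and (("L" if c.lit_arm == _ccw_neighbor(c.from_arm) else "R") == side)
        ]
        key = f"lit_{side}"
        if sel:
            out[f"turn_bias_{key}"] = float(
                np.mean([c.turn_direction == "R" for c in sel])
            )
            out[f"photo_bias_{key}"] = float(
                np.mean([c.photo_choice == "toward_lit" for c in sel])
            )
        else:
            out[f"turn_bias_{key}"] = np.nan
            out[f"photo_bias_{key}"] = np.nan
    return out


# ---------------------------------------------------------------------------
# optomotor
# ---------------------------------------------------------------------------

def wrap_angle(a):
    """Wrap to (-pi, pi] (shortest signed angular difference)."""
    return (np.asarray(a) + np.pi) % (2 * np.pi) - np.pi


def optomotor_index(
    headings: np.ndarray,
    trials: list[tuple[int, int, int]],
) -> tuple[np.ndarray, float]:
    """Per-trial and mean optomotor index in [-1, 1].

    Each trial is (onset, offset, direction) with direction +1 for
    counterclockwise (increasing heading) rotation.  The index is the
    magnitude-weighted fraction of body-angle change in the stimulus
    direction: (with − against) / (with + against), where the angle
    changes are shortest-arc frame-to-frame heading differences summed
    over the stimulus window.  A trial with zero total change is NaN.
    """
    h = np.asarray(headings, dtype=float)
    idx = np.full(len(trials), np.nan)
    for k, (onset, offset, direction) in enumerate(trials):
        seg = h[onset : offset + 1]
        if len(seg) < 2:
            continue
        d = wrap_angle(np.diff(seg))
        d = d[np.isfinite(d)]
        with_ = np.abs(d[np.sign(d) == np.sign(direction)]).sum()
        against = np.abs(d[np.sign(d) == -np.sign(direction)]).sum()
        tot = with_ + against
        if tot > 0:
            idx[k] = (with_ - against) / tot
    mean = float(np.nanmean(idx)) if np.isfinite(idx).any() else np.nan
    return idx, mean


def occupancy_entries(
    positions: np.ndarray,
    roi: ROI,
    rois: ROISet,
    lit_arm_by_frame,
) -> tuple[float, float]:
    """(fraction of time in the lit arm, fraction of entries into it).

    Occupancy counts frames whose subregion and lit-arm state are both
    defined; entries are first frames in a new arm after the center, with
    chance level 1/3 when one of three arms is reinforced.
    """
    labels = arm_sequence(positions, roi, rois)
    in_lit = 0
    scored = 0
    entries = 0
    lit_entries = 0
    last_arm = None
    passed_center = False
    for i, lab in enumerate(labels):
        lit = lit_arm_by_frame[i]
        if lab in ARMS and lit is not None:
            scored += 1
            if lab == lit:
                in_lit += 1
        if lab == "center":
            passed_center = True
            continue
        if lab in ARMS:
            if last_arm is not None and lab != last_arm and passed_center:
                entries += 1
                if lit is not None and lab == lit:
                    lit_entries += 1
            if lab != last_arm or passed_center:
                last_arm = lab
                passed_center = False
    occupancy = in_lit / scored if scored else 0.0
    entry_fraction = lit_entries / entries if entries else 0.0
    return occupancy, entry_fraction
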