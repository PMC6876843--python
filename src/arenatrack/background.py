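"""Per-ROI background reference from an activity-gated rolling stack.

Background subtraction for long experiments has two failure modes pulling
in opposite directions: a stale reference accumulates error as the scene
drifts, while continuous averaging absorbs inactive animals into the
background and loses them.  The middle road implemented here keeps, per
ROI, a small rolling stack of sample crops and only admits a new sample
when every tracked animal in that ROI has moved at least ``d_min`` pixels
away from where it sat in *all* stored samples.  The reference is then the
pixel-wise median (or mean) of the stack, so with three or more gated
samples the animal is background in a majority of samples and vanishes
from the reference.

Forced reacquisition (after a run of untrackable frames) resets the stack
to the single current frame.  That frame contains the animals, so the new
reference carries "dead spots": locations where an animal sitting still is
invisible to the difference image until gated updates rebuild the stack.
This transient is the price of recovering from reference corruption.
"""

from __future__ import annotations

import warnings

import numpy as np

from .roi import ROISet
from .segment import segment_binary, threshold_diff

__all__ = ["BackgroundModel", "initialize_background"]


class BackgroundModel:
    """Rolling-stack background references, one per ROI."""

    def __init__(
        self,
        rois: ROISet,
        stack_size: int = 10,
        combine: str = "median",
        d_min: float | None = None,
        invert_polarity: bool = False,
    ):
        if combine not in ("mean", "median"):
            raise ValueError("combine must be 'mean' or 'median'")
        self.rois = rois
        self.stack_size = int(stack_size)
        self.combine = combine
        self.d_min = d_min  # None -> caller estimates one body length
        self.invert_polarity = invert_polarity
        self._slices = [r.crop_slices(rois.image_size) for r in rois]
        self._masks = [r.mask(rois.image_size) for r in rois]
        self.stacks: list[list[np.ndarray]] = [[] for _ in rois]
        # blob centroids (crop coords) present when each sample was stored;
        # None means unknown (e.g. the forced-reacquisition sample)
        self.sample_positions: list[list[list[tuple[float, float]] | None]] = [
            [] for _ in rois
        ]
        self.references: list[np.ndarray | None] = [None for _ in rois]

    # -- construction -------------------------------------------------------
    def crop(self, frame: np.ndarray, roi_id: int) -> np.ndarray:
        sy, sx = self._slices[roi_id]
        return frame[sy, sx]

    def mask(self, roi_id: int) -> np.ndarray:
        return self._masks[roi_id]

    def seed(self, frame: np.ndarray) -> None:
        """Start every stack with the current frame (positions unknown)."""
        for rid in range(len(self.rois)):
            self.stacks[rid] = [self.crop(frame, rid).copy()]
            self.sample_positions[rid] = [None]
            self._recombine(rid)

    def _recombine(self, roi_id: int) -> None:
        stack = self.stacks[roi_id]
        if len(stack) == 1:
            self.references[roi_id] = stack[0].astype(np.float32)
        elif self.combine == "median":
            self.references[roi_id] = np.median(
                np.stack(stack).astype(np.float32), axis=0
            )
        else:
            self.references[roi_id] = np.mean(
                np.stack(stack).astype(np.float32), axis=0
            )

    def maybe_add_sample(
        self,
        frame: np.ndarray,
        roi_id: int,
        centroids: list[tuple[float, float]],
        d_min: float,
    ) -> bool:
        """Admit the current crop if every animal has moved ``>= d_min``.

        ``centroids`` are current blob positions in crop coordinates.  A
        stored sample with unknown positions never blocks admission (there
        is nothing to compare against), so the post-reacquisition stack can
        rebuild as soon as the animals are seen moving.
        """
        if not centroids:
            return False
        for stored in self.sample_positions[roi_id]:
            if stored is None or not stored:
                continue
            for cx, cy in centroids:
                d = min(
                    ((cx - px) ** 2 + (cy - py) ** 2) ** 0.5 for px, py in stored
                )
                if d < d_min:
                    return False
        stack = self.stacks[roi_id]
        stack.append(self.crop(frame, roi_id).copy())
        self.sample_positions[roi_id].append(list(centroids))
        if len(stack) > self.stack_size:
            stack.pop(0)
            self.sample_positions[roi_id].pop(0)
        self._recombine(roi_id)
        return True

    def stack_full(self, roi_id: int) -> bool:
        return len(self.stacks[roi_id]) >= self.stack_size

    # -- use ----------------------------------------------------------------
    def difference(self, frame: np.ndarray, roi_id: int) -> np.ndarray:
        """Clamped difference over the ROI crop (masked to the ROI shape).

        Default polarity is dark animal on bright field: ``reference −
        frame`` clamped at zero.  ``invert_polarity`` flips it for
        light-on-dark organisms.
        """
        ref = self.references[roi_id]
        if ref is None:
            raise RuntimeError(f"background not initialized for ROI {roi_id}")
        crop = self.crop(frame, roi_id)
        if crop.shape != ref.shape:
            raise ValueError("frame dimensions do not match the reference")
        crop = crop.astype(np.float32)
        d = crop - ref if self.invert_polarity else ref - crop
        np.maximum(d, 0.0, out=d)
        d[~self._masks[roi_id]] = 0.0
        return d

    def reacquire(
        self,
        frame: np.ndarray,
        last_positions: dict[int, list[tuple[float, float]]] | None = None,
    ) -> None:
        """Reset every stack to the single current frame.

        ``last_positions`` (crop coords per ROI) lets the gate know where
        the animals were at reset, so rebuilding waits for real movement.
        """
        for rid in range(len(self.rois)):
            self.stacks[rid] = [self.crop(frame, rid).copy()]
            pos = None
            if last_positions is not None:
                pos = last_positions.get(rid)
            self.sample_positions[rid] = [pos]
            self._recombine(rid)

    def shift_reference(self, dx: int, dy: int) -> None:
        """Displace all stored samples and references by whole pixels.

        This is the perturbation hook used to emulate an accidental nudge
        of the arena relative to the stored background (edges wrap).
        """
        for rid in range(len(self.rois)):
            self.stacks[rid] = [
                np.roll(s, (dy, dx), axis=(0, 1)) for s in self.stacks[rid]
            ]
            self._recombine(rid)


def initialize_background(
    frames,
    rois: ROISet,
    stack_size: int = 10,
    combine: str = "median",
    d_min: float | None = None,
    intensity_threshold: float = 25.0,
    min_area: float = 8.0,
    max_area: float = 1e9,
    invert_polarity: bool = False,
    max_frames: int | None = None,
) -> tuple[BackgroundModel, int]:
    """Build a background model from a frame stream.

    Consumes frames until all stacks are full, the stream ends, or
    ``max_frames`` is hit; warns (and proceeds with partial stacks) when
    the animals were not active enough to fill the stacks.  The gating
    distance ``d_min`` defaults to one body length estimated as
    ``2 * sqrt(median blob area)`` from the first frame with blobs.
    Returns the model and the number of frames consumed.
    """
    model = BackgroundModel(rois, stack_size, combine, d_min, invert_polarity)
    n_seen = 0
    est_dmin = d_min
    for frame in frames:
        if n_seen == 0:
            model.seed(frame)
            n_seen = 1
            continue
        all_full = True
        for rid in range(len(rois)):
            if model.stack_full(rid):
                continue
            diff = model.difference(frame, rid)
            bw = threshold_diff(diff, intensity_threshold)
            blobs = segment_binary(bw, min_area, max_area)
            cents = [b.centroid for b in blobs]
            if est_dmin is None and blobs:
                med_area = float(np.median([b.area for b in blobs]))
                est_dmin = 2.0 * med_area**0.5
                model.d_min = est_dmin
            if cents and est_dmin is not None:
                model.maybe_add_sample(frame, rid, cents, est_dmin)
            if not model.stack_full(rid):
                all_full = False
        n_seen += 1
        if all_full:
            break
        if max_frames is not None and n_seen >= max_frames:
            break
    if n_seen == 0:
        raise ValueError("frame stream yielded no frames")
    if not all(model.stack_full(r) for r in range(len(rois))):
        warnings.warn(
            "background stream ended before all stacks filled; proceeding "
            "with partial stacks (initialization time is activity-dependent)",
            stacklevel=2,
        )
    if model.d_min is None:
        model.d_min = 10.0
    return model, n_seen
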