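"""Binary blob extraction from thresholded difference images.

Kept separate from the tracker so the background initializer can reuse it
without a circular import.  Centroids are means of member-pixel
coordinates (binary-mask centroids), which is enough for sub-pixel
accuracy on blobs a few pixels across.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

_EIGHT = np.ones((3, 3), dtype=bool)

__all__ = ["Blob", "segment_binary", "threshold_diff"]


@dataclass
class Blob:
    """One connected foreground component (coordinates in crop space)."""

    centroid: tuple[float, float]  # (x, y), sub-pixel
    area: float  # px^2
    bbox: tuple[int, int, int, int]  # x0, y0, x1, y1 half-open
    orientation: float | None = None  # radians of ellipse major axis


_COORD_CACHE: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}


def _coords(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    # flat (y, x) coordinate arrays, cached per crop shape (hot path)
    got = _COORD_CACHE.get(shape)
    if got is None:
        h, w = shape
        got = np.divmod(np.arange(h * w), w)
        if len(_COORD_CACHE) > 64:
            _COORD_CACHE.clear()
        _COORD_CACHE[shape] = got
    return got


def threshold_diff(diff: np.ndarray, intensity_threshold: float) -> np.ndarray:
    """Binary foreground mask from a non-negative difference image."""
    return diff > intensity_threshold


def segment_binary(
    bw: np.ndarray,
    min_area: float,
    max_area: float,
    with_orientation: bool = False,
) -> list[Blob]:
    """Area-filtered 8-connected components of a binary image."""
    labels, nlab = ndimage.label(bw, structure=_EIGHT)
    if nlab == 0:
        return []
    flat = labels.ravel()
    areas = np.bincount(flat)
    keep = np.nonzero((areas >= min_area) & (areas <= max_area))[0]
    keep = keep[keep > 0]
    if keep.size == 0:
        return []
    yy, xx = _coords(bw.shape)
    sx = np.bincount(flat, weights=xx)
    sy = np.bincount(flat, weights=yy)
    slices = ndimage.find_objects(labels)
    blobs: list[Blob] = []
    for lab in keep:
        a = areas[lab]
        cx = sx[lab] / a
        cy = sy[lab] / a
        sl = slices[lab - 1]
        orient = None
        if with_orientation:
            comp = labels[sl] == lab
            ys, xs = np.nonzero(comp)
            xs = xs - xs.mean()
            ys = ys - ys.mean()
            cxx, cyy, cxy = (xs * xs).mean(), (ys * ys).mean(), (xs * ys).mean()
            orient = 0.5 * np.arctan2(2.0 * cxy, cxx - cyy)
        blobs.append(
            Blob(
                centroid=(float(cx), float(cy)),
                area=float(a),
                bbox=(sl[1].start, sl[0].start, sl[1].stop, sl[0].stop),
                orientation=orient,
            )
        )
    return blobs
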