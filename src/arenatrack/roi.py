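"""Regions of interest: the identity backbone of multi-arena tracking.

Each arena (well, Y-maze, circular dish) is one ROI.  Because animals are
spatially segregated, a blob's ROI membership *is* its identity, which is
what lets the per-frame loop stay cheap enough for thousands of arenas.

Coordinate convention: 0-based, ``x`` = column, ``y`` = row, origin at the
top-left pixel; centroids are continuous (sub-pixel).  "Visual" angles used
for Y-maze arms are measured counterclockwise as seen on screen, i.e.
``atan2(-(y - cy), x - cx)``, so 12 o'clock is +90 degrees.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "ROI",
    "ROISet",
    "detect_rois_auto",
    "define_roi_grid",
    "add_ymaze_subregions",
    "row_major_order",
]

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element


@dataclass
class ROI:
    """One tracked arena.

    ``bounds`` holds shape parameters in pixels: a radius for circles,
    ``(width, height)`` for rectangles, or an ``(n, 2)`` vertex array for
    polygons.  ``subregions`` maps names (e.g. ``arm_A``) to boolean masks
    over the ROI's crop window.
    """

    id: int
    shape_kind: str  # "circle" | "rectangle" | "polygon"
    center: tuple[float, float]
    bounds: object
    subregions: dict[str, np.ndarray] | None = None
    meta: dict = field(default_factory=dict)

    # -- geometry -----------------------------------------------------------
    def bbox(self) -> tuple[int, int, int, int]:
        """Integer crop window ``(x0, y0, x1, y1)`` (half-open)."""
        cx, cy = self.center
        if self.shape_kind == "circle":
            r = float(self.bounds)
            x0, x1 = cx - r, cx + r
            y0, y1 = cy - r, cy + r
        elif self.shape_kind == "rectangle":
            w, h = self.bounds
            x0, x1 = cx - w / 2.0, cx + w / 2.0
            y0, y1 = cy - h / 2.0, cy + h / 2.0
        elif self.shape_kind == "polygon":
            v = np.asarray(self.bounds, dtype=float)
            x0, y0 = v.min(axis=0)
            x1, y1 = v.max(axis=0)
        else:  # pragma: no cover - guarded at construction
            raise ValueError(f"unknown shape kind {self.shape_kind!r}")
        return (
            int(math.floor(x0)),
            int(math.floor(y0)),
            int(math.ceil(x1)) + 1,
            int(math.ceil(y1)) + 1,
        )

    def crop_slices(self, image_size: tuple[int, int]) -> tuple[slice, slice]:
        """(row, col) slices of the crop window, clipped to the image."""
        h, w = image_size
        x0, y0, x1, y1 = self.bbox()
        return slice(max(y0, 0), min(y1, h)), slice(max(x0, 0), min(x1, w))

    def mask(self, image_size: tuple[int, int]) -> np.ndarray:
        """Boolean membership mask over the crop window."""
        sy, sx = self.crop_slices(image_size)
        yy, xx = np.mgrid[sy, sx]
        return self._contains_grid(xx, yy)

    def _contains_grid(self, xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
        cx, cy = self.center
        if self.shape_kind == "circle":
            r = float(self.bounds)
            return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
        if self.shape_kind == "rectangle":
            w, h = self.bounds
            return (np.abs(xx - cx) <= w / 2.0) & (np.abs(yy - cy) <= h / 2.0)
        # polygon: even-odd rule
        v = np.asarray(self.bounds, dtype=float)
        inside = np.zeros(xx.shape, dtype=bool)
        n = len(v)
        for i in range(n):
            x1, y1 = v[i]
            x2, y2 = v[(i + 1) % n]
            crosses = (y1 > yy) != (y2 > yy)
            with np.errstate(divide="ignore", invalid="ignore"):
                xint = x1 + (yy - y1) * (x2 - x1) / (y2 - y1)
            inside ^= crosses & (xx < xint)
        return inside

    def contains(self, point: tuple[float, float]) -> bool:
        x, y = point
        return bool(
            self._contains_grid(np.asarray([[x]], float), np.asarray([[y]], float))[0, 0]
        )

    def subregion_at(
        self, point: tuple[float, float], image_size: tuple[int, int]
    ) -> str | None:
        """Name of the subregion containing ``point`` (None if outside all)."""
        if not self.subregions:
            return None
        sy, sx = self.crop_slices(image_size)
        j = int(round(point[0])) - sx.start
        i = int(round(point[1])) - sy.start
        for name, m in self.subregions.items():
            if 0 <= i < m.shape[0] and 0 <= j < m.shape[1] and m[i, j]:
                return name
        return None

    def translated(self, dx: float, dy: float, new_id: int) -> "ROI":
        cx, cy = self.center
        bounds = self.bounds
        if self.shape_kind == "polygon":
            bounds = np.asarray(self.bounds, float) + np.array([dx, dy])
        return ROI(new_id, self.shape_kind, (cx + dx, cy + dy), bounds,
                   meta=dict(self.meta))


@dataclass
class ROISet:
    """Ordered collection of ROIs sharing one image frame.

    Ids are contiguous ``0..n-1`` in row-major order of the arena grid.
    """

    rois: list[ROI]
    image_size: tuple[int, int]  # (height, width)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.rois]
        if ids != list(range(len(ids))):
            raise ValueError("ROI ids must be contiguous 0..n-1 in order")
        h, w = self.image_size
        for r in self.rois:
            x0, y0, x1, y1 = r.bbox()
            # 2 px slack absorbs the integer inflation of the crop window
            if x0 < -2 or y0 < -2 or x1 > w + 2 or y1 > h + 2:
                raise ValueError(f"ROI {r.id} exceeds image bounds")
        if self._any_overlap():
            warnings.warn("ROISet contains overlapping ROIs; locate() uses "
                          "nearest-center tie-break", stacklevel=2)

    def _any_overlap(self) -> bool:
        # bounding-box screen only; exact overlap is resolved in locate()
        boxes = [r.bbox() for r in self.rois]
        for i in range(len(boxes)):
            for j in range(i + 1, len(boxes)):
                a, b = boxes[i], boxes[j]
                if a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]:
                    # refine: centers further apart than sum of radii -> no
                    ri = _outer_radius(self.rois[i])
                    rj = _outer_radius(self.rois[j])
                    d = math.dist(self.rois[i].center, self.rois[j].center)
                    if d < ri + rj:
                        return True
        return False

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    def __getitem__(self, i: int) -> ROI:
        return self.rois[i]

    def locate(self, point: tuple[float, float]) -> tuple[int | None, str | None]:
        """ROI id (and subregion name) containing ``point``.

        Overlaps resolve to the nearest ROI center; outside all ROIs both
        entries are None.
        """
        x, y = point
        if not (np.isfinite(x) and np.isfinite(y)):
            return None, None
        hits = [r for r in self.rois if r.contains((x, y))]
        if not hits:
            return None, None
        best = min(hits, key=lambda r: (math.dist(r.center, (x, y)), r.id))
        return best.id, best.subregion_at((x, y), self.image_size)

    # -- plain-text layout file --------------------------------------------
    def to_text(self) -> str:
        lines = [f"# arenatrack roi layout", f"image {self.image_size[0]} {self.image_size[1]}"]
        for r in self.rois:
            if r.shape_kind == "circle":
                params = [*r.center, float(r.bounds)]
            elif r.shape_kind == "rectangle":
                params = [*r.center, *r.bounds]
            else:
                params = list(np.asarray(r.bounds, float).ravel())
            tail = ""
            if "ymaze_center_radius" in r.meta:
                tail = f" ymaze:{r.meta['ymaze_center_radius']:g}"
            params_s = " ".join(f"{p:g}" for p in params)
            lines.append(f"{r.id} {r.shape_kind} {params_s}{tail}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ROISet":
        image_size = None
        rois: list[ROI] = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0] == "image":
                image_size = (int(parts[1]), int(parts[2]))
                continue
            rid, kind = int(parts[0]), parts[1]
            ymaze_r = None
            if parts[-1].startswith("ymaze:"):
                ymaze_r = float(parts[-1].split(":", 1)[1])
                parts = parts[:-1]
            vals = [float(p) for p in parts[2:]]
            if kind == "circle":
                roi = ROI(rid, "circle", (vals[0], vals[1]), vals[2])
            elif kind == "rectangle":
                roi = ROI(rid, "rectangle", (vals[0], vals[1]), (vals[2], vals[3]))
            elif kind == "polygon":
                v = np.asarray(vals, float).reshape(-1, 2)
                roi = ROI(rid, "polygon", tuple(v.mean(axis=0)), v)
            else:
                raise ValueError(f"unknown ROI kind {kind!r}")
            rois.append(roi)
        if image_size is None:
            raise ValueError("layout file lacks an 'image H W' line")
        rs = cls(rois, image_size)
        if ymaze_r is not None:
            for r in rs.rois:
                add_ymaze_subregions(r, rs.image_size, center_radius=ymaze_r)
        return rs

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def load(cls, path) -> "ROISet":
        with open(path) as fh:
            return cls.from_text(fh.read())


def _outer_radius(roi: ROI) -> float:
    if roi.shape_kind == "circle":
        return float(roi.bounds)
    if roi.shape_kind == "rectangle":
        w, h = roi.bounds
        return math.hypot(w, h) / 2.0
    v = np.asarray(roi.bounds, float)
    return float(np.max(np.hypot(*(v - v.mean(axis=0)).T)))


def row_major_order(centers: np.ndarray) -> np.ndarray:
    """Permutation sorting arena centers into row-major reading order.

    Rows are found by clustering the y coordinates: sorted-y gaps larger
    than half the largest gap separate rows (a robust stand-in for the row
    pitch when the grid is regular).  Within a row, order is by x.
    """
    centers = np.asarray(centers, dtype=float)
    n = len(centers)
    if n <= 1:
        return np.arange(n)
    order_y = np.argsort(centers[:, 1], kind="stable")
    ys = centers[order_y, 1]
    gaps = np.diff(ys)
    row_idx = np.zeros(n, dtype=int)
    if len(gaps) and gaps.max() > 0:
        breaks = gaps > 0.5 * gaps.max()
        row_idx[order_y] = np.concatenate([[0], np.cumsum(breaks)])
    return np.lexsort((centers[:, 0], row_idx))


def detect_rois_auto(
    image: np.ndarray,
    min_area: float,
    max_area: float,
    intensity_quantile: float = 0.9,
) -> ROISet:
    """Detect bright back-lit arenas as ROIs.

    Global threshold at the given intensity quantile, 8-connected
    components, area filter, then a max-inscribed-circle fit for roughly
    round components and a bounding box otherwise.  Returns an empty
    ROISet when nothing passes the filters.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("detect_rois_auto expects a single-channel 2-D image")
    if not min_area < max_area:
        raise ValueError("min_area must be < max_area")
    thr = np.quantile(image, intensity_quantile)
    bw = image > thr
    # opening removes isolated noise pixels and 1-px bridges between
    # arenas, which matters when the threshold sits close to the surround
    bw = ndimage.binary_opening(bw)
    labels, nlab = ndimage.label(bw, structure=_EIGHT)
    rois: list[ROI] = []
    if nlab:
        areas = np.bincount(labels.ravel())
        slices = ndimage.find_objects(labels)
        for lab in range(1, nlab + 1):
            area = areas[lab]
            if not (min_area <= area <= max_area):
                continue
            sl = slices[lab - 1]
            comp = labels[sl] == lab
            yy, xx = np.nonzero(comp)
            cy = yy.mean() + sl[0].start
            cx = xx.mean() + sl[1].start
            # max inscribed radius from the Euclidean distance transform
            edt = ndimage.distance_transform_edt(comp)
            r_ins = float(edt.max())
            roundness = area / (math.pi * max(r_ins, 0.5) ** 2)
            if 0.6 <= roundness <= 1.6:
                rois.append(ROI(0, "circle", (cx, cy), r_ins))
            else:
                h = sl[0].stop - sl[0].start
                w = sl[1].stop - sl[1].start
                rois.append(ROI(0, "rectangle", (cx, cy), (float(w), float(h))))
    if rois:
        centers = np.array([r.center for r in rois])
        order = row_major_order(centers)
        rois = [rois[i] for i in order]
        for new_id, r in enumerate(rois):
            r.id = new_id
    return ROISet(rois, image.shape)


def define_roi_grid(
    origin: tuple[float, float],
    rows: int,
    cols: int,
    pitch: tuple[float, float],
    shape: ROI,
    image_size: tuple[int, int],
) -> ROISet:
    """Row-major grid of translated copies of a template ROI.

    The template's center is placed at ``origin`` for ROI 0; ROI
    ``r * cols + c`` sits at ``origin + (c * dx, r * dy)``.  Raises if any
    ROI exceeds the image bounds.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    dx, dy = pitch
    ox, oy = origin
    rois = []
    for r in range(rows):
        for c in range(cols):
            rid = r * cols + c
            tx = ox + c * dx - shape.center[0]
            ty = oy + r * dy - shape.center[1]
            rois.append(shape.translated(tx, ty, rid))
    return ROISet(rois, image_size)  # bounds check happens in __post_init__


def add_ymaze_subregions(
    roi: ROI, image_size: tuple[int, int], center_radius: float
) -> ROI:
    """Attach Y-maze arm masks to a circular ROI.

    Three 120-degree sectors (``arm_A`` nearest 12 o'clock, then ``arm_B``,
    ``arm_C`` counterclockwise as seen on screen) plus a central disc
    ``center``.  Masks are disjoint and contained in the ROI.
    """
    if roi.shape_kind != "circle":
        raise ValueError("Y-maze subregions require a circular ROI")
    sy, sx = roi.crop_slices(image_size)
    yy, xx = np.mgrid[sy, sx]
    cx, cy = roi.center
    r = float(roi.bounds)
    d2 = (xx - cx) ** 2 + (yy - cy) ** 2
    inside = d2 <= r * r
    centre = d2 <= center_radius**2
    # visual angle: counterclockwise on screen, 0 at 3 o'clock
    theta = np.degrees(np.arctan2(-(yy - cy), xx - cx)) % 360.0
    arms = {}
    for k, name in enumerate(("arm_A", "arm_B", "arm_C")):
        lo = (30.0 + 120.0 * k) % 360.0
        hi = (lo + 120.0) % 360.0
        if lo < hi:
            sector = (theta >= lo) & (theta < hi)
        else:
            sector = (theta >= lo) | (theta < hi)
        arms[name] = sector & inside & ~centre
    roi.subregions = {**arms, "center": centre & inside}
    roi.meta["ymaze_center_radius"] = float(center_radius)
    return roi
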