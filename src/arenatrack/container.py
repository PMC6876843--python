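"""Streamed binary trace container with memory-bounded batch access.

Long multi-arena experiments produce per-frame records for hundreds of
individuals over millions of frames — too large to hold in memory, and a
poor fit for text formats.  The container is a flat little-endian binary
file with a self-describing header, fixed-size frame-major records, and a
footer carrying the frame count and a CRC32 of the record bytes.  Missing
values are IEEE NaN.

Layout (all little-endian)::

    header:  magic b"ATRC" | version u8 | n_rois u16 | n_per_roi u16
             | fps f32 | px2mm f32 (NaN if unset) | n_fields u8
             | per field: name_len u8 + ascii name
             | start_time f64
    records: n_frames x (n_rois * n_per_roi * n_fields) f32
    footer:  magic b"ENDR" | n_frames u64 | crc32 u32

A reader therefore needs only: parse the header, compute the record size,
seek to ``header_size + frame * record_size``, and read ``f32`` values.
A file whose footer is missing or malformed (e.g. a crash mid-write) is
recovered by truncating to the last complete record, with a warning.
"""

from __future__ import annotations

import struct
import warnings
import zlib

import numpy as np
import pandas as pd

__all__ = ["TraceContainerWriter", "TraceContainer", "export_csv", "csv_to_container"]

_MAGIC = b"ATRC"
_FOOTER_MAGIC = b"ENDR"
_VERSION = 1
DEFAULT_FIELDS = ("x", "y", "area")


def _pack_header(n_rois, n_per_roi, fps, px2mm, fields, start_time) -> bytes:
    out = bytearray()
    out += _MAGIC
    out += struct.pack("<B", _VERSION)
    out += struct.pack("<HH", n_rois, n_per_roi)
    out += struct.pack("<ff", fps, np.nan if px2mm is None else px2mm)
    out += struct.pack("<B", len(fields))
    for f in fields:
        b = f.encode("ascii")
        out += struct.pack("<B", len(b)) + b
    out += struct.pack("<d", start_time)
    return bytes(out)


class TraceContainerWriter:
    """Append-only writer; one fixed-size record per frame."""

    def __init__(
        self,
        path,
        n_rois: int,
        n_per_roi: int = 1,
        fps: float = 30.0,
        px2mm: float | None = None,
        fields: tuple[str, ...] = DEFAULT_FIELDS,
        start_time: float = 0.0,
        flush_every: int = 0,
    ):
        # start_time defaults to 0 so identical runs produce identical
        # bytes; callers wanting wall-clock stamps pass time.time()
        self.path = path
        self.n_rois = int(n_rois)
        self.n_per_roi = int(n_per_roi)
        self.fields = tuple(fields)
        self.record_len = self.n_rois * self.n_per_roi * len(self.fields)
        self._fh = open(path, "wb")
        self._fh.write(
            _pack_header(
                self.n_rois,
                self.n_per_roi,
                fps,
                px2mm,
                self.fields,
                start_time,
            )
        )
        self._crc = 0
        self.n_frames = 0
        self._flush_every = flush_every
        self._closed = False

    def append(self, values: np.ndarray) -> None:
        """Append one frame; ``values`` reshapes to (n_rois, n_per, n_fields)."""
        arr = np.asarray(values, dtype="<f4").reshape(self.record_len)
        raw = arr.tobytes()
        self._fh.write(raw)
        self._crc = zlib.crc32(raw, self._crc)
        self.n_frames += 1
        if self._flush_every and self.n_frames % self._flush_every == 0:
            self._fh.flush()

    def append_frame_result(self, frame_result, state) -> None:
        """Convenience bridge from the tracker's per-frame output."""
        vals = np.full((self.n_rois, self.n_per_roi, len(self.fields)), np.nan)
        for rid, slots in enumerate(frame_result.assignments):
            for ind, xy in enumerate(slots):
                if xy is None:
                    continue
                rec = {"x": xy[0], "y": xy[1],
                       "area": state._areas[rid][ind][-1]}
                for k, f in enumerate(self.fields):
                    vals[rid, ind, k] = rec.get(f, np.nan)
        self.append(vals)

    def close(self) -> None:
        if self._closed:
            return
        self._fh.write(_FOOTER_MAGIC)
        self._fh.write(struct.pack("<QI", self.n_frames, self._crc))
        self._fh.close()
        self._closed = True

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


class TraceContainer:
    """Random-access reader (the on-disk dataset handle)."""

    FOOTER_SIZE = 4 + 8 + 4

    def __init__(self, path):
        self.path = path
        self._fh = open(path, "rb")
        head = self._fh.read(4)
        if head != _MAGIC:
            raise ValueError("not a trace container (bad magic)")
        (self.version,) = struct.unpack("<B", self._fh.read(1))
        self.n_rois, self.n_per_roi = struct.unpack("<HH", self._fh.read(4))
        self.fps, px2mm = struct.unpack("<ff", self._fh.read(8))
        self.px2mm = None if np.isnan(px2mm) else float(px2mm)
        (nf,) = struct.unpack("<B", self._fh.read(1))
        fields = []
        for _ in range(nf):
            (ln,) = struct.unpack("<B", self._fh.read(1))
            fields.append(self._fh.read(ln).decode("ascii"))
        self.fields = tuple(fields)
        (self.start_time,) = struct.unpack("<d", self._fh.read(8))
        self.header_size = self._fh.tell()
        self.record_len = self.n_rois * self.n_per_roi * len(self.fields)
        self.record_size = 4 * self.record_len

        self._fh.seek(0, 2)
        size = self._fh.tell()
        body = size - self.header_size
        self.n_frames, self.crc = self._read_footer(size, body)

    def _read_footer(self, size, body):
        if body >= self.FOOTER_SIZE:
            self._fh.seek(size - self.FOOTER_SIZE)
            tail = self._fh.read(self.FOOTER_SIZE)
            if tail[:4] == _FOOTER_MAGIC:
                n_frames, crc = struct.unpack("<QI", tail[4:])
                if n_frames * self.record_size == body - self.FOOTER_SIZE:
                    return int(n_frames), crc
        n_frames = body // self.record_size
        warnings.warn(
            f"container footer missing or inconsistent; recovered "
            f"{n_frames} complete frames by truncation",
            stacklevel=3,
        )
        return int(n_frames), None

    def batch(
        self,
        start: int = 0,
        stop: int | None = None,
        rois=None,
    ) -> np.ndarray:
        """Block ``[start, stop)`` as (frames, rois, individuals, fields).

        Memory use is bounded by the requested block; ``rois`` selects a
        subset of ROI indices after the read of the frame range.
        """
        stop = self.n_frames if stop is None else stop
        if not (0 <= start <= stop <= self.n_frames):
            raise IndexError("frame range out of bounds")
        n = stop - start
        self._fh.seek(self.header_size + start * self.record_size)
        raw = self._fh.read(n * self.record_size)
        arr = np.frombuffer(raw, dtype="<f4").reshape(
            n, self.n_rois, self.n_per_roi, len(self.fields)
        )
        if rois is not None:
            arr = arr[:, np.asarray(rois, dtype=int)]
        return arr.copy()

    def verify_checksum(self) -> bool:
        if self.crc is None:
            return False
        self._fh.seek(self.header_size)
        crc = 0
        remaining = self.n_frames * self.record_size
        while remaining:
            chunk = self._fh.read(min(1 << 20, remaining))
            crc = zlib.crc32(chunk, crc)
            remaining -= len(chunk)
        return crc == self.crc

    def to_dataframe(self, start=0, stop=None, rois=None) -> pd.DataFrame:
        block = self.batch(start, stop, rois)
        roi_ids = np.arange(self.n_rois) if rois is None else np.asarray(rois)
        nf, nr, ni, _ = block.shape
        frame = np.repeat(np.arange(start, start + nf), nr * ni)
        roi = np.tile(np.repeat(roi_ids, ni), nf)
        ind = np.tile(np.arange(ni), nf * nr)
        data = {"frame": frame, "time": frame / self.fps, "roi": roi,
                "individual": ind}
        flat = block.reshape(-1, len(self.fields))
        for k, f in enumerate(self.fields):
            data[f] = flat[:, k]
        return pd.DataFrame(data)

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def export_csv(container: TraceContainer, out_path, float_format="%.3f") -> None:
    """Tidy CSV (frame, time, roi, individual, fields...); NaN -> empty cell.

    Lossless except float formatting (three decimals: a milli-pixel, well
    below tracking precision).
    """
    df = container.to_dataframe()
    df.to_csv(out_path, index=False, float_format=float_format)


def csv_to_container(csv_path, out_path, fps=None, px2mm=None) -> None:
    """Rebuild a container from an exported CSV (round-trip helper)."""
    df = pd.read_csv(csv_path)
    n_frames = df["frame"].nunique()
    n_rois = int(df["roi"].max()) + 1
    n_per = int(df["individual"].max()) + 1
    fields = [c for c in df.columns if c not in ("frame", "time", "roi", "individual")]
    if fps is None:
        f = df["frame"].to_numpy()
        t = df["time"].to_numpy()
        nz = f > 0
        fps = float(np.round(np.nanmedian(f[nz] / t[nz]), 6)) if nz.any() else 30.0
    with TraceContainerWriter(
        out_path, n_rois, n_per, fps=fps, px2mm=px2mm, fields=tuple(fields)
    ) as w:
        df = df.sort_values(["frame", "roi", "individual"])
        vals = df[fields].to_numpy(dtype=np.float32).reshape(
            n_frames, n_rois, n_per, len(fields)
        )
        for rec in vals:
            w.append(rec)
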