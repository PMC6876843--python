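"""Video I/O: PNG sequences and a lossy inter-frame delta codec.

Multi-arena videos are overwhelmingly static: the background never moves
and each animal disturbs only a handful of pixels per frame.  The ``.adv``
codec exploits exactly that, the way inter-frame video codecs do: the
first frame is stored as a JPEG keyframe, and every later frame as the
set of pixels whose value changed — against the *reconstructed* previous
frame — by at least half the quantization step, compressed with zlib.
Quantization makes the codec lossy: sensor noise below the step vanishes
(which is where most of the size reduction comes from), while the
high-contrast animals survive almost untouched.  An optional 2x2 or 4x4
block-average downsampling trades spatial resolution for further size
reduction; decoded frames are smoothed back up to full size.

Quantizing against the reconstruction rather than the previous raw frame
keeps the error bounded (no drift): slow drifts accumulate until they
cross the step and are then flushed.

File layout (little-endian)::

    b"ADVC" | version u8 | downsample u8 | quant_step u8 | jpeg_quality u8
    | height u16 | width u16 | fps f32
    | keyframe_len u32 | JPEG bytes
    | zlib stream of per-frame payloads:
        count u32 | count x index u32 | count x value i16
"""

from __future__ import annotations

import io
import struct
import zlib
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "write_png_sequence",
    "read_png_sequence",
    "DeltaVideoWriter",
    "read_delta_video",
    "encode_video",
    "open_source",
]

_MAGIC = b"ADVC"
_VERSION = 1


# ---------------------------------------------------------------------------
# PNG sequences (lossless interchange format)
# ---------------------------------------------------------------------------

def write_png_sequence(frames, directory) -> int:
    """Write frames as ``frame_000000.png``...; returns the frame count."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n = 0
    for i, frame in enumerate(frames):
        iio.imwrite(directory / f"frame_{i:06d}.png", np.asarray(frame))
        n += 1
    return n


def read_png_sequence(directory):
    """Yield frames from a directory of numbered PNGs, in order."""
    for p in sorted(Path(directory).glob("frame_*.png")):
        yield iio.imread(p)


# ---------------------------------------------------------------------------
# delta codec
# ---------------------------------------------------------------------------

def _downsample(frame: np.ndarray, ds: int) -> np.ndarray:
    if ds == 1:
        return frame.astype(np.int16)
    h, w = frame.shape
    hp, wp = -(-h // ds) * ds, -(-w // ds) * ds  # pad up to a multiple
    pad = np.zeros((hp, wp), dtype=np.float32)
    pad[:h, :w] = frame
    if hp > h:
        pad[h:, :w] = frame[-1:, :]
    if wp > w:
        pad[:, w:] = pad[:, w - 1 : w]
    small = pad.reshape(hp // ds, ds, wp // ds, ds).mean(axis=(1, 3))
    return np.round(small).astype(np.int16)


def _upsample(small: np.ndarray, ds: int, shape: tuple[int, int]) -> np.ndarray:
    if ds == 1:
        return np.clip(small, 0, 255).astype(np.uint8)
    big = np.repeat(np.repeat(small.astype(np.float32), ds, axis=0), ds, axis=1)
    big = ndimage.uniform_filter(big, size=ds, mode="nearest")
    return np.clip(np.round(big[: shape[0], : shape[1]]), 0, 255).astype(np.uint8)


class DeltaVideoWriter:
    """Streaming encoder; call :meth:`append` per frame, then :meth:`close`."""

    def __init__(
        self,
        path,
        fps: float = 30.0,
        quant_step: int = 8,
        downsample: int = 1,
        keyframe_quality: int = 85,
    ):
        if quant_step < 1 or quant_step > 255:
            raise ValueError("quant_step must be in 1..255")
        if downsample not in (1, 2, 4):
            raise ValueError("downsample must be 1, 2 or 4")
        self.path = Path(path)
        self.fps = fps
        self.quant_step = int(quant_step)
        self.downsample = int(downsample)
        self.keyframe_quality = int(keyframe_quality)
        self._fh = open(path, "wb")
        self._recon: np.ndarray | None = None
        self._shape: tuple[int, int] | None = None
        self._z = zlib.compressobj(9)
        self.n_frames = 0
        self._closed = False

    def append(self, frame: np.ndarray) -> None:
        frame = np.asarray(frame)
        if frame.dtype != np.uint8 or frame.ndim != 2:
            raise ValueError("frames must be 2-D uint8")
        if self._recon is None:
            self._shape = frame.shape
            h, w = frame.shape
            self._fh.write(_MAGIC)
            self._fh.write(
                struct.pack(
                    "<BBBBHHf",
                    _VERSION,
                    self.downsample,
                    self.quant_step,
                    self.keyframe_quality,
                    h,
                    w,
                    self.fps,
                )
            )
            small = _downsample(frame, self.downsample)
            buf = io.BytesIO()
            Image.fromarray(np.clip(small, 0, 255).astype(np.uint8)).save(
                buf, format="JPEG", quality=self.keyframe_quality
            )
            data = buf.getvalue()
            self._fh.write(struct.pack("<I", len(data)))
            self._fh.write(data)
            self._recon = np.asarray(
                Image.open(io.BytesIO(data)), dtype=np.int16
            )
        else:
            if frame.shape != self._shape:
                raise ValueError("frame size changed mid-stream")
            small = _downsample(frame, self.downsample)
            d = small - self._recon
            q = np.round(d / self.quant_step).astype(np.int16) * self.quant_step
            idx = np.flatnonzero(q)
            vals = q.ravel()[idx]
            payload = (
                struct.pack("<I", len(idx))
                + idx.astype("<u4").tobytes()
                + vals.astype("<i2").tobytes()
            )
            self._fh.write(self._z.compress(payload))
            self._recon.ravel()[idx] += vals
        self.n_frames += 1

    def close(self) -> None:
        if self._closed:
            return
        self._fh.write(self._z.flush())
        self._fh.close()
        self._closed = True

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def encode_video(
    frames,
    path,
    fps: float = 30.0,
    quant_step: int = 8,
    downsample: int = 1,
    keyframe_quality: int = 85,
) -> dict:
    """Encode a frame stream; returns achieved sizes and ratio.

    The raw size is ``height * width * n_frames`` bytes (8-bit video); the
    compression factor is raw size over encoded file size, *measured*, not
    assumed.
    """
    with DeltaVideoWriter(path, fps, quant_step, downsample, keyframe_quality) as w:
        shape = None
        for frame in frames:
            if shape is None:
                shape = frame.shape
            w.append(frame)
        n = w.n_frames
    encoded = Path(path).stat().st_size
    raw = int(shape[0] * shape[1] * n)
    return {
        "n_frames": n,
        "raw_bytes": raw,
        "encoded_bytes": encoded,
        "ratio": raw / encoded,
    }


def read_delta_video(path):
    """Yield decoded uint8 frames from an ``.adv`` file."""
    with open(path, "rb") as fh:
        if fh.read(4) != _MAGIC:
            raise ValueError("not a delta video file")
        version, ds, step, _q, h, w, _fps = struct.unpack("<BBBBHHf", fh.read(12))
        if version != _VERSION:
            raise ValueError(f"unsupported version {version}")
        (klen,) = struct.unpack("<I", fh.read(4))
        key = np.asarray(Image.open(io.BytesIO(fh.read(klen))), dtype=np.int16)
        recon = key
        yield _upsample(recon, ds, (h, w))
        z = zlib.decompressobj()
        buf = b""
        flushed = False

        def need(nbytes):
            nonlocal buf, flushed
            while len(buf) < nbytes:
                chunk = fh.read(1 << 16)
                if not chunk:
                    if not flushed:
                        flushed = True
                        buf += z.flush()
                        continue
                    return False
                buf += z.decompress(chunk)
            return True

        while True:
            if not need(4):
                break
            (count,) = struct.unpack("<I", buf[:4])
            body = 4 * count + 2 * count
            if not need(4 + body):
                break
            idx = np.frombuffer(buf[4 : 4 + 4 * count], dtype="<u4")
            vals = np.frombuffer(
                buf[4 + 4 * count : 4 + body], dtype="<i2"
            )
            buf = buf[4 + body :]
            recon.ravel()[idx.astype(np.intp)] += vals
            yield _upsample(recon, ds, (h, w))


def open_source(source):
    """Frame iterable from a path (PNG directory or .adv file) or pass-through."""
    if isinstance(source, (str, Path)):
        p = Path(source)
        if p.is_dir():
            return read_png_sequence(p)
        if p.suffix == ".adv":
            return read_delta_video(p)
        raise ValueError(f"unrecognized video source {p}")
    return source
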