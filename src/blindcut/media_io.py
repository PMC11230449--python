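"""Probe, read and write the media formats the workflow accepts.

Images (PNG, JPEG, BMP) go through Pillow and are promoted to a single
internal pixel model: 8-bit RGB, alpha dropped.  Video support is built on a
self-contained RIFF/AVI container layer: frames are stored either as raw
24-bit DIB bitmaps (lossless, the default) or as MJPEG (one JPEG per frame,
encoded with Pillow).  MP4 files can be probed — dimensions, frame count and
frame rate are read from the ISO base-media ``moov`` metadata — but their
compressed streams cannot be decoded here, so frame access on MP4 raises
:class:`~blindcut.errors.UnsupportedCodec`.

Frame indexing is 0-based throughout; a frame's timestamp is
``frame_index / fps``.
"""

from __future__ import annotations

import io
import os
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import (
    CorruptMedia,
    InvalidInput,
    IOFailure,
    KindMismatch,
    UnsupportedCodec,
    UnsupportedFormat,
)

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".bmp"}
VIDEO_EXTENSIONS = {".mp4", ".avi"}

#: codec identifiers accepted by :func:`write_video`
VIDEO_CODECS = ("rawrgb", "mjpeg")
DEFAULT_VIDEO_CODEC = "rawrgb"

_PIL_FORMAT_FOR_EXT = {
    ".png": {"PNG"},
    ".jpg": {"JPEG"},
    ".jpeg": {"JPEG"},
    ".bmp": {"BMP"},
}

_MJPEG_QUALITY = 92


@dataclass(frozen=True)
class MediaSource:
    """A probed media file.

    ``frame_count`` is 1 and ``fps`` is ``None`` for still images.
    ``media_id`` is an opaque identifier; it must be unique within one
    manifest (the manifest builder enforces this).
    """

    path: str
    kind: str  # "image" | "video"
    width: int
    height: int
    frame_count: int
    fps: Optional[float] = None
    media_id: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("image", "video"):
            raise InvalidInput(f"unknown media kind {self.kind!r}")
        if self.width < 1 or self.height < 1 or self.frame_count < 1:
            raise CorruptMedia(
                f"{self.path}: nonpositive dimensions or frame count"
            )
        if self.kind == "image" and (self.frame_count != 1 or self.fps is not None):
            raise InvalidInput("images have frame_count=1 and no fps")


@dataclass
class Frame:
    """One RGB frame: an H x W x 3 uint8 array plus its 0-based index."""

    pixels: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise InvalidInput(f"frame must be HxWx3, got shape {px.shape}")
        self.pixels = np.ascontiguousarray(px, dtype=np.uint8)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


# ---------------------------------------------------------------------------
# probing
# ---------------------------------------------------------------------------

def probe_media(path: Union[str, os.PathLike], media_id: Optional[str] = None) -> MediaSource:
    """Probe a media file: infer its kind from the extension, verify the
    header actually matches, and populate dimensions and frame count.

    Raises ``UnsupportedFormat`` for an extension outside the accepted list
    and ``CorruptMedia`` when the file cannot be decoded or its header
    contradicts the extension (a lying extension is never silently
    reinterpreted).
    """
    p = Path(path)
    if not p.is_file():
        raise IOFailure(f"no such file: {p}")
    ext = p.suffix.lower()
    mid = media_id if media_id is not None else p.name
    if ext in IMAGE_EXTENSIONS:
        w, h = _probe_image(p, ext)
        return MediaSource(path=str(p), kind="image", width=w, height=h,
                           frame_count=1, fps=None, media_id=mid)
    if ext == ".avi":
        w, h, n, fps, _codec = _read_avi_header(p)
        return MediaSource(path=str(p), kind="video", width=w, height=h,
                           frame_count=n, fps=fps, media_id=mid)
    if ext == ".mp4":
        w, h, n, fps = _probe_mp4(p)
        return MediaSource(path=str(p), kind="video", width=w, height=h,
                           frame_count=n, fps=fps, media_id=mid)
    raise UnsupportedFormat(
        f"{p.name}: extension {ext!r} is not a supported media format "
        f"(accepted: {sorted(IMAGE_EXTENSIONS | VIDEO_EXTENSIONS)})"
    )


def _probe_image(p: Path, ext: str) -> tuple[int, int]:
    try:
        with Image.open(p) as im:
            detected = im.format
            w, h = im.size
    except (UnidentifiedImageError, OSError) as exc:
        raise CorruptMedia(f"{p.name}: cannot decode image ({exc})") from exc
    if detected not in _PIL_FORMAT_FOR_EXT[ext]:
        raise CorruptMedia(
            f"{p.name}: extension says {ext} but header is {detected}"
        )
    return int(w), int(h)


# ---------------------------------------------------------------------------
# frame access
# ---------------------------------------------------------------------------

def first_frame(src: MediaSource) -> Frame:
    """Return frame 0; for an image, the image itself (as RGB)."""
    if src.kind == "image":
        try:
            with Image.open(src.path) as im:
                rgb = im.convert("RGB")
                return Frame(np.asarray(rgb), frame_index=0)
        except (UnidentifiedImageError, OSError) as exc:
            raise CorruptMedia(f"{src.path}: cannot decode ({exc})") from exc
    return next(iter_frames(src))


def iter_frames(src: MediaSource) -> Iterator[Frame]:
    """Yield every frame of a video in order, with consecutive 0-based
    indices.  Raises ``KindMismatch`` when called on an image."""
    if src.kind != "video":
        raise KindMismatch("iter_frames requires a video source")
    ext = Path(src.path).suffix.lower()
    if ext == ".mp4":
        raise UnsupportedCodec(
            f"{src.path}: MP4 streams cannot be decoded (no codec available); "
            "probe metadata is supported, frame access is not"
        )
    return _iter_avi_frames(Path(src.path))


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_image(frame: Union[Frame, np.ndarray], path: Union[str, os.PathLike]) -> Path:
    """Write one frame losslessly as PNG (bit-exact round trip)."""
    p = Path(path)
    if p.suffix.lower() != ".png":
        raise InvalidInput(f"image segments are written as PNG, got {p.suffix!r}")
    px = frame.pixels if isinstance(frame, Frame) else np.asarray(frame, dtype=np.uint8)
    if px.ndim != 3 or px.shape[2] != 3:
        raise InvalidInput("write_image expects an HxWx3 RGB frame")
    try:
        Image.fromarray(px, mode="RGB").save(p, format="PNG")
    except OSError as exc:
        raise IOFailure(f"cannot write {p}: {exc}") from exc
    return p


def write_video(
    frames: Iterable[Union[Frame, np.ndarray]],
    fps: float,
    path: Union[str, os.PathLike],
    codec: str = DEFAULT_VIDEO_CODEC,
) -> Path:
    """Write a stream of frames into an AVI container.

    ``codec`` is ``"rawrgb"`` (uncompressed 24-bit DIB, lossless) or
    ``"mjpeg"`` (per-frame JPEG).  All frames must share one size; an empty
    stream raises ``InvalidInput``.
    """
    p = Path(path)
    if p.suffix.lower() != ".avi":
        raise InvalidInput(f"video segments are written as .avi, got {p.suffix!r}")
    if codec not in VIDEO_CODECS:
        raise InvalidInput(f"unknown codec {codec!r}; choose from {VIDEO_CODECS}")
    if not fps or fps <= 0:
        raise InvalidInput("fps must be positive")
    it = iter(frames)
    try:
        first = next(it)
    except StopIteration:
        raise InvalidInput("empty frame stream") from None

    def as_array(f: Union[Frame, np.ndarray]) -> np.ndarray:
        px = f.pixels if isinstance(f, Frame) else np.asarray(f, dtype=np.uint8)
        if px.ndim != 3 or px.shape[2] != 3:
            raise InvalidInput("video frames must be HxWx3 RGB")
        return np.ascontiguousarray(px, dtype=np.uint8)

    first_px = as_array(first)
    h, w = first_px.shape[:2]

    def stream() -> Iterator[np.ndarray]:
        yield first_px
        for f in it:
            px = as_array(f)
            if px.shape[:2] != (h, w):
                raise InvalidInput(
                    f"frame size {px.shape[1]}x{px.shape[0]} does not match "
                    f"stream size {w}x{h}"
                )
            yield px

    try:
        _write_avi(p, stream(), w, h, fps, codec)
    except OSError as exc:
        raise IOFailure(f"cannot write {p}: {exc}") from exc
    return p


# ---------------------------------------------------------------------------
# AVI container layer (RIFF)
# ---------------------------------------------------------------------------
# Only what the workflow needs: one 24-bit video stream, 'DIB ' (raw,
# bottom-up BGR rows padded to 4 bytes) or 'MJPG' (JPEG per frame).

_AVIF_HASINDEX = 0x00000010
_FPS_SCALE = 1000  # fps stored as rate/scale with scale fixed at 1000


def _dib_encode(px: np.ndarray) -> bytes:
    h, w = px.shape[:2]
    bgr = px[::-1, :, ::-1]  # bottom-up rows, BGR channel order
    row = w * 3
    pad = (-row) % 4
    if pad:
        padded = np.zeros((h, row + pad), dtype=np.uint8)
        padded[:, :row] = bgr.reshape(h, row)
        return padded.tobytes()
    return np.ascontiguousarray(bgr).tobytes()


def _dib_decode(data: bytes, w: int, h: int) -> np.ndarray:
    row = w * 3
    stride = row + ((-row) % 4)
    if len(data) < stride * h:
        raise CorruptMedia("truncated DIB frame")
    arr = np.frombuffer(data, dtype=np.uint8, count=stride * h).reshape(h, stride)
    bgr = arr[:, :row].reshape(h, w, 3)
    return np.ascontiguousarray(bgr[::-1, :, ::-1])


def _mjpeg_encode(px: np.ndarray) -> bytes:
    buf = io.BytesIO()
    Image.fromarray(px, mode="RGB").save(buf, format="JPEG", quality=_MJPEG_QUALITY)
    return buf.getvalue()


def _mjpeg_decode(data: bytes) -> np.ndarray:
    try:
        with Image.open(io.BytesIO(data)) as im:
            return np.asarray(im.convert("RGB"))
    except (UnidentifiedImageError, OSError) as exc:
        raise CorruptMedia(f"bad MJPEG frame ({exc})") from exc


def _write_avi(p: Path, frames: Iterator[np.ndarray], w: int, h: int,
               fps: float, codec: str) -> None:
    handler = b"DIB " if codec == "rawrgb" else b"MJPG"
    compression = 0 if codec == "rawrgb" else struct.unpack("<I", b"MJPG")[0]
    chunk_id = b"00db" if codec == "rawrgb" else b"00dc"
    rate = int(round(fps * _FPS_SCALE))
    usec_per_frame = int(round(1_000_000 * _FPS_SCALE / rate))
    frame_bytes = w * h * 3 + h * ((-w * 3) % 4)

    with open(p, "wb") as fh:
        fh.write(b"RIFF\x00\x00\x00\x00AVI ")
        # hdrl: avih + one strl (sizes fixed, values patched afterwards)
        fh.write(b"LIST" + struct.pack("<I", 4 + 64 + 124) + b"hdrl")
        avih_pos = fh.tell()
        fh.write(b"avih" + struct.pack("<I", 56))
        fh.write(struct.pack(
            "<14I", usec_per_frame, 0, 0, _AVIF_HASINDEX,
            0,  # dwTotalFrames, patched
            0, 1, frame_bytes, w, h, 0, 0, 0, 0,
        ))
        fh.write(b"LIST" + struct.pack("<I", 4 + 64 + 48) + b"strl")
        strh_pos = fh.tell()
        fh.write(b"strh" + struct.pack("<I", 56))
        fh.write(b"vids" + handler)
        fh.write(struct.pack(
            "<IHHIIIIIIII4H",
            0, 0, 0, 0, _FPS_SCALE, rate, 0,
            0,  # dwLength (frames), patched
            frame_bytes, 0xFFFFFFFF, 0, 0, 0, w, h,
        ))
        fh.write(b"strf" + struct.pack("<I", 40))
        fh.write(struct.pack("<IiiHHIIiiII", 40, w, h, 1, 24, compression,
                             frame_bytes, 0, 0, 0, 0))
        movi_pos = fh.tell()
        fh.write(b"LIST\x00\x00\x00\x00movi")

        index: list[tuple[int, int]] = []  # (offset within movi, size)
        n = 0
        for px in frames:
            data = _dib_encode(px) if codec == "rawrgb" else _mjpeg_encode(px)
            offset = fh.tell() - (movi_pos + 8)
            fh.write(chunk_id + struct.pack("<I", len(data)))
            fh.write(data)
            if len(data) % 2:
                fh.write(b"\x00")
            index.append((offset, len(data)))
            n += 1
        movi_end = fh.tell()

        fh.write(b"idx1" + struct.pack("<I", 16 * n))
        for offset, size in index:
            fh.write(chunk_id + struct.pack("<III", 0x10, offset, size))
        riff_end = fh.tell()

        fh.seek(avih_pos + 8 + 16)
        fh.write(struct.pack("<I", n))
        fh.seek(strh_pos + 8 + 32)
        fh.write(struct.pack("<I", n))
        fh.seek(movi_pos + 4)
        fh.write(struct.pack("<I", movi_end - movi_pos - 8))
        fh.seek(4)
        fh.write(struct.pack("<I", riff_end - 8))


def _read_avi_header(p: Path) -> tuple[int, int, int, float, str]:
    """Return (width, height, frame_count, fps, codec) from container
    metadata without decoding any frame."""
    try:
        with open(p, "rb") as fh:
            head = fh.read(12)
            if len(head) < 12 or head[:4] != b"RIFF" or head[8:12] != b"AVI ":
                raise CorruptMedia(f"{p.name}: not a RIFF/AVI file")
            total = width = height = None
            rate = scale = None
            compression = None
            while True:
                hdr = fh.read(8)
                if len(hdr) < 8:
                    break
                cid, size = hdr[:4], struct.unpack("<I", hdr[4:])[0]
                if cid == b"LIST":
                    list_type = fh.read(4)
                    if list_type in (b"hdrl", b"strl"):
                        continue  # descend
                    fh.seek(size - 4, os.SEEK_CUR)
                    continue
                body = fh.read(size + (size % 2))[:size]
                if cid == b"avih" and size >= 56:
                    vals = struct.unpack("<14I", body[:56])
                    total, width, height = vals[4], vals[8], vals[9]
                elif cid == b"strh" and size >= 56 and body[:4] == b"vids":
                    scale, rate = struct.unpack("<II", body[20:28])
                elif cid == b"strf" and size >= 40:
                    compression = struct.unpack("<I", body[16:20])[0]
                if total is not None and rate is not None and compression is not None:
                    break
    except OSError as exc:
        raise IOFailure(f"cannot read {p}: {exc}") from exc
    if total is None or rate is None or not scale:
        raise CorruptMedia(f"{p.name}: AVI headers incomplete")
    if width is None or width < 1 or height is None or height < 1 or total < 1:
        raise CorruptMedia(f"{p.name}: AVI header reports empty video")
    codec = "rawrgb" if compression == 0 else "mjpeg"
    return int(width), int(height), int(total), rate / scale, codec


def _iter_avi_frames(p: Path) -> Iterator[Frame]:
    w, h, total, _fps, codec = _read_avi_header(p)
    try:
        with open(p, "rb") as fh:
            fh.seek(12)
            movi_start = movi_size = None
            while True:
                hdr = fh.read(8)
                if len(hdr) < 8:
                    break
                cid, size = hdr[:4], struct.unpack("<I", hdr[4:])[0]
                if cid == b"LIST":
                    list_type = fh.read(4)
                    if list_type == b"movi":
                        movi_start, movi_size = fh.tell(), size - 4
                        break
                    if list_type == b"hdrl":
                        continue
                    fh.seek(size - 4, os.SEEK_CUR)
                else:
                    fh.seek(size + (size % 2), os.SEEK_CUR)
            if movi_start is None:
                raise CorruptMedia(f"{p.name}: no movi list")
            idx = 0
            end = movi_start + movi_size
            while fh.tell() < end:
                hdr = fh.read(8)
                if len(hdr) < 8:
                    break
                cid, size = hdr[:4], struct.unpack("<I", hdr[4:])[0]
                data = fh.read(size)
                if size % 2:
                    fh.seek(1, os.SEEK_CUR)
                if cid in (b"00db", b"00dc"):
                    px = _dib_decode(data, w, h) if codec == "rawrgb" else _mjpeg_decode(data)
                    if px.shape[:2] != (h, w):
                        raise CorruptMedia(f"{p.name}: frame size mismatch")
                    yield Frame(px, frame_index=idx)
                    idx += 1
    except OSError as exc:
        raise IOFailure(f"cannot read {p}: {exc}") from exc
    if idx != total:
        raise CorruptMedia(
            f"{p.name}: header promises {total} frames, found {idx}"
        )


# ---------------------------------------------------------------------------
# MP4 metadata probe (ISO base media file format)
# ---------------------------------------------------------------------------

def _iter_boxes(data: bytes, start: int, end: int) -> Iterator[tuple[bytes, int, int]]:
    """Yield (type, payload_start, payload_end) for boxes in data[start:end]."""
    pos = start
    while pos + 8 <= end:
        size = struct.unpack(">I", data[pos:pos + 4])[0]
        btype = data[pos + 4:pos + 8]
        payload = pos + 8
        if size == 1:
            if pos + 16 > end:
                raise CorruptMedia("truncated 64-bit box")
            size = struct.unpack(">Q", data[pos + 8:pos + 16])[0]
            payload = pos + 16
        elif size == 0:
            size = end - pos
        if size < 8 or pos + size > end:
            raise CorruptMedia("malformed box size")
        yield btype, payload, pos + size
        pos += size


def _find_box(data: bytes, start: int, end: int, btype: bytes) -> Optional[tuple[int, int]]:
    for t, a, b in _iter_boxes(data, start, end):
        if t == btype:
            return a, b
    return None


def _probe_mp4(p: Path) -> tuple[int, int, int, Optional[float]]:
    try:
        data = p.read_bytes()
    except OSError as exc:
        raise IOFailure(f"cannot read {p}: {exc}") from exc
    if len(data) < 12 or data[4:8] != b"ftyp":
        raise CorruptMedia(f"{p.name}: not an MP4 (no ftyp box)")
    try:
        moov = _find_box(data, 0, len(data), b"moov")
        if moov is None:
            raise CorruptMedia(f"{p.name}: no moov box")
        for t, a, b in _iter_boxes(data, *moov):
            if t != b"trak":
                continue
            mdia = _find_box(data, a, b, b"mdia")
            if mdia is None:
                continue
            hdlr = _find_box(data, *mdia, b"hdlr")
            if hdlr is None or data[hdlr[0] + 8:hdlr[0] + 12] != b"vide":
                continue
            tkhd = _find_box(data, a, b, b"tkhd")
            mdhd = _find_box(data, *mdia, b"mdhd")
            minf = _find_box(data, *mdia, b"minf")
            stbl = _find_box(data, *minf, b"stbl") if minf else None
            stsz = _find_box(data, *stbl, b"stsz") if stbl else None
            if tkhd is None or mdhd is None or stsz is None:
                raise CorruptMedia(f"{p.name}: video track metadata incomplete")
            # width/height: trailing 16.16 fixed-point fields of tkhd
            width = struct.unpack(">I", data[tkhd[1] - 8:tkhd[1] - 4])[0] >> 16
            height = struct.unpack(">I", data[tkhd[1] - 4:tkhd[1]])[0] >> 16
            version = data[mdhd[0]]
            if version == 1:
                timescale = struct.unpack(">I", data[mdhd[0] + 20:mdhd[0] + 24])[0]
                duration = struct.unpack(">Q", data[mdhd[0] + 24:mdhd[0] + 32])[0]
            else:
                timescale = struct.unpack(">I", data[mdhd[0] + 12:mdhd[0] + 16])[0]
                duration = struct.unpack(">I", data[mdhd[0] + 16:mdhd[0] + 20])[0]
            n = struct.unpack(">I", data[stsz[0] + 8:stsz[0] + 12])[0]
            if width < 1 or height < 1 or n < 1:
                raise CorruptMedia(f"{p.name}: empty video track")
            fps = n * timescale / duration if duration else None
            return int(width), int(height), int(n), fps
    except struct.error as exc:
        raise CorruptMedia(f"{p.name}: malformed MP4 metadata ({exc})") from exc
    raise CorruptMedia(f"{p.name}: no video track found")
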