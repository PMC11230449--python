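"""Labeled rectangular segments: definition, validation, extraction.

A segment is a rectangle on one media source, labeled with the well-plate
scheme (row letter A-Z, column number 1-36).  All segments of an analysis —
possibly pooled from several media files of one kind — live in a
:class:`SegmentManifest` together with the ordered list of analysis stages.
Labels are unique across the whole manifest; duplicate labeling raises.

Coordinates are 0-based, half-open ``[x0, x1) x [y0, y1)``.  The on-disk
segment-definition file stores ``(x, y, width, height)`` per common ROI
conventions and is converted on load.  Crops are exact pixel subgrids — no
resampling, so segment resolution equals source resolution.
"""

from __future__ import annotations

import json
import logging
import os
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from . import media_io
from .errors import (
    DuplicateLabel,
    EmptyRegion,
    InvalidInput,
    InvalidLabel,
    IOFailure,
    KindMismatch,
    NoSegments,
    ParseError,
)
from .media_io import Frame, MediaSource

log = logging.getLogger(__name__)

MAX_ROWS = 26  # rows A..Z
MAX_COLS = 36  # columns 1..36

_LABEL_RE = re.compile(r"^([A-Za-z])([0-9]{1,2})$")

MANIFEST_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class Rect:
    """Half-open pixel rectangle [x0, x1) x [y0, y1)."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if self.x0 >= self.x1 or self.y0 >= self.y1:
            raise EmptyRegion(f"empty rectangle {self.as_tuple()}")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.x0, self.y0, self.x1, self.y1)

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    def clamped(self, frame_width: int, frame_height: int) -> "Rect":
        """Clamp to frame bounds, as an interactive drag would; a rectangle
        entirely outside the frame raises ``EmptyRegion``."""
        x0, y0 = max(self.x0, 0), max(self.y0, 0)
        x1, y1 = min(self.x1, frame_width), min(self.y1, frame_height)
        if x0 >= x1 or y0 >= y1:
            raise EmptyRegion(
                f"rectangle {self.as_tuple()} lies outside the "
                f"{frame_width}x{frame_height} frame"
            )
        return Rect(x0, y0, x1, y1)

    def overlaps(self, other: "Rect") -> bool:
        return (self.x0 < other.x1 and other.x0 < self.x1
                and self.y0 < other.y1 and other.y0 < self.y1)


@dataclass(frozen=True, order=True)
class SegmentLabel:
    """Well-style label: row letter A-Z plus column number 1-36.

    Ordering is row-major (A1 < A2 < ... < B1), which is also the export
    sort order.
    """

    row_letter: str
    col_number: int

    def __post_init__(self) -> None:
        if len(self.row_letter) != 1 or not "A" <= self.row_letter <= "Z":
            raise InvalidLabel(f"row letter must be A-Z, got {self.row_letter!r}")
        if not 1 <= self.col_number <= MAX_COLS:
            raise InvalidLabel(
                f"column number must be 1-{MAX_COLS}, got {self.col_number}"
            )

    def render(self) -> str:
        return f"{self.row_letter}{self.col_number}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def validate_label(raw: str) -> SegmentLabel:
    """Parse ``"A1"`` .. ``"Z36"`` (case-insensitive, canonicalized upper)."""
    m = _LABEL_RE.match(str(raw).strip())
    if not m:
        raise InvalidLabel(
            f"label {raw!r} is not a letter A-Z followed by a number 1-{MAX_COLS}"
        )
    letter, number = m.group(1).upper(), int(m.group(2))
    if not 1 <= number <= MAX_COLS:
        raise InvalidLabel(f"label {raw!r}: column number out of range 1-{MAX_COLS}")
    return SegmentLabel(letter, number)


@dataclass
class SegmentDef:
    """One labeled rectangle bound to a media source; ``segment_path`` is
    filled by :func:`extract_segments`."""

    label: SegmentLabel
    rect: Rect
    media_id: str
    segment_path: Optional[str] = None


@dataclass
class SegmentManifest:
    """All sources and segments of one analysis, plus the stage names.

    Sources must all share one media kind; stage names are non-empty and
    unique.  Segments are kept in definition order.
    """

    sources: list[MediaSource] = field(default_factory=list)
    segments: list[SegmentDef] = field(default_factory=list)
    stages: list[str] = field(default_factory=list)
    results_folder: str = "results"

    def __post_init__(self) -> None:
        if not self.stages:
            raise InvalidInput("at least one analysis stage is required")
        if len(set(self.stages)) != len(self.stages):
            raise InvalidInput("stage names must be unique")
        kinds = {s.kind for s in self.sources}
        if len(kinds) > 1:
            raise KindMismatch("a manifest cannot mix image and video sources")
        ids = [s.media_id for s in self.sources]
        if len(set(ids)) != len(ids):
            raise InvalidInput("media_id values must be unique within a manifest")

    @property
    def kind(self) -> Optional[str]:
        return self.sources[0].kind if self.sources else None

    def add_source(self, src: MediaSource) -> None:
        if any(s.media_id == src.media_id for s in self.sources):
            raise InvalidInput(f"duplicate media_id {src.media_id!r}")
        if self.sources and src.kind != self.kind:
            raise KindMismatch(
                f"manifest holds {self.kind} media; cannot add {src.kind} "
                f"source {src.path}"
            )
        self.sources.append(src)

    def source_by_id(self, media_id: str) -> MediaSource:
        for s in self.sources:
            if s.media_id == media_id:
                return s
        raise InvalidInput(f"unknown media_id {media_id!r}")

    def labels(self) -> set[str]:
        return {seg.label.render() for seg in self.segments}


def add_segment(
    manifest: SegmentManifest,
    label: Union[SegmentLabel, str],
    rect: Rect,
    media_id: str,
) -> SegmentManifest:
    """Append one segment, clamping its rectangle to the source bounds.

    Duplicate labels anywhere in the manifest raise ``DuplicateLabel``
    (labels can never be reused, even across source files); a rectangle
    entirely outside the frame raises ``EmptyRegion``.
    """
    lab = validate_label(label) if isinstance(label, str) else label
    src = manifest.source_by_id(media_id)
    if lab.render() in manifest.labels():
        raise DuplicateLabel(f"label {lab.render()} already used in this manifest")
    clamped = rect.clamped(src.width, src.height)
    for other in manifest.segments:
        if other.media_id == media_id and clamped.overlaps(other.rect):
            log.warning(
                "segment %s overlaps segment %s on %s",
                lab.render(), other.label.render(), media_id,
            )
            break
    manifest.segments.append(SegmentDef(label=lab, rect=clamped, media_id=media_id))
    return manifest


def crop_frame(frame: Frame, rect: Rect) -> Frame:
    """Exact pixel crop: output is the (x1-x0) x (y1-y0) source subgrid."""
    if (rect.x0 < 0 or rect.y0 < 0
            or rect.x1 > frame.width or rect.y1 > frame.height):
        raise EmptyRegion(
            f"rect {rect.as_tuple()} exceeds {frame.width}x{frame.height} frame"
        )
    sub = frame.pixels[rect.y0:rect.y1, rect.x0:rect.x1, :]
    return Frame(np.ascontiguousarray(sub), frame_index=frame.frame_index)


def segment_filename(index: int, kind: str) -> str:
    """On-disk name of the extracted segment for manifest position
    ``index``.  Deliberately derived from the definition index only — never
    from the label — so the results folder does not leak identities."""
    ext = ".png" if kind == "image" else ".avi"
    return f"seg_{index:04d}{ext}"


def extract_segments(
    manifest: SegmentManifest,
    codec: str = media_io.DEFAULT_VIDEO_CODEC,
) -> SegmentManifest:
    """Cut every defined segment out of its source and write it to the
    results folder, filling ``segment_path`` on each :class:`SegmentDef`.

    Image segments are lossless PNG crops; video segments crop every frame
    with the segment's rectangle and are written at the source fps.  Output
    is deterministic: re-extracting identical inputs produces byte-identical
    PNG files.
    """
    if not manifest.segments:
        raise NoSegments("manifest defines no segments to extract")
    folder = Path(manifest.results_folder)
    try:
        folder.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOFailure(f"cannot create {folder}: {exc}") from exc

    # group by source so each video is decoded once
    by_source: dict[str, list[int]] = {}
    for i, seg in enumerate(manifest.segments):
        by_source.setdefault(seg.media_id, []).append(i)

    paths: dict[int, Path] = {}
    for media_id, indices in by_source.items():
        src = manifest.source_by_id(media_id)
        if src.kind == "image":
            base = media_io.first_frame(src)
            for i in indices:
                out = folder / segment_filename(i, "image")
                media_io.write_image(crop_frame(base, manifest.segments[i].rect), out)
                paths[i] = out
        else:
            _extract_video_segments(manifest, src, indices, folder, codec, paths)

    for i, seg in enumerate(manifest.segments):
        seg.segment_path = str(paths[i])
    log.info("extracted %d segments into %s", len(manifest.segments), folder)
    return manifest


def _extract_video_segments(
    manifest: SegmentManifest,
    src: MediaSource,
    indices: list[int],
    folder: Path,
    codec: str,
    paths: dict[int, Path],
) -> None:
    # one pass over the source: buffer cropped frames per segment
    buffers: dict[int, list[np.ndarray]] = {i: [] for i in indices}
    for frame in media_io.iter_frames(src):
        for i in indices:
            buffers[i].append(crop_frame(frame, manifest.segments[i].rect).pixels)
    for i in indices:
        out = folder / segment_filename(i, "video")
        media_io.write_video(
            (Frame(px, k) for k, px in enumerate(buffers[i])),
            fps=src.fps or 1.0, path=out, codec=codec,
        )
        paths[i] = out


# ---------------------------------------------------------------------------
# headless segment definition: definitions file and regular grids
# ---------------------------------------------------------------------------

def load_segment_file(
    path: Union[str, os.PathLike],
    stages: Sequence[str],
    results_folder: str = "results",
) -> SegmentManifest:
    """Build a manifest from a plain-text segment-definition file — the
    headless replacement for drawing rectangles with the mouse.

    One row per segment, whitespace- or comma-separated::

        # media_file  label  x  y  width  height
        plate.png     A1     10 12 30     30

    Media paths are resolved relative to the definition file.  Every row is
    validated through :func:`validate_label` and :func:`add_segment`, so
    duplicate labels and out-of-frame rectangles raise with the offending
    row number.
    """
    p = Path(path)
    try:
        lines = p.read_text(encoding="utf-8").splitlines()
    except OSError as exc:
        raise IOFailure(f"cannot read {p}: {exc}") from exc
    manifest = SegmentManifest(stages=list(stages), results_folder=results_folder)
    seen_media: dict[str, str] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 6:
            raise ParseError(
                f"{p.name}:{lineno}: expected 6 fields "
                "(media_file label x y width height), got "
                f"{len(parts)}"
            )
        media_file, label_raw = parts[0], parts[1]
        try:
            x, y, w, h = (int(v) for v in parts[2:])
        except ValueError as exc:
            raise ParseError(f"{p.name}:{lineno}: non-integer geometry") from exc
        media_path = str((p.parent / media_file).resolve())
        try:
            if media_path not in seen_media:
                media_id = f"m{len(seen_media)}"
                manifest.add_source(media_io.probe_media(media_path, media_id=media_id))
                seen_media[media_path] = media_id
            if w <= 0 or h <= 0:
                raise EmptyRegion(f"width/height must be positive, got {w}x{h}")
            add_segment(manifest, label_raw, Rect(x, y, x + w, y + h),
                        seen_media[media_path])
        except (InvalidLabel, DuplicateLabel, EmptyRegion, KindMismatch) as exc:
            raise ParseError(f"{p.name}:{lineno}: {exc}") from exc
    return manifest


def grid_segments(
    source: MediaSource,
    n_rows: int,
    n_cols: int,
    origin: tuple[int, int],
    pitch: Union[int, tuple[int, int]],
    cell_size: Union[int, tuple[int, int]],
) -> list[SegmentDef]:
    """Regular well-plate grid: row ``r``, column ``c`` gets label
    (letter(r), c+1); cells tile the grid without overlap.

    ``pitch`` is the center-to-center spacing, ``cell_size`` the rectangle
    size; both accept one value or an (x, y) pair.  ``cell_size`` must not
    exceed ``pitch`` (cells would overlap) and the grid must fit inside the
    frame.
    """
    if not 1 <= n_rows <= MAX_ROWS:
        raise InvalidLabel(f"n_rows must be 1-{MAX_ROWS} (row letters A-Z)")
    if not 1 <= n_cols <= MAX_COLS:
        raise InvalidLabel(f"n_cols must be 1-{MAX_COLS}")
    px, py = (pitch, pitch) if isinstance(pitch, int) else pitch
    cw, ch = (cell_size, cell_size) if isinstance(cell_size, int) else cell_size
    if cw <= 0 or ch <= 0:
        raise EmptyRegion("cell size must be positive")
    if cw > px or ch > py:
        raise InvalidInput("cell size exceeds pitch; grid cells would overlap")
    ox, oy = origin
    x_end = ox + (n_cols - 1) * px + cw
    y_end = oy + (n_rows - 1) * py + ch
    if ox < 0 or oy < 0 or x_end > source.width or y_end > source.height:
        raise EmptyRegion(
            f"grid spans ({ox},{oy})..({x_end},{y_end}) outside the "
            f"{source.width}x{source.height} frame"
        )
    out = []
    for r in range(n_rows):
        for c in range(n_cols):
            x0, y0 = ox + c * px, oy + r * py
            out.append(SegmentDef(
                label=SegmentLabel(chr(ord("A") + r), c + 1),
                rect=Rect(x0, y0, x0 + cw, y0 + ch),
                media_id=source.media_id,
            ))
    return out


# ---------------------------------------------------------------------------
# manifest persistence (JSON)
# ---------------------------------------------------------------------------

def manifest_to_dict(manifest: SegmentManifest) -> dict:
    return {
        "version": MANIFEST_SCHEMA_VERSION,
        "results_folder": manifest.results_folder,
        "stages": list(manifest.stages),
        "sources": [
            {"media_id": s.media_id, "path": s.path, "kind": s.kind,
             "width": s.width, "height": s.height,
             "frame_count": s.frame_count, "fps": s.fps}
            for s in manifest.sources
        ],
        "segments": [
            {"label": seg.label.render(), "rect": list(seg.rect.as_tuple()),
             "media_id": seg.media_id, "segment_path": seg.segment_path}
            for seg in manifest.segments
        ],
    }


def manifest_from_dict(data: dict) -> SegmentManifest:
    try:
        manifest = SegmentManifest(
            stages=list(data["stages"]),
            results_folder=data["results_folder"],
        )
        for s in data["sources"]:
            manifest.add_source(MediaSource(
                path=s["path"], kind=s["kind"], width=s["width"],
                height=s["height"], frame_count=s["frame_count"],
                fps=s["fps"], media_id=s["media_id"],
            ))
        for seg in data["segments"]:
            lab = validate_label(seg["label"])
            if lab.render() in manifest.labels():
                raise DuplicateLabel(f"label {lab.render()} repeated")
            manifest.segments.append(SegmentDef(
                label=lab, rect=Rect(*seg["rect"]),
                media_id=seg["media_id"],
                segment_path=seg.get("segment_path"),
            ))
        return manifest
    except (KeyError, TypeError) as exc:
        raise ParseError(f"malformed manifest: {exc}") from exc


def save_manifest(manifest: SegmentManifest, path: Union[str, os.PathLike]) -> Path:
    p = Path(path)
    try:
        p.write_text(json.dumps(manifest_to_dict(manifest), indent=2) + "\n",
                      encoding="utf-8")
    except OSError as exc:
        raise IOFailure(f"cannot write {p}: {exc}") from exc
    return p


def load_manifest(path: Union[str, os.PathLike]) -> SegmentManifest:
    p = Path(path)
    try:
        data = json.loads(p.read_text(encoding="utf-8"))
    except OSError as exc:
        raise IOFailure(f"cannot read {p}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise ParseError(f"{p.name}: not valid JSON ({exc})") from exc
    return manifest_from_dict(data)
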