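"""Synthetic multi-well-plate media with ground truth.

The generators emulate the scene the workflow is built for: a camera looking
down at a well plate, one specimen per well, rows lettered and columns
numbered.  Each well is a bright circle on a dark background holding one
dark particle; in videos the particle performs a seeded reflected random
walk whose step size ("motion amplitude", pixels/frame) is set per well by
its condition.  The default layout reproduces a 60-animal design: rows A-E
of a 96-well plate with four condition blocks of three columns each
(15 wells per condition) — a convulsant dose series plus an untreated
control, encoded here only as condition tags and activity levels.

Ground truth (label, condition, amplitude, trajectory seed per well) is
stored beside, never inside, the generated media — no label is burned into
the pixels — so blinding tests against these fixtures are meaningful.

``motion_energy`` is the measurement oracle used by scripted annotators:
the mean absolute inter-frame pixel difference per frame, zero for a static
clip and increasing with particle amplitude.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np

from . import media_io
from .errors import InvalidInput, InvalidSpec
from .media_io import Frame
from .segmentation import MAX_COLS, MAX_ROWS

_PARTICLE_RADIUS = 2
_PARTICLE_VALUE = 10  # dark dot on the bright well interior


@dataclass(frozen=True)
class PlateSpec:
    """Geometry of a synthetic plate image.

    ``pitch`` is the well center-to-center spacing; the image is sized to
    ``2*margin + n*pitch`` per axis unless overridden.  Defaults draw rows
    A-E x columns 1-12 (60 wells) at a scale where one well is a 32 px cell.
    """

    n_rows: int = 5
    n_cols: int = 12
    well_radius: int = 13
    margin: int = 16
    pitch: int = 32
    width: Optional[int] = None
    height: Optional[int] = None
    background: int = 40
    foreground: int = 200

    def __post_init__(self) -> None:
        if not 1 <= self.n_rows <= MAX_ROWS or not 1 <= self.n_cols <= MAX_COLS:
            raise InvalidSpec(
                f"grid must be 1-{MAX_ROWS} rows x 1-{MAX_COLS} cols, "
                f"got {self.n_rows}x{self.n_cols}"
            )
        if self.well_radius < _PARTICLE_RADIUS + 2:
            raise InvalidSpec("well radius too small to hold a particle")
        if 2 * self.well_radius > self.pitch:
            raise InvalidSpec("wells wider than the pitch would overlap")
        object.__setattr__(self, "width", self.width or
                           2 * self.margin + self.n_cols * self.pitch)
        object.__setattr__(self, "height", self.height or
                           2 * self.margin + self.n_rows * self.pitch)
        if (2 * self.margin + self.n_cols * self.pitch > self.width
                or 2 * self.margin + self.n_rows * self.pitch > self.height):
            raise InvalidSpec("grid does not fit inside the image")

    def well_center(self, row: int, col: int) -> tuple[float, float]:
        """(x, y) center of the well at 0-based (row, col)."""
        return (self.margin + col * self.pitch + self.pitch / 2,
                self.margin + row * self.pitch + self.pitch / 2)

    def grid_args(self) -> dict:
        """Arguments for ``segmentation.grid_segments`` that tile this
        plate with one cell per well."""
        return {"n_rows": self.n_rows, "n_cols": self.n_cols,
                "origin": (self.margin, self.margin),
                "pitch": self.pitch, "cell_size": self.pitch}


@dataclass(frozen=True)
class WellTruth:
    """Ground truth for one well."""

    label: str
    row: int
    col: int  # 0-based
    condition: str
    amplitude: float  # particle step scale, pixels/frame
    particle_seed: int


@dataclass(frozen=True)
class GroundTruth:
    """One entry per grid cell, in row-major (label) order."""

    wells: tuple[WellTruth, ...]

    def by_label(self) -> dict[str, WellTruth]:
        return {w.label: w for w in self.wells}

    def conditions(self) -> list[str]:
        seen: list[str] = []
        for w in self.wells:
            if w.condition not in seen:
                seen.append(w.condition)
        return seen


# The study design the default fixtures emulate: four condition blocks of
# three columns on rows A-E, 15 wells each.  Amplitudes encode "activity
# increases with dose"; the control still jitters slightly, as live
# untreated animals do.
DEFAULT_CONDITION_BLOCKS: tuple[tuple[str, tuple[int, int]], ...] = (
    ("PTZ_15mM", (1, 3)),
    ("PTZ_5mM", (4, 6)),
    ("PTZ_2.5mM", (7, 9)),
    ("control", (10, 12)),
)
DEFAULT_AMPLITUDES: dict[str, float] = {
    "PTZ_15mM": 8.0,
    "PTZ_5mM": 4.0,
    "PTZ_2.5mM": 2.0,
    "control": 0.5,
}


def condition_layout(
    column_blocks: Sequence[tuple[str, tuple[int, int]]],
    n_cols: int,
) -> dict[int, str]:
    """Map 1-based column number -> condition from (condition, (first_col,
    last_col)) blocks; ranges are inclusive, must be disjoint and inside
    1..n_cols."""
    out: dict[int, str] = {}
    for condition, (c0, c1) in column_blocks:
        if not (1 <= c0 <= c1 <= n_cols):
            raise InvalidSpec(
                f"block {condition!r} spans columns {c0}-{c1}, outside 1-{n_cols}"
            )
        for c in range(c0, c1 + 1):
            if c in out:
                raise InvalidSpec(
                    f"column {c} claimed by both {out[c]!r} and {condition!r}"
                )
            out[c] = condition
    return out


def build_ground_truth(
    spec: PlateSpec,
    seed: int,
    column_blocks: Sequence[tuple[str, tuple[int, int]]] = DEFAULT_CONDITION_BLOCKS,
    amplitudes: Optional[dict[str, float]] = None,
) -> GroundTruth:
    """Assign conditions by column block and derive one independent particle
    seed per well from ``seed`` (via a SeedSequence spawn, so wells are
    decorrelated and the whole truth is reproducible)."""
    amplitudes = dict(DEFAULT_AMPLITUDES if amplitudes is None else amplitudes)
    layout = condition_layout(column_blocks, spec.n_cols)
    missing = [c for c in layout.values() if c not in amplitudes]
    if missing:
        raise InvalidSpec(f"no amplitude given for conditions {sorted(set(missing))}")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(spec.n_rows * spec.n_cols)
    wells = []
    i = 0
    for r in range(spec.n_rows):
        for c in range(spec.n_cols):
            condition = layout.get(c + 1, "unassigned")
            wells.append(WellTruth(
                label=f"{chr(ord('A') + r)}{c + 1}",
                row=r, col=c,
                condition=condition,
                amplitude=float(amplitudes.get(condition, 0.0)),
                particle_seed=int(children[i].generate_state(1)[0]),
            ))
            i += 1
    return GroundTruth(wells=tuple(wells))


def save_ground_truth(truth: GroundTruth, path: Union[str, os.PathLike]) -> Path:
    p = Path(path)
    p.write_text(json.dumps(
        {"wells": [w.__dict__ for w in truth.wells]}, indent=2) + "\n",
        encoding="utf-8")
    return p


def load_ground_truth(path: Union[str, os.PathLike]) -> GroundTruth:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return GroundTruth(wells=tuple(WellTruth(**w) for w in data["wells"]))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _disk(img: np.ndarray, cx: float, cy: float, radius: float, value: int) -> None:
    h, w = img.shape[:2]
    x0, x1 = max(int(cx - radius) - 1, 0), min(int(cx + radius) + 2, w)
    y0, y1 = max(int(cy - radius) - 1, 0), min(int(cy + radius) + 2, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2
    img[y0:y1, x0:x1][mask] = value


class _Particle:
    """Reflected random walk confined to a well."""

    def __init__(self, well: WellTruth, spec: PlateSpec):
        self.cx, self.cy = spec.well_center(well.row, well.col)
        self.max_r = spec.well_radius - _PARTICLE_RADIUS - 1
        self.rng = np.random.Generator(np.random.PCG64(well.particle_seed))
        self.amplitude = well.amplitude
        r = self.max_r * math.sqrt(self.rng.uniform(0, 1))
        theta = self.rng.uniform(0, 2 * math.pi)
        self.x = self.cx + r * math.cos(theta)
        self.y = self.cy + r * math.sin(theta)

    def step(self) -> None:
        if self.amplitude <= 0:
            return
        dx, dy = self.rng.normal(0.0, self.amplitude, size=2)
        x, y = self.x + dx, self.y + dy
        # reflect at the well wall
        d = math.hypot(x - self.cx, y - self.cy)
        if d > self.max_r and d > 0:
            scale = (2 * self.max_r - d) / d
            if scale < 0:  # wild step: clamp onto the wall
                scale = self.max_r / d
            x = self.cx + (x - self.cx) * scale
            y = self.cy + (y - self.cy) * scale
        self.x, self.y = x, y


def _render_plate(spec: PlateSpec, particles: Sequence[_Particle]) -> np.ndarray:
    img = np.full((spec.height, spec.width), spec.background, dtype=np.uint8)
    for p in particles:
        _disk(img, p.cx, p.cy, float(spec.well_radius), spec.foreground)
    for p in particles:
        _disk(img, p.x, p.y, float(_PARTICLE_RADIUS), _PARTICLE_VALUE)
    return np.repeat(img[:, :, None], 3, axis=2)


def generate_plate_image(
    spec: PlateSpec,
    truth: GroundTruth,
    path: Union[str, os.PathLike],
) -> Path:
    """Render the plate with every particle at its seeded initial position.
    Deterministic: identical spec+truth give a byte-identical PNG."""
    _check_truth(spec, truth)
    particles = [_Particle(w, spec) for w in truth.wells]
    return media_io.write_image(Frame(_render_plate(spec, particles)), path)


def generate_plate_video(
    spec: PlateSpec,
    truth: GroundTruth,
    n_frames: int,
    fps: float,
    path: Union[str, os.PathLike],
    codec: str = media_io.DEFAULT_VIDEO_CODEC,
) -> Path:
    """Render a clip in which each well's particle random-walks with its
    ground-truth amplitude, reflected at the well wall.  Deterministic for
    identical spec+truth."""
    if n_frames < 2:
        raise InvalidInput("a video needs at least 2 frames")
    _check_truth(spec, truth)
    particles = [_Particle(w, spec) for w in truth.wells]

    def frames():
        for t in range(n_frames):
            if t > 0:
                for p in particles:
                    p.step()
            yield Frame(_render_plate(spec, particles), frame_index=t)

    return media_io.write_video(frames(), fps=fps, path=path, codec=codec)


def _check_truth(spec: PlateSpec, truth: GroundTruth) -> None:
    if len(truth.wells) != spec.n_rows * spec.n_cols:
        raise InvalidSpec(
            f"truth has {len(truth.wells)} wells, spec grid has "
            f"{spec.n_rows * spec.n_cols}"
        )


# ---------------------------------------------------------------------------
# measurement oracle + scripted annotator
# ---------------------------------------------------------------------------

def motion_energy(segment_video: Union[str, os.PathLike]) -> float:
    """Mean absolute inter-frame pixel difference per frame transition.

    For each consecutive frame pair the absolute difference is averaged
    over every pixel channel; pair values are averaged over the clip.  A
    static clip scores exactly 0; a single pixel changing by 10 between the
    only two frames of an H x W clip scores 10/(H*W).
    """
    src = media_io.probe_media(segment_video)
    if src.kind != "video" or src.frame_count < 2:
        raise InvalidInput("motion energy needs a video with >= 2 frames")
    total = 0.0
    pairs = 0
    prev: Optional[np.ndarray] = None
    for frame in media_io.iter_frames(src):
        cur = frame.pixels.astype(np.int16)
        if prev is not None:
            total += float(np.abs(cur - prev).mean())
            pairs += 1
        prev = cur
    return total / pairs


def scripted_annotator(
    stages: Sequence[str],
    rule: Callable[[str], Union[str, dict[str, str]]],
) -> Callable[[str, str], dict[str, str]]:
    """Build an annotation function for driving a session without a human.

    ``rule`` receives ONLY the blinded segment file path and returns either
    one note (applied to every stage) or a {stage: note} mapping.  The
    returned function has the (blind_id, segment_path) -> notes shape that
    the session loop expects.  Because the rule sees nothing but file
    content, scripted runs preserve the blinding contract by construction.
    """
    stage_list = list(stages)

    def annotate(blind_id: str, segment_path: str) -> dict[str, str]:
        note = rule(segment_path)
        if isinstance(note, dict):
            return {s: str(note.get(s, "")) for s in stage_list}
        return {s: str(note) for s in stage_list}

    return annotate


def motion_rule(segment_path: str) -> str:
    """Canonical scripted-annotator rule: the segment's motion energy."""
    return f"{motion_energy(segment_path):.6f}"
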