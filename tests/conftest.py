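from __future__ import annotations

from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from blindcut import (
    PlateSpec,
    SegmentManifest,
    add_segment,
    build_ground_truth,
    extract_segments,
    generate_plate_image,
    generate_plate_video,
    grid_segments,
    probe_media,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def build_plate_manifest(
    root: Path,
    n_rows: int = 2,
    n_cols: int = 3,
    stages: tuple[str, ...] = ("score",),
    truth_seed: int = 0,
    kind: str = "image",
    n_frames: int = 6,
    fps: float = 5.0,
    blocks=None,
    amplitudes=None,
    extract: bool = True,
):
    """Generate a synthetic plate, segment it on the well grid, and
    (optionally) extract the segment files.  Returns (manifest, truth, spec).
    """
    spec = PlateSpec(n_rows=n_rows, n_cols=n_cols)
    if blocks is None:
        blocks = (("uniform", (1, n_cols)),)
        amplitudes = amplitudes or {"uniform": 3.0}
    truth = build_ground_truth(spec, seed=truth_seed, column_blocks=blocks,
                               amplitudes=amplitudes)
    root.mkdir(parents=True, exist_ok=True)
    if kind == "image":
        media = generate_plate_image(spec, truth, root / "plate.png")
    else:
        media = generate_plate_video(spec, truth, n_frames=n_frames, fps=fps,
                                     path=root / "plate.avi")
    manifest = SegmentManifest(stages=list(stages),
                               results_folder=str(root / "res"))
    src = probe_media(media, media_id="m0")
    manifest.add_source(src)
    for seg in grid_segments(src, **spec.grid_args()):
        add_segment(manifest, seg.label, seg.rect, seg.media_id)
    if extract:
        extract_segments(manifest)
    return manifest, truth, spec


@pytest.fixture(scope="session")
def small_plate(tmp_path_factory):
    """A 2x3-well extracted image-plate manifest, shared read-only."""
    root = tmp_path_factory.mktemp("small_plate")
    return build_plate_manifest(root)
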