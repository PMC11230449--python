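import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from blindcut import (
    DuplicateLabel,
    EmptyRegion,
    Frame,
    InvalidLabel,
    KindMismatch,
    MediaSource,
    NoSegments,
    ParseError,
    Rect,
    SegmentManifest,
    add_segment,
    crop_frame,
    extract_segments,
    first_frame,
    generate_plate_image,
    grid_segments,
    iter_frames,
    load_segment_file,
    probe_media,
    validate_label,
    write_image,
)
from blindcut.segmentation import load_manifest, save_manifest

from conftest import build_plate_manifest


# --- labels -----------------------------------------------------------------

@pytest.mark.parametrize("raw, expected", [
    ("A1", ("A", 1)),
    ("a36", ("A", 36)),
    ("z9", ("Z", 9)),
    (" e12 ", ("E", 12)),
])
def test_label_parsing_and_canonicalization(raw, expected):
    lab = validate_label(raw)
    assert (lab.row_letter, lab.col_number) == expected
    assert lab.render() == f"{expected[0]}{expected[1]}"


@pytest.mark.parametrize("raw", ["A37", "AA1", "A0", "1A", "", "A", "37", "A1.5"])
def test_malformed_or_out_of_range_labels_rejected(raw):
    with pytest.raises(InvalidLabel):
        validate_label(raw)


# --- rectangles and cropping ------------------------------------------------

def test_empty_rect_cannot_be_constructed():
    with pytest.raises(EmptyRegion):
        Rect(5, 5, 5, 9)


def test_crop_columns_match_coordinate_fill():
    # frame whose pixel value equals its x coordinate
    px = np.tile(np.arange(16, dtype=np.uint8)[None, :, None], (4, 1, 3))
    out = crop_frame(Frame(px), Rect(3, 0, 7, 4))
    assert out.width == 4
    assert sorted(np.unique(out.pixels)) == [3, 4, 5, 6]


def test_crop_full_frame_is_identity_and_1x1_is_single_pixel():
    rng = np.random.default_rng(0)
    px = rng.integers(0, 256, (6, 8, 3), dtype=np.uint8)
    full = crop_frame(Frame(px), Rect(0, 0, 8, 6))
    np.testing.assert_array_equal(full.pixels, px)
    one = crop_frame(Frame(px), Rect(2, 3, 3, 4))
    np.testing.assert_array_equal(one.pixels, px[3:4, 2:3, :])


@given(st.integers(0, 2**32 - 1))
def test_crop_equals_direct_subarray_indexing(seed):
    rng = np.random.default_rng(seed)
    h, w = int(rng.integers(2, 40)), int(rng.integers(2, 40))
    px = rng.integers(0, 256, (h, w, 3), dtype=np.uint8)
    x0 = int(rng.integers(0, w)); x1 = int(rng.integers(x0 + 1, w + 1))
    y0 = int(rng.integers(0, h)); y1 = int(rng.integers(y0 + 1, h + 1))
    out = crop_frame(Frame(px), Rect(x0, y0, x1, y1))
    np.testing.assert_array_equal(out.pixels, px[y0:y1, x0:x1, :])


# --- manifests --------------------------------------------------------------

def _image_manifest(tmp_path, w=40, h=30):
    rng = np.random.default_rng(1)
    write_image(Frame(rng.integers(0, 256, (h, w, 3), dtype=np.uint8)),
                tmp_path / "img.png")
    m = SegmentManifest(stages=["score"], results_folder=str(tmp_path / "res"))
    m.add_source(probe_media(tmp_path / "img.png", media_id="m0"))
    return m


def test_duplicate_labels_always_rejected(tmp_path):
    m = _image_manifest(tmp_path)
    add_segment(m, "A1", Rect(0, 0, 10, 10), "m0")
    with pytest.raises(DuplicateLabel):
        add_segment(m, "a1", Rect(10, 10, 20, 20), "m0")


def test_rect_clamped_to_frame_edge(tmp_path):
    m = _image_manifest(tmp_path, w=40, h=30)
    add_segment(m, "A1", Rect(35, 25, 45, 35), "m0")  # 5 px over both edges
    assert m.segments[0].rect.as_tuple() == (35, 25, 40, 30)


def test_fully_outside_rect_rejected(tmp_path):
    m = _image_manifest(tmp_path, w=40, h=30)
    with pytest.raises(EmptyRegion):
        add_segment(m, "A1", Rect(40, 0, 50, 10), "m0")


def test_mixed_media_kinds_rejected(tmp_path):
    manifest, _, _ = build_plate_manifest(tmp_path / "vid", kind="video",
                                          extract=False)
    rng = np.random.default_rng(2)
    write_image(Frame(rng.integers(0, 256, (8, 8, 3), dtype=np.uint8)),
                tmp_path / "img.png")
    with pytest.raises(KindMismatch):
        manifest.add_source(probe_media(tmp_path / "img.png", media_id="m1"))


# --- grids ------------------------------------------------------------------

def test_grid_labels_a1_through_e12():
    src = MediaSource(path="x.png", kind="image", width=500, height=250,
                      frame_count=1, media_id="m0")
    segs = grid_segments(src, 5, 12, origin=(10, 10), pitch=40, cell_size=40)
    assert len(segs) == 60
    assert segs[0].label.render() == "A1"
    assert segs[-1].label.render() == "E12"
    rects = [s.rect for s in segs]
    assert not any(a.overlaps(b) for i, a in enumerate(rects)
                   for b in rects[i + 1:])


def test_grid_row_letters_exhaust_at_26():
    src = MediaSource(path="x.png", kind="image", width=100, height=1000,
                      frame_count=1, media_id="m0")
    with pytest.raises(InvalidLabel):
        grid_segments(src, 27, 1, origin=(0, 0), pitch=10, cell_size=10)


def test_grid_outside_frame_rejected():
    src = MediaSource(path="x.png", kind="image", width=50, height=50,
                      frame_count=1, media_id="m0")
    with pytest.raises(EmptyRegion):
        grid_segments(src, 2, 2, origin=(30, 30), pitch=20, cell_size=20)


def test_single_cell_grid_is_a1():
    src = MediaSource(path="x.png", kind="image", width=50, height=50,
                      frame_count=1, media_id="m0")
    segs = grid_segments(src, 1, 1, origin=(5, 5), pitch=20, cell_size=20)
    assert len(segs) == 1 and segs[0].label.render() == "A1"
    assert segs[0].rect.as_tuple() == (5, 5, 25, 25)


# --- extraction -------------------------------------------------------------

def test_extract_image_segments_bit_exact_and_deterministic(small_plate):
    manifest, _, _ = small_plate
    base = first_frame(manifest.sources[0])
    first_bytes = {}
    for seg in manifest.segments:
        data = open(seg.segment_path, "rb").read()
        first_bytes[seg.segment_path] = data
        back = first_frame(probe_media(seg.segment_path))
        np.testing.assert_array_equal(
            back.pixels, crop_frame(base, seg.rect).pixels)
    extract_segments(manifest)  # re-run: byte-identical outputs
    for path, data in first_bytes.items():
        assert open(path, "rb").read() == data


def test_extract_video_segments_keep_frame_count_and_fps(tmp_path):
    manifest, _, _ = build_plate_manifest(tmp_path, kind="video", n_frames=6,
                                          fps=5.0)
    for seg in manifest.segments:
        out = probe_media(seg.segment_path)
        assert out.frame_count == 6
        assert out.fps == pytest.approx(5.0)
        assert (out.width, out.height) == (seg.rect.width, seg.rect.height)


def test_extract_empty_manifest_raises(tmp_path):
    m = _image_manifest(tmp_path)
    with pytest.raises(NoSegments):
        extract_segments(m)


def test_segment_filenames_do_not_encode_labels(small_plate):
    manifest, _, _ = small_plate
    for seg in manifest.segments:
        assert seg.label.render() not in seg.segment_path


# --- definition files and manifest persistence ------------------------------

def test_segment_definition_file_round_trip(tmp_path):
    rng = np.random.default_rng(3)
    write_image(Frame(rng.integers(0, 256, (30, 40, 3), dtype=np.uint8)),
                tmp_path / "img.png")
    defs = tmp_path / "segments.txt"
    defs.write_text(
        "# media  label  x  y  w  h\n"
        "img.png  A1     0  0  10 10\n"
        "img.png  b2     10 10 10 10   # comma/space both fine\n"
    )
    m = load_segment_file(defs, stages=["score"],
                          results_folder=str(tmp_path / "res"))
    assert [s.label.render() for s in m.segments] == ["A1", "B2"]
    assert m.segments[1].rect.as_tuple() == (10, 10, 20, 20)


@pytest.mark.parametrize("bad_row, fragment", [
    ("img.png A1 0 0 10", ":2:"),          # wrong field count
    ("img.png A99 0 0 10 10", ":2:"),      # bad label
    ("img.png A1 0 0 ten 10", ":2:"),      # non-integer
])
def test_definition_file_errors_carry_row_number(tmp_path, bad_row, fragment):
    rng = np.random.default_rng(4)
    write_image(Frame(rng.integers(0, 256, (30, 40, 3), dtype=np.uint8)),
                tmp_path / "img.png")
    defs = tmp_path / "segments.txt"
    defs.write_text("# header comment\n" + bad_row + "\n")
    with pytest.raises(ParseError, match=fragment):
        load_segment_file(defs, stages=["score"])


def test_manifest_json_round_trip(small_plate, tmp_path):
    manifest, _, _ = small_plate
    save_manifest(manifest, tmp_path / "m.json")
    back = load_manifest(tmp_path / "m.json")
    assert back.stages == manifest.stages
    assert [s.label for s in back.segments] == [s.label for s in manifest.segments]
    assert [s.rect for s in back.segments] == [s.rect for s in manifest.segments]
    assert back.sources == manifest.sources
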