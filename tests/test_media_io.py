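import struct

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from PIL import Image

from blindcut import (
    CorruptMedia,
    Frame,
    InvalidInput,
    KindMismatch,
    UnsupportedCodec,
    UnsupportedFormat,
    first_frame,
    iter_frames,
    probe_media,
    write_image,
    write_video,
)


def _random_frame(rng, h=24, w=32):
    return Frame(rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8))


def test_probe_image_reads_back_written_dimensions(tmp_path):
    rng = np.random.default_rng(0)
    write_image(_random_frame(rng, 480, 640), tmp_path / "a.png")
    src = probe_media(tmp_path / "a.png")
    assert (src.kind, src.width, src.height, src.frame_count, src.fps) == (
        "image", 640, 480, 1, None)


def test_probe_is_idempotent(tmp_path):
    rng = np.random.default_rng(1)
    write_image(_random_frame(rng), tmp_path / "a.png")
    assert probe_media(tmp_path / "a.png") == probe_media(tmp_path / "a.png")


def test_unsupported_extension_rejected(tmp_path):
    p = tmp_path / "notes.txt"
    p.write_text("not media")
    with pytest.raises(UnsupportedFormat):
        probe_media(p)


def test_lying_extension_is_corrupt_not_reinterpreted(tmp_path):
    rng = np.random.default_rng(2)
    img = Image.fromarray(rng.integers(0, 256, (8, 8, 3), dtype=np.uint8))
    jpeg_as_png = tmp_path / "fake.png"
    img.save(jpeg_as_png, format="JPEG")
    with pytest.raises(CorruptMedia):
        probe_media(jpeg_as_png)
    png_as_avi = tmp_path / "fake.avi"
    img.save(png_as_avi, format="PNG")
    with pytest.raises(CorruptMedia):
        probe_media(png_as_avi)


def test_first_frame_is_image_identity(tmp_path):
    rng = np.random.default_rng(3)
    frame = _random_frame(rng)
    write_image(frame, tmp_path / "a.png")
    back = first_frame(probe_media(tmp_path / "a.png"))
    assert back.frame_index == 0
    np.testing.assert_array_equal(back.pixels, frame.pixels)


def test_alpha_dropped_and_grayscale_promoted(tmp_path):
    rng = np.random.default_rng(4)
    rgba = rng.integers(0, 256, (10, 12, 4), dtype=np.uint8)
    rgba[..., 3] = 255  # opaque, so RGB content survives the convert
    Image.fromarray(rgba, "RGBA").save(tmp_path / "a.png")
    frame = first_frame(probe_media(tmp_path / "a.png"))
    np.testing.assert_array_equal(frame.pixels, rgba[..., :3])

    gray = rng.integers(0, 256, (7, 9), dtype=np.uint8)
    Image.fromarray(gray, "L").save(tmp_path / "g.png")
    gframe = first_frame(probe_media(tmp_path / "g.png"))
    assert gframe.pixels.shape == (7, 9, 3)
    np.testing.assert_array_equal(gframe.pixels[..., 0], gray)


@given(arrays(np.uint8, st.tuples(st.integers(1, 12), st.integers(1, 12),
                                  st.just(3))))
def test_png_round_trip_bit_exact(tmp_path_factory, pixels):
    tmp = tmp_path_factory.mktemp("png_rt")
    write_image(Frame(pixels), tmp / "f.png")
    back = first_frame(probe_media(tmp / "f.png"))
    np.testing.assert_array_equal(back.pixels, pixels)


@pytest.mark.parametrize("codec", ["rawrgb", "mjpeg"])
def test_video_round_trip_metadata(tmp_path, codec):
    rng = np.random.default_rng(5)
    frames = [_random_frame(rng, 17, 23) for _ in range(30)]  # odd width pads rows
    write_video(frames, fps=10, path=tmp_path / "v.avi", codec=codec)
    src = probe_media(tmp_path / "v.avi")
    assert (src.kind, src.width, src.height, src.frame_count) == (
        "video", 23, 17, 30)
    assert src.fps == pytest.approx(10.0)
    out = list(iter_frames(src))
    assert [f.frame_index for f in out] == list(range(30))


def test_rawrgb_video_frames_bit_exact(tmp_path):
    rng = np.random.default_rng(6)
    frames = [_random_frame(rng, 9, 11) for _ in range(5)]
    write_video(frames, fps=4, path=tmp_path / "v.avi", codec="rawrgb")
    for orig, back in zip(frames, iter_frames(probe_media(tmp_path / "v.avi"))):
        np.testing.assert_array_equal(back.pixels, orig.pixels)


def test_mjpeg_video_frames_approximate(tmp_path):
    # smooth gradient content: JPEG is lossy but close
    x = np.linspace(0, 255, 32, dtype=np.uint8)
    frame = np.repeat(np.tile(x, (24, 1))[:, :, None], 3, axis=2)
    write_video([Frame(frame)] * 3, fps=2, path=tmp_path / "v.avi", codec="mjpeg")
    back = next(iter_frames(probe_media(tmp_path / "v.avi")))
    assert np.abs(back.pixels.astype(int) - frame.astype(int)).mean() < 3


def test_black_first_frame_round_trips_as_zeros(tmp_path):
    frames = [Frame(np.zeros((8, 8, 3), np.uint8)),
              Frame(np.full((8, 8, 3), 200, np.uint8))]
    write_video(frames, fps=2, path=tmp_path / "v.avi")
    f0 = first_frame(probe_media(tmp_path / "v.avi"))
    assert f0.frame_index == 0
    assert not f0.pixels.any()


def test_write_video_rejects_degenerate_streams(tmp_path):
    with pytest.raises(InvalidInput):
        write_video([], fps=10, path=tmp_path / "v.avi")
    mixed = [Frame(np.zeros((4, 4, 3), np.uint8)),
             Frame(np.zeros((5, 4, 3), np.uint8))]
    with pytest.raises(InvalidInput):
        write_video(mixed, fps=10, path=tmp_path / "v.avi")


def test_iter_frames_on_image_is_kind_mismatch(tmp_path):
    rng = np.random.default_rng(7)
    write_image(_random_frame(rng), tmp_path / "a.png")
    with pytest.raises(KindMismatch):
        iter_frames(probe_media(tmp_path / "a.png"))


# --- MP4 metadata probe -----------------------------------------------------

def _box(btype: bytes, payload: bytes) -> bytes:
    return struct.pack(">I", 8 + len(payload)) + btype + payload


def _minimal_mp4(width=64, height=48, n_frames=30, timescale=1000,
                 duration=3000) -> bytes:
    """Hand-assembled ISO-BMFF file with one video track (no media data)."""
    tkhd = _box(b"tkhd", bytes(4 + 20 + 8 + 8 + 36)
                + struct.pack(">II", width << 16, height << 16))
    mdhd = _box(b"mdhd", bytes(4) + struct.pack(">IIII", 0, 0, timescale,
                                                duration) + bytes(4))
    hdlr = _box(b"hdlr", bytes(8) + b"vide" + bytes(12))
    stsz = _box(b"stsz", bytes(4) + struct.pack(">II", 0, n_frames))
    stbl = _box(b"stbl", stsz)
    minf = _box(b"minf", stbl)
    mdia = _box(b"mdia", mdhd + hdlr + minf)
    trak = _box(b"trak", tkhd + mdia)
    moov = _box(b"moov", trak)
    ftyp = _box(b"ftyp", b"isom" + struct.pack(">I", 512))
    return ftyp + moov


def test_mp4_probe_reads_container_metadata(tmp_path):
    p = tmp_path / "clip.mp4"
    p.write_bytes(_minimal_mp4(width=64, height=48, n_frames=30))
    src = probe_media(p)
    assert (src.kind, src.width, src.height, src.frame_count) == (
        "video", 64, 48, 30)
    assert src.fps == pytest.approx(10.0)


def test_mp4_frame_access_reports_missing_codec(tmp_path):
    p = tmp_path / "clip.mp4"
    p.write_bytes(_minimal_mp4())
    with pytest.raises(UnsupportedCodec):
        list(iter_frames(probe_media(p)))


def test_mp4_without_moov_is_corrupt(tmp_path):
    p = tmp_path / "clip.mp4"
    p.write_bytes(_box(b"ftyp", b"isom" + struct.pack(">I", 512)))
    with pytest.raises(CorruptMedia):
        probe_media(p)
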