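"""Packed 10-bit codec and channel splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from rawphot import (
    Mosaic,
    PackedRawFrame,
    pack_raw,
    read_raw,
    read_rgb_image,
    split_channels,
    unpack_raw,
    write_raw,
)
from rawphot.bayer_io import packed_row_bytes, write_rgb_image, RgbImage, save_planes
from rawphot.errors import FormatError, GeometryError, MalformedFrameError


def naive_unpack(data, width, height, stride, msb=True):
    """Per-pixel bit-twiddling oracle for the 5-bytes-per-4-pixels layout."""
    out = np.zeros((height, width), dtype=int)
    for r in range(height):
        row = data[r * stride:(r + 1) * stride]
        for g in range(width // 4):
            b = row[5 * g:5 * g + 5]
            for i in range(4):
                shift = (6 - 2 * i) if msb else (2 * i)
                out[r, 4 * g + i] = (b[i] << 2) | ((b[4] >> shift) & 0x3)
    return out


class TestUnpack:
    def test_all_zero_frame(self):
        frame = PackedRawFrame(bytes(10), width=4, height=2)
        assert np.array_equal(unpack_raw(frame).values, np.zeros((2, 4)))

    def test_hand_decoded_group(self):
        # high bytes 1..4 with low-bit pairs 00,01,10,11 packed MSB-first
        data = bytes([0x01, 0x02, 0x03, 0x04, 0b00011011] * 2)
        frame = PackedRawFrame(data, width=4, height=2)
        assert unpack_raw(frame).values.tolist() == [[4, 9, 14, 19]] * 2

    def test_lsb_dialect(self):
        data = bytes([0x01, 0x02, 0x03, 0x04, 0b11100100]) * 2
        frame = PackedRawFrame(data, width=4, height=2)
        assert unpack_raw(frame, low_bit_order="lsb").values.tolist() == [[4, 9, 14, 19]] * 2

    def test_full_scale_frame_decodes_to_1023(self):
        frame = PackedRawFrame(b"\xff" * 20, width=8, height=2)
        assert np.all(unpack_raw(frame).values == 1023)

    def test_stride_padding_ignored(self):
        payload = bytes([0x01, 0x02, 0x03, 0x04, 0b00011011, 0xEE, 0xEE]) * 2
        frame = PackedRawFrame(payload, width=4, height=2, row_stride=7)
        assert unpack_raw(frame).values.tolist() == [[4, 9, 14, 19]] * 2

    def test_short_buffer_rejected(self):
        with pytest.raises(MalformedFrameError):
            PackedRawFrame(bytes(9), width=4, height=2)

    def test_width_not_multiple_of_four_rejected(self):
        with pytest.raises(GeometryError):
            PackedRawFrame(bytes(100), width=6, height=2)

    def test_agrees_with_naive_oracle_on_random_frames(self, rng):
        for _ in range(10):
            h, w = 2 * rng.integers(1, 4), 4 * rng.integers(1, 4)
            stride = packed_row_bytes(w) + int(rng.integers(0, 3))
            data = bytes(rng.integers(0, 256, size=h * stride, dtype=np.uint8))
            frame = PackedRawFrame(data, width=int(w), height=int(h), row_stride=stride)
            expected = naive_unpack(data, int(w), int(h), stride)
            assert np.array_equal(unpack_raw(frame).values, expected)


class TestPack:
    def test_zero_mosaic_packs_to_zero_bytes(self):
        frame = pack_raw(Mosaic(np.zeros((2, 4), dtype=int)))
        assert frame.data == bytes(10)

    def test_known_pixels_pack_to_known_bytes(self):
        frame = pack_raw(Mosaic(np.array([[4, 9, 14, 19]] * 2)))
        assert frame.data[:5] == bytes([0x01, 0x02, 0x03, 0x04, 0b00011011])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            Mosaic(np.full((2, 4), 1024))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        values=hnp.arrays(np.int64, (8, 8), elements=st.integers(0, 1023)),
        order=st.sampled_from(["msb", "lsb"]),
        pad=st.integers(0, 3),
    )
    def test_round_trip_identity(self, values, order, pad):
        mosaic = Mosaic(values)
        stride = packed_row_bytes(8) + pad
        back = unpack_raw(pack_raw(mosaic, row_stride=stride, low_bit_order=order),
                          low_bit_order=order)
        assert np.array_equal(back.values, mosaic.values)


class TestSplitChannels:
    def test_bggr_unit_cell(self):
        planes = split_channels(Mosaic(np.array([[5, 7], [11, 13]])))
        assert planes.blue.tolist() == [[5]]
        assert planes.green1.tolist() == [[7]]
        assert planes.green2.tolist() == [[11]]
        assert planes.red.tolist() == [[13]]

    def test_constant_mosaic_gives_constant_planes(self):
        planes = split_channels(Mosaic(np.full((4, 4), 77)))
        for p in planes:
            assert np.all(p == 77)

    def test_index_mosaic_matches_index_arithmetic(self):
        planes = split_channels(Mosaic(np.arange(16).reshape(4, 4)))
        assert planes.blue.tolist() == [[0, 2], [8, 10]]
        assert planes.green1.tolist() == [[1, 3], [9, 11]]
        assert planes.green2.tolist() == [[4, 6], [12, 14]]
        assert planes.red.tolist() == [[5, 7], [13, 15]]

    def test_conserves_pixel_count_and_values(self, rng):
        values = rng.integers(0, 1024, size=(6, 8))
        planes = split_channels(Mosaic(values))
        combined = np.concatenate([p.ravel() for p in planes])
        assert combined.size == values.size
        assert np.array_equal(np.sort(combined), np.sort(values.ravel()))

    def test_odd_dimensions_rejected(self):
        with pytest.raises(GeometryError):
            split_channels(Mosaic(np.zeros((3, 4), dtype=int)))


class TestImageAndFileIo:
    def test_black_and_white_png_round(self, tmp_path):
        black = RgbImage(np.zeros((2, 2, 3), dtype=np.uint8))
        white = RgbImage(np.full((2, 2, 3), 255, dtype=np.uint8))
        for name, img, value in [("black.png", black, 0), ("white.png", white, 255)]:
            write_rgb_image(tmp_path / name, img)
            loaded = read_rgb_image(tmp_path / name)
            assert np.all(loaded.values == value)

    def test_grayscale_input_rejected(self, tmp_path):
        from PIL import Image

        Image.fromarray(np.zeros((2, 2), dtype=np.uint8), mode="L").save(tmp_path / "g.png")
        with pytest.raises(FormatError):
            read_rgb_image(tmp_path / "g.png")

    def test_raw_file_round_trip_with_sidecar(self, tmp_path, rng):
        mosaic = Mosaic(rng.integers(0, 1024, size=(4, 8)))
        write_raw(tmp_path / "f.raw", pack_raw(mosaic))
        frame = read_raw(tmp_path / "f.raw")
        assert np.array_equal(unpack_raw(frame).values, mosaic.values)

    def test_plane_csv_export(self, tmp_path):
        planes = split_channels(Mosaic(np.arange(16).reshape(4, 4)))
        written = save_planes(planes, tmp_path, prefix="m")
        assert len(written) == 4
        assert np.array_equal(
            np.loadtxt(tmp_path / "m_blue.csv", delimiter=","), [[0, 2], [8, 10]]
        )
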