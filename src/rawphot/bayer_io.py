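"""Packed 10-bit Bayer raw I/O and channel extraction, without demosaicing.

The OmniVision-style raw capture path stores each group of four 10-bit pixel
values as five bytes: the four high-order bytes first, then the four 2-bit
remainders packed into a fifth byte.  Decoding that packing and splitting the
mosaic into its four colour-filter planes (blue, green1, green2, red for a
BGGR array) is all the "image processing" this package ever applies to raw
data — the point of the method is to read sensor counts before any ISP step.

Conventions
-----------
* Coordinates are 0-based, row-major ``(row, col)``; the mosaic origin is the
  top-left sensor pixel.
* For BGGR, mosaic position (0,0) is blue, (0,1) green1, (1,0) green2 and
  (1,1) red; green1 is green on blue rows, green2 green on red rows.
* Within the fifth packed byte the default dialect is MSB-first: pixel 0's
  low bits occupy bits 7-6, pixel 3's bits 1-0.  ``low_bit_order="lsb"``
  selects the opposite dialect; ``pack_raw``/``unpack_raw`` round-trip
  bit-exactly under either.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .errors import FormatError, GeometryError, MalformedFrameError

CFA_BGGR = "BGGR"

#: shifts of each pixel's 2-bit remainder within the fifth byte
_SHIFTS = {"msb": (6, 4, 2, 0), "lsb": (0, 2, 4, 6)}


def packed_row_bytes(width: int) -> int:
    """Minimum bytes per stored row: 5 bytes per 4 pixels."""
    if width % 4:
        raise GeometryError(f"width must be divisible by 4, got {width}")
    return (width // 4) * 5


@dataclass(frozen=True)
class PackedRawFrame:
    """A packed 10-bit Bayer capture: byte buffer plus geometry."""

    data: bytes
    width: int
    height: int
    row_stride: int | None = None
    bit_depth: int = 10
    cfa: str = CFA_BGGR

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0 or self.width % 2 or self.height % 2:
            raise GeometryError(
                f"frame geometry must be even and positive, got {self.width}x{self.height}"
            )
        if self.width % 4:
            raise GeometryError("width must be divisible by 4 (4 pixels per 5 bytes)")
        minimal = packed_row_bytes(self.width)
        if self.row_stride is None:
            object.__setattr__(self, "row_stride", minimal)
        if self.row_stride < minimal:
            raise GeometryError(
                f"row_stride {self.row_stride} < minimal packed row of {minimal} bytes"
            )
        if len(self.data) < self.height * self.row_stride:
            raise MalformedFrameError(
                f"buffer holds {len(self.data)} bytes, need {self.height * self.row_stride}"
            )


@dataclass(frozen=True)
class Mosaic:
    """A decoded Bayer mosaic: height x width counts in [0, 1023]."""

    values: np.ndarray
    cfa: str = CFA_BGGR

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise GeometryError("mosaic must be a 2-D matrix")
        if v.size and (v.min() < 0 or v.max() > 1023):
            raise ValueError("mosaic values must lie in [0, 1023]")
        object.__setattr__(self, "values", v.astype(np.uint16))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class ChannelPlanes:
    """The four colour-filter sub-matrices of a mosaic, half resolution each."""

    red: np.ndarray
    green1: np.ndarray
    green2: np.ndarray
    blue: np.ndarray
    source_shape: tuple[int, int]

    def __iter__(self):
        return iter((self.red, self.green1, self.green2, self.blue))


@dataclass(frozen=True)
class RgbImage:
    """An 8-bit three-channel processed image (the AM/MM capture path)."""

    values: np.ndarray
    mode: str = "AM"

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3 or v.shape[2] != 3:
            raise FormatError("RgbImage requires a height x width x 3 array")
        if v.size and (v.min() < 0 or v.max() > 255):
            raise ValueError("8-bit values must lie in [0, 255]")
        object.__setattr__(self, "values", v.astype(np.uint8))


def unpack_raw(frame: PackedRawFrame, low_bit_order: str = "msb") -> Mosaic:
    """Decode a packed frame into a 10-bit mosaic.

    Each 5-byte group yields pixels ``v_i = (byte_i << 2) | low2_i`` with the
    2-bit remainders read from the fifth byte (MSB-first by default).
    Trailing stride-padding bytes are ignored.
    """
    shifts = _SHIFTS[low_bit_order]
    used = packed_row_bytes(frame.width)
    raw = np.frombuffer(frame.data, dtype=np.uint8, count=frame.height * frame.row_stride)
    rows = raw.reshape(frame.height, frame.row_stride)[:, :used]
    groups = rows.reshape(frame.height, frame.width // 4, 5).astype(np.uint16)
    high = groups[:, :, :4] << 2
    fifth = groups[:, :, 4]
    low = np.stack([(fifth >> s) & 0x3 for s in shifts], axis=-1)
    values = (high | low).reshape(frame.height, frame.width)
    return Mosaic(values, cfa=frame.cfa)


def pack_raw(
    mosaic: Mosaic,
    row_stride: int | None = None,
    low_bit_order: str = "msb",
) -> PackedRawFrame:
    """Encode a mosaic back into the packed 5-bytes-per-4-pixels layout.

    Inverse of :func:`unpack_raw`: the round trip is the identity for every
    valid mosaic.  Stride padding bytes, if requested, are written as zeros.
    """
    v = mosaic.values
    h, w = v.shape
    if w % 4:
        raise GeometryError("width must be divisible by 4 to pack")
    shifts = _SHIFTS[low_bit_order]
    minimal = packed_row_bytes(w)
    stride = minimal if row_stride is None else row_stride
    if stride < minimal:
        raise GeometryError(f"row_stride {stride} < minimal {minimal}")
    quads = v.reshape(h, w // 4, 4)
    high = (quads >> 2).astype(np.uint8)
    low = (quads & 0x3).astype(np.uint8)
    fifth = np.zeros((h, w // 4), dtype=np.uint8)
    for i, s in enumerate(shifts):
        fifth |= low[:, :, i] << s
    packed = np.concatenate([high, fifth[:, :, None]], axis=2).reshape(h, minimal)
    if stride > minimal:
        pad = np.zeros((h, stride - minimal), dtype=np.uint8)
        packed = np.concatenate([packed, pad], axis=1)
    return PackedRawFrame(
        data=packed.tobytes(), width=w, height=h, row_stride=stride, cfa=mosaic.cfa
    )


def split_channels(mosaic: Mosaic) -> ChannelPlanes:
    """Split a BGGR mosaic into its four colour planes.

    Spatial order within each plane is preserved: plane coordinate (i, j)
    corresponds to mosaic coordinate (2i + dr, 2j + dc) for the plane's CFA
    offset (dr, dc).  No interpolation is performed anywhere.
    """
    if mosaic.cfa != CFA_BGGR:
        raise FormatError(f"unsupported CFA layout {mosaic.cfa!r}")
    v = mosaic.values
    h, w = v.shape
    if h % 2 or w % 2:
        raise GeometryError(f"mosaic dimensions must be even, got {h}x{w}")
    return ChannelPlanes(
        blue=v[0::2, 0::2],
        green1=v[0::2, 1::2],
        green2=v[1::2, 0::2],
        red=v[1::2, 1::2],
        source_shape=(h, w),
    )


def read_rgb_image(path: str | Path, mode: str = "AM") -> RgbImage:
    """Load a processed 8-bit capture (PNG/JPEG) for the AM/MM paths."""
    with Image.open(path) as im:
        if im.mode != "RGB":
            raise FormatError(
                f"{path}: expected a 3-channel RGB image, got mode {im.mode!r}"
            )
        values = np.asarray(im, dtype=np.uint8)
    return RgbImage(values, mode=mode)


def write_rgb_image(path: str | Path, image: RgbImage) -> None:
    Image.fromarray(image.values, mode="RGB").save(path)


# -- flat raw file with YAML sidecar ----------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_raw(path: str | Path, frame: PackedRawFrame) -> None:
    """Write the packed buffer plus a YAML sidecar describing its geometry."""
    path = Path(path)
    path.write_bytes(frame.data)
    meta = {
        "width": frame.width,
        "height": frame.height,
        "row_stride": frame.row_stride,
        "bit_depth": frame.bit_depth,
        "cfa": frame.cfa,
    }
    _sidecar_path(path).write_text(yaml.safe_dump(meta))


def read_raw(path: str | Path) -> PackedRawFrame:
    """Read a flat packed-raw file using its YAML sidecar for geometry."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing geometry sidecar {sidecar}")
    meta = yaml.safe_load(sidecar.read_text())
    return PackedRawFrame(
        data=path.read_bytes(),
        width=int(meta["width"]),
        height=int(meta["height"]),
        row_stride=int(meta["row_stride"]),
        bit_depth=int(meta.get("bit_depth", 10)),
        cfa=str(meta.get("cfa", CFA_BGGR)),
    )


def save_planes(planes: ChannelPlanes, directory: str | Path, prefix: str = "plane") -> list[Path]:
    """Export the four channel planes as plain-text CSV matrices."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name in ("red", "green1", "green2", "blue"):
        out = directory / f"{prefix}_{name}.csv"
        np.savetxt(out, getattr(planes, name), fmt="%d", delimiter=",")
        written.append(out)
    return written
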