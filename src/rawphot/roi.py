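"""LED-spot localisation and region-of-interest definition.

The measurement geometry is fixed: an LED behind a diffuser projects a bright
spot onto the sensor, and all photometry averages pixel counts over a small
rectangle inside that spot.  The ROI is defined once after device assembly —
find the brightest 20x20 window, then optionally grow a rectangle around it
while newly included strips stay above a fraction (default 95%) of the
central window's mean — and the coordinates are then reused for every
subsequent measurement of the session.

Even-sized windows have no integer centre pixel; the convention here is that
the centre is the top-left pixel of the central 2x2 block.  A box of height
``2*half_height`` centred at row r spans rows ``r-half_height+1`` through
``r+half_height`` inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .errors import GeometryError


@dataclass(frozen=True)
class RoiSpec:
    """A rectangular region of interest defined by centre and half extents."""

    center: tuple[int, int]
    half_height: int
    half_width: int
    mode: str | None = None

    def __post_init__(self) -> None:
        if self.half_height < 1 or self.half_width < 1:
            raise GeometryError("half extents must be >= 1")

    @property
    def height(self) -> int:
        return 2 * self.half_height

    @property
    def width(self) -> int:
        return 2 * self.half_width

    @property
    def row_slice(self) -> slice:
        r = self.center[0]
        return slice(r - self.half_height + 1, r + self.half_height + 1)

    @property
    def col_slice(self) -> slice:
        c = self.center[1]
        return slice(c - self.half_width + 1, c + self.half_width + 1)

    def halved(self) -> "RoiSpec":
        """The same ROI re-centred in half-resolution plane coordinates.

        Channel planes are half the mosaic resolution, so a centre stored in
        mosaic coordinates maps to ``(row // 2, col // 2)`` on each plane.
        The pixel extent of the box is kept unchanged.
        """
        r, c = self.center
        return RoiSpec((r // 2, c // 2), self.half_height, self.half_width, self.mode)

    def to_dict(self) -> dict:
        return {
            "center_row": int(self.center[0]),
            "center_col": int(self.center[1]),
            "half_height": int(self.half_height),
            "half_width": int(self.half_width),
            "mode": self.mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RoiSpec":
        return cls(
            (int(d["center_row"]), int(d["center_col"])),
            int(d["half_height"]),
            int(d["half_width"]),
            d.get("mode"),
        )


def _window_sums(matrix: np.ndarray, window: int) -> np.ndarray:
    """Sums of every window x window sub-matrix via a summed-area table."""
    acc = np.int64 if np.issubdtype(matrix.dtype, np.integer) else np.float64
    ii = np.zeros((matrix.shape[0] + 1, matrix.shape[1] + 1), dtype=acc)
    ii[1:, 1:] = matrix.astype(acc).cumsum(axis=0).cumsum(axis=1)
    w = window
    return ii[w:, w:] - ii[:-w, w:] - ii[w:, :-w] + ii[:-w, :-w]


def locate_led_center(intensity: np.ndarray, window: int = 20) -> tuple[int, int]:
    """Centre of the window x window sub-region with the highest mean intensity.

    Exhaustive scan over all window positions (computed with a summed-area
    table); ties are broken by the first occurrence in row-major order.
    """
    m = np.asarray(intensity)
    if m.ndim != 2 or m.shape[0] < window or m.shape[1] < window:
        raise GeometryError(
            f"matrix of shape {m.shape} is smaller than the {window}x{window} scan window"
        )
    sums = _window_sums(m, window)
    r0, c0 = divmod(int(np.argmax(sums)), sums.shape[1])
    off = (window - 1) // 2
    return (r0 + off, c0 + off)


def _strips_ok(
    m: np.ndarray,
    roi: RoiSpec,
    floor: float,
    criterion: str,
) -> bool:
    """Every row and column strip of the rectangle meets the intensity floor."""
    box = m[roi.row_slice, roi.col_slice]
    if criterion == "strip_mean":
        return bool(box.mean(axis=1).min() >= floor and box.mean(axis=0).min() >= floor)
    if criterion == "pixel_min":
        return bool(box.min() >= floor)
    raise ValueError(f"unknown criterion {criterion!r}")


def expand_roi(
    intensity: np.ndarray,
    center: tuple[int, int],
    threshold_fraction: float = 0.95,
    window: int = 20,
    criterion: str = "strip_mean",
) -> RoiSpec:
    """Grow a rectangle around the spot centre under an intensity criterion.

    Starting from the central window x window box, the half extents grow
    symmetrically one pixel at a time as long as every row/column strip of
    the candidate rectangle keeps a mean intensity (or, with
    ``criterion="pixel_min"``, a minimum) of at least ``threshold_fraction``
    times the central window's mean.  Growth in each dimension stops at the
    image border or when the criterion first fails; the result is the largest
    rectangle reachable this way.
    """
    m = np.asarray(intensity, dtype=float)
    H, W = m.shape
    r, c = center
    if not (0 <= r < H and 0 <= c < W):
        raise GeometryError(f"center {center} outside matrix of shape {m.shape}")
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must lie in (0, 1]")
    half = window // 2
    base = RoiSpec(center, half, half)
    if (
        base.row_slice.start < 0
        or base.col_slice.start < 0
        or base.row_slice.stop > H
        or base.col_slice.stop > W
    ):
        raise GeometryError("central window does not fit inside the matrix")
    floor = threshold_fraction * m[base.row_slice, base.col_slice].mean()

    hh = hw = half
    grew = True
    while grew:
        grew = False
        cand = RoiSpec(center, hh + 1, hw)
        if cand.row_slice.start >= 0 and cand.row_slice.stop <= H:
            if _strips_ok(m, cand, floor, criterion):
                hh += 1
                grew = True
        cand = RoiSpec(center, hh, hw + 1)
        if cand.col_slice.start >= 0 and cand.col_slice.stop <= W:
            if _strips_ok(m, cand, floor, criterion):
                hw += 1
                grew = True
    return RoiSpec(center, hh, hw)


def crop(matrix: np.ndarray, roi: RoiSpec) -> np.ndarray:
    """Extract the ROI sub-matrix (a copy; pure indexing, no interpolation)."""
    m = np.asarray(matrix)
    rs, cs = roi.row_slice, roi.col_slice
    if rs.start < 0 or cs.start < 0 or rs.stop > m.shape[0] or cs.stop > m.shape[1]:
        raise GeometryError(
            f"ROI rows {rs.start}:{rs.stop}, cols {cs.start}:{cs.stop} "
            f"out of bounds for shape {m.shape[:2]}"
        )
    return m[rs, cs].copy()


def save_roi(path: str | Path, roi: RoiSpec) -> None:
    Path(path).write_text(yaml.safe_dump(roi.to_dict()))


def load_roi(path: str | Path) -> RoiSpec:
    return RoiSpec.from_dict(yaml.safe_load(Path(path).read_text()))
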