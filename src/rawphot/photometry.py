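"""Dark-corrected absorbance from cropped pixel intensities.

The photometric model is Beer-Lambert with an explicit dark (residual) term:

    A = log10( (I0 - Id) / (Is - Id) )

where I0 is the mean green intensity of the reference (blank/source) frame,
Id the residual signal with the source off, and Is the mean green intensity
after sample introduction.  Because the dark-corrected ratio is taken, the
result is independent of any common linear gain — the property that makes
raw 10-bit sensor counts usable as photometric intensities.

Green is the working channel throughout: the LED emission sits in the green
band and a Bayer sensor has twice as many green sites as red or blue.  In raw
mode the two green planes are averaged with equal weight by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ContractError, InvalidReferenceError, OpaqueSampleError


@dataclass(frozen=True)
class IntensityReading:
    """Per-channel mean/sd of a cropped region, in ADU of the native scale."""

    mean_red: float
    mean_green: float
    mean_blue: float
    sd_red: float
    sd_green: float
    sd_blue: float
    n_pixels: int
    mode: str
    timestamp: float | None = None
    mean_green1: float | None = None
    mean_green2: float | None = None

    def channel(self, name: str) -> float:
        return {
            "red": self.mean_red,
            "green": self.mean_green,
            "blue": self.mean_blue,
            "green1": self.mean_green1,
            "green2": self.mean_green2,
        }[name]


@dataclass(frozen=True)
class AbsorbanceResult:
    """One absorbance value with its intensity provenance."""

    A: float
    I0: float
    Id: float
    Is: float
    channel: str = "green"
    mode: str | None = None


@dataclass(frozen=True)
class ReplicateStats:
    mean: float
    sd: float
    cv_percent: float


def intensity_from_rgb(
    cropped: np.ndarray, mode: str = "AM", timestamp: float | None = None
) -> IntensityReading:
    """Mean/sd per channel of a cropped 8-bit RGB region (AM/MM paths)."""
    c = np.asarray(cropped, dtype=float)
    if c.size == 0:
        raise ContractError("empty crop")
    if c.ndim != 3 or c.shape[2] != 3:
        raise ContractError("expected a height x width x 3 crop")
    means = c.mean(axis=(0, 1))
    sds = c.std(axis=(0, 1))
    return IntensityReading(
        mean_red=float(means[0]),
        mean_green=float(means[1]),
        mean_blue=float(means[2]),
        sd_red=float(sds[0]),
        sd_green=float(sds[1]),
        sd_blue=float(sds[2]),
        n_pixels=int(c.shape[0] * c.shape[1]),
        mode=mode,
        timestamp=timestamp,
    )


def intensity_from_planes(
    red: np.ndarray,
    green1: np.ndarray,
    green2: np.ndarray,
    blue: np.ndarray,
    timestamp: float | None = None,
    green_plane: str = "both",
) -> IntensityReading:
    """Mean/sd per channel from cropped raw channel planes (RM path).

    ``mean_green`` is by default the equal-weight average of the two green
    plane means; ``green_plane`` may select ``"green1"`` or ``"green2"``
    alone instead.
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in
              (("red", red), ("green1", green1), ("green2", green2), ("blue", blue))}
    if any(a.size == 0 for a in arrays.values()):
        raise ContractError("empty crop")
    g1m, g2m = arrays["green1"].mean(), arrays["green2"].mean()
    if green_plane == "both":
        mean_green = 0.5 * (g1m + g2m)
    elif green_plane == "green1":
        mean_green = g1m
    elif green_plane == "green2":
        mean_green = g2m
    else:
        raise ContractError(f"unknown green_plane {green_plane!r}")
    pooled_green = np.concatenate([arrays["green1"].ravel(), arrays["green2"].ravel()])
    return IntensityReading(
        mean_red=float(arrays["red"].mean()),
        mean_green=float(mean_green),
        mean_blue=float(arrays["blue"].mean()),
        sd_red=float(arrays["red"].std()),
        sd_green=float(pooled_green.std()),
        sd_blue=float(arrays["blue"].std()),
        n_pixels=int(sum(a.size for a in arrays.values())),
        mode="RM",
        timestamp=timestamp,
        mean_green1=float(g1m),
        mean_green2=float(g2m),
    )


def absorbance(
    I0: float, Id: float, Is: float, channel: str = "green", mode: str | None = None
) -> AbsorbanceResult:
    """A = log10((I0 - Id)/(Is - Id)), erroring on unusable intensities.

    A sample at or below the dark level is opaque (or the source failed);
    both conditions raise rather than returning NaN/inf.
    """
    if I0 <= Id:
        raise InvalidReferenceError(
            f"reference intensity I0={I0} does not exceed dark signal Id={Id}"
        )
    if Is <= Id:
        raise OpaqueSampleError(
            f"sample intensity Is={Is} does not exceed dark signal Id={Id}"
        )
    A = math.log10((I0 - Id) / (Is - Id))
    return AbsorbanceResult(A=A, I0=float(I0), Id=float(Id), Is=float(Is),
                            channel=channel, mode=mode)


def replicate_stats(values) -> ReplicateStats:
    """Mean, sample sd (n-1 denominator) and CV% of replicate absorbances."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ContractError("replicate statistics require at least 2 values")
    mean = float(v.mean())
    if mean == 0:
        raise ContractError("CV% undefined for zero mean")
    sd = float(v.std(ddof=1))
    return ReplicateStats(mean=mean, sd=sd, cv_percent=100.0 * sd / mean)
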