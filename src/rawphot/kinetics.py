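"""Time-resolved absorbance analysis.

Assay readouts used here are deliberately simple, matching how two-point
photometric kits are actually read: an absorbance difference between two
scheduled instants (e.g. A2 - A1 between 1 and 1.5 min, or a shifted 5/10 min
window for slower optics), an ordinary least-squares slope over the early
linear region, and a single end-point value near the reaction plateau.

Times are minutes throughout.  Readings are looked up at the sampled time
nearest to the requested one — the instruments read at scheduled instants,
they do not interpolate — with ties going to the earlier sample; linear
interpolation is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, CoverageError


@dataclass(frozen=True)
class KineticSeries:
    """Timestamped absorbance sequence for one cuvette."""

    times: np.ndarray
    absorbances: np.ndarray
    sample_id: str = ""
    mode: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.absorbances, dtype=float)
        if t.size != a.size or t.size == 0:
            raise ContractError("times and absorbances must be equal-length and non-empty")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ContractError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "absorbances", a)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])


@dataclass(frozen=True)
class LinearFit:
    slope: float        # absorbance per minute
    intercept: float
    r_squared: float


def _check_coverage(series: KineticSeries, t: float) -> None:
    lo, hi = series.span
    if not lo <= t <= hi:
        raise CoverageError(f"t={t} min outside series span [{lo}, {hi}]")


def _nearest_index(times: np.ndarray, t: float) -> int:
    """Index of the sample nearest to t; equidistant ties pick the earlier."""
    i = int(np.searchsorted(times, t))
    if i == 0:
        return 0
    if i == len(times):
        return len(times) - 1
    # strict '<' keeps the earlier sample on an exact tie
    return i if (times[i] - t) < (t - times[i - 1]) else i - 1


def value_at(series: KineticSeries, t: float, method: str = "nearest") -> float:
    """Absorbance at time t by nearest-sample lookup or linear interpolation."""
    _check_coverage(series, t)
    if method == "nearest":
        return float(series.absorbances[_nearest_index(series.times, t)])
    if method == "linear":
        return float(np.interp(t, series.times, series.absorbances))
    raise ValueError(f"unknown lookup method {method!r}")


def end_point(series: KineticSeries, t: float, method: str = "nearest") -> float:
    """Single-time reading, e.g. at 40 min near the reaction plateau."""
    return value_at(series, t, method)


def two_point_delta(
    series: KineticSeries,
    t1: float = 1.0,
    t2: float = 1.5,
    method: str = "nearest",
) -> float:
    """A(t2) - A(t1), the two-point kinetic readout."""
    if t2 <= t1:
        raise ContractError(f"t2={t2} must exceed t1={t1}")
    return value_at(series, t2, method) - value_at(series, t1, method)


def linear_region_slope(series: KineticSeries, t_start: float, t_end: float) -> LinearFit:
    """OLS fit of A on t restricted to [t_start, t_end] (needs >= 3 points)."""
    mask = (series.times >= t_start) & (series.times <= t_end)
    if mask.sum() < 3:
        raise ContractError(
            f"need >= 3 samples in [{t_start}, {t_end}] min, found {int(mask.sum())}"
        )
    fit = stats.linregress(series.times[mask], series.absorbances[mask])
    return LinearFit(slope=float(fit.slope), intercept=float(fit.intercept),
                     r_squared=float(fit.rvalue) ** 2)


def write_kinetic_csv(path: str | Path, series: KineticSeries) -> None:
    pd.DataFrame(
        {"time_min": series.times, "A": series.absorbances, "sample_id": series.sample_id}
    ).to_csv(path, index=False)


def read_kinetic_csv(path: str | Path) -> KineticSeries:
    df = pd.read_csv(path)
    sample_id = str(df["sample_id"].iloc[0]) if "sample_id" in df and len(df) else ""
    return KineticSeries(df["time_min"].to_numpy(), df["A"].to_numpy(), sample_id=sample_id)
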