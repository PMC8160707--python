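"""Measurement-session orchestration over stored frames.

A session fixes the acquisition mode — AM (camera-automatic 8-bit), MM
(manual-exposure 8-bit) or RM (10-bit raw Bayer) — takes one dark frame and
one reference frame, defines or reuses an ROI, then converts every sample
frame into a dark-corrected absorbance and, when a calibration curve is
supplied, a concentration.  Samples carrying timestamps are additionally
grouped into per-cuvette kinetic series.

Mode isolation is strict: the AM/MM paths only ever see 8-bit RGB images and
the RM path only raw mosaics; gamma or gain emulation never touches raw
data.  Live capture is out of scope — the session consumes stored frames —
but the capture parameters a camera front-end would need (framerate,
exposure mode, white-balance gains, shutter speed, warm-up) are carried as
documented metadata in :class:`SessionConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bayer_io, photometry, roi as roi_mod
from .bayer_io import Mosaic, PackedRawFrame, RgbImage, split_channels, unpack_raw
from .calibration import (
    CalibrationCurve,
    WavelengthCorrection,
    apply_wavelength_correction,
    predict_concentration,
)
from .errors import ConfigurationError, ContractError, FormatError, OpaqueSampleError
from .kinetics import KineticSeries
from .photometry import absorbance, intensity_from_planes, intensity_from_rgb
from .roi import RoiSpec, crop, locate_led_center

MODES = ("AM", "MM", "RM")

#: capture parameters preserved as metadata for future live front-ends
DEFAULT_CAMERA_METADATA = {
    "framerate": 30,
    "exposure_mode": "off",
    "awb_mode": "off",
    "awb_gains": (1.0, 1.0),
    "shutter_speed_us": 0,
    "warmup_s": 5,
}


@dataclass
class SessionConfig:
    mode: str
    roi: RoiSpec | None = None
    roi_window: int = 20          # spot-search window, pixels
    roi_half_size: int = 15       # fixed measurement ROI: 30x30 pixels
    wavelength_factor: float = 1.0
    calibration: CalibrationCurve | None = None
    green_plane: str = "both"     # RM green handling: both | green1 | green2
    camera: dict = field(default_factory=lambda: dict(DEFAULT_CAMERA_METADATA))

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"mode must be one of {MODES}, got {self.mode!r}")


@dataclass(frozen=True)
class FrameRecord:
    """One manifest entry: a dark, reference or sample frame."""

    kind: str                     # dark | reference | sample
    frame: object                 # Mosaic | PackedRawFrame | RgbImage
    sample_id: str = ""
    time_min: float | None = None


@dataclass(frozen=True)
class SessionResult:
    table: pd.DataFrame
    series: dict
    roi: RoiSpec
    mode: str


_COLUMNS = [
    "sample_id", "mode", "time_min", "I0", "Id", "Is", "A", "A_corrected",
    "channel", "concentration", "extrapolated", "flag",
]


def _coerce_frame(config: SessionConfig, frame: object):
    """Enforce mode isolation: RM sees raw data only, AM/MM images only."""
    if config.mode == "RM":
        if isinstance(frame, PackedRawFrame):
            return unpack_raw(frame)
        if isinstance(frame, Mosaic):
            return frame
        raise FormatError(f"RM session cannot read a {type(frame).__name__}")
    if isinstance(frame, RgbImage):
        return frame
    raise FormatError(
        f"{config.mode} session requires 8-bit RGB images, got {type(frame).__name__}"
    )


def _green_map(config: SessionConfig, frame) -> np.ndarray:
    if config.mode == "RM":
        p = split_channels(frame)
        return 0.5 * (p.green1.astype(float) + p.green2.astype(float))
    return frame.values[:, :, 1].astype(float)


def _auto_roi(config: SessionConfig, reference) -> RoiSpec:
    """Locate the LED spot on the reference frame and fix a 30x30 ROI.

    For RM the spot is found on the mean of the two green planes (half
    resolution) and the centre is stored in mosaic coordinates.
    """
    gmap = _green_map(config, reference)
    center = locate_led_center(gmap, window=config.roi_window)
    if config.mode == "RM":
        center = (2 * center[0], 2 * center[1])
    return RoiSpec(center, config.roi_half_size, config.roi_half_size, mode=config.mode)


def _read_intensity(config: SessionConfig, frame, spec: RoiSpec, time_min=None):
    if config.mode == "RM":
        p = split_channels(frame)
        pr = spec.halved()
        return intensity_from_planes(
            crop(p.red, pr), crop(p.green1, pr), crop(p.green2, pr), crop(p.blue, pr),
            timestamp=time_min, green_plane=config.green_plane,
        )
    return intensity_from_rgb(crop(frame.values, spec), mode=config.mode, timestamp=time_min)


def run_session(
    config: SessionConfig,
    frames: list[FrameRecord],
    output_csv: str | Path | None = None,
) -> SessionResult:
    """Process a manifest of stored frames into an absorbance results table.

    The manifest must contain one dark and one reference frame; sample
    frames may be empty (the result is then an empty table).  Opaque samples
    (intensity at or below dark) are flagged in the table rather than
    aborting the whole session.
    """
    darks = [f for f in frames if f.kind == "dark"]
    refs = [f for f in frames if f.kind == "reference"]
    if not darks or not refs:
        raise ConfigurationError("session manifest needs a dark and a reference frame")
    dark = _coerce_frame(config, darks[0].frame)
    reference = _coerce_frame(config, refs[0].frame)

    spec = config.roi if config.roi is not None else _auto_roi(config, reference)

    Id = _read_intensity(config, dark, spec).mean_green
    I0 = _read_intensity(config, reference, spec).mean_green

    rows = []
    for rec in (f for f in frames if f.kind == "sample"):
        frame = _coerce_frame(config, rec.frame)
        reading = _read_intensity(config, frame, spec, rec.time_min)
        row = {
            "sample_id": rec.sample_id, "mode": config.mode, "time_min": rec.time_min,
            "I0": I0, "Id": Id, "Is": reading.mean_green, "A": np.nan,
            "A_corrected": np.nan, "channel": "green", "concentration": np.nan,
            "extrapolated": False, "flag": "",
        }
        try:
            result = absorbance(I0, Id, reading.mean_green, mode=config.mode)
        except OpaqueSampleError:
            row["flag"] = "opaque"
        else:
            row["A"] = result.A
            row["A_corrected"] = config.wavelength_factor * result.A
            if config.calibration is not None:
                est = predict_concentration(config.calibration, row["A_corrected"])
                row["concentration"] = est.value
                row["extrapolated"] = est.extrapolated
        rows.append(row)

    table = pd.DataFrame(rows, columns=_COLUMNS)

    series: dict[str, KineticSeries] = {}
    timed = table.dropna(subset=["time_min", "A"])
    for sid, grp in timed.groupby("sample_id"):
        grp = grp.sort_values("time_min")
        series[str(sid)] = KineticSeries(
            grp["time_min"].to_numpy(), grp["A"].to_numpy(),
            sample_id=str(sid), mode=config.mode,
        )

    if output_csv is not None:
        table.to_csv(output_csv, index=False)
    return SessionResult(table=table, series=series, roi=spec, mode=config.mode)


def load_manifest(path: str | Path, config: SessionConfig) -> list[FrameRecord]:
    """Read a manifest CSV (columns kind, path, sample_id, time_min) and load
    each referenced frame with the mode-appropriate reader."""
    base = Path(path).parent
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        fpath = base / str(row.path)
        if config.mode == "RM":
            frame: object = bayer_io.read_raw(fpath)
        else:
            frame = bayer_io.read_rgb_image(fpath, mode=config.mode)
        t = getattr(row, "time_min", None)
        records.append(
            FrameRecord(
                kind=str(row.kind),
                frame=frame,
                sample_id="" if pd.isna(getattr(row, "sample_id", "")) else str(row.sample_id),
                time_min=None if t is None or pd.isna(t) else float(t),
            )
        )
    return records


# -- simulation-backed pipeline characterization -----------------------------

def measure_dilution_series(
    spot,
    true_A_list=None,
    replicates: int = 3,
    seed: int | None = None,
    mode: str = "RM",
    isp=None,
    use_packing: bool = False,
) -> pd.DataFrame:
    """Render a dilution series and measure it end to end in one mode.

    Returns one row per absorbance level with the replicate mean, sd, CV%
    and relative error of the recovered absorbance.  For RM,
    ``use_packing=True`` routes every frame through the packed-raw encode /
    decode step so the full byte-level pipeline is exercised.  For AM/MM an
    :class:`~rawphot.simulate.IspModel` must be given; the identical raw
    scenes are developed through it, which is how the raw and processed
    paths are compared like for like.
    """
    from . import simulate as sim

    if true_A_list is None:
        true_A_list = sim.DILUTION_LEVELS
    series = sim.dilution_series(spot, true_A_list, replicates=replicates, seed=seed)

    def prep(mosaic):
        if mode == "RM":
            if use_packing:
                return unpack_raw(bayer_io.pack_raw(mosaic))
            return mosaic
        if isp is None:
            raise ContractError("AM/MM measurement requires an IspModel")
        return sim.develop_rgb(mosaic, isp, mode=mode)

    records = [
        FrameRecord("dark", prep(series.dark)),
        FrameRecord("reference", prep(series.reference)),
    ]
    for a, frames in series.samples:
        for i, f in enumerate(frames):
            records.append(FrameRecord("sample", prep(f), sample_id=f"A{a:g}_r{i}"))

    config = SessionConfig(mode=mode)
    result = run_session(config, records)
    table = result.table.copy()
    table["true_A"] = [float(s.split("_")[0][1:]) for s in table["sample_id"]]

    rows = []
    for a, grp in table.groupby("true_A"):
        vals = grp["A"].to_numpy()
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        rows.append(
            {
                "true_A": float(a),
                "mean_A": mean,
                "sd_A": sd,
                "cv_percent": 100.0 * sd / mean if mean != 0 else np.nan,
                "rel_err": abs(mean - a) / a if a != 0 else np.nan,
                "n_replicates": int(len(vals)),
            }
        )
    return pd.DataFrame(rows).sort_values("true_A", ignore_index=True)


def max_recoverable_absorbance(
    spot,
    seed: int | None = None,
    replicates: int = 3,
    rel_tol: float = 0.05,
    start: float = 0.1,
    step: float = 0.1,
    stop: float = 3.0,
    use_packing: bool = True,
) -> float:
    """Largest absorbance the raw pipeline recovers to within ``rel_tol``.

    Sweeps true absorbance upward from ``start`` in ``step`` increments and
    returns the highest level of the unbroken run (from the bottom) whose
    replicate-mean recovery stays within the relative tolerance.
    """
    n_levels = int(round((stop - start) / step)) + 1
    levels = [round(start + i * step, 10) for i in range(n_levels)]
    df = measure_dilution_series(
        spot, levels, replicates=replicates, seed=seed, mode="RM", use_packing=use_packing
    )
    best = 0.0
    for row in df.itertuples(index=False):
        if row.rel_err <= rel_tol:
            best = row.true_A
        else:
            break
    return best
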