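"""Synthetic sensor-frame generator: the offline stand-in for the camera.

The optical scene is an LED spot behind a diffuser imaged onto a BGGR CMOS
sensor.  The expected count at a pixel of colour c is

    E(p) = dark_level + w_c * peak * 10^(-A_true) * G(p)

with G a unit-peak isotropic Gaussian around the spot centre, w_c the
relative spectral response of the colour filter to the (green) LED, and
Beer-Lambert attenuation 10^(-A_true) applied to the light term only — dark
current is not light.  Optional Poisson shot noise acts on the light term
(unit-gain assumption: one ADU per detected event), additive Gaussian read
noise on everything; values are then rounded, clipped to [0, 1023] and laid
out on the BGGR grid.

Rendering with ``true_A = 0`` produces the reference (I0) frame; with
``peak = 0`` the dark (Id) frame.  A second rendering path emulates the
camera's processed 8-bit output (2x2-binned demosaic, per-channel gains,
gamma) so the raw and processed analysis modes can be contrasted on
identical scenes.

All randomness flows from a single seed; identical seeds give bit-identical
frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .bayer_io import CFA_BGGR, Mosaic, RgbImage, split_channels
from .errors import ContractError
from .kinetics import KineticSeries

#: sensor active-array geometry of the 5-megapixel module being emulated
SENSOR_WIDTH = 2592
SENSOR_HEIGHT = 1944


@dataclass(frozen=True)
class SpotModel:
    """Gaussian LED spot on a dark background, plus sensor noise terms.

    Defaults emulate the measurement conditions of the characterization
    experiments: near-full-scale green illumination (peak 950 ADU on the
    10-bit scale), a small residual dark level (4 ADU), read noise of
    2 ADU rms and Poisson shot noise, on the full 2592x1944 active array
    with the spot centred on the optical axis.
    """

    peak: float = 950.0
    center: tuple[float, float] = (SENSOR_HEIGHT / 2, SENSOR_WIDTH / 2)
    sigma: float = 200.0
    dark_level: float = 4.0
    channel_weights: tuple[float, float, float] = (0.25, 1.0, 0.35)  # (R, G, B)
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    seed: int = 0
    width: int = SENSOR_WIDTH
    height: int = SENSOR_HEIGHT

    def __post_init__(self) -> None:
        if not 0 <= self.peak <= 1023:
            raise ContractError("peak must lie in [0, 1023]")
        if not 0 <= self.dark_level <= 1023:
            raise ContractError("dark_level must lie in [0, 1023]")
        if self.peak > 0 and self.dark_level >= self.peak:
            raise ContractError("dark_level must be below peak")
        if self.sigma <= 0:
            raise ContractError("sigma must be > 0")
        if any(not 0 <= w <= 1 for w in self.channel_weights):
            raise ContractError("channel weights must lie in [0, 1]")
        if self.read_noise_sd < 0:
            raise ContractError("read_noise_sd must be >= 0")
        if self.width % 4 or self.height % 2 or self.width <= 0 or self.height <= 0:
            raise ContractError("sensor geometry must be even (width divisible by 4)")


@dataclass(frozen=True)
class IspModel:
    """Minimal processed-pipeline emulation: gains then gamma to 8 bits."""

    gamma: float = 2.2
    gains: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.gamma <= 0 or any(g <= 0 for g in self.gains):
            raise ContractError("gamma and gains must be > 0")


@lru_cache(maxsize=8)
def _weight_map_cached(height, width, weights) -> np.ndarray:
    wr, wg, wb = weights
    w = np.empty((height, width))
    w[0::2, 0::2] = wb   # BGGR: blue at the origin
    w[0::2, 1::2] = wg   # green1 on blue rows
    w[1::2, 0::2] = wg   # green2 on red rows
    w[1::2, 1::2] = wr
    return w


@lru_cache(maxsize=8)
def _gaussian_cached(height, width, center, sigma) -> np.ndarray:
    r = np.arange(height)[:, None] - center[0]
    c = np.arange(width)[None, :] - center[1]
    return np.exp(-(r * r + c * c) / (2.0 * sigma**2))


def _weight_map(spot: SpotModel) -> np.ndarray:
    return _weight_map_cached(spot.height, spot.width, spot.channel_weights)


def _gaussian(spot: SpotModel) -> np.ndarray:
    return _gaussian_cached(spot.height, spot.width, spot.center, spot.sigma)


def render_mosaic(
    spot: SpotModel,
    true_A: float,
    rng: np.random.Generator | None = None,
) -> Mosaic:
    """Render one raw BGGR frame of the spot attenuated by ``true_A``."""
    if true_A < 0:
        raise ContractError("true absorbance must be >= 0")
    if rng is None:
        rng = np.random.default_rng(spot.seed)
    light = _weight_map(spot) * spot.peak * 10.0 ** (-true_A) * _gaussian(spot)
    if spot.shot_noise:
        light = rng.poisson(light).astype(float)
    signal = spot.dark_level + light
    if spot.read_noise_sd > 0:
        signal = signal + rng.normal(0.0, spot.read_noise_sd, size=signal.shape)
    values = np.clip(np.rint(signal), 0, 1023).astype(np.uint16)
    return Mosaic(values, cfa=CFA_BGGR)


def dark_frame(spot: SpotModel, rng: np.random.Generator | None = None) -> Mosaic:
    """Frame with the source off: only dark level and read noise remain."""
    return render_mosaic(replace(spot, peak=0.0), 0.0, rng)


def develop_rgb(mosaic: Mosaic, isp: IspModel, mode: str = "AM") -> RgbImage:
    """Emulate the processed 8-bit path on an already-rendered mosaic.

    Demosaic by 2x2 binning (each CFA cell becomes one RGB pixel, greens
    averaged), apply per-channel gains, then the display gamma
    ``v_out = round(255 * (v/1023)^(1/gamma))``, clipped to [0, 255].
    """
    planes = split_channels(mosaic)
    rgb = np.stack(
        [
            planes.red.astype(float),
            0.5 * (planes.green1.astype(float) + planes.green2.astype(float)),
            planes.blue.astype(float),
        ],
        axis=-1,
    )
    rgb *= np.asarray(isp.gains)
    norm = np.clip(rgb / 1023.0, 0.0, 1.0)
    out = np.clip(np.rint(255.0 * norm ** (1.0 / isp.gamma)), 0, 255).astype(np.uint8)
    return RgbImage(out, mode=mode)


def render_rgb(
    spot: SpotModel,
    true_A: float,
    isp: IspModel,
    rng: np.random.Generator | None = None,
    mode: str = "AM",
) -> RgbImage:
    """Render the scene straight to the processed 8-bit representation."""
    return develop_rgb(render_mosaic(spot, true_A, rng), isp, mode=mode)


def desk_spot(seed: int = 0, **overrides) -> SpotModel:
    """A reduced-geometry spot (640x480, sigma 80 px) with the standard
    illumination and noise conditions.

    Photometric statistics depend on the 30x30 measurement ROI, not on the
    sensor's total pixel count, so characterization results on this geometry
    match the full 2592x1944 array while rendering ~16x faster.
    """
    params = dict(width=640, height=480, center=(240.0, 320.0), sigma=80.0, seed=seed)
    params.update(overrides)
    return SpotModel(**params)


# -- scenario generators -----------------------------------------------------

#: the dye-dilution characterization range: A of 0.1 to 1.0 in steps of 0.1
DILUTION_LEVELS = tuple(round(0.1 * i, 1) for i in range(1, 11))


@dataclass(frozen=True)
class DilutionSeries:
    """Reference + dark frames and replicate sample frames per true A."""

    reference: Mosaic
    dark: Mosaic
    samples: tuple  # ((true_A, (Mosaic, ...)), ...)
    seed: int


def dilution_series(
    spot: SpotModel,
    true_A_list=DILUTION_LEVELS,
    replicates: int = 3,
    seed: int | None = None,
) -> DilutionSeries:
    """Simulate the dye-dilution characterization: one I0 frame, one dark
    frame, and ``replicates`` independently noisy frames per absorbance
    level.  Per-frame substreams are spawned deterministically from ``seed``.
    """
    levels = [float(a) for a in true_A_list]
    if not levels:
        raise ContractError("true_A_list must be non-empty")
    if replicates < 1:
        raise ContractError("replicates must be >= 1")
    if seed is None:
        seed = spot.seed
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(2 + len(levels) * replicates)
    reference = render_mosaic(spot, 0.0, np.random.default_rng(streams[0]))
    dark = dark_frame(spot, np.random.default_rng(streams[1]))
    samples = []
    k = 2
    for a in levels:
        frames = []
        for _ in range(replicates):
            frames.append(render_mosaic(spot, a, np.random.default_rng(streams[k])))
            k += 1
        samples.append((a, tuple(frames)))
    return DilutionSeries(reference=reference, dark=dark, samples=tuple(samples), seed=seed)


@dataclass(frozen=True)
class ReactionModel:
    """Logistic absorbance-vs-time fixture for kinetic assays.

    ``direction="up"`` emulates a reactive-oxygen-metabolites-type reaction
    rising towards a plateau; ``"down"`` the decreasing antioxidant-assay
    profile.  This is a test fixture shaped like the observed curves, not a
    chemical rate model.
    """

    plateau: float = 1.5       # absorbance units
    rate: float = 0.15         # 1/min logistic steepness
    t_mid: float = 12.0        # minutes to half-plateau
    direction: str = "up"
    baseline: float = 0.0

    def true_absorbance(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        x = self.rate * (t - self.t_mid)
        if self.direction == "up":
            logistic = self.plateau / (1.0 + np.exp(-x))
        elif self.direction == "down":
            logistic = self.plateau / (1.0 + np.exp(x))
        else:
            raise ContractError(f"unknown direction {self.direction!r}")
        return self.baseline + logistic


@dataclass(frozen=True)
class ReactionRun:
    truth: KineticSeries
    reference: Mosaic
    dark: Mosaic
    frames: tuple  # one Mosaic per scheduled time
    seed: int


def reaction_curve(
    spot: SpotModel,
    model: ReactionModel,
    schedule,
    seed: int | None = None,
    sample_id: str = "kinetic",
) -> ReactionRun:
    """Render one frame per scheduled time (minutes) of a reaction curve."""
    times = np.asarray(list(schedule), dtype=float)
    if times.size == 0 or (times.size > 1 and not np.all(np.diff(times) > 0)):
        raise ContractError("schedule must be non-empty and strictly increasing")
    if seed is None:
        seed = spot.seed
    truth_A = model.true_absorbance(times)
    if np.any(truth_A < 0):
        raise ContractError("reaction model produced negative absorbance")
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(2 + times.size)
    reference = render_mosaic(spot, 0.0, np.random.default_rng(streams[0]))
    dark = dark_frame(spot, np.random.default_rng(streams[1]))
    frames = tuple(
        render_mosaic(spot, float(a), np.random.default_rng(s))
        for a, s in zip(truth_A, streams[2:])
    )
    truth = KineticSeries(times, truth_A, sample_id=sample_id, mode="truth")
    return ReactionRun(truth=truth, reference=reference, dark=dark, frames=frames, seed=seed)


def write_truth_manifest(path: str | Path, rows: list[dict]) -> None:
    """Ground-truth manifest CSV (frame file, true_A, time, seed)."""
    pd.DataFrame(rows).to_csv(path, index=False)
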