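# Methods

## Measurement model

A cuvette sits between a green LED (behind a diffuser) and a Bayer-filter
CMOS sensor. With the source intensity `I0`, the residual sensor signal with
the source off `Id`, and the intensity after sample introduction `Is` — all
taken as mean green-channel counts over a fixed region of interest — the
absorbance is

    A = log10( (I0 − Id) / (Is − Id) )

This assumes (i) Beer–Lambert attenuation of the LED light by the sample,
(ii) a sensor response linear in irradiance (true of the raw ADC counts, not
of processed output), and (iii) a dark signal that is additive and stable
within a session. Because the dark-corrected ratio cancels any common linear
gain, the absolute illumination level and the sensor's conversion gain drop
out; this is also why 8-bit (0–255) and 10-bit (0–1023) modes need no
cross-rescaling.

`Id` is measured once per session from a source-off frame and reused;
per-measurement dark frames are supported but not required. A sample whose
intensity does not exceed `Id` is opaque to the device: the photometry layer
raises (`OpaqueSampleError`), and a session flags the row rather than
emitting NaN silently.

## Raw data path

The sensor emits 10-bit values packed 4-pixels-per-5-bytes: four high bytes
then the four 2-bit remainders in a fifth byte. The decoder treats the
remainder byte as MSB-first (pixel 0 in bits 7–6) with an LSB-first dialect
switch for interoperability; `pack_raw`/`unpack_raw` round-trip bit-exactly
under both, which is the binding contract. Rows may carry trailing stride
padding, which is ignored; the default stride is the minimal `width·5/4`
bytes.

The colour-filter layout is BGGR: mosaic (0,0) is blue, (0,1) green1, (1,0)
green2, (1,1) red; green1 is green-on-blue-rows. Splitting preserves plane
spatial order and never interpolates — demosaicing is deliberately bypassed.
The working channel is green throughout (the LED band; twice as many sites);
`mean_green` in raw mode is the equal-weight average of the two green plane
means, with single-plane selection exposed as an option since the two planes
can in principle differ by sensor crosstalk.

## Region of interest

The LED spot is located as the 20×20 window with the highest mean intensity
(exhaustive summed-area-table scan; row-major first occurrence on ties), on
the green channel (AM/MM) or the mean of the two green planes (RM). Even
windows have no centre pixel; the convention is centre = top-left of the
central 2×2. Measurement uses a fixed 30×30 box around the stored centre.
For raw mode the centre is stored in mosaic coordinates and halved for the
half-resolution channel planes, keeping the 30×30 extent per plane.

An optional expansion step grows the rectangle symmetrically while every
row/column strip of the candidate rectangle keeps a mean intensity of at
least a threshold fraction (default 95%) of the central window's mean. The
criterion is re-evaluated over the *whole* rectangle at its current extents,
so the returned ROI satisfies the strip property post hoc; a per-pixel
minimum criterion is available as a stricter alternative. ROI coordinates
serialize to YAML and are reused for all frames of a session.

## Kinetics and calibration

Time series are read the way two-point photometric instruments read them:
the value at a requested time is the sample nearest in time (ties to the
earlier sample; linear interpolation optional), the two-point readout is
`A(t2) − A(t1)` (defaults 1 and 1.5 min, with shifted windows such as 5/10
min for slower optics), the early-region slope is an ordinary least-squares
fit (≥ 3 points), and the end point is a single late reading near the
plateau (≈ 40 min for the rising assay).

Concentration comes from a linear standards curve,
`c = slope·A + intercept`, fitted by OLS with concentration as the response
(so collinear standards are recovered exactly); the assay range is covered
by three standards (≈ 30/130/300 CARR.U.). Predictions beyond the standards
span are returned but flagged as extrapolated. An instrument whose LED peak
(522 nm) differs from the reference photometer's reading wavelength
(505 nm) sees a proportionally different absorbance; this is modelled as a
single multiplicative factor supplied in configuration and determined
empirically against the reference — the minimal model for an
inter-instrument offset, and deliberately not a spectral calculation.

## Synthetic frames

The simulator renders the expected count at a pixel of colour c as

    E(p) = dark_level + w_c · peak · 10^(−A_true) · exp(−d(p)²/2σ²)

i.e. an isotropic Gaussian spot, per-channel spectral weights
(default R/G/B = 0.25/1.0/0.35 for a green LED), and Beer–Lambert applied to
the light term only — dark current is not light. Shot noise is Poisson with
mean equal to the noiseless light signal (unit-gain assumption, one ADU per
event); read noise is additive Gaussian; values are rounded and clipped to
[0, 1023] on the BGGR grid. The processed-path emulation develops a mosaic
by 2×2-binned demosaic, per-channel gains and display gamma
`v = round(255·(v/1023)^(1/γ))` — enough to reproduce the gamma
nonlinearity that motivates raw reading, with no claim of emulating a real
ISP bit-exactly.

Default conditions are the characterization conditions: peak 950 ADU, dark
level 4 ADU, read noise 2 ADU rms, shot noise on, three replicates, true
absorbance 0.1–1.0 in 0.1 steps. The default geometry is the full
2592×1944 active array (spot σ = 200 px); tests and the acceptance script
use `desk_spot()` (640×480, σ = 80 px), chosen because photometric accuracy
and replicate scatter depend on the 30×30 ROI pixel count, which is
identical on both geometries — full-frame and reduced runs give the same
recovered-absorbance profile. Kinetic fixtures are logistic curves (rising
or falling); the shape mimics observed assay profiles and is a fixture, not
a chemical rate model.

What the simulator does **not** emulate: optical point-spread/vignetting,
spectral integration over the LED emission curve, exposure drift, dust or
speckle, sensor fixed-pattern noise, and real ISP internals. Passing tests
therefore demonstrate correctness of the decoding, photometric arithmetic
and pipeline plumbing under a physically shaped noise model — not robustness
to every artefact of a physical device.

## Numerical choices and edge cases

- Mosaic values are stored as unsigned 16-bit integers (holds 0–1023
  losslessly); decoded output cannot exceed 1023 by construction.
- `SpotModel` accepts `peak = 0` (the dark frame) as the one exception to
  `dark_level < peak`.
- All randomness flows from one seed via `numpy` seed sequences; identical
  seeds give bit-identical frames, and replicate sub-streams are spawned
  deterministically.
- Replicate statistics use the sample standard deviation (n − 1).
- Session CSV output is fully deterministic; re-running a session over the
  same stored frames reproduces the file byte for byte.
- The dynamic-range sweep reports the top of the unbroken run of levels
  (from 0.1 upward) whose replicate-mean recovery stays within 5% relative
  error, capped at 3.0 where the sweep stops.

## Known limitations

- Live camera capture is out of scope; sessions consume stored frames. The
  capture parameters a front-end would need (framerate, exposure mode,
  white-balance gains, shutter speed, warm-up) are carried as metadata in
  `SessionConfig`.
- The wavelength correction is a single empirical factor, not a model of the
  two instruments' spectral response overlap.
- Only the BGGR phase is implemented; other CFA phases raise.
- The vendor container that appends raw Bayer data to a JPEG is not parsed;
  raw frames are flat files with a YAML geometry sidecar.
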