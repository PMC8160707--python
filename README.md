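# rawphot

Demosaic-free absorbance photometry from raw Bayer sensor data.

Low-cost colorimeters built around single-board computers and CMOS camera
modules usually measure through the camera's processed 8-bit output — after
auto-exposure, white balance, demosaicing and gamma have already reshaped the
pixel values nonlinearly. `rawphot` implements the alternative: read the
sensor's packed 10-bit Bayer data directly, skip every image-processing step,
and treat the green colour-filter sites as a linear photometer. The toolkit
covers the whole chain for point-of-care assay reading:

- **`bayer_io`** — decode/encode the packed 10-bit format (4 pixels per
  5 bytes, BGGR layout) and split mosaics into the red, green1, green2 and
  blue planes without interpolation;
- **`roi`** — locate the LED spot (brightest 20×20 window) and fix the
  measurement region of interest, reused for a whole session;
- **`photometry`** — dark-corrected Beer–Lambert absorbance
  `A = log10((I0 − Id)/(Is − Id))` from mean green intensities, plus
  replicate statistics (CV%);
- **`kinetics`** — two-point deltas (A₂ − A₁), early-region slopes and
  end-point readings of timestamped absorbance series;
- **`calibration`** — linear standards curves to concentration units
  (Carratelli Units for oxidative-stress assays) and the multiplicative
  inter-instrument wavelength correction;
- **`simulate`** — a synthetic sensor: Gaussian LED spot, Beer–Lambert
  attenuation, Poisson shot noise, Gaussian read noise, 10-bit quantization,
  raw packing, and an emulated gamma/gain processed path, so the entire
  pipeline runs and is testable without a camera;
- **`session`** — orchestration of dark/reference/sample frames in the three
  acquisition modes (AM/MM processed 8-bit, RM raw 10-bit), CSV output, and a
  thin `rawphot` command-line interface.

Because absorbance is a dark-corrected intensity *ratio*, the raw path is
immune to common linear gain; the processed path is not even linear — display
gamma compresses the ratio so measured absorbance comes out near `A/γ`.

## Worked example

```sh
python examples/dilution_series.py
```

simulates a dye-dilution series (true absorbance 0.1–1.0, three replicate
raw frames each, LED peak 950 ADU, dark level 4 ADU, shot + read noise) and
measures it end to end:

```
true_A  mean_A   sd_A    CV%   rel_err
   0.1  0.1012  0.0004   0.35   1.16%
   0.2  0.2005  0.0003   0.15   0.24%
   ...
   1.0  1.0011  0.0005   0.05   0.11%

measured-vs-true slope = 1.0003 (ideal 1.0), R^2 = 0.999998
```

The slope of measured-vs-true absorbance is unity within a fraction of a
percent and replicate CV% is small and flat across the range — the raw-mode
signature. Running the same scenes through the emulated gamma-2.2 processed
path (`examples/raw_vs_processed.py`) yields a mean absolute error several
hundred times larger. Other examples cover packed-raw decoding
(`unpack_and_split.py`), kinetic reading (`kinetic_assay.py`) and
concentration calibration (`calibrate_and_report.py`).

The same workflow is available from the shell:

```sh
rawphot simulate --scenario dilution --out-dir frames --seed 1
rawphot roi frames/reference.raw --mode RM --out roi.yaml
rawphot measure --manifest frames/manifest.csv --mode RM --roi roi.yaml --out results.csv
```

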