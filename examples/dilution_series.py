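"""Measure a simulated dye-dilution series in raw mode.

Renders three replicate raw frames at each true absorbance from 0.1 to 1.0,
runs the full raw pipeline (decode, BGGR split, auto-detected 30x30 ROI,
dark-corrected green absorbance) and prints the recovered values.  A slope
near 1 and a flat, sub-percent CV% profile are the signature of the raw
path's linear photometric response.
"""

from scipy import stats

from rawphot import desk_spot, measure_dilution_series

df = measure_dilution_series(desk_spot(seed=1), replicates=3, seed=1)

print("true_A  mean_A   sd_A    CV%   rel_err")
for row in df.itertuples(index=False):
    print(f"  {row.true_A:4.1f}  {row.mean_A:6.4f}  {row.sd_A:.4f}  {row.cv_percent:5.2f}  "
          f"{100 * row.rel_err:5.2f}%")

fit = stats.linregress(df["true_A"], df["mean_A"])
print(f"\nmeasured-vs-true slope = {fit.slope:.4f} (ideal 1.0), "
      f"R^2 = {fit.rvalue**2:.6f}")
print("CV% stays roughly constant across the range - replicate precision does")
print("not degrade at low concentration, unlike gamma-processed 8-bit readings.")
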