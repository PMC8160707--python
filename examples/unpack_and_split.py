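"""Decode a packed 10-bit Bayer frame and split it into colour planes.

Builds one synthetic raw capture, packs it into the 5-bytes-per-4-pixels
wire format, decodes it back and prints per-plane statistics.  The two
green planes carry the photometric signal; red and blue see the green LED
only weakly through their filters.
"""

import numpy as np

from rawphot import desk_spot, pack_raw, render_mosaic, split_channels, unpack_raw

spot = desk_spot(seed=1)
mosaic = render_mosaic(spot, true_A=0.3)

frame = pack_raw(mosaic)
print(f"packed frame: {spot.width}x{spot.height} px -> {len(frame.data)} bytes "
      f"({len(frame.data) / (spot.width * spot.height):.2f} bytes/px)")

decoded = unpack_raw(frame)
assert np.array_equal(decoded.values, mosaic.values)
print("decode is bit-exact: every 10-bit value survives the packing round trip")

planes = split_channels(decoded)
print("\nper-plane means at the spot centre (30x30 crop, ADU on the 0-1023 scale):")
r, c = 120, 160  # plane coords = mosaic centre halved
for name in ("red", "green1", "green2", "blue"):
    plane = getattr(planes, name)
    crop = plane[r - 14:r + 16, c - 14:c + 16].astype(float)
    print(f"  {name:7s} mean {crop.mean():7.2f}  sd {crop.std():5.2f}")
print("\ngreen dominates because the LED emission sits in the green filter band;")
print("absorbance is computed from the green means only.")
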