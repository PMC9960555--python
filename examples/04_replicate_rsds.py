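"""Spot-to-spot and extract-to-extract reproducibility from a 3-extract x
3-spot screening design (an n = 9 plate)."""

from maldiscreen import screen_plate, simulate_plate
from maldiscreen.report import rsd_frame
from maldiscreen.simulate import tv_housing_design

plate = simulate_plate(tv_housing_design(seed=8))
report = screen_plate(plate.spectra, plate.manifest)

df = rsd_frame(report)
cols = ["compound", "species", "spot_to_spot_rsd", "spot_n", "extract_to_extract_rsd", "extract_n"]
print(df[cols].to_string(index=False))
# spot_to_spot_rsd: mean over extracts of the within-extract RSD across the
# three spots (n=9 when every spot detects; a missed spot is flagged n=8).
# extract_to_extract_rsd: RSD over the three per-extract mean heights (n=3).
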