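"""Simulate a ground-truthed 48-well plate and run the full screening
workflow: lock-mass recalibration, exact-mass + isotope-fit matching, blank
filtering, and the all-replicates consensus rule.
"""

from maldiscreen import screen_plate, simulate_plate
from maldiscreen.simulate import default_design

plate = simulate_plate(default_design(seed=42))
report = screen_plate(plate.spectra, plate.manifest, seed=42)

print("validated detections (confidence level 4):")
for d in report.validated():
    print(
        f"  {d.sample_id}  {d.compound:12s} [{d.species}]{'+' if d.polarity == 'positive' else '-'}"
        f"  {d.times_detected}  mass error {d.mean_mass_error_mda:+.2f} mDa"
        f"  score {d.mean_score:5.1f} ({d.quality_band})"
    )
# Every spiked compound appears n/n (detected in all replicate wells); the
# mass errors are sub-mDa after calibration, and scores near 0 mean the
# measured isotope envelope matches theory almost exactly.

for pol, res in report.per_polarity.items():
    models = {m.kind for m in res.calibration.values()}
    print(f"{pol}: calibration kinds {models}, "
          f"reference-intensity RSD between calibrant wells: "
          f"{res.reference_rsd_percent:.1f} %")
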