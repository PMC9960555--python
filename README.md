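# maldiscreen

Suspect screening of plastic additives — flame retardants, plasticizers,
antioxidants, UV stabilizers — in **AP-MALDI-qTOF** high-resolution mass
spectra. The package is for analytical chemists screening polymer extracts on
well-plate MALDI targets: it turns a compound suspect list into screenable
ion species, recalibrates centroided well spectra against PFSA lock masses,
matches species by exact mass and isotope-pattern fit, applies blank and
replicate-consensus filters, and reports confidence-level-4 detections. A
fully ground-truthed synthetic plate generator makes every stage testable
without instrument data.

## The method

Each suspect compound M (molecular formula known) is expanded into singly
charged ion species written in a small grammar of signed formula deltas:
adducts [M+H]⁺, [M+K]⁺, [M+Na]⁺, [M+O+K]⁺, deprotonation [M−H]⁻, halide
attachment [M+Cl]⁻/[M+Br]⁻, and in-source fragments such as [M−C₆H₅]⁻ for
triaryl phosphates or [M−C₆H₂Br₃−H]⁻ for TTBP-TAZ. For each species the
theoretical m/z is the monoisotopic mass of the post-species composition
(electron-mass correction optional, off by default; the ≈0.55 mDa difference
is far inside the matching tolerance), and the theoretical isotope pattern
is computed by exact elemental convolution, pruned, and merged at the
instrument's resolving power (R = 25,000 FWHM, TOF-like constant).

A species is **detected** in a well when all three criteria hold:

1. **exact mass** — a peak lies within ±5 mDa of the theoretical m/z;
2. **isotope fit** — the sigma-style score
   `1000·√(mean((tᵢ − mᵢ)²))` between the sum-normalized theoretical and
   measured envelope intensities is `< 100` (`< 50` good, `< 25` excellent;
   0 is a perfect fit);
3. **blank filter** — the peak height is strictly greater than 3× the
   highest signal at that m/z across the plate's three blank wells.

A detection is **validated** (confidence level 4: exact mass + isotope
pattern) only when it passes in *every* replicate well of a sample —
reported as times detected per times measured (3/3, 9/9). Compounds whose
ions share a molecular formula (DEHP/DNOP; the BPA [M−CH₃]⁺ fragment vs
protonated benzyl benzoate; 2,4,6-TBP [M−H]⁻ vs the ATE [M−C₃H₅]⁻ fragment)
cannot be distinguished and are reported together in one isobar group.

Before matching, every spectrum is recalibrated against the C4/C6/C8
perfluoroalkyl sulfonic acid (PFSA) reference ions measured in the plate's
first and last wells (identity/linear/quadratic lock-mass fit, with
graceful degradation when references are missing).

## Worked example

```sh
python examples/02_simulate_and_screen_plate.py
```

simulates a 48-well plate (calibrant wells first/last, 3 blanks, one
triplicate sample spiked with six additives, systematic mass drift + 1 mDa
jitter, two-level lognormal intensity noise, background noise peaks) and
screens it:

```
validated detections (confidence level 4):
  S01  DBP          [M+K]+  3/3  mass error +0.48 mDa  score   0.0 (excellent)
  S01  TPhP         [M+H]+  3/3  mass error -0.08 mDa  score   0.0 (excellent)
  S01  TPhP         [M+K]+  3/3  mass error +0.77 mDa  score   6.0 (excellent)
  S01  TPhP         [M+Na]+  3/3  mass error +0.22 mDa  score   0.0 (excellent)
  S01  Tinuvin 770  [M+H]+  3/3  mass error -0.30 mDa  score   0.0 (excellent)
  S01  Irgafos 168  [M-C14H21+O]-  3/3  mass error -0.53 mDa  score   0.0 (excellent)
  S01  TBBPA        [M-H]-  3/3  mass error -0.15 mDa  score   0.0 (excellent)
  S01  TPhP         [M-C6H5]-  3/3  mass error +0.74 mDa  score   0.0 (excellent)
  S01  TTBP-TAZ     [M-C6H2Br3-H]-  3/3  mass error +0.27 mDa  score   0.0 (excellent)
```

Every spiked species validates in all three replicate wells; post-calibration
mass errors are sub-mDa; near-zero scores mean the measured isotope envelopes
match theory almost exactly. No unspiked compound validates.

The same workflow is available as a thin CLI:

```sh
maldiscreen simulate --seed 42 --out bundle/
maldiscreen screen --bundle bundle/ --out out/        # detections.tsv + audit.json
maldiscreen rsd --bundle bundle/ --out rsd.tsv        # replicate statistics
```

The other examples cover formula/isotope arithmetic (`01`), lock-mass
calibration recovery (`03`), and spot-to-spot / extract-to-extract RSDs on a
3-extract × 3-spot design (`04`).

## Layout

- `src/maldiscreen/chem.py` — formulas, monoisotopic masses, species grammar
- `src/maldiscreen/isotopes.py` — bundled isotope table, exact convolution,
  resolution merging
- `src/maldiscreen/spectra.py` — centroid spectra, nearest-peak query,
  TSV/mzML I/O
- `src/maldiscreen/plate.py` — manifests, suspect database, PFSA reference ions
- `src/maldiscreen/calibration.py` — lock-mass recalibration
- `src/maldiscreen/screening.py` — matching, scoring, blank/consensus rules
- `src/maldiscreen/rsd.py` — reproducibility statistics
- `src/maldiscreen/simulate.py` — synthetic plate generator with ground truth
- `src/maldiscreen/workflow.py`, `report.py`, `cli.py` — orchestration,
  report writers, CLI

See `docs/methods.md` for the modelling assumptions, parameter choices and
known limitations.
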