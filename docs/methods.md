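# Methods

This note documents the models, conventions and parameter choices behind
`maldiscreen`, and what the synthetic-data-based tests do and do not
establish about real instrument data.

## Mass and isotope arithmetic

**Isotope table.** Isotope masses and abundances are bundled in
`src/maldiscreen/data/isotopes.tsv` (IUPAC/CIAAW values: AME2020 masses,
CIAAW 2021 representative abundances) so results are version-pinned and
independent of external library updates. Supported elements: H, D (pure ²H
pseudo-element for isotope labels), C, N, O, F, Na, Si, P, S, Cl, K, Br, I.
For all of these the lightest isotope is also the most abundant, so the
monoisotopic peak is the first peak of every pattern.

**Electron-mass convention.** Theoretical m/z of a singly charged species is
the monoisotopic mass of the post-species composition with *no* electron
correction by default. The correction (±0.548 mDa) is an order of magnitude
below the 5 mDa matching tolerance and the convention matches how such
values are usually printed; `theoretical_mz(..., electron_correction=True)`
applies it when exactness matters.

**Isotopologue distribution.** Computed exactly: per element, the n-atom
distribution is built by binary-exponentiation convolution over
isotope-count tuples (isotopologues with identical composition are summed,
reproducing the multinomial law without evaluating factorials); elements are
combined by Cartesian convolution with a 1e-15 hard probability floor. The
test suite checks this against two independent oracles — a closed-form
multinomial evaluation and, for tiny molecules, exhaustive per-atom
enumeration — at 1e-12 probability / 1e-9 Da.

**Resolution merging.** Centroided TOF data do not resolve isotopic fine
structure. Patterns are collapsed with a greedy left-to-right merge: a peak
joins the running cluster when its gap to the cluster centroid is below half
the FWHM (m/z ÷ R ÷ 2, R = 25,000 constant across m/z, a reasonable model
for TOF analyzers), so a merged cluster spans about one FWHM. The same merge
rule is used when the simulator centroids its generated peaks; this
consistency is what makes the noiseless-limit invariant (score exactly 0,
mass error exactly 0) attainable and testable. Isotopologues below 1e-4
relative probability are pruned before merging (keeps Br₄/Br₉ envelopes
complete while bounding pattern size), and intensities are renormalized to
sum 1.

## Screening decision rule

Matching is per species, anchored on the species' monoisotopic peak: the
nearest measured peak within ±5 mDa (ties: closer, then more intense, then
lower m/z). Isotope peaks are scored but not independently required to be
present — the score carries that evidence.

**Isotope-fit score.** The vendor statistic used with qTOF screening
software is proprietary, so the package defines an open sigma-analog: the
theoretical pattern is restricted to the most intense peaks covering ≥ 99%
of cumulative intensity; each is looked up (shifted by the observed − 
theoretical anchor difference) as the nearest measured peak within the mass
tolerance, missing peaks contributing 0; both vectors are normalized to sum
1 and the score is `1000·√(mean((tᵢ−mᵢ)²))`. Zero means perfect agreement,
and the conventional < 25 / < 50 / < 100 bands are kept as configurable
quality labels. No numeric equivalence to any vendor implementation is
claimed — only the decision structure (bands, threshold at 100) is
preserved.

**Blank threshold.** Per plate (blanks are plate-resident): factor (default
3) × the maximum over the plate's blanks of the blank's signal at the target
m/z — the nearest blank peak within tolerance, or, when none exists, that
blank's noise floor (median peak intensity; 0 for an empty blank). The
sample peak must exceed the threshold *strictly*; a peak at exactly 3× the
highest blank fails.

**Consensus.** A sample's replicate wells (3 spots, or 3 extracts × 3 spots)
are pooled; a detection is validated iff it passed in every replicate well
(n_detected == n_measured). For 9-well designs this is equivalent to
all-of-3 within every extract; partial results (2/3, 8/9) are reported but
not validated. Validated detections carry confidence level 4 (exact mass +
isotope pattern, no MS/MS, no reference standard). One measured peak may
support several species/compounds — there is no peak exclusivity; instead,
compounds whose post-species ions share a molecular formula get one isobar
group id per sample and are reported together, because exact mass and
isotope pattern cannot distinguish them in principle.

**Default species sets.** When a database row lists no species for a mode:
positive {M+H, M+K, M+Na}, negative {M−H}. The bundled 24-compound suspect
list adds the class-specific chemistry (the [M+O+K]⁺ oxidation adduct for
phosphites, [M+Cl]⁻/[M+Br]⁻/[M−Br+O]⁻ for halogenated analytes, and the
characteristic in-source fragments of RDP/BDP/TPhP, Irgafos 168, TTBP-TAZ,
BPA and ATE). It is a deliberately small, synthetic stand-in for the
thousand-compound merged suspect databases used in practice; swap in your
own CSV with `--db`.

## Calibration

Lock-mass recalibration maps observed → corrected m/z with an identity,
linear (default) or quadratic polynomial fitted by least squares on the
reference ions matched in a calibrant well (coarse tolerance 0.05 Da).
Under-determined fits degrade (quadratic → linear → identity) with a
warning; with no calibrant wells screening proceeds uncalibrated and
flagged. Plate policies: `average` (default; mean of the first/last-well
models, appropriate for a plate-constant drift), `nearest` (per-well nearest
calibrant, better under within-plate drift gradients), `first`. Applying a
model must preserve peak order (monotone over the data range); violations
raise. The intensity RSD of the reference ions across calibrant wells is
reported as the between-run reproducibility figure.

**Reference ions.** The shipped list is computed from the C4/C6/C8 PFSA
formulas: negative mode [M−H]⁻ monomers plus proton-bound [2M−H]⁻ dimers
(≈ m/z 299–1037); positive mode [M+H]⁺ of C6/C8 plus [2M+H]⁺ of all three
(≈ 377–1115). The positive-mode list is a repository convention (PFSAs are
poor positive-mode ionizers); both lists are user-replaceable TSV configs,
and the simulator uses the same list, keeping tests self-consistent.

## Synthetic plates

The generator emulates a 48-well acquisition: calibrant mix first and last
well, 3 blanks, triplicate sample spots (optionally × triplicate extracts).
Defaults and rationale:

| parameter | default | why |
|---|---|---|
| mass jitter σ | 1 mDa | centroid-level accuracy of a well-tuned qTOF |
| systematic drift | slope 1.000002, offset 2 mDa | small gain + offset error for the lock-mass fit to remove |
| spot lognormal σ | 0.20 (≈ 20% RSD) | inside the 6–48% spot-to-spot range typical of GNP-doped plates |
| extract lognormal σ | 0.15 (≈ 15% RSD) | inside the 1–46% extract-to-extract range |
| noise peaks | 40/well, Exp(30) intensities, uniform m/z 100–1100 | sparse chemical background |
| spike base height | 5000 | ≥ 10× typical blank-derived thresholds |
| resolution | 25,000 FWHM | instrument class modelled |

Extract factors are shared across the wells of an extract; spot factors are
drawn per well per compound; all randomness derives from the design seed via
independent per-well substreams, making bundles byte-identical across runs.
A `height_ceiling` option crudely approximates detector saturation for
stress tests.

**What the generator does not model:** matrix/background chemistry and
chemical noise correlated with analytes, detector saturation and
isotope-envelope distortion at percent-level concentrations (the regime
where heavily brominated compounds defeat isotope-fit software and need
manual identification), ionization suppression between co-deposited
analytes, profile-mode peak shapes, and scan-level time structure within the
15 s per-well acquisition (wells are single pre-summed centroid spectra).
Passing the end-to-end recovery tests therefore demonstrates the decision
logic and numerics are correct under the stated noise model — not that the
method achieves any particular sensitivity on real extracts.

## Reproducibility statistics

RSD = sd/mean × 100 with the sample (n−1) denominator (configurable via
`ddof`; the convention is not universal). Non-detects are excluded, never
zero-filled: extract-to-extract uses per-extract means over detected spots;
spot-to-spot averages within-extract RSDs over extracts having ≥ 2 detected
spots, reporting the effective n (9, 8, …) so reduced-n values are visibly
flagged.

## Numerical and interface choices

- m/z in Da everywhere; CLI tolerances in mDa, converted once at the
  boundary; mass errors reported signed in mDa.
- TSV spectra are written with 6-decimal fixed formatting, which bounds
  round-trip error at 5e-7 Da — two orders below the mass jitter.
- The mzML reader/writer pair is minimal (centroided single-spectrum files,
  uncompressed or zlib 32/64-bit floats) and is not a general mzML
  implementation.
- "Peak height" means stored centroid intensity; no area integration.
- Problem sizes in the test suite (20-plate recovery runs, 40-formula oracle
  sweeps, 300–400-draw moment checks) were chosen as the smallest sizes at
  which the checked statistics are stable, keeping the full suite in the
  tens of seconds.

## Known limitations

- Positive-mode reference ions are a convention, not a measured list; real
  instruments need their vendor reference table.
- The sigma-analog score is not numerically comparable to vendor mSigma
  values, only band-compatible.
- Isobar groups are per sample and based on exact formula identity only;
  near-isobaric collisions inside the 5 mDa window are reported as separate
  detections of the same peak.
- Charge is fixed at 1; multiply charged species and cluster-ion series
  beyond the explicit dimer references are out of scope.
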