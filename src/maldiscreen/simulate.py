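"""Synthetic 48-well plate acquisitions with ground truth.

The generator emulates the statistical structure the screening pipeline
assumes: a plate with the calibrant mix in the first and last well, three
blanks, and triplicate sample spots (optionally triplicate extracts ×
triplicate spots for n/9 designs); spiked compounds contribute their full
resolution-merged isotope envelopes; every signal peak's m/z passes through
a systematic drift model (slope, offset, optional per-well gradient) plus
Gaussian jitter; intensities carry two-level lognormal noise (extract ×
spot) sized to land inside the spot-to-spot / extract-to-extract RSD ranges
observed for GNP-doped AP-MALDI plates; background is uniform-m/z noise
with exponential intensities. All randomness derives from the design seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .chem import Polarity, apply_species, parse_species, theoretical_mz
from .isotopes import isotope_pattern, merge_by_resolution
from .plate import (
    CompoundRecord,
    PlateManifest,
    ReferenceIon,
    WellInfo,
    default_database,
    default_reference_ions,
    write_manifest,
)
from .spectra import CentroidSpectrum, write_tsv_spectrum

POLARITIES: Tuple[Polarity, Polarity] = ("positive", "negative")


@dataclass(frozen=True)
class Spike:
    """One spiked compound: species labels per polarity and the base peak
    height of the most intense isotopologue (arbitrary counts)."""

    compound: str
    pos_species: Tuple[str, ...] = ()
    neg_species: Tuple[str, ...] = ()
    base_height: float = 5000.0

    def species_labels(self, polarity: Polarity) -> Tuple[str, ...]:
        return self.pos_species if polarity == "positive" else self.neg_species


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    spikes: Tuple[Spike, ...] = ()
    n_extracts: int = 1
    n_spots: int = 3


@dataclass
class PlateDesign:
    """Everything the generator needs; the defaults are the study conditions
    (48 wells, first/last calibrant, 3 blanks, triplicate spots, 1 mDa mass
    jitter, ~20%/15% spot/extract lognormal intensity noise, R = 25,000)."""

    samples: Tuple[SampleSpec, ...] = ()
    seed: int = 0
    n_wells: int = 48
    n_blanks: int = 3
    fill_unspiked: bool = True
    # noise peaks
    n_noise_peaks: int = 40
    noise_scale: float = 30.0
    mz_range: Tuple[float, float] = (100.0, 1100.0)
    # mass error model: mz_obs = slope*mz + offset + gradient*well_index + N(0, sigma)
    drift_slope: float = 1.000002
    drift_offset_da: float = 0.002
    drift_gradient_mda_per_well: float = 0.0
    mz_sigma_mda: float = 1.0
    # intensity noise (lognormal sigmas of the underlying normal)
    sigma_spot: float = 0.20
    sigma_extract: float = 0.15
    # instrument
    resolution: float = 25000.0
    prune: float = 1e-4
    calibrant_height: float = 2000.0
    height_ceiling: Optional[float] = None
    blank_contaminants: Tuple[Tuple[str, float, float], ...] = ()  # (polarity, mz, height)

    def drift(self, mz: np.ndarray, well_index: int) -> np.ndarray:
        return (
            self.drift_slope * np.asarray(mz)
            + self.drift_offset_da
            + self.drift_gradient_mda_per_well * well_index / 1000.0
        )


@dataclass
class SimulatedPlate:
    manifest: PlateManifest
    spectra: Dict[Tuple[str, Polarity], CentroidSpectrum]
    ground_truth: dict
    design: PlateDesign


def _layout(design: PlateDesign) -> List[WellInfo]:
    """Well roles: calibrant first/last, blanks spread through the plate,
    sample blocks (extract-major) in between; leftover wells become unspiked
    filler samples when ``fill_unspiked``."""
    n = design.n_wells
    ids = [f"W{i:02d}" for i in range(1, n + 1)]
    roles: Dict[int, WellInfo] = {}
    roles[0] = WellInfo(ids[0], "calibrant")
    roles[n - 1] = WellInfo(ids[n - 1], "calibrant")
    blank_positions = [round(1 + i * (n - 3) / max(design.n_blanks - 1, 1)) for i in range(design.n_blanks)]
    for p in blank_positions:
        while p in roles:
            p += 1
        roles[p] = WellInfo(ids[p], "blank")
    free = [i for i in range(n) if i not in roles]
    cursor = 0
    for spec in design.samples:
        for e in range(1, spec.n_extracts + 1):
            for s in range(1, spec.n_spots + 1):
                if cursor >= len(free):
                    raise ValueError("plate design needs more wells than available")
                i = free[cursor]
                cursor += 1
                rep = (e - 1) * spec.n_spots + s
                roles[i] = WellInfo(ids[i], "sample", spec.sample_id, rep, e)
    if design.fill_unspiked:
        u = 0
        while cursor < len(free):
            u += 1
            block = free[cursor : cursor + 3]
            for j, i in enumerate(block, start=1):
                roles[i] = WellInfo(ids[i], "sample", f"U{u:02d}", j, 1)
            cursor += len(block)
    return [roles[i] for i in sorted(roles)]


def _spike_peaks(
    spike: Spike,
    record: CompoundRecord,
    polarity: Polarity,
    design: PlateDesign,
    scale: float,
) -> List[Tuple[float, float, str]]:
    """Theoretical (mz, height, species-label) peaks of one spike at unit
    drift, scaled so the pattern's base peak equals ``scale``."""
    peaks = []
    for label in spike.species_labels(polarity):
        sp = parse_species(label, polarity)
        if not sp.applicable_to(record.formula):
            continue
        ion = apply_species(record.formula, sp)
        pat = isotope_pattern(ion, prune=design.prune, resolution=design.resolution)
        top = max(pat.rel_intensity)
        for mz, rel in pat.peaks():
            peaks.append((mz, scale * rel / top, label))
    return peaks


def simulate_well(
    design: PlateDesign,
    well: WellInfo,
    polarity: Polarity,
    rng: np.random.Generator,
    database: Sequence[CompoundRecord],
    refs: Sequence[ReferenceIon],
    spikes: Sequence[Spike] = (),
    extract_factor: float = 1.0,
    well_index: int = 0,
) -> Tuple[CentroidSpectrum, List[dict]]:
    """One well's centroided spectrum for one polarity, plus its ground-truth
    signal list. Draw order is fixed so outputs are seed-deterministic."""
    by_name = {c.name: c for c in database}
    signal: List[Tuple[float, float]] = []
    truth: List[dict] = []
    if well.role == "calibrant":
        for r in refs:
            if r.polarity != polarity:
                continue
            h = design.calibrant_height * _lognormal(rng, design.sigma_spot)
            signal.append((r.mz, h))
            truth.append({"compound": r.label, "species": "ref", "mz_true": r.mz, "height": h})
    elif well.role == "sample":
        for spike in spikes:
            record = by_name[spike.compound]
            spot_factor = _lognormal(rng, design.sigma_spot)
            scale = spike.base_height * extract_factor * spot_factor
            for mz, h, label in _spike_peaks(spike, record, polarity, design, scale):
                signal.append((mz, h))
            for label in spike.species_labels(polarity):
                sp = parse_species(label, polarity)
                if sp.applicable_to(record.formula):
                    truth.append(
                        {
                            "compound": spike.compound,
                            "species": label,
                            "mz_true": theoretical_mz(record.formula, sp),
                            "height": scale,
                        }
                    )
    for pol, mz, h in design.blank_contaminants:
        if pol == polarity and well.role == "blank":
            signal.append((mz, h))
    # systematic drift + jitter on signal peaks
    peaks: List[Tuple[float, float]] = []
    if signal:
        mzs = design.drift(np.array([m for m, _ in signal]), well_index)
        if design.mz_sigma_mda > 0:
            mzs = mzs + rng.normal(0.0, design.mz_sigma_mda / 1000.0, size=len(mzs))
        peaks = list(zip(mzs.tolist(), (h for _, h in signal)))
    # background noise
    if design.n_noise_peaks > 0:
        nmz = rng.uniform(*design.mz_range, size=design.n_noise_peaks)
        nint = rng.exponential(design.noise_scale, size=design.n_noise_peaks)
        peaks += list(zip(nmz.tolist(), nint.tolist()))
    merged = merge_by_resolution(peaks, design.resolution)
    if design.height_ceiling is not None:
        merged = [(m, min(h, design.height_ceiling)) for m, h in merged]
    mz_arr = np.array([m for m, _ in merged])
    int_arr = np.array([h for _, h in merged])
    spec = CentroidSpectrum(mz_arr, int_arr, polarity, well.well_id)
    return spec, truth


def _lognormal(rng: np.random.Generator, sigma: float) -> float:
    # mean-1 lognormal; sigma 0 short-circuits so noiseless designs are exact
    if sigma <= 0:
        return 1.0
    return float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))


def simulate_plate(
    design: PlateDesign,
    database: Optional[Sequence[CompoundRecord]] = None,
    refs: Optional[Sequence[ReferenceIon]] = None,
    out_dir=None,
) -> SimulatedPlate:
    """Simulate a full plate (both polarities), deterministic given the seed.

    With ``out_dir`` the bundle is written to disk: ``manifest.csv``,
    ``spectra/<well>_<pos|neg>.tsv``, ``ground_truth.json``, ``design.json``.
    """
    database = list(database) if database is not None else default_database()
    refs = list(refs) if refs is not None else default_reference_ions()
    wells = _layout(design)
    manifest = PlateManifest(wells, plate_id=f"synthetic-seed{design.seed}")
    spikes_of = {s.sample_id: s.spikes for s in design.samples}
    extracts_of = {s.sample_id: s for s in design.samples}

    # extract-level intensity factors, shared across wells of one extract
    rng_extract = np.random.default_rng([design.seed, 10_007])
    extract_factor: Dict[Tuple[str, int], float] = {}
    for spec in design.samples:
        for e in range(1, spec.n_extracts + 1):
            extract_factor[(spec.sample_id, e)] = _lognormal(rng_extract, design.sigma_extract)

    spectra: Dict[Tuple[str, Polarity], CentroidSpectrum] = {}
    truth_wells: Dict[str, Dict[str, List[dict]]] = {}
    for idx, w in enumerate(wells):
        for p_idx, polarity in enumerate(POLARITIES):
            rng = np.random.default_rng([design.seed, idx, p_idx])
            spikes = spikes_of.get(w.sample_id, ()) if w.role == "sample" else ()
            ef = extract_factor.get((w.sample_id, w.extract), 1.0)
            spec, truth = simulate_well(
                design, w, polarity, rng, database, refs,
                spikes=spikes, extract_factor=ef, well_index=idx,
            )
            spectra[(w.well_id, polarity)] = spec
            if truth:
                truth_wells.setdefault(w.well_id, {})[polarity] = truth

    expected: Dict[str, List[List[str]]] = {}
    for spec in design.samples:
        rows = []
        for spike in spec.spikes:
            record = next(c for c in database if c.name == spike.compound)
            for polarity in POLARITIES:
                for label in spike.species_labels(polarity):
                    if parse_species(label, polarity).applicable_to(record.formula):
                        rows.append([spike.compound, label, polarity])
        expected[spec.sample_id] = rows
    ground_truth = {
        "seed": design.seed,
        "wells": truth_wells,
        "samples": {sid: {"expected_validated": rows} for sid, rows in expected.items()},
    }

    plate = SimulatedPlate(manifest, spectra, ground_truth, design)
    if out_dir is not None:
        write_bundle(plate, out_dir)
    return plate


def write_bundle(plate: SimulatedPlate, out_dir) -> None:
    out = Path(out_dir)
    (out / "spectra").mkdir(parents=True, exist_ok=True)
    write_manifest(out / "manifest.csv", plate.manifest)
    for (wid, polarity), spec in sorted(plate.spectra.items()):
        suffix = "pos" if polarity == "positive" else "neg"
        write_tsv_spectrum(out / "spectra" / f"{wid}_{suffix}.tsv", spec)
    (out / "ground_truth.json").write_text(
        json.dumps(plate.ground_truth, indent=1, sort_keys=True) + "\n"
    )
    (out / "design.json").write_text(
        json.dumps(dataclasses.asdict(plate.design), indent=1, sort_keys=True, default=list) + "\n"
    )


# ---------------------------------------------------------------------------
# Ready-made designs
# ---------------------------------------------------------------------------

def default_design(seed: int = 0, **overrides) -> PlateDesign:
    """The standard test plate: one triplicate sample spiked with six
    additives whose screened ions are mutually non-isobaric within the
    bundled database, remaining wells unspiked."""
    spikes = (
        Spike("TPhP", pos_species=("M+H", "M+K", "M+Na"), neg_species=("M-C6H5",)),
        Spike("DBP", pos_species=("M+K",)),
        Spike("TBBPA", neg_species=("M-H",)),
        Spike("TTBP-TAZ", neg_species=("M-C6H2Br3-H",)),
        Spike("Irgafos 168", neg_species=("M-C14H21+O",)),
        Spike("Tinuvin 770", pos_species=("M+H",)),
    )
    samples = (SampleSpec("S01", spikes=spikes, n_extracts=1, n_spots=3),)
    return PlateDesign(samples=samples, seed=seed, **overrides)


def tv_housing_design(seed: int = 0, **overrides) -> PlateDesign:
    """A plate encoding the TV-housing ground-truth pattern: BDP, TPhP,
    TTBP-TAZ and 2,4,6-TBP present (3 extracts × 3 spots → expected 9/9);
    TCEP, TCP, TBBPA and BDE209 absent (expected 0/9)."""
    spikes = (
        Spike("BDP", pos_species=("M+K",)),
        Spike("TPhP", pos_species=("M+K",), neg_species=("M-C6H5",)),
        Spike("TTBP-TAZ", neg_species=("M-C6H2Br3-H",)),
        Spike("2,4,6-TBP", neg_species=("M-H",)),
    )
    samples = (SampleSpec("2", spikes=spikes, n_extracts=3, n_spots=3),)
    return PlateDesign(samples=samples, seed=seed, **overrides)
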