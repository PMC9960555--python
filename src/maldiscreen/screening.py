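"""Suspect screening: exact-mass matching, isotope-fit scoring, blank and
replicate-consensus criteria, confidence-level-4 detections.

Identification follows the three-criterion rule used in qTOF suspect
screening of plastic additives: isotope-fit score < 100, absolute mass
deviation < 5 mDa, and peak height strictly greater than 3× the highest
signal found in the plate's blanks (n = 3), with a compound validated only
when it passes in ALL replicate wells of a sample. The resulting confidence
is level 4 of the Schymanski scheme (exact mass + isotope pattern only).

The vendor mSigma statistic is proprietary; the open sigma-analog used here
is ``1000 × sqrt(mean((t_i − m_i)^2))`` over sum-normalized theoretical and
measured isotope-intensity vectors. It shares the vendor scale's anchor
points — 0 is perfect agreement; the <25 / <50 / <100 bands are kept as
configurable quality labels — without claiming numeric equivalence.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .chem import Formula, IonSpecies, Polarity, apply_species, theoretical_mz
from .isotopes import IsotopePattern, isotope_pattern
from .plate import CompoundRecord, PlateManifest
from .spectra import CentroidSpectrum, nearest_peak


@dataclass(frozen=True)
class ScreeningCriteria:
    """Thresholds of the screening decision rule (defaults: 5 mDa, sigma 100,
    blank factor 3, all-of-n replicates)."""

    mass_tol: float = 0.005  # Da
    sigma_max: float = 100.0
    blank_factor: float = 3.0
    n_blanks: int = 3
    replicate_rule: str = "all"
    quality_bands: Tuple[Tuple[float, str], ...] = (
        (25.0, "excellent"),
        (50.0, "good"),
        (100.0, "acceptable"),
    )
    prune: float = 1e-4
    resolution: float = 25000.0

    def __post_init__(self) -> None:
        if self.mass_tol <= 0 or self.sigma_max <= 0 or self.blank_factor <= 0:
            raise ValueError("criteria thresholds must be positive")

    def quality_band(self, score: float) -> str:
        for thr, label in self.quality_bands:
            if score < thr:
                return label
        return "fail"


@dataclass
class MatchResult:
    """One compound × species match attempt in one well (pass or fail)."""

    compound: str
    species: str
    polarity: Polarity
    well_id: str
    theoretical_mz: float
    observed_mz: float
    mass_error_mda: float  # signed, observed - theoretical
    peak_height: float
    iso_fit_score: float
    blank_threshold: float
    ion_formula: str = ""
    mass_ok: bool = True
    sigma_ok: bool = False
    blank_ok: bool = False

    @property
    def passed_all(self) -> bool:
        return self.mass_ok and self.sigma_ok and self.blank_ok


@dataclass
class Detection:
    """Replicate-consensus result for one sample × compound × species."""

    sample_id: str
    compound: str
    species: str
    polarity: Polarity
    n_detected: int
    n_measured: int
    mean_mass_error_mda: float
    mean_score: float
    quality_band: str
    validated: bool
    confidence_level: int = 4
    isobar_group: str = ""
    ion_formula: str = ""

    @property
    def times_detected(self) -> str:
        return f"{self.n_detected}/{self.n_measured}"


@functools.lru_cache(maxsize=4096)
def _cached_pattern(hill: str, prune: float, resolution: float) -> IsotopePattern:
    return isotope_pattern(Formula.parse(hill), prune=prune, resolution=resolution)


def iso_fit_score(
    theoretical: IsotopePattern,
    s: CentroidSpectrum,
    anchor_mz: float,
    tol: float,
) -> float:
    """Sigma-analog goodness of fit between theoretical and measured pattern.

    The theoretical pattern is restricted to its most intense peaks covering
    ≥ 99% cumulative intensity; each is looked up (shifted so the theoretical
    monoisotopic peak sits on the matched anchor) as the nearest measured
    peak within ``tol``, missing peaks counting as intensity 0. Both vectors
    are normalized to sum 1 and the score is 1000 × the RMS difference.
    """
    if len(theoretical) == 0:
        raise ValueError("empty theoretical pattern")
    order = np.argsort(theoretical.rel_intensity)[::-1]
    cum = 0.0
    keep = []
    for i in order:
        keep.append(int(i))
        cum += theoretical.rel_intensity[i]
        if cum >= 0.99:
            break
    keep.sort()
    shift = anchor_mz - theoretical.monoisotopic_mz
    theo = np.array([theoretical.rel_intensity[i] for i in keep])
    meas = np.zeros(len(keep))
    for j, i in enumerate(keep):
        hit = nearest_peak(s, theoretical.mz[i] + shift, tol)
        if hit is not None:
            meas[j] = hit[1]
    theo = theo / theo.sum()
    meas_sum = meas.sum()
    if meas_sum > 0:
        meas = meas / meas_sum
    return float(1000.0 * np.sqrt(np.mean((theo - meas) ** 2)))


def blank_threshold(
    blank_spectra: Sequence[CentroidSpectrum],
    target_mz: float,
    tol: float,
    factor: float = 3.0,
) -> float:
    """factor × max over blanks of the blank's signal at target m/z.

    A blank's signal is its nearest peak intensity within ±tol, or — when no
    blank peak lies near the target — that blank's noise floor (the median of
    its peak intensities; 0 for an empty blank). Sample peaks must exceed the
    returned threshold STRICTLY.
    """
    best = 0.0
    for b in blank_spectra:
        hit = nearest_peak(b, target_mz, tol)
        if hit is not None:
            signal = hit[1]
        elif len(b) > 0:
            signal = float(np.median(b.intensity))
        else:
            signal = 0.0
        best = max(best, signal)
    return factor * best


def screen_well(
    s: CentroidSpectrum,
    database: Sequence[CompoundRecord],
    criteria: ScreeningCriteria,
    blanks: Sequence[CentroidSpectrum],
) -> List[MatchResult]:
    """Match every compound × applicable species of the spectrum's polarity.

    Returns ALL matched results (passing and failing) for audit; screen
    positives are those with ``passed_all``. Species whose deltas are
    inapplicable to a compound are skipped. Empty spectrum → empty list.
    """
    results: List[MatchResult] = []
    for comp in database:
        for sp in comp.species_for(s.polarity):
            if not sp.applicable_to(comp.formula):
                continue
            ion = apply_species(comp.formula, sp)
            mz_theo = theoretical_mz(comp.formula, sp)
            hit = nearest_peak(s, mz_theo, criteria.mass_tol)
            if hit is None:
                continue
            obs_mz, height = hit
            pattern = _cached_pattern(ion.hill(), criteria.prune, criteria.resolution)
            score = iso_fit_score(pattern, s, obs_mz, criteria.mass_tol)
            thr = blank_threshold(blanks, mz_theo, criteria.mass_tol, criteria.blank_factor)
            results.append(
                MatchResult(
                    compound=comp.name,
                    species=sp.label,
                    polarity=s.polarity,
                    well_id=s.well_id,
                    theoretical_mz=mz_theo,
                    observed_mz=obs_mz,
                    mass_error_mda=(obs_mz - mz_theo) * 1000.0,
                    peak_height=height,
                    iso_fit_score=score,
                    blank_threshold=thr,
                    ion_formula=ion.hill(),
                    mass_ok=abs(obs_mz - mz_theo) <= criteria.mass_tol,
                    sigma_ok=score < criteria.sigma_max,
                    blank_ok=height > thr,
                )
            )
    return results


def consensus(
    results_by_well: Dict[str, List[MatchResult]],
    manifest: PlateManifest,
    criteria: ScreeningCriteria,
    database: Optional[Sequence[CompoundRecord]] = None,
    include_absent: bool = False,
) -> List[Detection]:
    """Replicate consensus per sample: n detected / n measured.

    ``results_by_well`` maps well_id → match results for ONE polarity. A
    detection is validated iff it passed in every replicate well of the
    sample (all-of-n; reported as n/3 or n/9 depending on the extract × spot
    layout). Compounds whose post-species ion has the same molecular formula
    cannot be distinguished by exact mass + isotope pattern and share one
    isobar group id. With ``include_absent`` and a database, 0/n rows are
    emitted for every screenable compound × species (Table-style reporting).
    """
    samples = manifest.samples()
    polarity: Polarity = "positive"
    for res in results_by_well.values():
        if res:
            polarity = res[0].polarity
            break
    detections: List[Detection] = []
    for sample_id, wells in sorted(samples.items()):
        well_ids = [w.well_id for w in wells]
        measured = [wid for wid in well_ids if wid in results_by_well]
        if not measured:
            continue
        if len(measured) != len(well_ids):
            missing = sorted(set(well_ids) - set(measured))
            raise ValueError(
                f"sample {sample_id}: manifest lists {len(well_ids)} replicate wells "
                f"but no results for {missing}"
            )
        n_measured = len(measured)
        # collect per (compound, species) the passing results per well
        keys: Dict[Tuple[str, str], Dict[str, MatchResult]] = {}
        for wid in measured:
            for r in results_by_well[wid]:
                if r.passed_all:
                    keys.setdefault((r.compound, r.species), {})[wid] = r
        all_keys = dict(keys)
        ion_formula_of: Dict[Tuple[str, str], str] = {
            k: next(iter(v.values())).ion_formula for k, v in keys.items()
        }
        if include_absent and database is not None:
            for comp in database:
                for sp in comp.species_for(polarity):
                    if not sp.applicable_to(comp.formula):
                        continue
                    k = (comp.name, sp.label)
                    if k not in all_keys:
                        all_keys[k] = {}
                        ion_formula_of[k] = apply_species(comp.formula, sp).hill()
        # isobar groups: shared post-species formula within this sample
        groups: Dict[str, List[Tuple[str, str]]] = {}
        for k, hill in ion_formula_of.items():
            groups.setdefault(hill, []).append(k)
        group_id: Dict[Tuple[str, str], str] = {}
        gnum = 0
        for hill in sorted(groups):
            members = groups[hill]
            if len(members) > 1:
                gnum += 1
                for k in members:
                    group_id[k] = f"{sample_id}:iso{gnum}"
        for (comp_name, sp_label) in sorted(all_keys):
            per_well = all_keys[(comp_name, sp_label)]
            n_det = len(per_well)
            if n_det:
                errs = [r.mass_error_mda for r in per_well.values()]
                scores = [r.iso_fit_score for r in per_well.values()]
                mean_err, mean_score = float(np.mean(errs)), float(np.mean(scores))
            else:
                mean_err = mean_score = float("nan")
            validated = n_det == n_measured and n_det > 0
            detections.append(
                Detection(
                    sample_id=sample_id,
                    compound=comp_name,
                    species=sp_label,
                    polarity=polarity,
                    n_detected=n_det,
                    n_measured=n_measured,
                    mean_mass_error_mda=mean_err,
                    mean_score=mean_score,
                    quality_band=criteria.quality_band(mean_score) if n_det else "n/a",
                    validated=validated,
                    isobar_group=group_id.get((comp_name, sp_label), ""),
                    ion_formula=ion_formula_of[(comp_name, sp_label)],
                )
            )
    return detections
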