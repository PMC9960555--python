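"""Plate-level workflow: load → recalibrate → screen → consensus → report.

This is the programmatic face of the screening tool; the CLI is a thin
wrapper around :func:`screen_plate` / :func:`screen_bundle`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from . import __version__
from .calibration import (
    CalibrationModel,
    apply_calibration,
    plate_calibration,
    reference_intensity_rsd,
)
from .chem import Polarity
from .plate import (
    CompoundRecord,
    PlateManifest,
    ReferenceIon,
    default_database,
    default_reference_ions,
    read_manifest,
)
from .screening import Detection, MatchResult, ScreeningCriteria, consensus, screen_well
from .spectra import CentroidSpectrum, read_spectrum

POLARITIES: Tuple[Polarity, Polarity] = ("positive", "negative")


@dataclass
class PolarityResult:
    polarity: Polarity
    calibration: Dict[str, CalibrationModel]
    matches_by_well: Dict[str, List[MatchResult]]
    detections: List[Detection]
    reference_rsd_percent: Optional[float] = None


@dataclass
class ScreenReport:
    """Everything a screening run produced, traceable down to per-well
    match results."""

    manifest: PlateManifest
    criteria: ScreeningCriteria
    per_polarity: Dict[Polarity, PolarityResult]
    seed: Optional[int] = None
    version: str = __version__

    @property
    def detections(self) -> List[Detection]:
        out: List[Detection] = []
        for polarity in POLARITIES:
            if polarity in self.per_polarity:
                out.extend(self.per_polarity[polarity].detections)
        return out

    def validated(self) -> List[Detection]:
        return [d for d in self.detections if d.validated]

    def validated_compounds(self, sample_id: Optional[str] = None) -> set:
        return {
            d.compound
            for d in self.validated()
            if sample_id is None or d.sample_id == sample_id
        }

    def detection_for(
        self, sample_id: str, compound: str, species: str, polarity: Polarity
    ) -> Optional[Detection]:
        for d in self.per_polarity.get(polarity, PolarityResult(polarity, {}, {}, [])).detections:
            if d.sample_id == sample_id and d.compound == compound and d.species == species:
                return d
        return None


def screen_plate(
    spectra: Dict[Tuple[str, Polarity], CentroidSpectrum],
    manifest: PlateManifest,
    database: Optional[Sequence[CompoundRecord]] = None,
    refs: Optional[Sequence[ReferenceIon]] = None,
    criteria: Optional[ScreeningCriteria] = None,
    modes: Sequence[Polarity] = POLARITIES,
    calibration_kind: str = "linear",
    calibration_policy: str = "average",
    include_absent: bool = False,
    seed: Optional[int] = None,
) -> ScreenReport:
    """Run the full screening workflow on in-memory plate spectra.

    Per polarity: fit lock-mass models on the calibrant wells, recalibrate
    every spectrum, compute blank thresholds from the (calibrated) blank
    wells, screen each sample well against the database, then apply the
    all-replicates consensus rule per sample.
    """
    database = list(database) if database is not None else default_database()
    refs = list(refs) if refs is not None else default_reference_ions()
    criteria = criteria or ScreeningCriteria()
    per_polarity: Dict[Polarity, PolarityResult] = {}
    for polarity in modes:
        pol_spectra = {
            wid: s for (wid, p), s in spectra.items() if p == polarity
        }
        if not pol_spectra:
            continue
        models = plate_calibration(
            pol_spectra, manifest, refs, policy=calibration_policy, kind=calibration_kind
        )
        calibrated = {
            wid: apply_calibration(s, models[wid]) for wid, s in pol_spectra.items()
        }
        blank_ids = [w.well_id for w in manifest.by_role("blank") if w.well_id in calibrated]
        blanks = [calibrated[wid] for wid in blank_ids]
        matches: Dict[str, List[MatchResult]] = {}
        for w in manifest.by_role("sample"):
            if w.well_id in calibrated:
                matches[w.well_id] = screen_well(
                    calibrated[w.well_id], database, criteria, blanks
                )
        dets = consensus(matches, manifest, criteria, database=database, include_absent=include_absent)
        per_polarity[polarity] = PolarityResult(
            polarity=polarity,
            calibration=models,
            matches_by_well=matches,
            detections=dets,
            reference_rsd_percent=reference_intensity_rsd(pol_spectra, manifest, refs),
        )
    return ScreenReport(manifest, criteria, per_polarity, seed=seed)


def load_bundle_spectra(
    bundle_dir,
) -> Tuple[PlateManifest, Dict[Tuple[str, Polarity], CentroidSpectrum]]:
    """Read a simulated (or equivalently laid out) plate bundle from disk."""
    bundle = Path(bundle_dir)
    manifest = read_manifest(bundle / "manifest.csv")
    spectra: Dict[Tuple[str, Polarity], CentroidSpectrum] = {}
    spectra_dir = bundle / "spectra"
    for w in manifest.wells:
        for polarity, suffix in (("positive", "pos"), ("negative", "neg")):
            for ext in ("tsv", "mzml", "mzML"):
                path = spectra_dir / f"{w.well_id}_{suffix}.{ext}"
                if path.exists():
                    spectra[(w.well_id, polarity)] = read_spectrum(
                        path, polarity=polarity, well_id=w.well_id
                    )
                    break
    return manifest, spectra


def screen_bundle(bundle_dir, **kwargs) -> ScreenReport:
    manifest, spectra = load_bundle_spectra(bundle_dir)
    return screen_plate(spectra, manifest, **kwargs)
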