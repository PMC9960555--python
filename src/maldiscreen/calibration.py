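"""Internal (lock-mass) recalibration against PFSA reference ions.

Calibrant wells carry a perfluoroalkyl sulfonic acid mixture; each reference
ion is matched to its nearest measured peak within a coarse tolerance and a
low-order polynomial (identity / linear / quadratic) mapping observed m/z to
corrected m/z is least-squares fitted. If fewer references match than the
model order needs, the fit degrades (quadratic → linear → identity) rather
than failing, and screening proceeds with a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .plate import PlateManifest, ReferenceIon
from .spectra import CentroidSpectrum, nearest_peak

logger = logging.getLogger(__name__)

_MIN_REFS = {"identity": 0, "linear": 2, "quadratic": 3}
_DEGREE = {"linear": 1, "quadratic": 2}


@dataclass(frozen=True)
class CalibrationModel:
    """corrected_mz = polyval(coefficients, observed_mz); coefficients in
    ascending power. Identity is (0, 1)."""

    kind: str
    coefficients: Tuple[float, ...]
    n_refs_used: int = 0
    rms_residual: float = 0.0
    polarity: str = "positive"

    @staticmethod
    def identity(polarity: str = "positive") -> "CalibrationModel":
        return CalibrationModel("identity", (0.0, 1.0), 0, 0.0, polarity)

    def predict(self, mz: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(mz, dtype=float), self.coefficients)

    @property
    def is_identity(self) -> bool:
        return self.kind == "identity"


def fit_calibration(
    cal_spectrum: CentroidSpectrum,
    refs: Sequence[ReferenceIon],
    coarse_tol: float = 0.05,
    kind: str = "linear",
) -> CalibrationModel:
    """Fit a recalibration polynomial from one calibrant-well spectrum.

    References are filtered to the spectrum polarity, matched to their nearest
    peak within ``coarse_tol`` (Da), and fitted theoretical-vs-observed. With
    too few matches the model degrades toward identity with a log warning.
    """
    if coarse_tol <= 0:
        raise ValueError("coarse_tol must be positive")
    if kind not in _MIN_REFS:
        raise ValueError(f"unknown calibration kind {kind!r}")
    usable = [r for r in refs if r.polarity == cal_spectrum.polarity]
    obs, theo = [], []
    for r in usable:
        hit = nearest_peak(cal_spectrum, r.mz, coarse_tol)
        if hit is not None:
            obs.append(hit[0])
            theo.append(r.mz)
    n = len(obs)
    eff_kind = kind
    while n < _MIN_REFS[eff_kind]:
        eff_kind = {"quadratic": "linear", "linear": "identity"}[eff_kind]
        logger.warning(
            "well %s (%s): only %d/%d reference ions matched; degrading to %s",
            cal_spectrum.well_id, cal_spectrum.polarity, n, len(usable), eff_kind,
        )
    if eff_kind == "identity":
        if n == 0 and usable:
            logger.warning(
                "well %s: no reference ions matched; spectra remain uncalibrated",
                cal_spectrum.well_id,
            )
        return CalibrationModel.identity(cal_spectrum.polarity)
    obs_a, theo_a = np.array(obs), np.array(theo)
    coef = np.polynomial.polynomial.polyfit(obs_a, theo_a, deg=_DEGREE[eff_kind])
    resid = np.polynomial.polynomial.polyval(obs_a, coef) - theo_a
    return CalibrationModel(
        eff_kind,
        tuple(float(c) for c in coef),
        n_refs_used=n,
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        polarity=cal_spectrum.polarity,
    )


def apply_calibration(s: CentroidSpectrum, m: CalibrationModel) -> CentroidSpectrum:
    """Map every m/z through the model polynomial; intensities untouched.

    The correction must be monotone over the spectrum's m/z range (it always
    is for sane lock-mass fits); a non-monotone mapping raises."""
    if m.polarity and m.polarity != s.polarity:
        raise ValueError(f"model polarity {m.polarity} != spectrum polarity {s.polarity}")
    if len(s) == 0 or m.is_identity:
        return CentroidSpectrum(s.mz.copy(), s.intensity.copy(), s.polarity, s.well_id)
    new_mz = m.predict(s.mz)
    if len(new_mz) > 1 and np.any(np.diff(new_mz) <= 0):
        raise ValueError("calibration model is non-monotone over the spectrum range")
    return CentroidSpectrum(new_mz, s.intensity.copy(), s.polarity, s.well_id)


def _average_models(models: List[CalibrationModel]) -> CalibrationModel:
    width = max(len(m.coefficients) for m in models)
    coefs = np.zeros(width)
    for m in models:
        c = np.zeros(width)
        c[: len(m.coefficients)] = m.coefficients
        coefs += c / len(models)
    kind = max((m.kind for m in models), key=lambda k: _MIN_REFS[k])
    return CalibrationModel(
        kind,
        tuple(float(c) for c in coefs),
        n_refs_used=min(m.n_refs_used for m in models),
        rms_residual=float(np.mean([m.rms_residual for m in models])),
        polarity=models[0].polarity,
    )


def plate_calibration(
    spectra: Dict[str, CentroidSpectrum],
    manifest: PlateManifest,
    refs: Sequence[ReferenceIon],
    policy: str = "average",
    coarse_tol: float = 0.05,
    kind: str = "linear",
) -> Dict[str, CalibrationModel]:
    """Per-well calibration models from the plate's calibrant wells.

    ``spectra`` maps well_id → spectrum for ONE polarity. Policies:
    ``nearest`` (each well uses the closest calibrant well's model, by well
    position), ``average`` (mean of the calibrant models; the default for a
    first/last-well layout), ``first``. With no calibrant wells every well
    gets the identity model and a warning is logged.
    """
    if policy not in ("nearest", "average", "first"):
        raise ValueError(f"unknown policy {policy!r}")
    order = [w.well_id for w in manifest.wells]
    cal_wells = [w.well_id for w in manifest.by_role("calibrant") if w.well_id in spectra]
    if not cal_wells:
        logger.warning("plate %s: no calibrant wells; all spectra uncalibrated", manifest.plate_id)
        return {wid: CalibrationModel.identity(_plate_polarity(spectra)) for wid in spectra}
    models = {wid: fit_calibration(spectra[wid], refs, coarse_tol, kind) for wid in cal_wells}
    if policy == "first":
        chosen = models[cal_wells[0]]
        return {wid: chosen for wid in spectra}
    if policy == "average":
        avg = _average_models([models[w] for w in cal_wells])
        return {wid: avg for wid in spectra}
    # nearest by position in the manifest well order
    pos = {wid: i for i, wid in enumerate(order)}
    out = {}
    for wid in spectra:
        nearest_cal = min(cal_wells, key=lambda c: abs(pos.get(c, 0) - pos.get(wid, 0)))
        out[wid] = models[nearest_cal]
    return out


def _plate_polarity(spectra: Dict[str, CentroidSpectrum]) -> str:
    return next(iter(spectra.values())).polarity if spectra else "positive"


def reference_intensity_rsd(
    spectra: Dict[str, CentroidSpectrum],
    manifest: PlateManifest,
    refs: Sequence[ReferenceIon],
    coarse_tol: float = 0.05,
) -> Optional[float]:
    """Mean over reference ions of the RSD (%) of their matched peak
    intensities across calibrant wells — the between-run/between-plate
    reproducibility figure of merit. None when fewer than 2 calibrant wells
    contribute."""
    cal_wells = [w.well_id for w in manifest.by_role("calibrant") if w.well_id in spectra]
    if len(cal_wells) < 2:
        return None
    polarity = _plate_polarity(spectra)
    rsds = []
    for r in refs:
        if r.polarity != polarity:
            continue
        heights = []
        for wid in cal_wells:
            hit = nearest_peak(spectra[wid], r.mz, coarse_tol)
            if hit is not None:
                heights.append(hit[1])
        if len(heights) >= 2:
            h = np.array(heights)
            if h.mean() > 0:
                rsds.append(100.0 * h.std(ddof=1) / h.mean())
    return float(np.mean(rsds)) if rsds else None
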