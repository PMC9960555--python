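"""Centroided spectra: container, nearest-peak query, TSV and mzML I/O.

TSV peak lists are the fixture-friendly dialect: two numeric columns
(m/z, intensity), tab- or comma-separated, ``#`` comment lines allowed.
mzML support is a self-contained minimal reader/writer pair (uncompressed or
zlib-compressed 32/64-bit float binary arrays, one spectrum per file on the
write side) sufficient for centroided peak lists; it is not a general mzML
implementation.
"""

from __future__ import annotations

import base64
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple
from xml.sax.saxutils import escape

import numpy as np

from .chem import Polarity


class SpectrumError(ValueError):
    """Unreadable, profile-mode or structurally invalid spectrum input."""


@dataclass
class CentroidSpectrum:
    """A centroided (peak-picked) spectrum for one well and polarity."""

    mz: np.ndarray
    intensity: np.ndarray
    polarity: Polarity = "positive"
    well_id: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise SpectrumError("mz and intensity must be 1-D arrays of equal length")
        if np.any(self.intensity < 0):
            raise SpectrumError("negative intensities")
        if len(self.mz) > 1 and np.any(np.diff(self.mz) < 0):
            raise SpectrumError("m/z not sorted; use from_peaks to sort")

    def __len__(self) -> int:
        return len(self.mz)

    @staticmethod
    def from_peaks(
        mz, intensity, polarity: Polarity = "positive", well_id: str = "", warn_unsorted: bool = False
    ) -> "CentroidSpectrum":
        mz = np.asarray(mz, dtype=float)
        intensity = np.asarray(intensity, dtype=float)
        if len(mz) > 1 and np.any(np.diff(mz) < 0):
            if warn_unsorted:
                warnings.warn(f"peak list for {well_id or 'spectrum'} was unsorted; sorting")
            order = np.argsort(mz, kind="stable")
            mz, intensity = mz[order], intensity[order]
        return CentroidSpectrum(mz, intensity, polarity, well_id)


def nearest_peak(
    s: CentroidSpectrum, target_mz: float, tol: float
) -> Optional[Tuple[float, float]]:
    """The peak minimizing |mz − target| among peaks within ±tol, or None.

    Ties on distance are broken by higher intensity, then lower m/z. Total on
    empty spectra (returns None).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if len(s) == 0:
        return None
    lo = int(np.searchsorted(s.mz, target_mz - tol, side="left"))
    hi = int(np.searchsorted(s.mz, target_mz + tol, side="right"))
    best: Optional[Tuple[float, float]] = None
    best_key = None
    for i in range(lo, hi):
        d = abs(s.mz[i] - target_mz)
        if d > tol:
            continue
        key = (d, -s.intensity[i], s.mz[i])
        if best_key is None or key < best_key:
            best_key = key
            best = (float(s.mz[i]), float(s.intensity[i]))
    return best


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def read_tsv_spectrum(
    path, polarity: Polarity = "positive", well_id: str = ""
) -> CentroidSpectrum:
    """Two numeric columns (m/z, intensity), tab or comma separated; ``#``
    comments skipped. Duplicate m/z rows are kept as-is (the reader is
    faithful); unsorted input is sorted with a warning."""
    mzs: List[float] = []
    ints: List[float] = []
    text = Path(path).read_text()
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split(",")
        if len(parts) < 2:
            raise SpectrumError(f"{path}:{ln}: expected two columns, got {line!r}")
        try:
            mzs.append(float(parts[0]))
            ints.append(float(parts[1]))
        except ValueError as e:
            raise SpectrumError(f"{path}:{ln}: {e}") from None
    return CentroidSpectrum.from_peaks(
        mzs, ints, polarity, well_id or Path(path).stem, warn_unsorted=True
    )


def write_tsv_spectrum(path, s: CentroidSpectrum) -> None:
    lines = [f"# well={s.well_id} polarity={s.polarity}", "# mz\tintensity"]
    for mz, inten in zip(s.mz, s.intensity):
        lines.append(f"{mz:.6f}\t{inten:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------

def _encode64(arr: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{len(arr)}d", *arr)).decode("ascii")


_MZML_TEMPLATE = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <run id="{run_id}">
    <spectrumList count="1" defaultDataProcessingRef="dp">
      <spectrum index="0" id="well={well_id}" defaultArrayLength="{n}">
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <cvParam cvRef="MS" accession="{pol_acc}" name="{pol_name}" value=""/>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len_mz}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{b64_mz}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len_int}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{b64_int}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
    </spectrumList>
  </run>
</mzML>
"""


def write_mzml_spectrum(path, s: CentroidSpectrum) -> None:
    """Write one centroided spectrum as minimal uncompressed mzML."""
    b64_mz = _encode64(s.mz)
    b64_int = _encode64(s.intensity)
    pol_acc, pol_name = (
        ("MS:1000130", "positive scan")
        if s.polarity == "positive"
        else ("MS:1000129", "negative scan")
    )
    Path(path).write_text(
        _MZML_TEMPLATE.format(
            run_id=escape(s.well_id or "run"),
            well_id=escape(s.well_id or "0"),
            n=len(s),
            pol_acc=pol_acc,
            pol_name=pol_name,
            len_mz=len(b64_mz),
            b64_mz=b64_mz,
            len_int=len(b64_int),
            b64_int=b64_int,
        )
    )


_ACC_CENTROID = "MS:1000127"
_ACC_PROFILE = "MS:1000128"
_ACC_NEGATIVE = "MS:1000129"
_ACC_POSITIVE = "MS:1000130"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"


def _decode_binary_array(bda) -> np.ndarray:
    import zlib

    accs = {cv.get("accession") for cv in bda if cv.tag.endswith("cvParam")}
    binary = None
    for child in bda:
        if child.tag.endswith("binary"):
            binary = child.text or ""
    raw = base64.b64decode(binary)
    if _ACC_ZLIB in accs:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_F32 in accs else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml_spectrum(path, well_id: str = "") -> CentroidSpectrum:
    """Read the first spectrum of an mzML file.

    Handles uncompressed or zlib-compressed 32/64-bit float m/z and intensity
    arrays. Profile-mode spectra are rejected: screening operates on
    centroided data only."""
    from xml.etree import ElementTree

    try:
        root = ElementTree.parse(str(path)).getroot()
    except ElementTree.ParseError as e:
        raise SpectrumError(f"{path}: not parseable mzML: {e}") from None
    spectrum_el = None
    for el in root.iter():
        if el.tag.endswith("}spectrum") or el.tag == "spectrum":
            spectrum_el = el
            break
    if spectrum_el is None:
        raise SpectrumError(f"{path}: no spectra found")
    accs = {
        cv.get("accession")
        for cv in spectrum_el.iter()
        if cv.tag.endswith("cvParam")
    }
    if _ACC_PROFILE in accs or _ACC_CENTROID not in accs:
        raise SpectrumError(f"{path}: spectrum is not centroided")
    polarity: Polarity = "negative" if _ACC_NEGATIVE in accs else "positive"
    mz = intensity = None
    for bda in spectrum_el.iter():
        if not bda.tag.endswith("binaryDataArray"):
            continue
        arr_accs = {cv.get("accession") for cv in bda if cv.tag.endswith("cvParam")}
        if _ACC_MZ_ARRAY in arr_accs:
            mz = _decode_binary_array(bda)
        elif _ACC_INT_ARRAY in arr_accs:
            intensity = _decode_binary_array(bda)
    if mz is None or intensity is None:
        raise SpectrumError(f"{path}: missing m/z or intensity array")
    sid = str(spectrum_el.get("id", ""))
    if not well_id and sid.startswith("well="):
        well_id = sid.split("=", 1)[1]
    return CentroidSpectrum.from_peaks(mz, intensity, polarity, well_id, warn_unsorted=True)


def read_spectrum(
    path, dialect: Optional[str] = None, polarity: Polarity = "positive", well_id: str = ""
) -> CentroidSpectrum:
    """Dispatch on dialect ('mzml' | 'tsv'; inferred from the suffix if None).

    For TSV the polarity must be supplied (sidecar/manifest knowledge); for
    mzML it is taken from the file metadata.
    """
    p = Path(path)
    if dialect is None:
        dialect = "mzml" if p.suffix.lower() == ".mzml" else "tsv"
    dialect = dialect.lower()
    if dialect == "mzml":
        return read_mzml_spectrum(p, well_id=well_id)
    if dialect == "tsv":
        return read_tsv_spectrum(p, polarity=polarity, well_id=well_id)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_spectrum(path, s: CentroidSpectrum, dialect: Optional[str] = None) -> None:
    p = Path(path)
    if dialect is None:
        dialect = "mzml" if p.suffix.lower() == ".mzml" else "tsv"
    if dialect.lower() == "mzml":
        write_mzml_spectrum(p, s)
    else:
        write_tsv_spectrum(p, s)
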