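"""Report writers: detections TSV, audit JSON (schema-validated), RSD TSV.

The detections table mirrors the times-detected-per-times-measured (n/3,
n/9) presentation used when reporting plate screening results; the audit
JSON keeps every per-well match (pass or fail) so each validated detection
is traceable to the replicate-level evidence behind it.
"""

from __future__ import annotations

import dataclasses
import json
import math
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .rsd import ReplicateHeights, extract_to_extract_rsd, spot_to_spot_rsd
from .workflow import ScreenReport


def detections_frame(report: ScreenReport, validated_only: bool = False) -> pd.DataFrame:
    rows = []
    for d in report.detections:
        if validated_only and not d.validated:
            continue
        rows.append(
            {
                "sample_id": d.sample_id,
                "compound": d.compound,
                "species": d.species,
                "polarity": d.polarity,
                "detected": d.times_detected,
                "validated": d.validated,
                "mean_mass_error_mda": round(d.mean_mass_error_mda, 3)
                if math.isfinite(d.mean_mass_error_mda)
                else "",
                "mean_score": round(d.mean_score, 2) if math.isfinite(d.mean_score) else "",
                "quality_band": d.quality_band,
                "confidence_level": d.confidence_level,
                "isobar_group": d.isobar_group,
                "ion_formula": d.ion_formula,
            }
        )
    return pd.DataFrame(rows)


def write_detections_tsv(path, report: ScreenReport, validated_only: bool = False) -> None:
    detections_frame(report, validated_only).to_csv(path, sep="\t", index=False)


def report_to_dict(report: ScreenReport) -> dict:
    per_pol = {}
    for polarity, res in report.per_polarity.items():
        per_pol[polarity] = {
            "calibration": {
                wid: {
                    "kind": m.kind,
                    "coefficients": list(m.coefficients),
                    "n_refs_used": m.n_refs_used,
                    "rms_residual": m.rms_residual,
                }
                for wid, m in sorted(res.calibration.items())
            },
            "reference_rsd_percent": res.reference_rsd_percent,
            "matches": [
                {**dataclasses.asdict(r), "passed_all": r.passed_all}
                for wid in sorted(res.matches_by_well)
                for r in res.matches_by_well[wid]
            ],
            "detections": [dataclasses.asdict(d) for d in res.detections],
        }
    return {
        "version": report.version,
        "seed": report.seed,
        "plate_id": report.manifest.plate_id,
        "criteria": dataclasses.asdict(report.criteria),
        "polarities": per_pol,
    }


def write_audit_json(path, report: ScreenReport) -> None:
    obj = report_to_dict(report)
    validate_report(obj)
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=_jsonify) + "\n")


def _jsonify(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, tuple):
        return list(x)
    raise TypeError(f"not JSON serializable: {type(x)}")


def load_schema() -> dict:
    return json.loads(
        resources.files("maldiscreen.data").joinpath("report_schema.json").read_text()
    )


def validate_report(obj: dict, schema: Optional[dict] = None, path: str = "$") -> None:
    """Validate an audit-report object against the shipped structural schema
    (a minimal required-keys/type check, not full JSON Schema)."""
    schema = schema if schema is not None else load_schema()
    _validate(obj, schema, path)


_TYPES = {"object": dict, "array": list, "string": str, "number": (int, float), "integer": int, "boolean": bool}


def _validate(obj, schema: dict, path: str) -> None:
    t = schema.get("type")
    if t:
        if obj is None and schema.get("nullable"):
            return
        if not isinstance(obj, _TYPES[t]) or (t == "number" and isinstance(obj, bool)):
            raise ValueError(f"{path}: expected {t}, got {type(obj).__name__}")
    for key, sub in schema.get("properties", {}).items():
        if key in schema.get("required", []) and key not in obj:
            raise ValueError(f"{path}: missing required key {key!r}")
        if key in obj:
            _validate(obj[key], sub, f"{path}.{key}")
    if "items" in schema and isinstance(obj, list):
        for i, item in enumerate(obj):
            _validate(item, schema["items"], f"{path}[{i}]")
    if "additionalValues" in schema and isinstance(obj, dict):
        for k, v in obj.items():
            _validate(v, schema["additionalValues"], f"{path}.{k}")


# ---------------------------------------------------------------------------
# RSD table from screening results
# ---------------------------------------------------------------------------

def replicate_heights_from_report(report: ScreenReport) -> Dict[str, List[ReplicateHeights]]:
    """Arrange per-well passing peak heights into extract × spot matrices,
    one per sample × compound × species × polarity."""
    out: Dict[str, List[ReplicateHeights]] = {}
    wells_by_sample = report.manifest.samples()
    for polarity, res in report.per_polarity.items():
        for sample_id, wells in sorted(wells_by_sample.items()):
            extracts = sorted({w.extract for w in wells})
            spots_per_extract = {
                e: sorted(w.well_id for w in wells if w.extract == e) for e in extracts
            }
            n_spots = max(len(v) for v in spots_per_extract.values())
            keys = sorted(
                {
                    (r.compound, r.species)
                    for w in wells
                    for r in res.matches_by_well.get(w.well_id, [])
                    if r.passed_all
                }
            )
            for comp, species in keys:
                mat = np.full((len(extracts), n_spots), np.nan)
                for ei, e in enumerate(extracts):
                    for si, wid in enumerate(spots_per_extract[e]):
                        for r in res.matches_by_well.get(wid, []):
                            if r.compound == comp and r.species == species and r.passed_all:
                                mat[ei, si] = r.peak_height
                out.setdefault(sample_id, []).append(
                    ReplicateHeights(mat, compound=comp, species=f"{species} ({polarity})")
                )
    return out


def rsd_frame(report: ScreenReport, ddof: int = 1) -> pd.DataFrame:
    rows = []
    for sample_id, hs in replicate_heights_from_report(report).items():
        for h in hs:
            spot = spot_to_spot_rsd(h, ddof=ddof)
            ext = extract_to_extract_rsd(h, ddof=ddof)
            rows.append(
                {
                    "sample_id": sample_id,
                    "compound": h.compound,
                    "species": h.species,
                    "spot_to_spot_rsd": round(spot.value, 2) if spot.value is not None else "n/a",
                    "spot_n": f"{spot.effective_n}/{spot.nominal_n}",
                    "spot_note": spot.note,
                    "extract_to_extract_rsd": round(ext.value, 2) if ext.value is not None else "n/a",
                    "extract_n": f"{ext.effective_n}/{ext.nominal_n}",
                    "extract_note": ext.note,
                }
            )
    return pd.DataFrame(rows)


def write_rsd_tsv(path, report: ScreenReport, ddof: int = 1) -> None:
    rsd_frame(report, ddof=ddof).to_csv(path, sep="\t", index=False)
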