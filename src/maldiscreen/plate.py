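"""Plate manifests, the suspect compound database, and PFSA reference ions.

The manifest maps wells to roles (blank / calibrant / sample) following the
48-well plate layout with the calibrant mix in the first and last well and
three blanks per plate. The compound database is a CSV suspect list (name,
CAS, formula, class, per-mode ion-species labels); formulas and species are
parsed eagerly so malformed rows fail at load time with their line number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .chem import (
    Formula,
    FormulaError,
    IonSpecies,
    Polarity,
    default_species,
    monoisotopic_mass,
    parse_formula,
    parse_species,
)


class ManifestError(ValueError):
    pass


class DatabaseError(ValueError):
    pass


@dataclass(frozen=True)
class WellInfo:
    well_id: str
    role: str  # blank | calibrant | sample
    sample_id: str = ""
    replicate: int = 0
    extract: int = 1


@dataclass
class PlateManifest:
    wells: List[WellInfo]
    plate_id: str = "plate"

    def __post_init__(self) -> None:
        roles = {w.role for w in self.wells}
        bad = roles - {"blank", "calibrant", "sample"}
        if bad:
            raise ManifestError(f"unknown roles: {sorted(bad)}")

    def by_role(self, role: str) -> List[WellInfo]:
        return [w for w in self.wells if w.role == role]

    def samples(self) -> Dict[str, List[WellInfo]]:
        out: Dict[str, List[WellInfo]] = {}
        for w in self.wells:
            if w.role == "sample" and w.sample_id:
                out.setdefault(w.sample_id, []).append(w)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "well_id": w.well_id,
                    "role": w.role,
                    "sample_id": w.sample_id,
                    "replicate": w.replicate,
                    "extract": w.extract,
                }
                for w in self.wells
            ]
        )


MANIFEST_COLUMNS = ("well_id", "role", "sample_id", "replicate")


def read_manifest(path) -> PlateManifest:
    df = pd.read_csv(path, dtype={"well_id": str, "sample_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"{path}: missing manifest columns {missing}")
    wells = []
    for i, row in df.iterrows():
        sample_id = row["sample_id"]
        sample_id = "" if pd.isna(sample_id) else str(sample_id)
        rep = row["replicate"]
        wells.append(
            WellInfo(
                well_id=str(row["well_id"]),
                role=str(row["role"]).strip().lower(),
                sample_id=sample_id,
                replicate=0 if pd.isna(rep) else int(rep),
                extract=int(row["extract"]) if "extract" in df.columns and not pd.isna(row.get("extract")) else 1,
            )
        )
    return PlateManifest(wells, plate_id=Path(path).stem)


def write_manifest(path, manifest: PlateManifest) -> None:
    manifest.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Compound database
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompoundRecord:
    """One suspect-list entry. ``pos_species``/``neg_species`` of None mean
    "use the mode-wide default species set" for that polarity."""

    name: str
    cas: str
    formula: Formula
    compound_class: str = ""
    pos_species: Optional[Tuple[IonSpecies, ...]] = None
    neg_species: Optional[Tuple[IonSpecies, ...]] = None

    def species_for(self, polarity: Polarity) -> List[IonSpecies]:
        explicit = self.pos_species if polarity == "positive" else self.neg_species
        if explicit is None:
            return default_species(polarity)
        return list(explicit)


DATABASE_COLUMNS = ("name", "cas", "formula", "class", "pos_species", "neg_species")


def _parse_species_cell(cell, polarity: Polarity, where: str):
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() == "":
        return None
    out = []
    for lbl in str(cell).split(";"):
        lbl = lbl.strip()
        if not lbl:
            continue
        try:
            out.append(parse_species(lbl, polarity))
        except FormulaError as e:
            raise DatabaseError(f"{where}: bad species label {lbl!r}: {e}") from None
    return tuple(out) if out else None


def read_database(path) -> List[CompoundRecord]:
    df = pd.read_csv(path)
    missing = [c for c in DATABASE_COLUMNS if c not in df.columns]
    if missing:
        raise DatabaseError(f"{path}: missing database columns {missing}")
    records: List[CompoundRecord] = []
    for i, row in df.iterrows():
        where = f"{path}:row {i + 2}"  # header is line 1
        try:
            formula = parse_formula(str(row["formula"]))
        except FormulaError as e:
            raise DatabaseError(f"{where}: {e}") from None
        records.append(
            CompoundRecord(
                name=str(row["name"]),
                cas=str(row["cas"]),
                formula=formula,
                compound_class="" if pd.isna(row["class"]) else str(row["class"]),
                pos_species=_parse_species_cell(row["pos_species"], "positive", where),
                neg_species=_parse_species_cell(row["neg_species"], "negative", where),
            )
        )
    return records


def default_database() -> List[CompoundRecord]:
    """The bundled suspect list: a small emulation of a merged
    flame-retardant + plastic-additive database with the adduct and
    in-source-fragment chemistry typical of AP-MALDI screening."""
    with resources.as_file(
        resources.files("maldiscreen.data").joinpath("default_suspects.csv")
    ) as p:
        return read_database(p)


# ---------------------------------------------------------------------------
# PFSA reference ions (lock masses)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceIon:
    label: str
    polarity: Polarity
    mz: float


_PFSA = {"C4": "C4HF9O3S", "C6": "C6HF13O3S", "C8": "C8HF17O3S"}


def default_reference_ions() -> List[ReferenceIon]:
    """Default lock-mass list computed from the C4/C6/C8 perfluoroalkyl
    sulfonic acids.

    Negative mode: the three [M−H]− monomers plus proton-bound dimers
    [2M−H]− (spanning roughly m/z 299–1037). Positive mode: PFSAs are poor
    positive-mode ionizers, so the shipped positive list ([M+H]+ of C6/C8 and
    [2M+H]+ of all three, spanning roughly m/z 377–1115) is a repository
    convention intended for use with the matching synthetic calibrant wells;
    replace it with your instrument's reference list for real data.
    """
    h = monoisotopic_mass(parse_formula("H"))
    refs: List[ReferenceIon] = []
    for name, formula in _PFSA.items():
        m = monoisotopic_mass(parse_formula(formula))
        refs.append(ReferenceIon(f"{name} [M-H]-", "negative", m - h))
        refs.append(ReferenceIon(f"{name} [2M-H]-", "negative", 2 * m - h))
    for name in ("C6", "C8"):
        m = monoisotopic_mass(parse_formula(_PFSA[name]))
        refs.append(ReferenceIon(f"{name} [M+H]+", "positive", m + h))
    for name, formula in _PFSA.items():
        m = monoisotopic_mass(parse_formula(formula))
        refs.append(ReferenceIon(f"{name} [2M+H]+", "positive", 2 * m + h))
    return sorted(refs, key=lambda r: (r.polarity, r.mz))


def read_reference_ions(path) -> List[ReferenceIon]:
    """TSV config: columns label, polarity, mz."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("label", "polarity", "mz"):
        if col not in df.columns:
            raise ManifestError(f"{path}: missing reference-ion column {col!r}")
    return [
        ReferenceIon(str(r["label"]), str(r["polarity"]), float(r["mz"]))
        for _, r in df.iterrows()
    ]


def write_reference_ions(path, refs: Sequence[ReferenceIon]) -> None:
    lines = ["label\tpolarity\tmz"]
    for r in refs:
        lines.append(f"{r.label}\t{r.polarity}\t{r.mz:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
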