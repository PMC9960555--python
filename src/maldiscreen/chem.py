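"""Molecular formula arithmetic and the ion-species grammar.

A :class:`Formula` is an element→count map; an :class:`IonSpecies` is a label
like ``"M+K"`` or ``"M-C6H2Br3-H"`` describing the signed formula deltas that
turn a neutral compound into one screenable singly-charged ion. Monoisotopic
masses come from the bundled isotope table (see :mod:`maldiscreen.isotopes`).

By default no electron-mass correction is applied to theoretical m/z values:
for singly charged ions the correction (≈0.55 mDa) is far inside the 5 mDa
screening tolerance, and omitting it reproduces the conventional
neutral-fragment values printed in the suspect-screening literature. Pass
``electron_correction=True`` to :func:`theoretical_mz` to subtract/add one
electron mass for positive/negative ions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Literal, Tuple

from .isotopes import ELEMENTS, monoisotopic_mass_of_element

ELECTRON_MASS = 0.000548579909065  # u (CODATA)

Polarity = Literal["positive", "negative"]

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed formula string or unknown element symbol."""


class InapplicableSpecies(ValueError):
    """Species deltas would drive some element count negative."""


@dataclass(frozen=True)
class Formula:
    """An elemental composition (no charge, no isotope labelling beyond
    pseudo-elements like ``D``)."""

    counts: Tuple[Tuple[str, int], ...] = ()

    @staticmethod
    def from_counts(counts: Dict[str, int]) -> "Formula":
        items = tuple(sorted((el, int(n)) for el, n in counts.items() if n != 0))
        for el, n in items:
            if el not in ELEMENTS:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if n < 0:
                raise FormulaError(f"negative count for {el}: {n}")
        return Formula(items)

    @staticmethod
    def parse(text: str) -> "Formula":
        """Parse a Hill-style formula string, e.g. ``"C18H15O4P"``."""
        if not isinstance(text, str) or not text.strip():
            raise FormulaError("empty formula string")
        text = text.strip()
        counts: Dict[str, int] = {}
        pos = 0
        for m in _TOKEN_RE.finditer(text):
            if m.start() != pos:
                raise FormulaError(f"malformed formula {text!r} at offset {pos}")
            el, num = m.group(1), m.group(2)
            if el not in ELEMENTS:
                raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
            pos = m.end()
        if pos != len(text):
            raise FormulaError(f"malformed formula {text!r} at offset {pos}")
        return Formula.from_counts(counts)

    def as_dict(self) -> Dict[str, int]:
        return dict(self.counts)

    def __add__(self, other: "Formula") -> "Formula":
        c = self.as_dict()
        for el, n in other.counts:
            c[el] = c.get(el, 0) + n
        return Formula.from_counts(c)

    def __sub__(self, other: "Formula") -> "Formula":
        c = self.as_dict()
        for el, n in other.counts:
            c[el] = c.get(el, 0) - n
            if c[el] < 0:
                raise InapplicableSpecies(
                    f"removing {other.hill()} from {self.hill()} gives negative {el}"
                )
        return Formula.from_counts(c)

    def n_atoms(self) -> int:
        return sum(n for _, n in self.counts)

    def hill(self) -> str:
        """Hill notation: C first, then H, then other elements alphabetically;
        without carbon all elements are alphabetical."""
        c = self.as_dict()
        parts: List[str] = []
        order: List[str] = []
        if "C" in c:
            order.append("C")
            if "H" in c:
                order.append("H")
            order += sorted(el for el in c if el not in ("C", "H"))
        else:
            order = sorted(c)
        for el in order:
            n = c[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> Formula:
    """Module-level alias for :meth:`Formula.parse`."""
    return Formula.parse(text)


def monoisotopic_mass(f: Formula) -> float:
    """Sum of count × most-abundant-isotope mass; the empty formula has mass 0."""
    return sum(n * monoisotopic_mass_of_element(el) for el, n in f.counts)


# ---------------------------------------------------------------------------
# Ion-species grammar
# ---------------------------------------------------------------------------

_SPECIES_RE = re.compile(r"^M((?:[+\-][A-Za-z0-9]+)*)$")
_DELTA_RE = re.compile(r"([+\-])([A-Za-z0-9]+)")


@dataclass(frozen=True)
class IonSpecies:
    """A signed sequence of formula deltas applied to the neutral molecule M.

    The grammar makes no chemical distinction between adducts, in-source
    fragments and oxidation products ("M+O+K"): screening only needs the mass
    of the resulting composition. Charge magnitude is fixed at 1.
    """

    deltas: Tuple[Tuple[int, Formula], ...]  # (+1 | -1, delta formula)
    polarity: Polarity = "positive"

    @property
    def label(self) -> str:
        out = ["M"]
        for sign, f in self.deltas:
            out.append(("+" if sign > 0 else "-") + f.hill())
        return "".join(out)

    def apply(self, base: Formula) -> Formula:
        out = base
        for sign, f in self.deltas:
            out = out + f if sign > 0 else out - f
        return out

    def applicable_to(self, base: Formula) -> bool:
        try:
            self.apply(base)
            return True
        except InapplicableSpecies:
            return False

    def __str__(self) -> str:  # pragma: no cover
        sign = "+" if self.polarity == "positive" else "-"
        return f"[{self.label}]{sign}"


def parse_species(label: str, polarity: Polarity = "positive") -> IonSpecies:
    """Parse a species label such as ``"M+O+K"`` or ``"M-C6H2Br3-H"``.

    Unicode minus (``−``) is accepted as a synonym for ``-``. The label
    round-trips: ``parse_species(x).label`` is the canonical (Hill-per-delta)
    spelling of ``x``.
    """
    if polarity not in ("positive", "negative"):
        raise ValueError(f"polarity must be positive|negative, got {polarity!r}")
    norm = label.strip().replace("−", "-").replace(" ", "")
    m = _SPECIES_RE.match(norm)
    if not m:
        raise FormulaError(f"malformed species label {label!r}")
    deltas = []
    for sign, text in _DELTA_RE.findall(m.group(1)):
        deltas.append((1 if sign == "+" else -1, Formula.parse(text)))
    return IonSpecies(tuple(deltas), polarity)


def apply_species(base: Formula, s: IonSpecies) -> Formula:
    """Element-wise application of the species deltas to a neutral formula.

    Raises :class:`InapplicableSpecies` if any count would go negative (for
    example ``M-C6H5`` applied to ethane)."""
    return s.apply(base)


def theoretical_mz(base: Formula, s: IonSpecies, electron_correction: bool = False) -> float:
    """Theoretical m/z for the singly charged ion ``s`` of ``base``.

    With ``electron_correction=False`` (default) this is simply the
    monoisotopic mass of the post-species composition.
    """
    mass = monoisotopic_mass(apply_species(base, s))
    if electron_correction:
        mass += ELECTRON_MASS if s.polarity == "negative" else -ELECTRON_MASS
    return mass


#: Mode-wide default species screened when a compound record lists none.
DEFAULT_POSITIVE_SPECIES = ("M+H", "M+K", "M+Na")
DEFAULT_NEGATIVE_SPECIES = ("M-H",)


def default_species(polarity: Polarity) -> List[IonSpecies]:
    labels = DEFAULT_POSITIVE_SPECIES if polarity == "positive" else DEFAULT_NEGATIVE_SPECIES
    return [parse_species(lbl, polarity) for lbl in labels]
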