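"""Isotope table and isotope-pattern (isotopologue distribution) computation.

The fine-structure distribution is computed exactly by convolution: each
element's n-atom distribution is built by binary-exponentiation convolution of
the single-atom isotope distribution (tracking isotope-count tuples, so
isotopologues that coincide in composition are summed exactly), and elements
are then combined by Cartesian convolution with a hard probability floor.
Centroided instruments do not resolve fine structure, so for screening the
exact distribution is collapsed to a resolution-merged, pruned, renormalized
:class:`IsotopePattern`.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Sequence, Tuple

import numpy as np

_HARD_FLOOR = 1e-15  # absolute probability floor during convolution


def _load_table() -> Dict[str, List[Tuple[float, float]]]:
    table: Dict[str, List[Tuple[float, float]]] = {}
    text = resources.files("maldiscreen.data").joinpath("isotopes.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        el, _nominal, mass, ab = line.split("\t")
        table.setdefault(el, []).append((float(mass), float(ab)))
    for el, isos in table.items():
        total = sum(a for _, a in isos)
        if not (0.999 < total < 1.001):
            raise ValueError(f"isotope abundances for {el} sum to {total}")
        isos.sort()  # ascending mass; lightest first
    return table


#: element symbol -> list of (isotope mass, abundance), ascending mass
ISOTOPES: Dict[str, List[Tuple[float, float]]] = _load_table()
ELEMENTS = frozenset(ISOTOPES)


def monoisotopic_mass_of_element(el: str) -> float:
    """Mass of the element's most abundant isotope."""
    return max(ISOTOPES[el], key=lambda t: t[1])[0]


def _convolve_counts(
    a: Dict[Tuple[int, ...], float], b: Dict[Tuple[int, ...], float]
) -> Dict[Tuple[int, ...], float]:
    out: Dict[Tuple[int, ...], float] = {}
    for ka, pa in a.items():
        for kb, pb in b.items():
            p = pa * pb
            if p < _HARD_FLOOR:
                continue
            key = tuple(x + y for x, y in zip(ka, kb))
            out[key] = out.get(key, 0.0) + p
    return out


@functools.lru_cache(maxsize=4096)
def _element_distribution(el: str, n: int) -> Tuple[Tuple[float, float], ...]:
    """(mass, probability) of the isotopologues of n atoms of one element,
    computed by binary-exponentiation convolution over isotope-count tuples."""
    isos = ISOTOPES[el]
    k = len(isos)
    single = {tuple(1 if j == i else 0 for j in range(k)): ab for i, (_, ab) in enumerate(isos)}
    result = {tuple(0 for _ in range(k)): 1.0}
    power = single
    m = n
    while m:
        if m & 1:
            result = _convolve_counts(result, power)
        m >>= 1
        if m:
            power = _convolve_counts(power, power)
    masses = [m_ for m_, _ in isos]
    out = []
    for key, p in result.items():
        mass = sum(c * mm for c, mm in zip(key, masses))
        out.append((mass, p))
    out.sort()
    return tuple(out)


def isotopologue_distribution(formula, floor: float = 1e-13) -> List[Tuple[float, float]]:
    """Exact (mass, probability) isotopologue list of a formula, unmerged.

    ``floor`` drops cross-element combinations with probability below it;
    probabilities are NOT renormalized here.
    """
    dist: List[Tuple[float, float]] = [(0.0, 1.0)]
    for el, n in formula.counts:
        el_dist = _element_distribution(el, n)
        nxt: Dict[float, float] = {}
        for m1, p1 in dist:
            for m2, p2 in el_dist:
                p = p1 * p2
                if p < floor:
                    continue
                key = m1 + m2
                nxt[key] = nxt.get(key, 0.0) + p
        dist = sorted(nxt.items())
    return dist


def merge_by_resolution(
    peaks: Sequence[Tuple[float, float]], resolution: float
) -> List[Tuple[float, float]]:
    """Greedy left-to-right merge of peaks whose gap to the running
    intensity-weighted centroid is below half the FWHM (m/z ÷ R ÷ 2), so a
    merged cluster spans at most about one FWHM."""
    merged: List[Tuple[float, float]] = []
    for mz, inten in sorted(peaks):
        if merged:
            cmz, cint = merged[-1]
            if mz - cmz < (mz / resolution) / 2.0:
                tot = cint + inten
                merged[-1] = ((cmz * cint + mz * inten) / tot, tot)
                continue
        merged.append((mz, inten))
    return merged


@dataclass(frozen=True)
class IsotopePattern:
    """Resolution-merged, pruned, renormalized isotope pattern.

    ``mz`` ascending; ``rel_intensity`` sums to 1 over retained peaks. The
    first peak is the monoisotopic peak for CHNOPS/halogen chemistry (lightest
    isotope of every supported element is also its most abundant).
    """

    mz: Tuple[float, ...]
    rel_intensity: Tuple[float, ...]

    def __len__(self) -> int:
        return len(self.mz)

    def peaks(self) -> List[Tuple[float, float]]:
        return list(zip(self.mz, self.rel_intensity))

    @property
    def monoisotopic_mz(self) -> float:
        return self.mz[0]

    def base_peak_index(self) -> int:
        return int(np.argmax(self.rel_intensity))


def isotope_pattern(
    formula, prune: float = 1e-4, resolution: float = 25000.0
) -> IsotopePattern:
    """Isotope pattern of a formula at instrument resolution.

    Parameters
    ----------
    formula : Formula
    prune : relative-probability threshold; isotopologues below it are
        dropped before merging (default 1e-4 keeps Br4 envelopes complete).
    resolution : FWHM resolving power, treated as constant across m/z
        (TOF-like); merged peaks are closer than (m/z / R) / 2.
    """
    if not (0.0 < prune <= 0.01):
        raise ValueError(f"prune must be in (0, 0.01], got {prune}")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    dist = isotopologue_distribution(formula)
    if not dist:
        raise ValueError("empty isotopologue distribution")
    pmax = max(p for _, p in dist)
    kept = [(m, p) for m, p in dist if p >= prune * pmax]
    merged = merge_by_resolution(kept, resolution)
    total = sum(p for _, p in merged)
    mzs = tuple(m for m, _ in merged)
    rel = tuple(p / total for _, p in merged)
    return IsotopePattern(mzs, rel)
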