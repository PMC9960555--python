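"""Spot-to-spot and extract-to-extract relative standard deviations.

Peak heights for one compound × species are arranged as an extract × spot
matrix (NaN = non-detect). The extract-to-extract RSD is the RSD over the
per-extract mean heights (n = number of extracts); the spot-to-spot RSD is
the mean over extracts of the within-extract RSD across spots, with the
effective n reported alongside because non-detects are excluded rather than
zero-filled (an n=9 design with one missed spot is flagged n=8).

Standard deviations use the sample (n−1) denominator; set ``ddof=0`` for the
population convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np


@dataclass
class ReplicateHeights:
    """Heights indexed (extract, spot); NaN marks a non-detect."""

    heights: np.ndarray
    compound: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2-D (extract x spot) matrix")
        if np.any(self.heights[np.isfinite(self.heights)] <= 0):
            raise ValueError("detected heights must be positive")

    @property
    def n_extracts(self) -> int:
        return self.heights.shape[0]

    @property
    def n_spots(self) -> int:
        return self.heights.shape[1]


@dataclass(frozen=True)
class RsdResult:
    value: Optional[float]  # percent, None = n/a
    effective_n: int
    nominal_n: int
    note: str = ""


def _rsd(values: np.ndarray, ddof: int) -> float:
    if len(values) < 2:
        raise ValueError("need >= 2 values for an RSD")
    mean = values.mean()
    return float(100.0 * values.std(ddof=ddof) / mean)


def extract_to_extract_rsd(h: ReplicateHeights, ddof: int = 1) -> RsdResult:
    """RSD over the per-extract mean heights (n = E). n/a for E < 2 or when
    an extract has no detected spot at all."""
    means = []
    for e in range(h.n_extracts):
        row = h.heights[e][np.isfinite(h.heights[e])]
        if len(row) > 0:
            means.append(row.mean())
    nominal = h.n_extracts
    if len(means) < 2:
        return RsdResult(None, len(means), nominal, "n/a: fewer than 2 extracts with detections")
    note = "" if len(means) == nominal else f"based on n={len(means)} extracts instead of n={nominal}"
    return RsdResult(_rsd(np.array(means), ddof), len(means), nominal, note)


def spot_to_spot_rsd(h: ReplicateHeights, ddof: int = 1) -> RsdResult:
    """Mean over extracts of the within-extract RSD across spots.

    Extracts with fewer than 2 detected spots are dropped with a note; the
    effective total spot count (e.g. n=8 instead of n=9) is reported."""
    rsds = []
    n_eff = 0
    dropped = 0
    for e in range(h.n_extracts):
        row = h.heights[e][np.isfinite(h.heights[e])]
        if len(row) >= 2:
            rsds.append(_rsd(row, ddof))
            n_eff += len(row)
        else:
            dropped += 1
    nominal = h.n_extracts * h.n_spots
    if not rsds:
        return RsdResult(None, 0, nominal, "n/a: no extract with >= 2 detected spots")
    note = ""
    if n_eff != nominal:
        note = f"based on n={n_eff} instead of n={nominal}"
        if dropped:
            note += f"; {dropped} extract(s) dropped"
    return RsdResult(float(np.mean(rsds)), n_eff, nominal, note)
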