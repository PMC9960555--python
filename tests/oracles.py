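"""Independent brute-force / closed-form oracles used to check the package's
convolution-based isotope computation. Kept deliberately separate from the
implementation: the multinomial probability mass function is evaluated
directly from factorials, and for tiny molecules every per-atom isotope
assignment is enumerated exhaustively."""

import itertools
import math
from collections import defaultdict

from maldiscreen.isotopes import ISOTOPES


def _compositions(n, k):
    """All tuples of k non-negative integers summing to n."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, k - 1):
            yield (first,) + rest


def multinomial_isotopologues(formula, floor=0.0):
    """Exact isotopologue (mass, probability) list via the closed-form
    multinomial distribution per element, combined across elements."""
    dist = [(0.0, 1.0)]
    for el, n in formula.counts:
        isos = ISOTOPES[el]
        el_dist = []
        for comp in _compositions(n, len(isos)):
            coef = math.factorial(n)
            p = 1.0
            mass = 0.0
            for c, (m, ab) in zip(comp, isos):
                coef //= math.factorial(c)
                p *= ab**c
                mass += c * m
            el_dist.append((mass, coef * p))
        nxt = defaultdict(float)
        for m1, p1 in dist:
            for m2, p2 in el_dist:
                nxt[m1 + m2] += p1 * p2
        dist = sorted(nxt.items())
    return [(m, p) for m, p in dist if p >= floor]


def per_atom_isotopologues(formula):
    """Exhaustive enumeration over every individual atom's isotope choice;
    only feasible for a handful of atoms."""
    atoms = []
    for el, n in formula.counts:
        atoms.extend([ISOTOPES[el]] * n)
    dist = defaultdict(float)
    for choice in itertools.product(*atoms):
        mass = sum(m for m, _ in choice)
        prob = math.prod(a for _, a in choice)
        dist[round(mass, 9)] += prob
    return sorted(dist.items())
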