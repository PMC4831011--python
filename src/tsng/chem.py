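"""Elemental compositions and isotopic-envelope arithmetic.

Monoisotopic masses and isotopic abundances follow the IUPAC/CODATA
recommended values.  Masses are in dalton (Da); the charge carrier used
throughout the package is a sodium cation, so singly charged ion masses
subtract one electron mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Tuple

import numpy as np

__all__ = [
    "ELECTRON_MASS",
    "ElementalComposition",
    "IsotopePattern",
    "isotope_pattern",
    "monoisotopic_mass",
]

ELECTRON_MASS = 0.000548579909  # Da

# element -> list of (isotope mass [Da], abundance), most abundant first,
# ordered by neutron number.
ISOTOPES: Mapping[str, Tuple[Tuple[float, float], ...]] = {
    "C": ((12.0, 0.9893), (13.003354838, 0.0107)),
    "H": ((1.007825032, 0.999885), (2.014101778, 0.000115)),
    "N": ((14.003074005, 0.99636), (15.000108899, 0.00364)),
    "O": ((15.994914620, 0.99757), (16.999131757, 0.00038), (17.999159613, 0.00205)),
    "Na": ((22.989769282, 1.0),),
}

MONOISOTOPIC: Mapping[str, float] = {el: iso[0][0] for el, iso in ISOTOPES.items()}


@dataclass(frozen=True)
class ElementalComposition:
    """Integer atom counts per chemical element.

    Addition and integer scaling are supported so residue formulas can be
    summed; all counts must be non-negative.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {el: int(n) for el, n in self.counts.items() if n != 0}
        for el, n in clean.items():
            if el not in ISOTOPES:
                raise ValueError(f"unknown element {el!r}")
            if n < 0:
                raise ValueError(f"negative count for element {el!r}")
        object.__setattr__(self, "counts", clean)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalComposition(merged)

    def __mul__(self, k: int) -> "ElementalComposition":
        return ElementalComposition({el: n * k for el, n in self.counts.items()})

    __rmul__ = __mul__

    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    def formula(self) -> str:
        order = ["C", "H", "N", "O", "Na"]
        parts = []
        for el in order:
            n = self.counts.get(el, 0)
            if n:
                parts.append(f"{el}{n}" if n > 1 else el)
        for el in sorted(set(self.counts) - set(order)):
            parts.append(f"{el}{self.counts[el]}")
        return "".join(parts)

    def monoisotopic_mass(self) -> float:
        return sum(MONOISOTOPIC[el] * n for el, n in self.counts.items())


def monoisotopic_mass(comp: ElementalComposition) -> float:
    """Monoisotopic (lightest-isotopologue) mass of a neutral formula, Da."""
    return comp.monoisotopic_mass()


@dataclass(frozen=True)
class IsotopePattern:
    """Aggregated isotopic envelope of a formula.

    Isotopologues are binned by nominal neutron shift; each retained peak
    carries the abundance-weighted centroid m/z of its bin.  ``fraction``
    holds the raw fractions of the full (untruncated) distribution; the
    ``renormalised`` property rescales them to sum to 1 over the retained
    peaks.
    """

    mz: Tuple[float, ...]
    fraction: Tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.mz) != len(self.fraction):
            raise ValueError("mz and fraction length mismatch")
        if any(b <= a for a, b in zip(self.mz, self.mz[1:])):
            raise ValueError("m/z values must be strictly increasing")

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def renormalised(self) -> Tuple[float, ...]:
        total = sum(self.fraction)
        return tuple(f / total for f in self.fraction)

    @property
    def coverage(self) -> float:
        """Summed raw fraction of the retained peaks."""
        return float(sum(self.fraction))


def _element_distribution(el: str, n: int, prune: float) -> Dict[int, Tuple[float, float]]:
    """Distribution of (neutron shift -> (probability, mean mass)) for n atoms.

    Built by binary exponentiation of the single-atom distribution; bins with
    probability below ``prune`` are dropped.
    """
    isotopes = ISOTOPES[el]
    base_mass = isotopes[0][0]
    single: Dict[int, Tuple[float, float]] = {}
    for mass, ab in isotopes:
        shift = int(round(mass - base_mass))
        p, m = single.get(shift, (0.0, 0.0))
        single[shift] = (p + ab, m + ab * mass)
    single = {s: (p, m / p) for s, (p, m) in single.items()}

    result: Dict[int, Tuple[float, float]] = {0: (1.0, 0.0)}
    power = single
    k = n
    while k:
        if k & 1:
            result = _convolve(result, power, prune)
        k >>= 1
        if k:
            power = _convolve(power, power, prune)
    return result


def _convolve(
    a: Dict[int, Tuple[float, float]],
    b: Dict[int, Tuple[float, float]],
    prune: float,
) -> Dict[int, Tuple[float, float]]:
    out: Dict[int, List[float]] = {}
    for sa, (pa, ma) in a.items():
        for sb, (pb, mb) in b.items():
            p = pa * pb
            if p < prune:
                continue
            acc = out.setdefault(sa + sb, [0.0, 0.0])
            acc[0] += p
            acc[1] += p * (ma + mb)
    return {s: (p, m / p) for s, (p, m) in out.items()}


def isotope_pattern(
    comp: ElementalComposition,
    min_cumulative_fraction: float = 1.0,
    extra_mass: float = 0.0,
    prune: float = 1e-15,
) -> IsotopePattern:
    """Aggregated isotope pattern of a neutral formula.

    Parameters
    ----------
    comp
        Elemental composition of the species.
    min_cumulative_fraction
        Peaks are retained, in m/z order, until their cumulative raw
        fraction reaches this value (1.0 keeps everything above ``prune``).
    extra_mass
        Constant added to every peak m/z, e.g. ``-ELECTRON_MASS`` for a
        singly charged cation whose adduct is already part of ``comp``.
    """
    if not 0 < min_cumulative_fraction <= 1:
        raise ValueError("min_cumulative_fraction must be in (0, 1]")
    total: Dict[int, Tuple[float, float]] = {0: (1.0, 0.0)}
    for el, n in comp.counts.items():
        total = _convolve(total, _element_distribution(el, n, prune), prune)
    shifts = sorted(total)
    mzs, fracs = [], []
    cum = 0.0
    for s in shifts:
        p, m = total[s]
        mzs.append(m + extra_mass)
        fracs.append(p)
        cum += p
        if cum >= min_cumulative_fraction:
            break
    return IsotopePattern(tuple(mzs), tuple(fracs))
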