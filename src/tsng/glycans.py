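"""Glycan compositions, derivatisation-aware masses and structure features.

Compositions use the single-letter code common in released-N-glycome
MALDI work on ethyl-esterified glycans:

* ``H`` hexose, ``N`` N-acetylhexosamine, ``F`` fucose (deoxyhexose),
* ``E`` alpha2,6-linked N-acetylneuraminic acid, stabilised as an ethyl
  ester (residue gains C2H4),
* ``L`` alpha2,3-linked N-acetylneuraminic acid, driven to the
  intramolecular lactone (residue loses H2O).

All ions are singly charged sodium adducts ([M+Na]+) of glycans with a
free (unreduced, unlabelled) reducing end.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .chem import ELECTRON_MASS, ElementalComposition, IsotopePattern, isotope_pattern

__all__ = [
    "GlycanComposition",
    "StructureAssignment",
    "GlycanParseError",
    "StructureError",
    "LibraryEntry",
    "parse_composition",
    "elemental_composition",
    "monoisotopic_mz",
    "glycan_isotope_pattern",
    "assign_structure",
    "default_library",
    "generate_library",
    "write_library",
    "read_library",
]

# Residue (in-chain, i.e. dehydrated) formulas.
RESIDUES: Mapping[str, ElementalComposition] = {
    "H": ElementalComposition({"C": 6, "H": 10, "O": 5}),   # hexose
    "N": ElementalComposition({"C": 8, "H": 13, "N": 1, "O": 5}),  # HexNAc
    "F": ElementalComposition({"C": 6, "H": 10, "O": 4}),   # deoxyhexose
    # NeuAc residue C11H17NO8 + C2H4 (ethyl ester, alpha2,6)
    "E": ElementalComposition({"C": 13, "H": 21, "N": 1, "O": 8}),
    # NeuAc residue C11H17NO8 - H2O (lactone, alpha2,3)
    "L": ElementalComposition({"C": 11, "H": 15, "N": 1, "O": 7}),
}

WATER = ElementalComposition({"H": 2, "O": 1})
SODIUM = ElementalComposition({"Na": 1})

_LETTERS = "HNFEL"
_TOKEN = re.compile(r"([A-Za-z])(\d*)")


class GlycanParseError(ValueError):
    pass


class StructureError(ValueError):
    """No structural interpretation satisfies the feature constraints."""

    def __init__(self, message: str, rejected: Sequence[str] = ()):  # noqa: D107
        super().__init__(message)
        self.rejected = tuple(rejected)


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Counts of monosaccharide residues (H, N, F, E, L)."""

    hex: int = 0
    hexnac: int = 0
    fuc: int = 0
    neuac_26: int = 0  # E
    neuac_23: int = 0  # L

    def __post_init__(self) -> None:
        for name in ("hex", "hexnac", "fuc", "neuac_26", "neuac_23"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} count must be >= 0")
        if self.total_residues < 1:
            raise ValueError("composition must contain at least one residue")

    @property
    def total_residues(self) -> int:
        return self.hex + self.hexnac + self.fuc + self.neuac_26 + self.neuac_23

    @property
    def counts(self) -> Dict[str, int]:
        return {
            "H": self.hex,
            "N": self.hexnac,
            "F": self.fuc,
            "E": self.neuac_26,
            "L": self.neuac_23,
        }

    def __str__(self) -> str:
        return "".join(
            f"{letter}{n}" for letter, n in self.counts.items() if n > 0
        )

    @classmethod
    def from_string(cls, code: str) -> "GlycanComposition":
        return parse_composition(code)


def parse_composition(code: str) -> GlycanComposition:
    """Parse a single-letter composition string such as ``"H5N4F1E2L1"``.

    Letters must come from {H, N, F, E, L}, each followed by its count and
    appearing at most once.
    """
    if not code or not code.strip():
        raise GlycanParseError("empty composition string")
    code = code.strip()
    pos = 0
    seen: Dict[str, int] = {}
    while pos < len(code):
        m = _TOKEN.match(code, pos)
        if not m or m.start() != pos:
            raise GlycanParseError(f"unparseable token at {code[pos:]!r}")
        letter, digits = m.group(1).upper(), m.group(2)
        if letter not in _LETTERS:
            raise GlycanParseError(f"unknown monosaccharide letter {m.group(1)!r}")
        if not digits:
            raise GlycanParseError(f"missing count after letter {letter!r}")
        if letter in seen:
            raise GlycanParseError(f"duplicate letter {letter!r}")
        seen[letter] = int(digits)
        pos = m.end()
    return GlycanComposition(
        hex=seen.get("H", 0),
        hexnac=seen.get("N", 0),
        fuc=seen.get("F", 0),
        neuac_26=seen.get("E", 0),
        neuac_23=seen.get("L", 0),
    )


def elemental_composition(
    g: GlycanComposition, reducing_end: str = "free", adduct: str = "sodium"
) -> ElementalComposition:
    """Neutral-molecule-plus-adduct elemental composition of a glycan ion.

    The free reducing end adds one water to the summed residue formulas; the
    sodium charge carrier adds one Na (charge is handled at the m/z level).
    """
    if reducing_end != "free":
        raise ValueError(f"unsupported reducing end {reducing_end!r}")
    if adduct != "sodium":
        raise ValueError(f"unsupported adduct {adduct!r}")
    total = ElementalComposition({})
    for letter, n in g.counts.items():
        if n:
            total = total + n * RESIDUES[letter]
    return total + WATER + SODIUM


def monoisotopic_mz(g: GlycanComposition) -> float:
    """Monoisotopic m/z of the singly charged [M+Na]+ ion, Da."""
    return elemental_composition(g).monoisotopic_mass() - ELECTRON_MASS


@lru_cache(maxsize=4096)
def glycan_isotope_pattern(
    g: GlycanComposition, min_cumulative_fraction: float = 1.0
) -> IsotopePattern:
    """Aggregated isotopic envelope of the [M+Na]+ ion of a glycan."""
    return isotope_pattern(
        elemental_composition(g),
        min_cumulative_fraction=min_cumulative_fraction,
        extra_mass=-ELECTRON_MASS,
    )


@dataclass(frozen=True)
class StructureAssignment:
    """Structural features of the most common structure for a composition.

    Derived traits are computed from these feature counts, not from
    topology: for a complex glycan the antennae (A) and galactoses (G)
    follow from the HexNAc and hexose counts once a bisecting GlcNAc is
    (or is not) assumed.
    """

    glycan_class: str  # oligomannose | hybrid | complex
    antennae: int = 0
    galactoses: int = 0
    bisected: bool = False
    core_fucoses: int = 0
    antenna_fucoses: int = 0
    sialic_23: int = 0
    sialic_26: int = 0

    def __post_init__(self) -> None:
        if self.glycan_class not in ("oligomannose", "hybrid", "complex"):
            raise ValueError(f"unknown glycan class {self.glycan_class!r}")
        if self.glycan_class == "complex":
            if self.antennae not in (2, 3, 4):
                raise ValueError("complex glycans have 2-4 antennae")
            if not 0 <= self.galactoses <= self.antennae:
                raise ValueError("galactoses must lie in [0, antennae]")
            if self.sialic_23 + self.sialic_26 > self.galactoses:
                raise ValueError("sialic acids cannot exceed galactoses")

    @property
    def fucoses(self) -> int:
        return self.core_fucoses + self.antenna_fucoses


def _complex_features(
    g: GlycanComposition, bisected: bool
) -> Optional[StructureAssignment]:
    a = g.hexnac - (3 if bisected else 2)
    gal = g.hex - 3
    if not (2 <= a <= 4 and 0 <= gal <= a):
        return None
    if g.neuac_26 + g.neuac_23 > gal:
        return None
    # Fucose placement: the first fucose of a di-antennary glycan is core;
    # extra fucoses are antenna fucoses.  A single fucose on a tri/tetra-
    # antennary glycan is an antenna fucose when alpha2,3-sialylation is
    # present (sialyl-Lewis context), else core.
    core_f = antenna_f = 0
    if g.fuc:
        if a >= 3 and g.neuac_23 >= 1:
            antenna_f = g.fuc
        else:
            core_f = 1
            antenna_f = g.fuc - 1
    return StructureAssignment(
        glycan_class="complex",
        antennae=a,
        galactoses=gal,
        bisected=bisected,
        core_fucoses=core_f,
        antenna_fucoses=antenna_f,
        sialic_23=g.neuac_23,
        sialic_26=g.neuac_26,
    )


def assign_structure(g: GlycanComposition) -> StructureAssignment:
    """Most-common-structure feature assignment for a composition.

    Compositions are classified by HexNAc count: N=2 with H>=4 and no
    further decoration is oligomannosidic, N=3 is hybrid, N>=4 is complex.
    For complex glycans the bisected reading (A=N-3) is preferred over the
    non-bisected one (A=N-2) whenever it satisfies the feature constraints,
    reflecting that e.g. H5N5 is far more commonly a bisected diantennary
    glycan than a truncated triantennary one.
    """
    if g.hexnac == 2:
        if g.hex >= 4 and g.fuc == 0 and g.neuac_26 == 0 and g.neuac_23 == 0:
            return StructureAssignment(glycan_class="oligomannose")
        raise StructureError(
            f"{g}: N=2 composition is not a plausible oligomannose glycan"
        )
    if g.hexnac == 3:
        sial = g.neuac_26 + g.neuac_23
        if g.hex < 3 or sial > 1 or g.fuc > 1 or (sial and g.hex < 5):
            raise StructureError(f"{g}: not a plausible hybrid glycan")
        return StructureAssignment(
            glycan_class="hybrid",
            antennae=1,
            galactoses=1 if sial else max(0, min(1, g.hex - 4)),
            core_fucoses=min(g.fuc, 1),
            sialic_23=g.neuac_23,
            sialic_26=g.neuac_26,
        )
    if g.hexnac >= 4:
        bis = _complex_features(g, bisected=True)
        if bis is not None:
            return bis
        non = _complex_features(g, bisected=False)
        if non is not None:
            return non
        raise StructureError(
            f"{g}: neither bisected (A={g.hexnac - 3}) nor non-bisected "
            f"(A={g.hexnac - 2}) complex reading satisfies the constraints",
            rejected=("bisected", "non-bisected"),
        )
    raise StructureError(f"{g}: fewer than two HexNAc residues")


@dataclass(frozen=True)
class LibraryEntry:
    composition: GlycanComposition
    structure: StructureAssignment
    mz: float

    @property
    def name(self) -> str:
        return str(self.composition)


def _sial_pairs(max_total: int) -> List[Tuple[int, int]]:
    return [
        (e, l)
        for e in range(max_total + 1)
        for l in range(max_total + 1 - e)
    ]


def generate_library(
    antennae: Sequence[int] = (2, 3, 4),
    max_fucoses: Mapping[int, int] | None = None,
    allow_bisection: bool = True,
    sialylation: str = "EL",
    include_oligomannose: bool = True,
    include_hybrids: bool = True,
    mz_range: Tuple[float, float] = (1000.0, 5000.0),
    galactoses: Mapping[int, Sequence[int]] | None = None,
) -> List[LibraryEntry]:
    """Combinatorial serum-plausible analyte library.

    Enumerates oligomannose H4-H9, hybrid, and complex compositions over
    the requested antennarity/fucosylation/sialylation space, keeps those
    passing :func:`assign_structure` and the m/z range, deduplicates and
    sorts by m/z.

    ``sialylation`` selects the allowed sialic-acid letters ("E", "L" or
    "EL"); ``galactoses`` optionally restricts the galactose counts per
    antennarity (default: 0..A, but tetraantennary glycans are restricted
    to the highly galactosylated forms seen in serum).
    """
    max_fucoses = dict(max_fucoses or {2: 2, 3: 1, 4: 1})
    comps: List[GlycanComposition] = []
    if include_oligomannose:
        comps += [GlycanComposition(hex=h, hexnac=2) for h in range(4, 10)]
    if include_hybrids:
        for h, f in itertools.product((4, 5, 6), range(2)):
            comps.append(GlycanComposition(hex=h, hexnac=3, fuc=f))
            if h >= 5:
                if "E" in sialylation:
                    comps.append(
                        GlycanComposition(hex=h, hexnac=3, fuc=f, neuac_26=1)
                    )
                if "L" in sialylation:
                    comps.append(
                        GlycanComposition(hex=h, hexnac=3, fuc=f, neuac_23=1)
                    )
    for a in antennae:
        if galactoses and a in galactoses:
            gal_range: Sequence[int] = galactoses[a]
        elif a == 4:
            gal_range = (3, 4)
        else:
            gal_range = range(a + 1)
        bis_options = (False, True) if (allow_bisection and a <= 3) else (False,)
        for gal, bis, f in itertools.product(
            gal_range, bis_options, range(max_fucoses.get(a, 1) + 1)
        ):
            if a == 4 and gal < 3:
                continue
            pairs = _sial_pairs(gal)
            if a == 4:
                pairs = [p for p in pairs if sum(p) >= gal - 1]
            for e, l in pairs:
                if "E" not in sialylation and e:
                    continue
                if "L" not in sialylation and l:
                    continue
                n = a + (3 if bis else 2)
                comps.append(
                    GlycanComposition(
                        hex=3 + gal, hexnac=n, fuc=f, neuac_26=e, neuac_23=l
                    )
                )
    entries: Dict[str, LibraryEntry] = {}
    for g in comps:
        try:
            s = assign_structure(g)
        except StructureError:
            continue
        mz = monoisotopic_mz(g)
        if not mz_range[0] <= mz <= mz_range[1]:
            continue
        entries.setdefault(str(g), LibraryEntry(g, s, mz))
    return sorted(entries.values(), key=lambda e: e.mz)


def default_library() -> List[LibraryEntry]:
    """Default serum N-glycome analyte library (initial extraction list)."""
    return generate_library()


LIBRARY_COLUMNS = [
    "composition",
    "class",
    "antennae",
    "galactoses",
    "bisected",
    "core_fucose",
    "antenna_fucose",
    "E",
    "L",
    "mz_theoretical",
]


def write_library(entries: Iterable[LibraryEntry], path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(LIBRARY_COLUMNS)
        for e in entries:
            s = e.structure
            w.writerow(
                [
                    e.name,
                    s.glycan_class,
                    s.antennae,
                    s.galactoses,
                    int(s.bisected),
                    s.core_fucoses,
                    s.antenna_fucoses,
                    s.sialic_26,
                    s.sialic_23,
                    f"{e.mz:.4f}",
                ]
            )


def read_library(path) -> List[LibraryEntry]:
    """Read an analyte library written by :func:`write_library`.

    Structure features and the theoretical m/z are recomputed from the
    composition, so hand-edited composition lists (one composition per
    row) are accepted as long as the ``composition`` column is present.
    """
    import csv

    entries: List[LibraryEntry] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "composition" not in reader.fieldnames:
            raise ValueError(f"{path}: missing 'composition' column")
        for row in reader:
            g = parse_composition(row["composition"])
            entries.append(LibraryEntry(g, assign_structure(g), monoisotopic_mz(g)))
    return sorted(entries, key=lambda e: e.mz)
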