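"""Relative quantification and derived glycosylation traits.

A derived trait summarises the relative-abundance profile over all
compositions sharing a structural feature.  Two kinds exist:

* ``proportion`` — the percentage of the denominator's abundance carried
  by compositions satisfying the numerator predicate (e.g. ``F``:
  fucosylated fraction of complex glycans);
* ``per_antenna`` — the abundance-weighted mean of ``feature / antennae``
  within the denominator, as a percentage (e.g. ``AG``: galactoses per
  antenna of complex glycans).  Sialylation traits also divide by the
  antenna count, so a fully alpha2,6-sialylated diantennary profile has
  ``A2E`` = 100.

Traits whose denominator has zero abundance are undefined and propagate
as missing values (never as zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .glycans import LibraryEntry, StructureAssignment

__all__ = [
    "TraitDefinition",
    "normalize",
    "trait_value",
    "compute_traits",
    "trait_catalogue",
    "feature_fractions",
    "replicate_rsd",
    "write_catalogue",
    "read_catalogue",
]

_ALLOWED_NAMES = {"cls", "A", "G", "B", "Fc", "Fa", "Ftot", "E", "L", "S"}


def _env(s: StructureAssignment) -> Dict[str, object]:
    return {
        "cls": s.glycan_class,
        "A": s.antennae,
        "G": s.galactoses,
        "B": s.bisected,
        "Fc": s.core_fucoses,
        "Fa": s.antenna_fucoses,
        "Ftot": s.fucoses,
        "E": s.sialic_26,
        "L": s.sialic_23,
        "S": s.sialic_26 + s.sialic_23,
    }


def _evaluate(expr: str, s: StructureAssignment) -> bool:
    code = compile(expr, "<selector>", "eval")
    for name in code.co_names:
        if name not in _ALLOWED_NAMES:
            raise ValueError(f"selector {expr!r} uses unknown name {name!r}")
    return bool(eval(code, {"__builtins__": {}}, _env(s)))


@dataclass(frozen=True)
class TraitDefinition:
    """A named derived trait over structure features.

    ``denominator`` and ``numerator`` are boolean expressions over the
    feature names cls, A, G, B, Fc, Fa, Ftot, E, L, S;
    ``feature`` names the per-antenna feature count for per_antenna kind
    ("galactoses", "sialic_26" or "sialic_23").
    """

    name: str
    kind: str                       # "proportion" | "per_antenna"
    denominator: str
    numerator: str = ""
    feature: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("proportion", "per_antenna"):
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if self.kind == "proportion" and not self.numerator:
            raise ValueError(f"{self.name}: proportion trait needs a numerator")
        if self.kind == "per_antenna" and self.feature not in (
            "galactoses",
            "sialic_26",
            "sialic_23",
        ):
            raise ValueError(f"{self.name}: invalid per-antenna feature")


def normalize(areas: Mapping[str, float], sample_id: str = "") -> pd.Series:
    """Total-area normalisation to relative abundances in percent."""
    ser = pd.Series(dict(areas), dtype=float)
    total = ser.sum()
    if not total > 0:
        raise ValueError(f"{sample_id or 'profile'}: non-positive total area")
    out = 100.0 * ser / total
    out.name = sample_id or None
    return out


def feature_fractions(
    d: TraitDefinition, library: Sequence[LibraryEntry]
) -> Tuple[np.ndarray, np.ndarray]:
    """Denominator mask and per-entry numerator value over a library.

    For proportion traits the value is the 0/1 numerator indicator; for
    per-antenna traits it is ``feature / antennae``.  Used both for trait
    evaluation and by the cohort simulator's profile tilts.
    """
    mask = np.array([_evaluate(d.denominator, e.structure) for e in library])
    if d.kind == "proportion":
        x = np.array(
            [float(_evaluate(d.numerator, e.structure)) for e in library]
        )
    else:
        x = np.array(
            [
                getattr(e.structure, d.feature) / e.structure.antennae
                if e.structure.antennae
                else 0.0
                for e in library
            ]
        )
    return mask, x


def trait_value(
    profile: pd.Series,
    d: TraitDefinition,
    library: Sequence[LibraryEntry],
) -> float:
    """Evaluate one trait on a relative-abundance profile (percent).

    Only library entries present in the profile contribute.  Returns NaN
    when the denominator abundance is zero (undefined, not 0).
    """
    lib = [e for e in library if e.name in profile.index]
    mask, x = feature_fractions(d, lib)
    rel = profile.reindex([e.name for e in lib]).to_numpy(dtype=float)
    denom = rel[mask].sum()
    if denom == 0 or not np.isfinite(denom):
        return float("nan")
    return float(100.0 * np.sum(rel[mask] * x[mask]) / denom)


def compute_traits(
    profile: pd.Series,
    library: Sequence[LibraryEntry],
    catalogue: Optional[Sequence[TraitDefinition]] = None,
) -> pd.Series:
    catalogue = catalogue if catalogue is not None else trait_catalogue()
    values = {d.name: trait_value(profile, d, library) for d in catalogue}
    return pd.Series(values, name=profile.name)


def replicate_rsd(values: Sequence[float]) -> float:
    """Relative standard deviation (%) across technical replicates."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two replicates")
    mean = arr.mean()
    if mean == 0:
        return float("nan")
    return float(100.0 * arr.std(ddof=1) / mean)


_COMPLEX = "cls == 'complex'"


def _prop(name, denom, num, desc) -> TraitDefinition:
    return TraitDefinition(name, "proportion", denom, numerator=num, description=desc)


def _pa(name, denom, feature, desc) -> TraitDefinition:
    return TraitDefinition(name, "per_antenna", denom, feature=feature, description=desc)


def trait_catalogue() -> List[TraitDefinition]:
    """The default 42-trait catalogue.

    Contains the class fractions, antennarity, fucosylation, bisection and
    antenna-fucosylation traits plus the per-antenna galactosylation and
    linkage-specific sialylation traits over the systematic denominator
    grammar {all complex, A2, A3, A4} x {any, fucosylated, non-fucosylated}.
    """
    cx = _COMPLEX
    a2 = f"{cx} and A == 2"
    a3 = f"{cx} and A == 3"
    a4 = f"{cx} and A == 4"
    defs: List[TraitDefinition] = [
        _prop("M", "True", "cls == 'oligomannose'", "oligomannose fraction of all glycans"),
        _prop("Hy", "True", "cls == 'hybrid'", "hybrid fraction of all glycans"),
        _prop("A2", cx, "A == 2", "diantennary fraction of complex glycans"),
        _prop("A3", cx, "A == 3", "triantennary fraction of complex glycans"),
        _prop("A4", cx, "A == 4", "tetraantennary fraction of complex glycans"),
        _prop("F", cx, "Ftot >= 1", "fucosylation of complex glycans"),
        _prop("A2F", a2, "Ftot >= 1", "fucosylation of diantennary glycans"),
        _prop("A3F", a3, "Ftot >= 1", "fucosylation of triantennary glycans"),
        _prop("A4F", a4, "Ftot >= 1", "fucosylation of tetraantennary glycans"),
        _prop("Fa", cx, "Fa >= 1", "antenna fucosylation of complex glycans"),
        _prop("B", cx, "B", "bisection of complex glycans"),
        _prop("A2B", a2, "B", "bisection of diantennary glycans"),
        _prop("A2FB", f"{a2} and Ftot >= 1", "B", "bisection of diantennary fucosylated glycans"),
        _prop("A2F0B", f"{a2} and Ftot == 0", "B", "bisection of diantennary non-fucosylated glycans"),
        _pa("AG", cx, "galactoses", "galactosylation of complex glycans per antenna"),
        _pa("A2G", a2, "galactoses", "galactosylation of diantennary glycans"),
        _pa("A2FG", f"{a2} and Ftot >= 1", "galactoses", "galactosylation of diantennary fucosylated glycans"),
        _pa("A2F0G", f"{a2} and Ftot == 0", "galactoses", "galactosylation of diantennary non-fucosylated glycans"),
        _pa("A3G", a3, "galactoses", "galactosylation of triantennary glycans"),
        _pa("A3FG", f"{a3} and Ftot >= 1", "galactoses", "galactosylation of triantennary fucosylated glycans"),
        _pa("A3F0G", f"{a3} and Ftot == 0", "galactoses", "galactosylation of triantennary non-fucosylated glycans"),
        _pa("A4G", a4, "galactoses", "galactosylation of tetraantennary glycans"),
        _pa("A4FG", f"{a4} and Ftot >= 1", "galactoses", "galactosylation of tetraantennary fucosylated glycans"),
        _pa("AE", cx, "sialic_26", "alpha2,6-sialylation of complex glycans per antenna"),
        _pa("A2E", a2, "sialic_26", "alpha2,6-sialylation of diantennary glycans"),
        _pa("A2FE", f"{a2} and Ftot >= 1", "sialic_26", "alpha2,6-sialylation of diantennary fucosylated glycans"),
        _pa("A2F0E", f"{a2} and Ftot == 0", "sialic_26", "alpha2,6-sialylation of diantennary non-fucosylated glycans"),
        _pa("A3E", a3, "sialic_26", "alpha2,6-sialylation of triantennary glycans"),
        _pa("A3FE", f"{a3} and Ftot >= 1", "sialic_26", "alpha2,6-sialylation of triantennary fucosylated glycans"),
        _pa("A3F0E", f"{a3} and Ftot == 0", "sialic_26", "alpha2,6-sialylation of triantennary non-fucosylated glycans"),
        _pa("A4E", a4, "sialic_26", "alpha2,6-sialylation of tetraantennary glycans"),
        _pa("A4FE", f"{a4} and Ftot >= 1", "sialic_26", "alpha2,6-sialylation of tetraantennary fucosylated glycans"),
        _pa("AL", cx, "sialic_23", "alpha2,3-sialylation of complex glycans per antenna"),
        _pa("A2L", a2, "sialic_23", "alpha2,3-sialylation of diantennary glycans"),
        _pa("A2FL", f"{a2} and Ftot >= 1", "sialic_23", "alpha2,3-sialylation of diantennary fucosylated glycans"),
        _pa("A2F0L", f"{a2} and Ftot == 0", "sialic_23", "alpha2,3-sialylation of diantennary non-fucosylated glycans"),
        _pa("A3L", a3, "sialic_23", "alpha2,3-sialylation of triantennary glycans"),
        _pa("A3FL", f"{a3} and Ftot >= 1", "sialic_23", "alpha2,3-sialylation of triantennary fucosylated glycans"),
        _pa("A3F0L", f"{a3} and Ftot == 0", "sialic_23", "alpha2,3-sialylation of triantennary non-fucosylated glycans"),
        _pa("A4L", a4, "sialic_23", "alpha2,3-sialylation of tetraantennary glycans"),
        _pa("A4FL", f"{a4} and Ftot >= 1", "sialic_23", "alpha2,3-sialylation of tetraantennary fucosylated glycans"),
        _pa("A4F0L", f"{a4} and Ftot == 0", "sialic_23", "alpha2,3-sialylation of tetraantennary non-fucosylated glycans"),
    ]
    names = [d.name for d in defs]
    assert len(names) == len(set(names)), "duplicate trait names"
    return defs


CATALOGUE_COLUMNS = ["name", "kind", "denominator", "numerator", "feature", "description"]


def write_catalogue(catalogue: Sequence[TraitDefinition], path) -> None:
    pd.DataFrame(
        [
            {
                "name": d.name,
                "kind": d.kind,
                "denominator": d.denominator,
                "numerator": d.numerator,
                "feature": d.feature,
                "description": d.description,
            }
            for d in catalogue
        ]
    ).to_csv(path, index=False)


def read_catalogue(path) -> List[TraitDefinition]:
    df = pd.read_csv(path).fillna("")
    return [
        TraitDefinition(
            name=row["name"],
            kind=row["kind"],
            denominator=row["denominator"],
            numerator=row.get("numerator", ""),
            feature=row.get("feature", ""),
            description=row.get("description", ""),
        )
        for _, row in df.iterrows()
    ]
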