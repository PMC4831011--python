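"""Text-based (x,y) spectrum files and the sample manifest.

Spectra are the flat text export common to MALDI-TOF workflows: one
``m/z<TAB>intensity`` pair per line.  Intensities may dip below zero
(baseline-subtracted exports); m/z must be strictly increasing after
parsing, which is enforced by a stable sort with duplicate averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectrumParseError",
    "read_spectrum",
    "write_spectrum",
    "TIME_POINTS",
    "read_manifest",
    "write_manifest",
    "validate_manifest",
]

TIME_POINTS = ("trim1", "trim2", "trim3", "wpp6", "wpp12", "wpp26plus", "control")


class SpectrumParseError(ValueError):
    pass


@dataclass(frozen=True)
class Spectrum:
    """An ordered (m/z, intensity) series with calibration state."""

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    calibrated: bool = False
    calibration_coeffs: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.ndim != 1 or inten.ndim != 1 or mz.size != inten.size:
            raise ValueError("mz and intensity must be equal-length 1-D arrays")
        if mz.size < 2:
            raise ValueError("a spectrum needs at least two points")
        if not np.all(np.diff(mz) > 0):
            raise ValueError("m/z must be strictly increasing")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def mz_range(self) -> tuple:
        return float(self.mz[0]), float(self.mz[-1])

    def slice(self, lo: float, hi: float) -> tuple:
        """Views of (mz, intensity) with lo <= m/z <= hi."""
        i, j = np.searchsorted(self.mz, [lo, hi], side="left")
        j = np.searchsorted(self.mz, hi, side="right")
        return self.mz[i:j], self.intensity[i:j]

    def with_axis(self, new_mz: np.ndarray, coeffs=None) -> "Spectrum":
        return Spectrum(
            mz=new_mz,
            intensity=self.intensity,
            sample_id=self.sample_id,
            calibrated=True,
            calibration_coeffs=None if coeffs is None else np.asarray(coeffs),
        )


def read_spectrum(path, sample_id: Optional[str] = None) -> Spectrum:
    """Read a tab-separated (x,y) spectrum file.

    Lines must contain two decimal numbers (decimal point, not comma);
    out-of-order points are sorted and exact duplicate m/z values are
    averaged.  Errors name the offending line.
    """
    path = Path(path)
    mzs: List[float] = []
    intens: List[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                parts = line.split()
            if len(parts) != 2:
                raise SpectrumParseError(
                    f"{path}:{lineno}: expected 'm/z<TAB>intensity', got {line!r}"
                )
            if "," in parts[0] or "," in parts[1]:
                raise SpectrumParseError(
                    f"{path}:{lineno}: comma decimals are not accepted"
                )
            try:
                mzs.append(float(parts[0]))
                intens.append(float(parts[1]))
            except ValueError:
                raise SpectrumParseError(
                    f"{path}:{lineno}: unparseable numbers in {line.strip()!r}"
                ) from None
    if len(mzs) < 2:
        raise SpectrumParseError(f"{path}: fewer than two data points")
    mz = np.asarray(mzs)
    inten = np.asarray(intens)
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    if np.any(np.diff(mz) == 0):
        # average intensities at duplicated m/z values
        uniq, inverse = np.unique(mz, return_inverse=True)
        sums = np.bincount(inverse, weights=inten)
        counts = np.bincount(inverse)
        mz, inten = uniq, sums / counts
    if mz.size < 2:
        raise SpectrumParseError(f"{path}: fewer than two distinct m/z values")
    return Spectrum(mz, inten, sample_id=sample_id or path.stem)


def write_spectrum(s: Spectrum, path) -> None:
    """Write a spectrum as a tab-separated (x,y) file (>=6 sig. digits)."""
    arr = np.column_stack([s.mz, s.intensity])
    np.savetxt(path, arr, fmt="%.6f\t%.6f", delimiter="\t")


MANIFEST_COLUMNS = ["sample_id", "subject_id", "time_point", "path"]


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    bad_tp = set(manifest["time_point"]) - set(TIME_POINTS)
    if bad_tp:
        raise ValueError(f"unknown time points: {sorted(bad_tp)}")
    if manifest["sample_id"].duplicated().any():
        dup = manifest.loc[manifest["sample_id"].duplicated(), "sample_id"]
        raise ValueError(f"duplicate sample ids: {sorted(set(dup))}")
    counts = manifest.groupby(["subject_id", "time_point"], sort=False).size()
    if (counts > 1).any():
        bad = counts[counts > 1].index.tolist()
        raise ValueError(f"subjects with >1 sample at a time point: {bad}")
    return manifest


def read_manifest(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    manifest = pd.read_csv(path, sep=sep, dtype=str)
    return validate_manifest(manifest)


def write_manifest(manifest: pd.DataFrame, path) -> None:
    validate_manifest(manifest)
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    manifest.to_csv(path, sep=sep, index=False)
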