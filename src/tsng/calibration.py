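"""Internal mass calibration against a fixed list of glycan calibrants.

A spectrum is accepted for recalibration only when enough calibrants are
detected above the S/N threshold and their m/z coverage satisfies the
region rules (by default: at least 5 of 7 calibrants overall, at least 4
below m/z 2,333 and at least 1 between m/z 2,333 and 3,667).  Accepted
spectra have their full m/z axis transformed by a least-squares polynomial
fit of theoretical on observed calibrant masses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .extraction import ExtractionPolicy, estimate_background_noise, find_apex
from .glycans import (
    GlycanComposition,
    glycan_isotope_pattern,
    monoisotopic_mz,
    parse_composition,
)
from .spectra import Spectrum

__all__ = [
    "DEFAULT_CALIBRANTS",
    "CalibrationPolicy",
    "CalibrantHit",
    "CalibrationResult",
    "find_calibrant",
    "calibrate",
]

DEFAULT_CALIBRANTS = (
    "H5N4E1",
    "H5N4F1E1",
    "H5N4E2",
    "H6N5E2L1",
    "H6N5F1E2L1",
    "H7N6E1L3",
    "H7N6E2L2",
)


@dataclass(frozen=True)
class CalibrationPolicy:
    """Calibrant list, detection window, S/N gate and coverage rules."""

    calibrants: Tuple[str, ...] = DEFAULT_CALIBRANTS
    detection_window: float = 0.4     # +/- Da around the exact mass
    sn_threshold: float = 9.0
    min_calibrants: int = 5
    # (low m/z, high m/z, minimum number of accepted calibrants).  Only 3
    # of the 7 default calibrants lie below m/z 2,333, so the low-region
    # minimum demands all of them; the rules are policy data and can be
    # tightened for calibrant lists with denser low-mass coverage.
    region_rules: Tuple[Tuple[float, float, int], ...] = (
        (1000.0, 2333.0, 3),
        (2333.0, 3667.0, 1),
    )
    fit_degree: int = 2
    condition_limit: float = 1e8      # fall back to degree 1 above this
    smooth_points: int = 3
    refine_apex: bool = True


@dataclass(frozen=True)
class CalibrantHit:
    composition: str
    mz_theoretical: float
    mz_observed: float
    sn: float
    ppm_pre: float
    ppm_post: float = float("nan")


@dataclass
class CalibrationResult:
    status: str                      # "calibrated" | "failed"
    hits: List[CalibrantHit] = field(default_factory=list)
    coefficients: Optional[np.ndarray] = None
    rms_ppm_pre: float = float("nan")
    rms_ppm_post: float = float("nan")
    reason: str = ""

    @property
    def n_calibrants(self) -> int:
        return len(self.hits)


def find_calibrant(
    s: Spectrum,
    mz_theoretical: float,
    window: float = 0.4,
    policy: Optional[CalibrationPolicy] = None,
    extraction_policy: Optional[ExtractionPolicy] = None,
    isotope_centers: Optional[Sequence[float]] = None,
) -> Optional[Tuple[float, float]]:
    """Apex m/z and S/N of a calibrant peak, or ``None`` when not found.

    The apex is the smoothed local maximum inside ``+/- window``; S/N uses
    the extraction module's robust background/noise estimator with the
    calibrant's own isotopologue positions masked out.
    """
    policy = policy or CalibrationPolicy()
    lo_s, hi_s = s.mz_range
    if mz_theoretical - window < lo_s or mz_theoretical + window > hi_s:
        return None
    mz, inten = s.slice(mz_theoretical - window, mz_theoretical + window)
    if mz.size < 3:
        return None
    apex_mz, apex_h = find_apex(
        mz, inten, smooth=policy.smooth_points, refine=policy.refine_apex
    )
    if isotope_centers is None:
        isotope_centers = mz_theoretical + 1.00336 * np.arange(6)
    bg, noise = estimate_background_noise(
        s, mz_theoretical, isotope_centers, extraction_policy
    )
    sn = (apex_h - bg) / noise
    return float(apex_mz), float(sn)


def _check_policy(
    policy: CalibrationPolicy, accepted: Sequence[CalibrantHit]
) -> str:
    if len(accepted) < policy.min_calibrants:
        return (
            f"only {len(accepted)} calibrants above S/N "
            f"{policy.sn_threshold:g} (need {policy.min_calibrants})"
        )
    for lo, hi, need in policy.region_rules:
        n = sum(1 for h in accepted if lo <= h.mz_theoretical < hi)
        if n < need:
            return f"only {n} calibrants in [{lo:g}, {hi:g}) (need {need})"
    return ""


def calibrate(
    s: Spectrum,
    policy: Optional[CalibrationPolicy] = None,
    extraction_policy: Optional[ExtractionPolicy] = None,
) -> Tuple[Spectrum, CalibrationResult]:
    """Internally recalibrate a spectrum; on failure return it untouched."""
    policy = policy or CalibrationPolicy()
    hits: List[CalibrantHit] = []
    for code in policy.calibrants:
        g = parse_composition(code)
        theo = monoisotopic_mz(g)
        pattern = glycan_isotope_pattern(g, 0.99)
        found = find_calibrant(
            s,
            theo,
            window=policy.detection_window,
            policy=policy,
            extraction_policy=extraction_policy,
            isotope_centers=pattern.mz,
        )
        if found is None:
            continue
        obs, sn = found
        if sn < policy.sn_threshold:
            continue
        hits.append(
            CalibrantHit(
                composition=code,
                mz_theoretical=theo,
                mz_observed=obs,
                sn=sn,
                ppm_pre=(obs - theo) / theo * 1e6,
            )
        )
    reason = _check_policy(policy, hits)
    if reason:
        return s, CalibrationResult(status="failed", hits=hits, reason=reason)
    obs = np.array([h.mz_observed for h in hits])
    theo = np.array([h.mz_theoretical for h in hits])
    degree = policy.fit_degree
    # scale to [-1, 1] for conditioning of the Vandermonde system
    mid, half = obs.mean(), max(np.ptp(obs) / 2, 1.0)
    x = (obs - mid) / half
    if np.linalg.cond(np.vander(x, degree + 1)) > policy.condition_limit:
        degree = 1
    coeffs = np.polyfit(x, theo, deg=degree)
    new_mz = np.polyval(coeffs, (s.mz - mid) / half)
    if np.any(np.diff(new_mz) <= 0):
        return s, CalibrationResult(
            status="failed", hits=hits, reason="non-monotonic fitted axis"
        )
    post = np.polyval(coeffs, x)
    hits = [
        CalibrantHit(
            composition=h.composition,
            mz_theoretical=h.mz_theoretical,
            mz_observed=h.mz_observed,
            sn=h.sn,
            ppm_pre=h.ppm_pre,
            ppm_post=(p - h.mz_theoretical) / h.mz_theoretical * 1e6,
        )
        for h, p in zip(hits, post)
    ]
    result = CalibrationResult(
        status="calibrated",
        hits=hits,
        coefficients=np.concatenate([coeffs, [mid, half]]),
        rms_ppm_pre=float(np.sqrt(np.mean([h.ppm_pre**2 for h in hits]))),
        rms_ppm_post=float(np.sqrt(np.mean([h.ppm_post**2 for h in hits]))),
    )
    return s.with_axis(new_mz, coeffs=result.coefficients), result
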