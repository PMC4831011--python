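"""Synthetic spectra and a longitudinal cohort with known ground truth.

The simulator emulates reflectron MALDI-TOF spectra of an ethyl-esterified
serum N-glycome: Gaussian isotopologue peaks (FWHM = m/R), a gentle
polynomial baseline, additive Gaussian noise and a smooth mass-axis
miscalibration expressed in ppm.  The cohort generator programmes derived-
trait trajectories by multiplicatively tilting a serum-like base abundance
profile until each subject-visit profile hits its target trait values
exactly (within a small tolerance); those exact values are emitted as
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .glycans import LibraryEntry, glycan_isotope_pattern
from .spectra import Spectrum, write_manifest, write_spectrum
from .traits import TraitDefinition, compute_traits, feature_fractions, trait_catalogue

__all__ = [
    "InstrumentModel",
    "CohortDesign",
    "SimulatedCohort",
    "DEFAULT_TRAIT_TARGETS",
    "simulate_spectrum",
    "simulate_cohort",
    "serum_base_profile",
    "tilt_profile",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class InstrumentModel:
    """Peak shape, axis, baseline, noise and miscalibration settings.

    ``miscalibration_ppm`` are polynomial coefficients (highest power
    first, numpy convention) in the scaled coordinate
    ``x = (m - mid)/half`` of the m/z range; the polynomial value is the
    mass-axis error in ppm, so ``(100.0,)`` shifts every peak by +100 ppm.
    """

    resolving_power: float = 20000.0
    mz_range: Tuple[float, float] = (1000.0, 5000.0)
    step: float = 0.02
    baseline_coeffs: Tuple[float, ...] = (0.5, -2.0, 3.0)  # quadratic in x
    noise_sd: float = 1.0
    miscalibration_ppm: Tuple[float, ...] = (0.0,)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolving_power <= 0 or self.step <= 0:
            raise ValueError("resolving power and step must be positive")
        x = np.linspace(-1, 1, 101)
        if np.max(np.abs(np.polyval(self.miscalibration_ppm, x))) > 500:
            raise ValueError("miscalibration exceeds 500 ppm across the range")

    def axis(self) -> np.ndarray:
        lo, hi = self.mz_range
        return np.arange(lo, hi + self.step / 2, self.step)

    def _x(self, m: np.ndarray) -> np.ndarray:
        lo, hi = self.mz_range
        mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
        return (m - mid) / half

    def observed_mz(self, true_mz: np.ndarray) -> np.ndarray:
        ppm = np.polyval(self.miscalibration_ppm, self._x(np.asarray(true_mz)))
        return np.asarray(true_mz) * (1.0 + ppm * 1e-6)

    def baseline(self, m: np.ndarray) -> np.ndarray:
        return np.polyval(self.baseline_coeffs, self._x(m))


def simulate_spectrum(
    abundances: Mapping[str, float],
    library: Sequence[LibraryEntry],
    inst: InstrumentModel,
    rng: Optional[np.random.Generator] = None,
    sample_id: str = "sim",
    envelope_coverage: float = 0.9999,
) -> Tuple[Spectrum, Dict[str, float]]:
    """Render one spectrum; returns it with the injected areas as ground truth.

    ``abundances`` maps composition strings (present in ``library``) to the
    total ion area (intensity x Da) injected for that analyte; each
    isotopologue receives its theoretical share.
    """
    if not abundances:
        raise ValueError("empty abundance map")
    rng = rng if rng is not None else np.random.default_rng(inst.seed)
    by_name = {e.name: e for e in library}
    mz = inst.axis()
    intensity = inst.baseline(mz).astype(float)
    for name, area in abundances.items():
        if area < 0:
            raise ValueError(f"negative abundance for {name}")
        if area == 0:
            continue
        entry = by_name[name]
        pattern = glycan_isotope_pattern(entry.composition, envelope_coverage)
        centers = inst.observed_mz(np.asarray(pattern.mz))
        sigmas = centers / inst.resolving_power * _FWHM_TO_SIGMA
        for c, f, sg in zip(centers, pattern.fraction, sigmas):
            lo = np.searchsorted(mz, c - 6 * sg)
            hi = np.searchsorted(mz, c + 6 * sg)
            if hi <= lo:
                continue
            w = mz[lo:hi]
            intensity[lo:hi] += (
                area * f / (sg * np.sqrt(2 * np.pi))
            ) * np.exp(-0.5 * ((w - c) / sg) ** 2)
    if inst.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, inst.noise_sd, size=mz.size)
    spectrum = Spectrum(mz, intensity, sample_id=sample_id)
    return spectrum, dict(abundances)


# Programmed per-time-point derived-trait means (%), following the
# longitudinal trajectories reported for a healthy pregnancy cohort:
# alpha2,3-sialylation and triantennary glycans rise to the third
# trimester and fall after delivery; galactosylation falls and
# fucosylation/bisection rise with delivery.
DEFAULT_TRAIT_TARGETS: Mapping[str, Mapping[str, float]] = {
    "AL": {"trim1": 9.4, "trim2": 10.1, "trim3": 10.8, "wpp6": 9.4, "wpp12": 9.0, "wpp26plus": 8.7},
    "A3": {"trim1": 10.5, "trim2": 11.6, "trim3": 12.6, "wpp6": 11.5, "wpp12": 10.4, "wpp26plus": 9.4},
    "A2FG": {"trim1": 86.8, "trim2": 88.5, "trim3": 90.1, "wpp6": 85.6, "wpp12": 85.2, "wpp26plus": 84.9},
    "AE": {"trim1": 76.4, "trim2": 76.8, "trim3": 77.2, "wpp6": 75.4, "wpp12": 76.3, "wpp26plus": 77.2},
    "F": {"trim1": 22.1, "trim2": 22.0, "trim3": 21.9, "wpp6": 25.5, "wpp12": 25.0, "wpp26plus": 24.6},
    "B": {"trim1": 6.6, "trim2": 6.5, "trim3": 6.5, "wpp6": 8.6, "wpp12": 8.4, "wpp26plus": 8.2},
}


@dataclass(frozen=True)
class CohortDesign:
    """Longitudinal cohort layout and programmed trait trajectories."""

    n_subjects: int = 29
    time_points: Tuple[str, ...] = ("trim1", "trim2", "trim3", "wpp6", "wpp12", "wpp26plus")
    trait_targets: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_TRAIT_TARGETS
    )
    between_subject_sd: float = 1.5   # programmed-trait random effect, pp
    within_subject_sd: float = 0.5    # programmed-trait visit noise, pp
    analyte_subject_sd: float = 0.10  # per-analyte log-normal subject effect
    analyte_visit_sd: float = 0.05    # per-analyte log-normal visit noise
    total_area: float = 2.0e5         # summed ion area per spectrum
    area_log_sd: float = 0.15         # spot-to-spot total-area variation
    miscal_jitter_ppm: float = 5.0    # per-spectrum calibration offset jitter
    n_technical: int = 10             # pooled-plasma technical replicates
    base_profile: Optional[Mapping[str, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for trait, targets in self.trait_targets.items():
            for tp, v in targets.items():
                if not 0 <= v <= 100:
                    raise ValueError(
                        f"unreachable target for trait {trait} at {tp}: "
                        f"{v} outside [0, 100]"
                    )


@dataclass
class SimulatedCohort:
    manifest: pd.DataFrame
    spectra: List[Spectrum]
    ground_truth_traits: pd.DataFrame       # sample_id x trait (%)
    ground_truth_areas: Dict[str, Dict[str, float]]
    library: List[LibraryEntry]


def serum_base_profile(library: Sequence[LibraryEntry]) -> Dict[str, float]:
    """Heuristic serum-like base abundance profile over a library.

    Weights favour diantennary, fully galactosylated, alpha2,6-sialylated
    complex glycans (the H5N4E2-type profile that dominates serum), with
    minor tri/tetraantennary, bisected, fucosylated, hybrid and
    oligomannosidic species.  Normalised to sum to 1.
    """
    ant_w = {2: 1.0, 3: 0.12, 4: 0.02}
    weights: Dict[str, float] = {}
    for e in library:
        s = e.structure
        if s.glycan_class == "oligomannose":
            weights[e.name] = 0.006
            continue
        if s.glycan_class == "hybrid":
            w = 0.004
            if s.fucoses:
                w *= 0.3
            if s.sialic_23:
                w *= 0.3
            weights[e.name] = w
            continue
        w = ant_w[s.antennae]
        fucosylated = s.fucoses >= 1
        # under-galactosylation is rare overall but common on the
        # IgG-type fucosylated diantennary glycans
        gal_penalty = 0.22 if (s.antennae == 2 and fucosylated) else 0.06
        w *= gal_penalty ** (s.antennae - s.galactoses)
        if s.bisected:
            w *= 0.33 if fucosylated else 0.012   # bisection travels with core fucose
        if s.fucoses == 1:
            w *= 0.28
        elif s.fucoses >= 2:
            w *= 0.01
        # sialylation arrangement: per-galactose multinomial; fucosylated
        # diantennary (largely IgG/IgM) glycans are sialylated less
        if s.antennae >= 3:
            p_e, p_l = 0.55, 0.32
        elif fucosylated:
            p_e, p_l = 0.47, 0.10
        else:
            p_e, p_l = 0.82, 0.055
        p_u = 1.0 - p_e - p_l
        e26, l23 = s.sialic_26, s.sialic_23
        free = s.galactoses - e26 - l23
        from math import comb

        w *= (
            comb(s.galactoses, e26)
            * comb(s.galactoses - e26, l23)
            * p_e**e26
            * p_l**l23
            * p_u**free
        )
        if s.antenna_fucoses:
            w *= 0.02
        weights[e.name] = w
    total = sum(weights.values())
    return {k: v / total for k, v in weights.items()}


def select_resolved_subset(
    library: Sequence[LibraryEntry],
    n: int,
    must_include: Sequence[str] = (),
    base_profile: Optional[Mapping[str, float]] = None,
    min_gap: float = 0.98,
    n_isotopes: int = 6,
) -> List[LibraryEntry]:
    """Pick up to ``n`` abundant analytes with non-overlapping envelopes.

    Near-isobaric composition pairs (e.g. H5N4E2 vs H6N5L1, 0.036 Da
    apart) share extraction windows and are legitimately discarded by
    isotopic-pattern curation on real data; reduced simulation designs
    that need every analyte retained should draw from a mass-resolved
    subset instead.  Candidates are taken in order: ``must_include``
    first, then by base-profile weight, keeping an entry only if all its
    first ``n_isotopes`` isotopologue centers stay ``min_gap`` away from
    every center already selected.
    """
    base = base_profile or serum_base_profile(library)
    by_name = {e.name: e for e in library}
    order = [by_name[c] for c in must_include]
    order += [
        by_name[c]
        for c in sorted(base, key=base.get, reverse=True)
        if c not in must_include and c in by_name
    ]
    selected: List[LibraryEntry] = []
    centers: List[float] = []
    for e in order:
        cand = [e.mz + 1.00336 * k for k in range(n_isotopes)]
        if centers and min(
            abs(c - c0) for c in cand for c0 in centers
        ) < min_gap:
            if e.name in must_include:
                raise ValueError(f"required analyte {e.name} overlaps the subset")
            continue
        selected.append(e)
        centers.extend(cand)
        if len(selected) >= n:
            break
    return sorted(selected, key=lambda x: x.mz)


def _tilt_once(
    weights: np.ndarray,
    mask: np.ndarray,
    x: np.ndarray,
    target: float,
) -> np.ndarray:
    """Multiplicative tilt w <- w * f**x on the denominator set to hit target."""
    t = target / 100.0
    xm = x[mask]
    wm = weights[mask]
    if xm.size == 0:
        raise ValueError("target unreachable (empty denominator)")

    def value(logf: float) -> float:
        wt = wm * np.exp(logf * xm)
        return float(np.sum(wt * xm) / np.sum(wt)) - t

    lo_x, hi_x = float(np.min(xm)), float(np.max(xm))
    if not lo_x < t < hi_x:
        raise ValueError(
            f"target {target} unreachable (attainable range "
            f"{100 * lo_x:.2f}-{100 * hi_x:.2f})"
        )
    lo, hi = -50.0, 50.0
    logf = brentq(value, lo, hi, xtol=1e-10)
    out = weights.copy()
    out[mask] = wm * np.exp(logf * xm)
    return out


def tilt_profile(
    base: Mapping[str, float],
    targets: Mapping[str, float],
    library: Sequence[LibraryEntry],
    catalogue: Optional[Sequence[TraitDefinition]] = None,
    tol: float = 0.05,
    max_iter: int = 100,
) -> Dict[str, float]:
    """Reweight a profile so named traits hit their targets (pp tolerance).

    Traits are tilted in a fixed (sorted-name) order, repeatedly, because
    traits sharing analytes interact; convergence within ``tol`` is
    required.
    """
    catalogue = catalogue if catalogue is not None else trait_catalogue()
    by_name = {d.name: d for d in catalogue}
    lib = list(library)
    names = [e.name for e in lib]
    weights = np.array([base[n] for n in names], dtype=float)
    order = sorted(targets)
    feats = {}
    for t in order:
        if t not in by_name:
            raise KeyError(f"unknown trait {t!r}")
        feats[t] = feature_fractions(by_name[t], lib)
    for _ in range(max_iter):
        worst = 0.0
        for t in order:
            mask, x = feats[t]
            try:
                weights = _tilt_once(weights, mask, x, targets[t])
            except ValueError as exc:
                raise ValueError(f"trait {t}: {exc}") from None
        for t in order:
            mask, x = feats[t]
            cur = 100.0 * np.sum(weights[mask] * x[mask]) / np.sum(weights[mask])
            worst = max(worst, abs(cur - targets[t]))
        if worst <= tol:
            break
    else:
        raise RuntimeError(f"profile tilt did not converge (worst error {worst:.3f} pp)")
    weights /= weights.sum()
    return dict(zip(names, weights))


def _clip_target(
    value: float, mask: np.ndarray, x: np.ndarray
) -> float:
    lo = 100.0 * float(np.min(x[mask]))
    hi = 100.0 * float(np.max(x[mask]))
    margin = 0.02 * (hi - lo)
    return float(np.clip(value, lo + margin, hi - margin))


def simulate_cohort(
    design: CohortDesign,
    library: Sequence[LibraryEntry],
    inst: InstrumentModel,
    out_dir: Optional[Path] = None,
    render: bool = True,
    catalogue: Optional[Sequence[TraitDefinition]] = None,
) -> SimulatedCohort:
    """Generate the full longitudinal cohort plus technical replicates.

    Subject-level targets are time-point means plus a per-subject random
    effect (constant over visits) plus visit noise; each profile is tilted
    to hit its targets exactly, the exact derived traits of the tilted
    profile are recorded as ground truth, and the profile is rendered into
    a spectrum.  With ``out_dir`` set, spectra, the manifest and the
    ground-truth table are written to disk.
    """
    rng = np.random.default_rng(design.seed)
    lib = list(library)
    catalogue = catalogue if catalogue is not None else trait_catalogue()
    by_name = {d.name: d for d in catalogue}
    base = dict(design.base_profile) if design.base_profile else serum_base_profile(lib)
    feats = {
        t: feature_fractions(by_name[t], lib) for t in design.trait_targets
    }
    manifest_rows = []
    spectra: List[Spectrum] = []
    gt_traits = {}
    gt_areas: Dict[str, Dict[str, float]] = {}

    subj_eff = {
        t: rng.normal(0.0, design.between_subject_sd, size=design.n_subjects)
        for t in design.trait_targets
    }
    names = [e.name for e in lib]
    base_w = np.array([base[n] for n in names], dtype=float)
    for i in range(design.n_subjects):
        subject = f"subj{i + 1:02d}"
        # biological variation: every analyte carries a subject-level
        # log-normal effect (constant over visits) plus visit-level noise,
        # so non-programmed traits fluctuate instead of tracking the
        # programmed tilts deterministically
        subj_w = base_w * np.exp(
            rng.normal(0.0, design.analyte_subject_sd, size=base_w.size)
        )
        subj_profile = dict(zip(names, subj_w / subj_w.sum()))
        for tp in design.time_points:
            sample_id = f"{subject}_{tp}"
            targets = {}
            for t, tp_means in design.trait_targets.items():
                v = tp_means[tp] + subj_eff[t][i] + rng.normal(0.0, design.within_subject_sd)
                mask, x = feats[t]
                targets[t] = _clip_target(v, mask, x)
            profile = tilt_profile(subj_profile, targets, lib, catalogue)
            w = np.array([profile[n] for n in names]) * np.exp(
                rng.normal(0.0, design.analyte_visit_sd, size=base_w.size)
            )
            profile = dict(zip(names, w / w.sum()))
            rel = pd.Series(profile, name=sample_id) * 100.0
            gt_traits[sample_id] = compute_traits(rel, lib, catalogue)
            total = design.total_area * float(
                np.exp(rng.normal(0.0, design.area_log_sd))
            )
            areas = {n: w * total for n, w in profile.items()}
            gt_areas[sample_id] = areas
            spec = _render(areas, lib, inst, design, rng, sample_id) if render else None
            if spec is not None:
                spectra.append(spec)
            manifest_rows.append(
                {
                    "sample_id": sample_id,
                    "subject_id": subject,
                    "time_point": tp,
                    "path": f"{sample_id}.xy",
                }
            )
    for r in range(design.n_technical):
        sample_id = f"pool_rep{r + 1:02d}"
        total = design.total_area * float(np.exp(rng.normal(0.0, design.area_log_sd)))
        areas = {n: w * total for n, w in base.items()}
        gt_areas[sample_id] = areas
        rel = pd.Series(base, name=sample_id) * 100.0
        gt_traits[sample_id] = compute_traits(rel, lib, catalogue)
        spec = _render(areas, lib, inst, design, rng, sample_id) if render else None
        if spec is not None:
            spectra.append(spec)
        manifest_rows.append(
            {
                "sample_id": sample_id,
                "subject_id": f"pool_rep{r + 1:02d}",
                "time_point": "control",
                "path": f"{sample_id}.xy",
            }
        )
    manifest = pd.DataFrame(manifest_rows)
    gt = pd.DataFrame(gt_traits).T
    gt.index.name = "sample_id"
    cohort = SimulatedCohort(
        manifest=manifest,
        spectra=spectra,
        ground_truth_traits=gt,
        ground_truth_areas=gt_areas,
        library=lib,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for spec in spectra:
            write_spectrum(spec, out_dir / f"{spec.sample_id}.xy")
        write_manifest(manifest, out_dir / "manifest.csv")
        gt.to_csv(out_dir / "ground_truth_traits.csv")
    return cohort


def _render(
    areas: Mapping[str, float],
    lib: Sequence[LibraryEntry],
    inst: InstrumentModel,
    design: CohortDesign,
    rng: np.random.Generator,
    sample_id: str,
) -> Spectrum:
    jitter = rng.normal(0.0, design.miscal_jitter_ppm)
    coeffs = list(inst.miscalibration_ppm)
    coeffs[-1] += jitter
    inst_j = InstrumentModel(
        resolving_power=inst.resolving_power,
        mz_range=inst.mz_range,
        step=inst.step,
        baseline_coeffs=inst.baseline_coeffs,
        noise_sd=inst.noise_sd,
        miscalibration_ppm=tuple(coeffs),
        seed=inst.seed,
    )
    spec, _ = simulate_spectrum(areas, lib, inst_j, rng=rng, sample_id=sample_id)
    return spec
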