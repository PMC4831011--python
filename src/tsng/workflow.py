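"""Pipeline orchestration: simulate / calibrate / extract / curate /
quantify / test, with per-stage checkpoints on disk.

Every stage is a pure function of (inputs, config, seed); re-running a
stage from its checkpoints reproduces downstream outputs.  A run
directory receives: ``calibration.csv``, ``extraction.csv``,
``spectrum_summaries.csv``, ``curation_samples.csv``,
``curation_analytes.csv``, ``traits.csv``, ``stats.csv`` and
``run_report.json``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationPolicy, CalibrationResult, calibrate
from .curation import CurationPolicy, CurationReport, curate_analytes, curate_spectra
from .extraction import (
    AnalyteResult,
    ExtractionContext,
    ExtractionPolicy,
    extract_all,
    results_frame,
)
from .glycans import LibraryEntry, default_library, read_library, write_library
from .simulate import CohortDesign, InstrumentModel, simulate_cohort
from .spectra import Spectrum, read_manifest, read_spectrum
from .stats import DEFAULT_COMPARISONS, PairedTraitModel, PairedTraitResults
from .traits import compute_traits, normalize, trait_catalogue

__all__ = [
    "RunConfig",
    "PipelineResult",
    "load_config",
    "cmd_simulate",
    "cmd_run",
    "run_pipeline",
]

log = logging.getLogger(__name__)


def _build(cls, overrides: Optional[Mapping] = None):
    overrides = dict(overrides or {})
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(overrides) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    for key in ("mz_range", "time_points", "miscalibration_ppm", "baseline_coeffs"):
        if key in overrides and isinstance(overrides[key], list):
            overrides[key] = tuple(overrides[key])
    return cls(**overrides)


@dataclass
class RunConfig:
    """Declarative configuration of a full run (YAML-loadable)."""

    spectra_dir: str = "."
    manifest: str = "manifest.csv"
    library: Optional[str] = None          # CSV path; None = built-in library
    output_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"
    skip_calibration: bool = False
    calibration: Dict = field(default_factory=dict)
    extraction: Dict = field(default_factory=dict)
    curation: Dict = field(default_factory=dict)
    stats: Dict = field(default_factory=dict)
    simulate: Dict = field(default_factory=dict)
    instrument: Dict = field(default_factory=dict)

    def calibration_policy(self) -> CalibrationPolicy:
        return _build(CalibrationPolicy, self.calibration)

    def extraction_policy(self) -> ExtractionPolicy:
        return _build(ExtractionPolicy, self.extraction)

    def curation_policy(self) -> CurationPolicy:
        return _build(CurationPolicy, self.curation)

    def instrument_model(self) -> InstrumentModel:
        kw = dict(self.instrument)
        kw.setdefault("seed", self.seed)
        return _build(InstrumentModel, kw)

    def cohort_design(self) -> CohortDesign:
        kw = dict(self.simulate)
        kw.setdefault("seed", self.seed)
        return _build(CohortDesign, kw)

    def load_library(self) -> List[LibraryEntry]:
        if self.library:
            return read_library(self.library)
        return default_library()


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _build(RunConfig, data)


@dataclass
class PipelineResult:
    calibration: pd.DataFrame
    extraction: pd.DataFrame
    summaries: pd.DataFrame
    spectrum_curation: CurationReport
    analyte_curation: CurationReport
    trait_table: pd.DataFrame
    stats: Optional[PairedTraitResults]
    failed_samples: Dict[str, str]


def cmd_simulate(config: RunConfig):
    """Generate a synthetic cohort on disk (spectra, manifest, ground truth)."""
    design = config.cohort_design()
    inst = config.instrument_model()
    library = config.load_library()
    out = Path(config.output_dir)
    cohort = simulate_cohort(design, library, inst, out_dir=out)
    write_library(library, out / "library.csv")
    log.info(
        "simulated %d spectra (%d subjects x %d time points + %d replicates)",
        len(cohort.spectra),
        design.n_subjects,
        len(design.time_points),
        design.n_technical,
    )
    return cohort


def run_pipeline(
    config: RunConfig,
    spectra: Optional[Mapping[str, Spectrum]] = None,
    manifest: Optional[pd.DataFrame] = None,
    library: Optional[Sequence[LibraryEntry]] = None,
    write: bool = True,
) -> PipelineResult:
    """Calibrate, extract, curate, quantify and test a cohort.

    ``spectra`` may be supplied in memory (sample_id -> Spectrum);
    otherwise files are read from ``config.spectra_dir`` as named in the
    manifest.  A corrupt or uncalibratable sample is logged and excluded,
    never fatal.
    """
    out = Path(config.output_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
    manifest = manifest if manifest is not None else read_manifest(config.manifest)
    library = list(library) if library is not None else config.load_library()
    cal_policy = config.calibration_policy()
    ext_policy = config.extraction_policy()
    cur_policy = config.curation_policy()
    ctx = ExtractionContext(library, ext_policy)

    failed: Dict[str, str] = {}
    cal_rows = []
    all_results: List[AnalyteResult] = []
    summaries: Dict[str, Dict[str, float]] = {}
    for _, row in manifest.iterrows():
        sid = row["sample_id"]
        try:
            if spectra is not None:
                spec = spectra[sid]
            else:
                spec = read_spectrum(Path(config.spectra_dir) / row["path"], sid)
        except Exception as exc:  # corrupt file: skip, keep going
            failed[sid] = f"read: {exc}"
            log.error("sample %s failed at read stage: %s", sid, exc)
            continue
        if config.skip_calibration:
            cal_res = CalibrationResult(status="skipped")
        else:
            spec, cal_res = calibrate(spec, cal_policy, ext_policy)
        cal_rows.append(
            {
                "sample_id": sid,
                "status": cal_res.status,
                "n_calibrants": cal_res.n_calibrants,
                "rms_ppm_pre": cal_res.rms_ppm_pre,
                "rms_ppm_post": cal_res.rms_ppm_post,
                "reason": cal_res.reason,
            }
        )
        if cal_res.status == "failed":
            failed[sid] = f"calibration: {cal_res.reason}"
            log.warning("sample %s failed calibration: %s", sid, cal_res.reason)
            continue
        results, summary = extract_all(spec, library, ctx=ctx)
        all_results.extend(results)
        summaries[sid] = summary

    spec_report = curate_spectra(summaries, cur_policy)
    analyte_report = curate_analytes(
        all_results, cur_policy, retained_samples=spec_report.retained_samples
    )
    retained = set(analyte_report.retained_analytes)

    profiles = {}
    for sid in spec_report.retained_samples:
        areas = {
            r.composition: r.area
            for r in all_results
            if r.sample_id == sid and r.composition in retained and not r.out_of_range
        }
        try:
            profiles[sid] = normalize(areas, sid)
        except ValueError as exc:
            failed[sid] = f"normalise: {exc}"
            log.warning("sample %s dropped at normalisation: %s", sid, exc)
    catalogue = trait_catalogue()
    lib_retained = [e for e in library if e.name in retained]
    trait_table = pd.DataFrame(
        {
            sid: compute_traits(profile, lib_retained, catalogue)
            for sid, profile in profiles.items()
        }
    ).T
    trait_table.index.name = "sample_id"

    stats_results: Optional[PairedTraitResults] = None
    study = manifest[manifest["time_point"] != "control"]
    study = study[study["sample_id"].isin(trait_table.index)]
    if len(study):
        kw = dict(config.stats)
        comparisons = kw.pop("comparisons", None)
        try:
            model = PairedTraitModel(
                trait_table.loc[study["sample_id"]],
                study,
                comparisons=comparisons,
                **kw,
            )
            stats_results = model.fit()
        except ValueError as exc:
            log.warning("statistics stage skipped: %s", exc)

    result = PipelineResult(
        calibration=pd.DataFrame(cal_rows),
        extraction=results_frame(all_results),
        summaries=pd.DataFrame(summaries).T,
        spectrum_curation=spec_report,
        analyte_curation=analyte_report,
        trait_table=trait_table,
        stats=stats_results,
        failed_samples=failed,
    )
    if write:
        _write_outputs(result, out, config)
    return result


def _write_outputs(result: PipelineResult, out: Path, config: RunConfig) -> None:
    result.calibration.to_csv(out / "calibration.csv", index=False)
    result.extraction.to_csv(out / "extraction.csv", index=False)
    result.summaries.rename_axis("sample_id").to_csv(out / "spectrum_summaries.csv")
    pd.DataFrame(
        {
            "sample_id": result.spectrum_curation.retained_samples
            + result.spectrum_curation.discarded_samples,
            "retained": [True] * len(result.spectrum_curation.retained_samples)
            + [False] * len(result.spectrum_curation.discarded_samples),
        }
    ).to_csv(out / "curation_samples.csv", index=False)
    means = result.analyte_curation.analyte_means
    pd.DataFrame(
        {
            "composition": result.analyte_curation.retained_analytes
            + result.analyte_curation.discarded_analytes,
            "retained": [True] * len(result.analyte_curation.retained_analytes)
            + [False] * len(result.analyte_curation.discarded_analytes),
        }
    ).merge(means.reset_index(), on="composition", how="left").to_csv(
        out / "curation_analytes.csv", index=False
    )
    result.trait_table.to_csv(out / "traits.csv")
    report = {
        "failed_samples": result.failed_samples,
        "curation_counts": {
            **result.spectrum_curation.counts,
            **result.analyte_curation.counts,
        },
        "seed": config.seed,
    }
    if result.stats is not None:
        result.stats.to_csv(out / "stats.csv")
        report["bonferroni_alpha"] = result.stats.adjusted_alpha
        report["n_tests"] = result.stats.n_tests
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)


def cmd_run(config: RunConfig) -> PipelineResult:
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    return run_pipeline(config)
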