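"""Spectrum- and analyte-level quality filtering.

Spectra are retained when every spectrum-level quality metric lies within
mean +/- 3 SD of the cohort (single pass, statistics computed over all
samples including the one under test).  Analytes are retained when their
cross-sample mean isotopic-pattern QC is at or below the threshold AND
their mean S/N is at or above the cut-off; the boundary follows the
discard wording (QC strictly above, S/N strictly below discards).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd

from .extraction import AnalyteResult

__all__ = ["CurationPolicy", "CurationReport", "curate_spectra", "curate_analytes"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CurationPolicy:
    sd_multiplier: float = 3.0
    qc_max: float = 1.8e-4        # on the cross-sample mean QC
    sn_min: float = 6.0           # on the cross-sample mean S/N

    def __post_init__(self) -> None:
        if self.sd_multiplier <= 0 or self.qc_max <= 0 or self.sn_min <= 0:
            raise ValueError("curation thresholds must be positive")


@dataclass
class CurationReport:
    retained_samples: List[str] = field(default_factory=list)
    discarded_samples: List[str] = field(default_factory=list)
    sample_zscores: pd.DataFrame = field(default_factory=pd.DataFrame)
    retained_analytes: List[str] = field(default_factory=list)
    discarded_analytes: List[str] = field(default_factory=list)
    analyte_means: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def counts(self) -> Dict[str, int]:
        return {
            "samples_in": len(self.retained_samples) + len(self.discarded_samples),
            "samples_retained": len(self.retained_samples),
            "analytes_in": len(self.retained_analytes) + len(self.discarded_analytes),
            "analytes_retained": len(self.retained_analytes),
        }


def curate_spectra(
    summaries: Mapping[str, Mapping[str, float]],
    policy: CurationPolicy | None = None,
) -> CurationReport:
    """Retain samples whose every metric is within mean +/- k*SD.

    ``summaries`` maps sample_id to its spectrum-level metrics (e.g.
    fraction_in_analytes, fraction_above_sn).  With fewer than 3 samples
    the rule passes trivially (logged).
    """
    policy = policy or CurationPolicy()
    df = pd.DataFrame(summaries).T.astype(float)
    report = CurationReport()
    if len(df) < 3:
        log.info("spectrum curation skipped: only %d samples", len(df))
        report.retained_samples = list(df.index)
        report.sample_zscores = pd.DataFrame(0.0, index=df.index, columns=df.columns)
        return report
    mean = df.mean(axis=0)
    sd = df.std(axis=0, ddof=1)
    z = (df - mean).divide(sd.replace(0.0, np.inf), axis=1)
    ok = (z.abs() <= policy.sd_multiplier).all(axis=1)
    report.sample_zscores = z
    report.retained_samples = list(df.index[ok])
    report.discarded_samples = list(df.index[~ok])
    for sid in report.discarded_samples:
        worst = z.loc[sid].abs().idxmax()
        log.info(
            "spectrum %s discarded: |z| = %.2f on %s", sid, abs(z.loc[sid, worst]), worst
        )
    return report


def curate_analytes(
    results: Sequence[AnalyteResult],
    policy: CurationPolicy | None = None,
    retained_samples: Sequence[str] | None = None,
) -> CurationReport:
    """Retain analytes by cross-sample mean QC and mean S/N.

    Out-of-range results are excluded from the means; an analyte observed
    only out of range is discarded.
    """
    policy = policy or CurationPolicy()
    rows = [
        r
        for r in results
        if not r.out_of_range
        and (retained_samples is None or r.sample_id in set(retained_samples))
    ]
    df = pd.DataFrame(
        {
            "composition": [r.composition for r in rows],
            "qc": [r.qc for r in rows],
            "sn": [r.sn for r in rows],
        }
    )
    report = CurationReport()
    all_comps = sorted({r.composition for r in results}, key=str)
    if df.empty:
        report.discarded_analytes = all_comps
        return report
    means = df.groupby("composition")[["qc", "sn"]].mean()
    report.analyte_means = means
    for comp in all_comps:
        if comp not in means.index:
            report.discarded_analytes.append(comp)
            continue
        qc, sn = means.loc[comp, "qc"], means.loc[comp, "sn"]
        if qc > policy.qc_max or sn < policy.sn_min:
            report.discarded_analytes.append(comp)
            log.info("analyte %s discarded: mean QC %.2e, mean S/N %.1f", comp, qc, sn)
        else:
            report.retained_analytes.append(comp)
    return report
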