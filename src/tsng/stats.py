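"""Longitudinal paired statistics on derived-trait tables.

The testing scheme mirrors a longitudinal glycomics cohort analysis:
per-trait Shapiro-Wilk normality checks (recorded, never gating), paired
two-sided Wilcoxon signed-rank tests between named time-point pairs, and
Bonferroni control of the family-wise error rate within each comparison.

The Wilcoxon test drops zero differences before ranking (Wilcoxon's
original treatment) and mid-ranks ties.  For small samples the exact null
distribution of the positive-rank sum is computed by dynamic programming
over the (doubled, hence integer) mid-ranks; larger samples use the
tie-corrected normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "WilcoxonResult",
    "shapiro_wilk",
    "wilcoxon_signed_rank",
    "bonferroni_alpha",
    "DEFAULT_COMPARISONS",
    "PairedTraitModel",
    "PairedTraitResults",
    "run_comparisons",
]

DEFAULT_COMPARISONS: Mapping[str, Tuple[str, str]] = {
    "pregnancy": ("trim1", "trim3"),
    "short_term_recovery": ("trim3", "wpp6"),
    "long_term_recovery": ("trim3", "wpp26plus"),
}


def shapiro_wilk(values: Sequence[float]) -> Tuple[float, float]:
    """Shapiro-Wilk W and p; (nan, nan) outside 3 <= n <= 5000 or at zero
    variance."""
    arr = np.asarray([v for v in np.asarray(values, float) if np.isfinite(v)])
    if not 3 <= arr.size <= 5000 or np.ptp(arr) == 0:
        return float("nan"), float("nan")
    w, p = sps.shapiro(arr)
    return float(w), float(p)


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float      # W+ = sum of ranks of positive differences
    p_value: float
    n_used: int           # pairs after dropping zero differences
    method: str           # "exact" | "normal" | "degenerate"


def _exact_p_two_sided(double_ranks: np.ndarray, w_plus_doubled: int) -> float:
    """Exact two-sided p for the positive-rank sum via subset-sum DP.

    ``double_ranks`` are mid-ranks times two (integers); the null assigns
    each rank to the positive set with probability 1/2.
    """
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in double_ranks:
        r = int(r)
        counts[r:] += counts[:-r] if r else counts
    denom = counts.sum()
    cdf_lo = counts[: w_plus_doubled + 1].sum() / denom
    cdf_hi = counts[w_plus_doubled:].sum() / denom
    return float(min(1.0, 2.0 * min(cdf_lo, cdf_hi)))


def wilcoxon_signed_rank(
    differences: Sequence[float],
    exact_max_n: int = 25,
    method: str = "auto",
) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test on a vector of differences.

    Zero differences are dropped; if all differences are zero the result
    is degenerate (W+ = 0, p = 1).  ``method`` may force "exact" or
    "normal"; "auto" uses the exact distribution up to ``exact_max_n``
    pairs.
    """
    d = np.asarray(differences, dtype=float)
    d = d[np.isfinite(d)]
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, "degenerate")
    ranks = sps.rankdata(np.abs(d))          # mid-ranks for ties
    w_plus = float(ranks[d > 0].sum())
    if method == "exact" or (method == "auto" and n <= exact_max_n):
        dbl = np.rint(2 * ranks).astype(int)
        p = _exact_p_two_sided(dbl, int(round(2 * w_plus)))
        return WilcoxonResult(w_plus, p, n, "exact")
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    if var <= 0:
        return WilcoxonResult(w_plus, 1.0, n, "degenerate")
    z = (w_plus - mu) / np.sqrt(var)
    p = float(2 * sps.norm.sf(abs(z)))
    return WilcoxonResult(w_plus, min(1.0, p), n, "normal")


def bonferroni_alpha(family_alpha: float, n_tests: int, decimals: int = 4) -> float:
    """Bonferroni-adjusted per-test significance level, rounded for report."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return round(family_alpha / n_tests, decimals)


@dataclass
class PairedTraitResults:
    """Estimates and paired-test results for every trait x comparison."""

    frame: pd.DataFrame
    adjusted_alpha: float
    family_alpha: float
    n_tests: int
    normality: pd.DataFrame

    def summary(self, significant_only: bool = False) -> str:
        df = self.frame
        if significant_only:
            df = df[df["significant"]]
        lines = [
            "Paired Wilcoxon signed-rank tests "
            f"(family alpha {self.family_alpha:g}, {self.n_tests} tests per "
            f"comparison, adjusted alpha {self.adjusted_alpha:g})",
            "-" * 88,
            f"{'trait':<8}{'comparison':<22}{'n':>4}  "
            f"{'mean1±SEM':>14}  {'mean2±SEM':>14}  {'p':>10}  sig dir",
        ]
        for _, r in df.iterrows():
            lines.append(
                f"{r['trait']:<8}{r['comparison']:<22}{r['n_pairs']:>4}  "
                f"{r['mean_1']:>7.2f}±{r['sem_1']:<5.2f}  "
                f"{r['mean_2']:>7.2f}±{r['sem_2']:<5.2f}  "
                f"{r['p_value']:>10.4g}  "
                f"{'*' if r['significant'] else ' '}   {r['direction']}"
            )
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def plot_trait(self, trait: str, ax=None):
        """Mean +/- SEM trajectory of one trait over time points."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tp = self._trajectory[self._trajectory["trait"] == trait]
        ax.errorbar(
            range(len(tp)), tp["mean"], yerr=tp["sem"], marker="o", capsize=3
        )
        ax.set_xticks(range(len(tp)))
        ax.set_xticklabels(tp["time_point"])
        ax.set_ylabel(f"{trait} (%)")
        ax.set_title(trait)
        return ax

    _trajectory: pd.DataFrame = field(default_factory=pd.DataFrame)


class PairedTraitModel:
    """Paired longitudinal comparison model over a trait table.

    Parameters
    ----------
    trait_table
        DataFrame of trait values (%) indexed by sample_id, one column per
        trait.
    manifest
        Sample manifest with sample_id, subject_id and time_point columns.
    comparisons
        Mapping of comparison name to (time point 1, time point 2); only
        comparisons whose both time points occur in the manifest are kept.
    family_alpha, n_tests
        Family-wise level and Bonferroni family size (default: the number
        of traits in the table).
    """

    def __init__(
        self,
        trait_table: pd.DataFrame,
        manifest: pd.DataFrame,
        comparisons: Optional[Mapping[str, Tuple[str, str]]] = None,
        family_alpha: float = 0.05,
        n_tests: Optional[int] = None,
        exact_max_n: int = 25,
    ):
        self.trait_table = trait_table
        self.manifest = manifest
        available = set(manifest["time_point"])
        comparisons = dict(comparisons or DEFAULT_COMPARISONS)
        self.comparisons = {
            name: pair
            for name, pair in comparisons.items()
            if pair[0] in available and pair[1] in available
        }
        if not self.comparisons:
            raise ValueError("no requested comparison is covered by the manifest")
        self.family_alpha = family_alpha
        self.n_tests = n_tests or trait_table.shape[1]
        self.exact_max_n = exact_max_n

    @classmethod
    def from_frames(cls, trait_table, manifest, **kwargs) -> "PairedTraitModel":
        return cls(trait_table, manifest, **kwargs)

    def _samples_at(self, tp: str) -> pd.Series:
        m = self.manifest[self.manifest["time_point"] == tp]
        return pd.Series(m["sample_id"].values, index=m["subject_id"].values)

    def fit(self) -> PairedTraitResults:
        alpha_adj = bonferroni_alpha(self.family_alpha, self.n_tests)
        rows = []
        norm_rows = []
        traj_rows = []
        for trait in self.trait_table.columns:
            values = self.trait_table[trait]
            w, p_norm = shapiro_wilk(values.to_numpy())
            norm_rows.append({"trait": trait, "shapiro_w": w, "shapiro_p": p_norm})
            for tp in dict.fromkeys(self.manifest["time_point"]):
                ids = self._samples_at(tp)
                v = values.reindex(ids.values).dropna()
                if len(v):
                    traj_rows.append(
                        {
                            "trait": trait,
                            "time_point": tp,
                            "mean": v.mean(),
                            "sem": v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
                        }
                    )
            for name, (tp1, tp2) in self.comparisons.items():
                s1, s2 = self._samples_at(tp1), self._samples_at(tp2)
                subjects = s1.index.intersection(s2.index)
                v1 = values.reindex(s1.reindex(subjects).values).to_numpy(float)
                v2 = values.reindex(s2.reindex(subjects).values).to_numpy(float)
                ok = np.isfinite(v1) & np.isfinite(v2)
                v1, v2 = v1[ok], v2[ok]
                n_pairs = int(ok.sum())
                low_n = n_pairs < max(1, len(subjects) / 2) or n_pairs < 1
                if n_pairs == 0:
                    res = WilcoxonResult(float("nan"), float("nan"), 0, "degenerate")
                    direction = ""
                else:
                    res = wilcoxon_signed_rank(
                        v2 - v1, exact_max_n=self.exact_max_n
                    )
                    med = float(np.median(v2 - v1))
                    direction = "up" if med > 0 else ("down" if med < 0 else "")
                rows.append(
                    {
                        "trait": trait,
                        "comparison": name,
                        "time_point_1": tp1,
                        "time_point_2": tp2,
                        "n_pairs": n_pairs,
                        "mean_1": float(np.mean(v1)) if n_pairs else np.nan,
                        "sem_1": float(np.std(v1, ddof=1) / np.sqrt(n_pairs))
                        if n_pairs > 1
                        else np.nan,
                        "mean_2": float(np.mean(v2)) if n_pairs else np.nan,
                        "sem_2": float(np.std(v2, ddof=1) / np.sqrt(n_pairs))
                        if n_pairs > 1
                        else np.nan,
                        "statistic": res.statistic,
                        "p_value": res.p_value,
                        "method": res.method,
                        "significant": bool(
                            np.isfinite(res.p_value) and res.p_value < alpha_adj
                        ),
                        "direction": direction,
                        "low_n": low_n,
                    }
                )
        results = PairedTraitResults(
            frame=pd.DataFrame(rows),
            adjusted_alpha=alpha_adj,
            family_alpha=self.family_alpha,
            n_tests=self.n_tests,
            normality=pd.DataFrame(norm_rows),
        )
        results._trajectory = pd.DataFrame(traj_rows)
        return results


def run_comparisons(
    trait_table: pd.DataFrame,
    manifest: pd.DataFrame,
    comparisons: Optional[Mapping[str, Tuple[str, str]]] = None,
    family_alpha: float = 0.05,
    n_tests: Optional[int] = None,
) -> PairedTraitResults:
    """Functional wrapper around :class:`PairedTraitModel`."""
    return PairedTraitModel(
        trait_table, manifest, comparisons, family_alpha, n_tests
    ).fit()
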