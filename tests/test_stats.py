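"""Wilcoxon signed-rank exactness, Bonferroni control and the paired model."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tsng.stats import (
    PairedTraitModel,
    bonferroni_alpha,
    run_comparisons,
    shapiro_wilk,
    wilcoxon_signed_rank,
)


def enumeration_p(diffs):
    """Full 2^n enumeration of the two-sided exact signed-rank p-value."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    ws = np.asarray(ws)
    lo = np.mean(ws <= w_obs + 1e-9)
    hi = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(lo, hi))


class TestWilcoxon:
    def test_n6_all_positive_gives_p_03125(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 0.5, 3.0, 1.5, 2.5])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.03125)

    def test_antisymmetric_differences_give_p_1(self):
        res = wilcoxon_signed_rank([2.0, -2.0, 1.0, -1.0])
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        d = np.round(rng.normal(0.3, 1.0, size=n), 1)  # rounding makes ties
        res = wilcoxon_signed_rank(d, method="exact")
        assert res.p_value == pytest.approx(enumeration_p(d), abs=1e-12)

    def test_matches_scipy_without_ties(self):
        rng = np.random.default_rng(42)
        d = rng.normal(0.5, 1.0, size=12)
        res = wilcoxon_signed_rank(d, method="exact")
        ref = sps.wilcoxon(d, alternative="two-sided", method="exact")
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_differences_dropped(self):
        a = wilcoxon_signed_rank([0.0, 0.0, 1.0, 2.0, -0.5, 1.5])
        b = wilcoxon_signed_rank([1.0, 2.0, -0.5, 1.5])
        assert a.n_used == b.n_used == 4
        assert a.p_value == pytest.approx(b.p_value)

    def test_all_zero_is_degenerate(self):
        res = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert (res.statistic, res.p_value, res.method) == (0.0, 1.0, "degenerate")

    def test_normal_approximation_close_to_exact_at_n25(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0.4, 1.0, size=25)
        exact = wilcoxon_signed_rank(d, method="exact")
        approx = wilcoxon_signed_rank(d, method="normal")
        assert approx.p_value == pytest.approx(exact.p_value, rel=0.35)

    def test_power_for_one_sd_shift_at_n20(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            d = rng.normal(1.0, 1.0, size=20)
            if wilcoxon_signed_rank(d).p_value < 0.05:
                hits += 1
        assert hits >= 40  # >= 80% power


class TestShapiroAndBonferroni:
    def test_bonferroni_42_tests(self):
        assert bonferroni_alpha(0.05, 42) == pytest.approx(0.0012)

    def test_bonferroni_trivial_and_77(self):
        assert bonferroni_alpha(0.05, 1) == 0.05
        assert bonferroni_alpha(0.05, 77, decimals=6) == pytest.approx(0.000649)

    def test_normal_sample_usually_passes(self):
        passes = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            _, p = shapiro_wilk(rng.normal(size=200))
            passes += p > 0.05
        assert passes >= 18

    def test_skewed_sample_usually_fails(self):
        fails = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            _, p = shapiro_wilk(rng.exponential(size=50))
            fails += p < 0.05
        assert fails >= 18

    def test_constant_vector_flagged(self):
        w, p = shapiro_wilk([2.0, 2.0, 2.0, 2.0])
        assert np.isnan(w) and np.isnan(p)


def _paired_cohort(n=12, effect=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    values = {}
    for i in range(n):
        subj = f"p{i}"
        base = rng.normal(10.0, 1.5)
        for tp, delta in (("trim1", 0.0), ("trim3", effect)):
            sid = f"{subj}_{tp}"
            rows.append((sid, subj, tp, f"{sid}.xy"))
            values[sid] = base + delta + rng.normal(0, 0.4)
    manifest = pd.DataFrame(
        rows, columns=["sample_id", "subject_id", "time_point", "path"]
    )
    table = pd.DataFrame({"AL": pd.Series(values)})
    table.index.name = "sample_id"
    return table, manifest


class TestPairedModel:
    def test_detects_programmed_shift(self):
        table, manifest = _paired_cohort(n=20, effect=1.4, seed=1)
        res = PairedTraitModel(table, manifest, n_tests=42).fit()
        row = res.frame.iloc[0]
        assert row["comparison"] == "pregnancy"
        assert row["n_pairs"] == 20
        assert row["p_value"] < res.adjusted_alpha
        assert row["significant"] and row["direction"] == "up"

    def test_null_effect_usually_not_significant(self):
        sig = 0
        for seed in range(20):
            table, manifest = _paired_cohort(n=12, effect=0.0, seed=seed)
            res = PairedTraitModel(table, manifest, n_tests=42).fit()
            sig += int(res.frame["significant"].any())
        assert sig <= 1

    def test_only_available_comparisons_kept(self):
        table, manifest = _paired_cohort()
        model = PairedTraitModel(table, manifest)
        assert set(model.comparisons) == {"pregnancy"}

    def test_means_and_sem_reported(self):
        table, manifest = _paired_cohort(n=10, effect=2.0, seed=2)
        res = run_comparisons(table, manifest, n_tests=1)
        row = res.frame.iloc[0]
        ids = manifest[manifest.time_point == "trim1"]["sample_id"]
        assert row["mean_1"] == pytest.approx(table.loc[ids, "AL"].mean())
        v = table.loc[ids, "AL"]
        assert row["sem_1"] == pytest.approx(v.std(ddof=1) / np.sqrt(len(v)))

    def test_missing_trait_values_flagged_low_n(self):
        table, manifest = _paired_cohort(n=8)
        table.loc[table.index[:10], "AL"] = np.nan
        res = PairedTraitModel(table, manifest).fit()
        assert bool(res.frame.iloc[0]["low_n"])

    def test_summary_mentions_adjusted_alpha(self):
        table, manifest = _paired_cohort(n=8, effect=1.0)
        res = PairedTraitModel(table, manifest, n_tests=42).fit()
        assert "0.0012" in res.summary()
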