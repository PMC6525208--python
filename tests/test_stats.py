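"""Diversity, contingency, rank-sum, normality and dominant-hue statistics."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pearlhue import (
    ContingencyTable2x2,
    GroupColourTable,
    chi2_yates,
    compare_groups,
    count_distinct_hues,
    diversity_index,
    dominant_hues,
    match_rate,
    shapiro_normality,
    wilcoxon_rank_sum,
)
from pearlhue.stats import DegenerateDataWarning


class TestCountsAndRatios:
    def test_count_distinct_hues(self):
        assert count_distinct_hues([0.5, 0.5, 0.5]) == 1
        assert count_distinct_hues([0.41664, 0.41666], precision=4) == 2
        grid = np.round(np.linspace(0.0, 0.99, 100), 4)
        assert count_distinct_hues(grid) == 100
        with pytest.raises(ValueError):
            count_distinct_hues([])

    def test_diversity_index(self):
        assert diversity_index(84, 197) == pytest.approx(0.43, abs=0.005)
        assert diversity_index(103, 143) == pytest.approx(0.72, abs=0.005)
        assert diversity_index(5, 5) == 1.0
        with pytest.raises(ValueError):
            diversity_index(6, 5)
        with pytest.raises(ValueError):
            diversity_index(0, 5)

    def test_match_rate(self):
        assert match_rate(132, 197) == pytest.approx(67.0, abs=0.05)
        assert match_rate(118, 163) == pytest.approx(72.4, abs=0.05)
        assert match_rate(0, 10) == 0.0
        with pytest.raises(ValueError):
            match_rate(11, 10)


class TestChi2Yates:
    def test_balanced_table_gives_zero(self):
        stat, p = chi2_yates(ContingencyTable2x2(10, 10, 10, 10))
        assert stat == 0.0 and p == 1.0

    def test_against_scipy_on_specific_and_random_tables(self, rng):
        tables = [(132, 65, 66, 100), (84, 59, 118, 45)]
        tables += [tuple(int(x) for x in rng.integers(1, 200, 4)) for _ in range(200)]
        for cells in tables:
            stat, p = chi2_yates(ContingencyTable2x2(*cells))
            ref = sps.chi2_contingency(np.array(cells).reshape(2, 2), correction=True)
            assert stat == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_row_and_column_swap_invariance(self, rng):
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 100, 4))
            s0, _ = chi2_yates(ContingencyTable2x2(a, b, c, d))
            s_rows, _ = chi2_yates(ContingencyTable2x2(c, d, a, b))
            s_cols, _ = chi2_yates(ContingencyTable2x2(b, a, d, c))
            assert s0 == pytest.approx(s_rows) == pytest.approx(s_cols)
            assert s0 >= 0.0

    def test_yates_never_exceeds_uncorrected_pearson(self, rng):
        for _ in range(1_000):
            a, b, c, d = (int(x) for x in rng.integers(1, 150, 4))
            yates, p = chi2_yates(ContingencyTable2x2(a, b, c, d))
            pearson = sps.chi2_contingency(
                np.array([[a, b], [c, d]]), correction=False
            ).statistic
            assert yates <= pearson + 1e-12
            assert 0.0 < p <= 1.0

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi2_yates(ContingencyTable2x2(0, 0, 5, 5))


class TestWilcoxon:
    def test_identical_samples_are_degenerate(self):
        with pytest.warns(DegenerateDataWarning):
            _, p = wilcoxon_rank_sum([2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_fully_separated_small_samples_exact(self):
        # the most extreme of C(6,3)=20 orderings, doubled: p = 2/20
        stat, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_exact_matches_brute_force_enumeration(self):
        """Exact p equals the tail fraction over all rank assignments."""
        x, y = [1.0, 4.0, 6.0], [2.0, 3.0, 5.0]
        _, p = wilcoxon_rank_sum(x, y, mode="exact")
        n = len(x)
        pooled = sorted(x + y)
        u_obs = sum(1 for xi in x for yi in y if xi > yi)
        mu = n * n / 2.0
        us = []
        for idx in combinations(range(6), n):
            xs = [pooled[i] for i in idx]
            ys = [pooled[i] for i in range(6) if i not in idx]
            us.append(sum(1 for xi in xs for yi in ys if xi > yi))
        brute = sum(1 for u in us if abs(u - mu) >= abs(u_obs - mu)) / len(us)
        assert p == pytest.approx(min(1.0, brute), abs=1e-12)

    def test_exact_mode_rejects_ties(self):
        with pytest.raises(ValueError, match="tie"):
            wilcoxon_rank_sum([1, 2, 2], [2, 3, 4], mode="exact")

    def test_exact_vs_approximation_gap_at_4_plus_4(self):
        """The corrected normal approximation tracks exact enumeration.

        Exhaustive over all 70 tie-free 4+4 splits; the largest achievable
        gap for the standard continuity-corrected approximation is ~0.031,
        pinned here at 0.04 as a regression bound.
        """
        worst = 0.0
        for xs in combinations(range(1, 9), 4):
            ys = [v for v in range(1, 9) if v not in xs]
            _, pe = wilcoxon_rank_sum(list(xs), ys, mode="exact")
            _, pa = wilcoxon_rank_sum(list(xs), ys, mode="approx")
            worst = max(worst, abs(pe - pa))
        assert worst <= 0.04

    def test_detects_saturation_shift_at_study_scale(self):
        """A 0.1 saturation drop at n=150/group is found in >=95/100 runs."""
        rejections = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = np.clip(rng.normal(0.55, 0.05, 150), 0, 1)
            y = np.clip(rng.normal(0.45, 0.05, 150), 0, 1)
            _, p = wilcoxon_rank_sum(x, y)
            rejections += p < 0.05
        assert rejections >= 95


class TestShapiro:
    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            shapiro_normality([1.0] * 10)

    def test_type_one_error_on_normal_samples(self):
        keeps = sum(
            shapiro_normality(np.random.default_rng(s).normal(size=50))[1] > 0.05
            for s in range(100)
        )
        assert keeps >= 90

    def test_power_on_bimodal_samples(self):
        rejects = 0
        for s in range(100):
            u = np.random.default_rng(s).uniform(size=50)
            bimodal = np.where(u < 0.5, 0.0, 1.0) + 0.01 * (u - 0.5)
            rejects += shapiro_normality(bimodal)[1] < 0.05
        assert rejects >= 90


class TestDominantHues:
    def test_two_tight_clusters_give_two_peaks(self):
        rng = np.random.default_rng(0)
        hues = np.clip(
            np.concatenate([rng.normal(0.10, 0.01, 100), rng.normal(0.50, 0.01, 100)]), 0, 1
        )
        peaks = dominant_hues(hues)
        assert len(peaks) == 2
        assert sorted(peaks) == pytest.approx([0.10, 0.50], abs=0.02)

    def test_single_cluster_gives_one_peak(self):
        hues = np.clip(np.random.default_rng(1).normal(0.45, 0.02, 150), 0, 1)
        peaks = dominant_hues(hues)
        assert len(peaks) == 1
        assert peaks[0] == pytest.approx(0.45, abs=0.02)

    def test_boundary_red_mode_detected_at_zero(self):
        hues = np.clip(np.random.default_rng(3).normal(0.0, 0.03, 150), 0, 1)
        peaks = dominant_hues(hues)
        assert peaks and peaks[0] == pytest.approx(0.0, abs=0.02)

    def test_uniform_hues_have_no_dominant_hue(self):
        hues = np.random.default_rng(7).uniform(0, 1, 200)
        assert dominant_hues(hues) == []

    def test_too_few_hues_rejected(self):
        with pytest.raises(ValueError):
            dominant_hues([0.5])


class TestGroupsAndComparisons:
    @staticmethod
    def _summaries(rng, n, hue, sat, val, phenotype):
        return pd.DataFrame(
            {
                "hue": np.clip(rng.normal(hue, 0.01, n), 0, 1),
                "saturation": np.clip(rng.normal(sat, 0.05, n), 0, 1),
                "value": np.clip(rng.normal(val, 0.05, n), 0, 1),
                "phenotype": [phenotype] * n,
                "status": ["ok"] * n,
            }
        )

    def test_identical_groups_show_no_differences(self, rng):
        df = self._summaries(rng, 80, 0.45, 0.55, 0.65, "green")
        df.loc[:19, "phenotype"] = "other"  # a 2x2 test needs both outcomes
        a = GroupColourTable.from_summaries("a", df, donor_phenotype="green")
        b = GroupColourTable.from_summaries("b", df, donor_phenotype="green")
        report = compare_groups([(a, b)])
        row = report.iloc[0]
        assert row["wilcoxon_saturation_p"] == pytest.approx(1.0, abs=0.05)
        assert row["diversity_a"] == row["diversity_b"]
        assert row["chi2_yates"] == 0.0

    def test_imposed_saturation_shift_flagged_value_not(self, rng):
        a = GroupColourTable.from_summaries(
            "4m", self._summaries(rng, 150, 0.45, 0.55, 0.65, "green"), "green"
        )
        b = GroupColourTable.from_summaries(
            "30m", self._summaries(rng, 150, 0.45, 0.45, 0.65, "green"), "green"
        )
        row = compare_groups([(a, b)]).iloc[0]
        assert row["wilcoxon_saturation_p"] < 0.05
        assert row["wilcoxon_value_p"] > 0.05
        assert row["mean_saturation_shift"] == pytest.approx(-0.1, abs=0.02)

    def test_count_only_groups_reproduce_published_statistics(self):
        from pearlhue.reference_data import pearl_count_groups

        groups = pearl_count_groups()
        row = compare_groups([(groups["green_4m"], groups["green_30m"])]).iloc[0]
        assert row["match_rate_a"] == pytest.approx(67.0, abs=0.05)
        assert row["chi2_yates"] == pytest.approx(25.9, abs=0.05)
        assert row["chi2_p"] < 0.001

    def test_empty_group_skipped_with_warning(self):
        a = GroupColourTable(label="empty")
        b = GroupColourTable.from_counts("b", 10, 5, 5)
        with pytest.warns(DegenerateDataWarning):
            report = compare_groups([(a, b)])
        assert len(report) == 0
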