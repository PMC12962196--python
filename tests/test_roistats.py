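"""ROI aggregation, exact Wilcoxon rank-sum, percent change, correlations."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from cordmap import roistats
from cordmap.phantom import (CohortDesign, LesionEffectTable, RoiLabelScheme,
                             sample_cohort_parameters)
from cordmap.roistats import (correlation_entries, correlation_matrix,
                              extract_roi_means, percent_change,
                              region_table_from_truth, wilcoxon_rank_sum)


def brute_force_ranksum_p(x, y):
    """Exhaustive permutation oracle for the two-sided rank-sum test."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n = len(x)
    t_obs = ranks[:n].sum()
    t_all = np.array([sum(ranks[list(c)]) for c in
                      combinations(range(len(pooled)), n)])
    eps = 1e-9
    p_lo = np.mean(t_all <= t_obs + eps)
    p_hi = np.mean(t_all >= t_obs - eps)
    return min(1.0, 2 * min(p_lo, p_hi))


class TestWilcoxon:
    def test_identical_samples_give_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        _, p = wilcoxon_rank_sum(x, x.copy())
        assert p == 1.0

    def test_complete_separation_8v8_exact_p(self):
        x = np.arange(8.0)
        y = np.arange(8.0) + 100
        _, p = wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(2 / 12870, rel=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(3, 6), st.integers(3, 6), st.integers(0, 10_000),
           st.booleans())
    def test_matches_exhaustive_oracle_up_to_n12(self, n, m, seed, with_ties):
        rng = np.random.default_rng(seed)
        if with_ties:
            x = rng.integers(0, 4, n).astype(float)
            y = rng.integers(0, 4, m).astype(float)
        else:
            x, y = rng.normal(size=n), rng.normal(size=m)
        _, p = wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(brute_force_ranksum_p(x, y), abs=1e-12)

    def test_tiefree_exact_matches_scipy_mannwhitney(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=8), rng.normal(size=8)
            _, p = wilcoxon_rank_sum(x, y)
            p_ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                                     method="exact").pvalue
            assert p == pytest.approx(p_ref, rel=1e-9)

    def test_large_sample_normal_approximation_close_to_scipy(self, rng):
        x, y = rng.normal(size=15, loc=0.3), rng.normal(size=15)
        _, p = wilcoxon_rank_sum(x, y)
        p_ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic").pvalue
        assert p == pytest.approx(p_ref, rel=0.05)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0, 2.0])


class TestPercentChange:
    @pytest.mark.parametrize("lesion, pre, expected", [
        ([0.10982] * 3, [0.17] * 3, -35.4),   # the DNR PSR arithmetic instance
        ([2.0, 2.0], [2.0, 2.0], 0.0),
        ([3.0], [2.0], 50.0),
    ])
    def test_examples(self, lesion, pre, expected):
        assert percent_change(lesion, pre) == pytest.approx(expected, abs=1e-9)

    def test_zero_pre_mean_flagged(self):
        with pytest.raises(ValueError, match="undefined"):
            percent_change([1.0], [0.0])


class TestExtractRoiMeans:
    def test_constant_map_gives_constant_means(self):
        from cordmap.phantom import build_label_map
        scheme = RoiLabelScheme.default()
        labels = build_label_map((48, 48), scheme)
        table = extract_roi_means({"FA": np.full(labels.shape, 0.37)},
                                  labels, scheme)
        assert np.allclose(table["value"], 0.37)
        assert len(table) == 14

    def test_two_voxel_mean_and_missing_count(self):
        scheme = RoiLabelScheme.default()
        labels = np.zeros((8, 8), dtype=int)
        codes = list(scheme.labels)
        for i, code in enumerate(codes):
            labels[i // 4, (i % 4) * 2:(i % 4) * 2 + 2] = code
        m = np.zeros((8, 8))
        first = codes[0]
        m[labels == first] = [1.0, 3.0]
        table = extract_roi_means({"x": m}, labels, scheme)
        row = table[(table["metric"] == "x")
                    & (table["roi"] == scheme.labels[first][0])
                    & (table["side"] == scheme.labels[first][1])].iloc[0]
        assert row["value"] == 2.0
        # NaN voxels are excluded and reported
        m[labels == first] = [np.nan, 4.0]
        table = extract_roi_means({"x": m}, labels, scheme)
        row = table[(table["roi"] == scheme.labels[first][0])
                    & (table["side"] == scheme.labels[first][1])].iloc[0]
        assert row["value"] == 4.0 and row["n_missing"] == 1


def truth_table(seed=0, effects=None, cv=0.05):
    design = CohortDesign(seed=seed)
    cohort = sample_cohort_parameters(
        design, between_subject_cv=cv,
        effects=effects if effects is not None else LesionEffectTable.default())
    return design, region_table_from_truth(cohort, design.lesion_side)


class TestGroupStats:
    def test_percent_change_matches_configured_effects_at_truth_level(self):
        design, table = truth_table(seed=1)
        comp = roistats.group_comparisons(table, design.lesion_side)
        dnr = comp[(comp.roi == "DNR") & (comp.metric == "PSR")].iloc[0]
        assert dnr.percent_change_lesion == pytest.approx(-35.4, abs=1.5)
        noe = comp[(comp.roi == "DREZ") & (comp.metric == "NOE1.6")].iloc[0]
        assert noe.percent_change_lesion == pytest.approx(-72.5, abs=1.5)
        assert dnr.stars_lesion in ("*", "**", "***")

    def test_entry_bookkeeping_168_per_metric(self):
        design, table = truth_table(seed=2)
        entries = correlation_entries(table, design.lesion_side)
        counts = entries.groupby("metric").size()
        assert (counts == 168).all()

    def test_correlation_matrix_properties(self):
        design, table = truth_table(seed=3)
        entries = correlation_entries(table, design.lesion_side)
        r, p, ns, n = correlation_matrix(entries)
        assert n == 168
        assert np.allclose(r.values, r.values.T)
        assert np.allclose(np.diag(r.values), 1.0)
        # positive semidefinite within numerical tolerance
        assert np.linalg.eigvalsh(r.values).min() > -1e-10
        assert ((p.values >= 0) & (p.values <= 1)).all()

    def test_self_and_negated_correlations(self):
        design, table = truth_table(seed=4)
        neg = table.copy()
        neg["value"] *= -1
        neg["metric"] = neg["metric"].map(lambda s: s)  # same labels
        entries = correlation_entries(table, design.lesion_side)
        r, _, _, _ = correlation_matrix(entries)
        assert np.allclose(np.diag(r.values), 1.0)
        wide = entries.pivot_table(index=["subject", "segment", "roi", "group"],
                                   columns="metric", values="value")
        r_neg = np.corrcoef(wide["FA"], -wide["FA"])[0, 1]
        assert r_neg == pytest.approx(-1.0)

    def test_benjamini_hochberg_option_adds_adjusted_columns(self):
        design, table = truth_table(seed=5)
        report = roistats.compute_stats(table, design.lesion_side,
                                        benjamini_hochberg=True)
        comp = report.comparisons
        assert "p_lesion_vs_pre_bh" in comp.columns
        # BH adjustment never decreases a p-value
        assert (comp["p_lesion_vs_pre_bh"] >= comp["p_lesion_vs_pre"] - 1e-12).all()

    def test_null_cohort_type_one_error_calibrated(self):
        rate, n = roistats.type_one_error_rate(n_cohorts=60, seed=12)
        se = np.sqrt(0.05 * 0.95 / n)
        assert rate <= 0.05 + 3 * se
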