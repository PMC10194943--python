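"""Glycemic classes, experimental groups, interval flags, cluster summaries
and association statistics."""

import numpy as np
import pandas as pd
import pytest

from beatshape.phenotype import (
    annotate_beats,
    assign_group,
    chi_square_independence,
    classify_glycemia,
    cluster_centers,
    feature_cluster_table,
    flag_intervals,
    group_cluster_heatmap,
    ks_normality,
    mgdl_to_mmoll,
    phenotype_table,
    spearman_by_group,
    strength_band,
    summarize_median_iqr,
)


class TestGlycemia:
    @pytest.mark.parametrize(
        "glucose, expected",
        [
            (50.0, "hypoglycemia"),
            (14.9, "severe"),
            (15.0, "hypoglycemia"),  # boundary closed at 15
            (70.0, "hypoglycemia"),
            (70.1, "euglycemic"),
            (80.0, "euglycemic"),
        ],
    )
    def test_classification(self, glucose, expected):
        assert classify_glycemia(glucose) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            classify_glycemia(0.0)

    def test_threshold_unit_conversion(self):
        assert round(mgdl_to_mmoll(70.0), 2) == 3.89
        assert round(mgdl_to_mmoll(15.0), 2) == 0.83


class TestGroups:
    @pytest.mark.parametrize(
        "diabetic, died, gclass, expected",
        [
            (True, True, "severe", "SH-D-X"),
            (False, False, "hypoglycemia", "H-ND-L"),
            (False, True, "severe", "SH-ND-X"),
            (True, False, "hypoglycemia", "H-D-L"),
            (True, False, "euglycemic", "none"),
        ],
    )
    def test_group_labels(self, diabetic, died, gclass, expected):
        assert assign_group(diabetic, died, gclass) == expected

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            assign_group(True, True, "mystery")


class TestFlags:
    def test_reference_limits_strict(self):
        assert flag_intervals(71, 76, 23) == (True, True, True)
        assert flag_intervals(70, 75.9, 22) == (False, False, False)

    def test_absent_interval_absent_flag(self):
        pr, qt, qrs = flag_intervals(np.nan, 80, 20)
        assert pr is None and qt is True and qrs is False


class TestCenters:
    def test_singleton_and_mean(self):
        X = np.array([[0.0, 1.0], [1.0, 0.0], [5.0, 5.0]])
        centers = cluster_centers(X, np.array([1, 1, 2]))
        assert np.allclose(centers.loc[1], [0.5, 0.5])
        assert np.allclose(centers.loc[2], [5.0, 5.0])

    def test_planted_families_recovered_pointwise(self, three_family_fixture):
        X, _, y = three_family_fixture
        centers = cluster_centers(X, y)
        for fam in np.unique(y):
            template_mean = X[y == fam].mean(axis=0)
            assert np.max(np.abs(centers.loc[fam] - template_mean)) < 1e-12


class TestChiSquare:
    def test_balanced_table_zero_statistic(self):
        stat, dof, p = chi_square_independence([[10, 10], [10, 10]])
        assert stat == 0.0 and dof == 1 and p == pytest.approx(1.0)

    def test_diagonal_table_closed_form(self):
        stat, dof, _ = chi_square_independence([[50, 0], [0, 50]])
        assert stat == pytest.approx(100.0)  # n(ad-bc)^2 / prod(margins)
        assert dof == 1

    def test_ten_by_two_degrees_of_freedom(self):
        table = np.full((10, 2), 5)
        _, dof, _ = chi_square_independence(table)
        assert dof == 9

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_independence([[0, 0], [5, 5]])


class TestKsNormality:
    def test_normal_sample_not_rejected(self):
        x = np.random.default_rng(0).normal(3.0, 2.0, 5000)
        stat, p = ks_normality(x)
        assert 0.0 <= stat <= 1.0
        assert p > 0.05

    def test_exponential_sample_rejected(self):
        x = np.random.default_rng(1).exponential(1.0, 5000)
        _, p = ks_normality(x)
        assert p < 0.001

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_normality(np.full(20, 3.0))


class TestMedianIqr:
    def test_examples(self):
        assert summarize_median_iqr([1, 2, 3, 4, 5]) == (3.0, 2.0)
        assert summarize_median_iqr([7.0] * 9) == (7.0, 0.0)

    def test_matches_numpy_quantiles(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            x = rng.normal(size=rng.integers(5, 60))
            med, iqr = summarize_median_iqr(x)
            assert med == pytest.approx(np.median(x))
            assert iqr == pytest.approx(
                np.percentile(x, 75) - np.percentile(x, 25)
            )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_median_iqr([])


class TestStrengthBands:
    @pytest.mark.parametrize(
        "rho, band",
        [
            (1.0, "very strong"),
            (0.145, "weak"),
            (-0.05, "negligible"),
            (0.10, "weak"),  # left-closed boundaries
            (0.40, "moderate"),
            (0.70, "strong"),
            (0.90, "very strong"),
            (-0.69, "moderate"),
        ],
    )
    def test_band_boundaries(self, rho, band):
        assert strength_band(rho) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            strength_band(1.5)


class TestSpearman:
    def test_perfect_monotone(self):
        g = np.arange(20.0)
        rho, p, band = spearman_by_group(g, g * 3 + 1)
        assert rho == 1.0 and band == "very strong" and p < 1e-6

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            spearman_by_group(np.ones(20), np.arange(20.0))

    def test_planted_glycemic_coupling_gives_negative_qt_rho(self, small_cohort):
        """QT lengthens as glucose falls by construction, so glucose-QT
        correlation over hypo/severe beats of a diabetic rat is negative."""
        diabetic = next(r for r in small_cohort.rats if r.diabetic)
        truth = small_cohort.truth[diabetic.rat_id]
        sub = truth[(truth["glucose_mg_dl"] <= 70) & (truth["template"] != "pvc")]
        rho, p, _ = spearman_by_group(sub["glucose_mg_dl"], sub["qt_ms"])
        assert rho < 0 and p < 1e-6


def _toy_annotations():
    rng = np.random.default_rng(0)
    n = 400
    beat = pd.DataFrame(
        {
            "beat_id": np.arange(n),
            "rat_id": np.where(np.arange(n) % 2 == 0, "a", "b"),
            "glucose_mg_dl": rng.choice([100.0, 50.0, 12.0], n),
            "pr_ms": rng.normal(60, 10, n),
            "qt_ms": rng.normal(76, 5, n),
            "qrs_ms": rng.normal(21, 3, n),
        }
    )
    beat.loc[0, "pr_ms"] = np.nan
    labels = rng.integers(1, 5, n)
    meta = pd.DataFrame(
        {"rat_id": ["a", "b"], "diabetic": [True, False], "died": [False, True]}
    )
    return annotate_beats(beat, labels, meta)


class TestTablesAndHeatmap:
    def test_phenotype_table_counts_and_ranges(self):
        ann = _toy_annotations()
        table = phenotype_table(ann)
        assert table["n"].sum() == len(ann)
        pct_cols = [c for c in table.columns if c.startswith("pct_")]
        assert ((table[pct_cols] >= 0) & (table[pct_cols] <= 100)).all().all()

    def test_group_none_iff_euglycemic(self):
        ann = _toy_annotations()
        assert ((ann["group"] == "none") == (ann["glycemic_class"] == "euglycemic")).all()

    def test_absent_interval_absent_flag_in_annotations(self):
        ann = _toy_annotations()
        assert pd.isna(ann.loc[0, "pr_increased"])

    def test_feature_table_resums_to_cluster_sizes(self):
        ann = _toy_annotations()
        tab = feature_cluster_table(ann, "diabetic")
        sizes = ann.groupby("cluster").size().to_numpy()
        assert np.array_equal(tab.sum(axis=1), sizes)

    def test_heatmap_rows_sum_to_100(self):
        ann = _toy_annotations()
        mat, order = group_cluster_heatmap(ann)
        assert np.allclose(mat.sum(axis=1), 100.0, atol=1e-9)
        assert sorted(order) == sorted(mat.index)

    def test_single_cluster_heatmap_all_100(self):
        ann = _toy_annotations()
        ann["cluster"] = 1
        mat, _ = group_cluster_heatmap(ann)
        assert np.allclose(mat.to_numpy(), 100.0)

    def test_identical_rows_adjacent_in_leaf_order(self):
        ann = _toy_annotations()
        sub = ann[ann["group"] != "none"].copy()
        # duplicate one group's beats under another label -> identical rows
        dup = sub[sub["group"] == "SH-D-L"].copy()
        dup["group"] = "H-D-X"
        merged = pd.concat([sub[sub["group"] != "H-D-X"], dup])
        mat, order = group_cluster_heatmap(merged)
        assert abs(order.index("SH-D-L") - order.index("H-D-X")) == 1
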