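import itertools

import numpy as np
import pandas as pd
import pytest

from psicohort.expression import (
    blood_marker_report,
    classical_mds,
    cpm,
    detected_genes,
    fold_change_categories,
    homolog_overlap,
    mds_embedding,
    metadata_summary,
)

GROUPS = {"y1": "young", "y2": "young", "o1": "old", "o2": "old"}


class TestCpm:
    def test_detection_level_arithmetic(self):
        # 20 reads in a ~66.7M library sit right at the 0.3 CPM level
        counts = pd.DataFrame({"s": [20, 66_666_647]}, index=["g1", "rest"])
        out = cpm(counts)
        assert out.loc["g1", "s"] == pytest.approx(0.30, abs=1e-6)

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(50, (100, 4)), columns=list(GROUPS))
        assert np.allclose(cpm(counts).sum(axis=0), 1e6)

    def test_zero_count_and_zero_pattern(self):
        counts = pd.DataFrame({"s1": [0, 10], "s2": [5, 0]})
        out = cpm(counts)
        assert (out.to_numpy() == 0) .tolist() == [[True, False], [False, True]]

    def test_scale_invariance(self):
        counts = pd.DataFrame({"s1": [3, 7], "s2": [1, 9]})
        libs = pd.Series({"s1": 100, "s2": 50})
        a = cpm(counts, libs)
        b = cpm(counts * 10, libs * 10)
        pd.testing.assert_frame_equal(a, b, check_dtype=False)

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"s1": [0, 0]})
        with pytest.raises(ValueError, match="s1"):
            cpm(counts)


class TestDetectedGenes:
    def test_exclusive_and_shared_classes(self):
        cpm_df = pd.DataFrame(
            {
                "y1": [0.5, 1.0, 0.0, 0.1],
                "y2": [0.0, 2.0, 0.0, 0.2],
                "o1": [0.0, 0.4, 0.9, 0.1],
                "o2": [0.0, 0.3, 0.0, 0.2],
            },
            index=["young_only", "both", "old_only", "neither"],
        )
        res = detected_genes(cpm_df, GROUPS)
        assert res.exclusive_young == {"young_only"}
        assert res.exclusive_old == {"old_only"}
        assert res.shared == {"both"}
        # for the young-exclusive gene all old samples are below threshold
        assert res.other_cohort_below["young_only"] == 1.0

    def test_partition_invariant_on_random_matrix(self):
        rng = np.random.default_rng(3)
        cpm_df = pd.DataFrame(
            rng.exponential(0.5, (200, 4)), columns=list(GROUPS)
        )
        res = detected_genes(cpm_df, GROUPS)
        all_detected = res.detected_young | res.detected_old
        parts = [res.exclusive_young, res.exclusive_old, res.shared]
        assert set().union(*parts) == all_detected
        for a, b in itertools.combinations(parts, 2):
            assert not (a & b)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(4)
        cpm_df = pd.DataFrame(rng.exponential(0.4, (10, 4)), columns=list(GROUPS))
        res = detected_genes(cpm_df, GROUPS, detect_threshold=0.3)
        for gene in cpm_df.index:
            det_y = any(cpm_df.loc[gene, s] >= 0.3 for s in ["y1", "y2"])
            det_o = any(cpm_df.loc[gene, s] >= 0.3 for s in ["o1", "o2"])
            assert (gene in res.detected_young) == det_y
            assert (gene in res.exclusive_old) == (det_o and not det_y)


class TestFoldChangeCategories:
    def test_reported_shares(self):
        # 1735 up (339 of them beyond 1.5x) and 1701 down (106 at or
        # below 0.5x): shares 19.5% and 6.2%, total 3436
        fc = (
            [2.0] * 339 + [1.2] * (1735 - 339)
            + [0.4] * 106 + [0.8] * (1701 - 106)
        )
        cats = fold_change_categories(pd.DataFrame({"fold_change": fc}))
        assert cats.n_total == 3436
        assert cats.n_up == 1735 and cats.n_down == 1701
        assert cats.pct_up_gt_1p5 == 19.5
        assert cats.pct_down_le_0p5 == 6.2

    def test_boundaries(self):
        fc = [1.5, 0.5, 1.0]
        cats = fold_change_categories(pd.DataFrame({"fold_change": fc}))
        assert cats.n_up_gt_1p5 == 0  # 1.5 is not "> 1.5"
        assert cats.n_down_le_0p5 == 1  # 0.5 counts as a 50% decrease
        assert cats.n_ties == 1
        assert cats.n_up + cats.n_down + cats.n_ties == cats.n_total

    def test_empty_list(self):
        cats = fold_change_categories(pd.DataFrame({"fold_change": []}))
        assert cats.n_total == 0 and cats.pct_up_gt_1p5 == 0.0

    def test_nonpositive_fc_rejected(self):
        with pytest.raises(ValueError):
            fold_change_categories(pd.DataFrame({"fold_change": [1.0, -2.0]}))


class TestBloodMarkers:
    def test_absent_markers_reported_not_raised(self):
        cpm_df = pd.DataFrame({"y1": [1.0], "o1": [2.0]}, index=["gene_x"])
        report = blood_marker_report(cpm_df, {"y1": "young", "o1": "old"})
        assert len(report) == 4
        assert not report["present"].any()

    def test_present_marker_values_and_cohort_means(self):
        markers = ["m1", "m2"]
        cpm_df = pd.DataFrame(
            {"y1": [1.0, 0.0], "y2": [3.0, 0.0], "o1": [5.0, 2.0], "o2": [7.0, 4.0]},
            index=markers,
        )
        report = blood_marker_report(cpm_df, GROUPS, markers)
        assert report.loc["m1", "y1"] == 1.0
        assert report.loc["m1", "mean_young"] == pytest.approx(2.0)
        assert report.loc["m2", "mean_old"] == pytest.approx(3.0)


class TestMetadataSummary:
    # the two study cohorts' body masses (kg)
    YOUNG = [20.2, 10.3, 11.2, 10.7, 20.1, 7.5]
    OLD = [29.7, 13.2, 22.0, 12.7, 25.4, 25.0, 21.5]

    def make_meta(self):
        rows = [
            {"sample_id": f"y{i}", "cohort": "young", "age": a, "sex": "Female", "body_mass": m}
            for i, (a, m) in enumerate(zip([4, 3, 3, 1, 1, 3], self.YOUNG))
        ] + [
            {"sample_id": f"o{i}", "cohort": "old", "age": a, "sex": s, "body_mass": m}
            for i, (a, s, m) in enumerate(
                zip([14, 14, 17, 17, 14, 15, 14],
                    ["Female"] * 5 + ["Male"] * 2, self.OLD)
            )
        ]
        return pd.DataFrame(rows)

    def test_cohort_mass_mean_and_sd(self):
        out = metadata_summary(self.make_meta())
        assert out.loc["young", "body_mass_mean"] == 13.3
        assert out.loc["old", "body_mass_mean"] == 21.4
        assert out.loc["old", "body_mass_sd"] == 6.3
        assert out.loc["young", "body_mass_sd"] == 5.4

    def test_age_range_and_sex_counts(self):
        out = metadata_summary(self.make_meta())
        assert (out.loc["young", "age_min"], out.loc["young", "age_max"]) == (1, 4)
        assert out.loc["old", "n_male"] == 2
        assert out.loc["young", "n_female"] == 6

    def test_repeated_value_sd_zero(self):
        meta = pd.DataFrame(
            {
                "sample_id": ["a", "b"],
                "cohort": ["c", "c"],
                "age": [1, 1],
                "sex": ["Female", "Female"],
                "body_mass": [5.0, 5.0],
            }
        )
        assert metadata_summary(meta).loc["c", "body_mass_sd"] == 0.0


class TestMds:
    def test_three_point_metric_reproduced(self):
        # 3-4-5 right triangle: Euclidean, so Torgerson is exact
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        coords = classical_mds(d)
        recon = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        assert np.abs(recon - d).max() < 1e-9

    def test_identical_columns_have_zero_distance(self):
        cpm_df = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [10.0, 0.0, 5.0]}
        )
        _, dist = mds_embedding(cpm_df, top_n=None)
        assert dist.loc["a", "b"] == 0.0
        assert dist.loc["a", "c"] > 0

    def test_distance_matrix_properties_and_order_invariance(self):
        rng = np.random.default_rng(5)
        cpm_df = pd.DataFrame(rng.exponential(5, (50, 5)), columns=list("abcde"))
        coords, dist = mds_embedding(cpm_df, top_n=20)
        assert np.allclose(dist, dist.T) and np.allclose(np.diag(dist), 0)
        shuffled = cpm_df[["c", "a", "e", "b", "d"]]
        _, dist2 = mds_embedding(shuffled, top_n=20)
        assert dist2.loc["a", "c"] == pytest.approx(dist.loc["a", "c"])

    def test_cohort_shift_separates_clusters(self):
        from sklearn.metrics import silhouette_score

        from psicohort.simulate import SimulationConfig, simulate_counts

        cfg = SimulationConfig(
            n_genes=500, deg_fraction=0.3, logfc_sd=2.0, depth_factor=0.01,
            dispersion=0.05, seed=12,
        )
        counts, _ = simulate_counts(cfg)
        coords, _ = mds_embedding(cpm(counts), top_n=500)
        labels = [0] * cfg.n_young + [1] * cfg.n_old
        assert silhouette_score(coords.to_numpy(), labels) > 0

    def test_bcv_mode_runs_and_differs(self):
        rng = np.random.default_rng(6)
        cpm_df = pd.DataFrame(rng.exponential(5, (100, 4)), columns=list(GROUPS))
        _, d_logfc = mds_embedding(cpm_df, top_n=50, mode="logfc")
        _, d_bcv = mds_embedding(cpm_df, top_n=50, mode="bcv")
        assert not np.allclose(d_logfc, d_bcv)

    def test_too_few_samples_rejected(self):
        cpm_df = pd.DataFrame({"a": [1.0], "b": [2.0]})
        with pytest.raises(ValueError):
            mds_embedding(cpm_df)


class TestHomologOverlap:
    def test_disjoint_sets(self):
        regions = homolog_overlap({"A": {"x"}, "B": {"y"}})
        assert regions[("A",)] == 1 and regions[("B",)] == 1
        assert regions[("A", "B")] == 0

    def test_identical_sets_all_in_center(self):
        regions = homolog_overlap({"A": {"x", "y"}, "B": {"x", "y"}})
        assert regions[("A", "B")] == 2
        assert regions[("A",)] == regions[("B",)] == 0

    def test_three_sets_match_brute_force(self):
        sets = {"A": {1, 2, 3, 4}, "B": {3, 4, 5}, "C": {4, 5, 6, 7}}
        regions = homolog_overlap(sets)
        names = sorted(sets)
        universe = set().union(*sets.values())
        for element in universe:
            membership = tuple(n for n in names if element in sets[n])
            # each element is counted in exactly its membership region
            assert regions[membership] >= 1
        assert regions[("A", "B", "C")] == 1  # only gene 4
        assert regions[("B", "C")] == 1  # only gene 5
        assert sum(regions.values()) == len(universe)
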