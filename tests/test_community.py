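import numpy as np
import pandas as pd
import pytest

from islandbeta import (
    build_pair_table,
    classify_islands,
    read_community,
    richness,
    subset_by_pft,
    write_community,
)
from islandbeta.beta import jaccard, raup_crick, NullModelConfig
from islandbeta.community import group_summary, pair_classes, validate_community


class TestCommunityIO:
    def test_round_trip_identity(self, tiny_matrix, tmp_path):
        path = tmp_path / "community.csv"
        write_community(tiny_matrix, path)
        again = read_community(path)
        pd.testing.assert_frame_equal(again, tiny_matrix.astype(np.int64))

    def test_negative_cell_rejected_with_context(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("island_id,s1,s2\nA,1,2\nB,-1,0\n")
        with pytest.raises(ValueError, match=r"'B'.*'s1'"):
            read_community(path)

    def test_non_integer_cell_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("island_id,s1,s2\nA,1.5,2\nB,1,0\n")
        with pytest.raises(ValueError, match="non-negative integers"):
            read_community(path)

    def test_duplicate_island_labels_rejected(self):
        m = pd.DataFrame([[1, 0], [2, 1]], index=["A", "A"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="duplicate island"):
            validate_community(m)


class TestRichness:
    def test_counts_positive_cells(self):
        m = pd.DataFrame([[3, 0, 1], [0, 0, 0], [1, 1, 1]], index=list("ABC"), columns=list("xyz"))
        assert richness(m).tolist() == [2, 0, 3]

    def test_saturated_island(self, default_landscape):
        matrix, _, _ = default_landscape
        assert richness(matrix).max() <= matrix.shape[1]


class TestClassification:
    def test_thresholds_boundary_in_lower_class(self):
        attrs = pd.DataFrame(
            {"area_ha": [1.5, 1.0], "dni_m": [50.0, 80.0], "dm_m": [2000.0, 2500.0]},
            index=["big", "small"],
        )
        g = classify_islands(attrs)
        assert g.loc["big", "size_class"] == "large"
        assert g.loc["small", "size_class"] == "small"  # area == 1 ha is small
        assert g.loc["big", "clumping_class"] == "clumped"  # DNI == 50 m
        assert g.loc["small", "clumping_class"] == "isolated"
        assert g.loc["big", "distance_class"] == "near"  # DM == 2000 m
        assert g.loc["small", "distance_class"] == "far"

    def test_invalid_threshold_rejected(self):
        attrs = pd.DataFrame({"area_ha": [1.0], "dni_m": [1.0], "dm_m": [1.0]}, index=["a"])
        with pytest.raises(ValueError, match="threshold"):
            classify_islands(attrs, area_cut_ha=0)


class TestPftSubset:
    def test_partition_reconstructs_matrix_and_richness(self, tiny_matrix):
        assignment = pd.Series([1, 1, 2, 2], index=tiny_matrix.columns)
        parts = [subset_by_pft(tiny_matrix, assignment, p) for p in (1, 2)]
        union = pd.concat(parts, axis=1)[tiny_matrix.columns]
        pd.testing.assert_frame_equal(union, tiny_matrix)
        total = sum(richness(p) for p in parts)
        pd.testing.assert_series_equal(total, richness(tiny_matrix))

    def test_unknown_pft_rejected(self, tiny_matrix):
        assignment = pd.Series([1, 1, 2, 2], index=tiny_matrix.columns)
        with pytest.raises(ValueError, match="unknown PFT"):
            subset_by_pft(tiny_matrix, assignment, 9)

    def test_islands_kept_when_empty(self, tiny_matrix):
        assignment = pd.Series([1, 1, 1, 2], index=tiny_matrix.columns)
        sub = subset_by_pft(tiny_matrix, assignment, 2)
        assert list(sub.index) == list(tiny_matrix.index)
        assert richness(sub).min() == 0


class TestPairTable:
    def test_pair_count_and_fields(self, default_landscape):
        matrix, attrs, _ = default_landscape
        bj = jaccard(matrix)
        brc = raup_crick(matrix, NullModelConfig(n_reps=50, seed=0))
        pairs = build_pair_table(matrix, attrs, bj, brc)
        assert len(pairs) == 29 * 28 // 2 == 406
        assert (pairs["island_a"] < pairs["island_b"]).all()
        assert (pairs["delta_richness"] >= 0).all()

    def test_log10_area_contrast(self, tiny_matrix):
        attrs = pd.DataFrame(
            {"area_ha": [10.0, 1.0, 1.0, 1.0], "dni_m": [5.0] * 4, "dm_m": [100.0] * 4},
            index=tiny_matrix.index,
        )
        bj = jaccard(tiny_matrix)
        brc = raup_crick(tiny_matrix, NullModelConfig(n_reps=20, seed=0))
        pairs = build_pair_table(tiny_matrix, attrs, bj, brc)
        ab = pairs.set_index(["island_a", "island_b"])
        assert ab.at[("A", "B"), "pred_area"] == pytest.approx(1.0)
        assert ab.at[("A", "B"), "delta_richness"] == 0

    def test_row_permutation_invariance(self, tiny_matrix):
        attrs = pd.DataFrame(
            {"area_ha": [1.0, 2.0, 4.0, 8.0], "dni_m": [10, 20, 30, 40], "dm_m": [1e3] * 4},
            index=tiny_matrix.index, dtype=float,
        )
        bj = jaccard(tiny_matrix)
        brc = jaccard(tiny_matrix)  # any symmetric pairwise table works here
        base = build_pair_table(tiny_matrix, attrs, bj, brc)
        shuffled = tiny_matrix.iloc[::-1]
        other = build_pair_table(shuffled, attrs, jaccard(shuffled), brc, reduction="difference")
        pd.testing.assert_frame_equal(base, other)

    def test_doubling_counts_changes_no_beta(self, tiny_matrix):
        cfg = NullModelConfig(n_reps=100, seed=7)
        pd.testing.assert_frame_equal(jaccard(tiny_matrix), jaccard(tiny_matrix * 2))
        pd.testing.assert_frame_equal(
            raup_crick(tiny_matrix, cfg), raup_crick(tiny_matrix * 2, cfg)
        )

    def test_index_mismatch_rejected(self, tiny_matrix):
        attrs = pd.DataFrame(
            {"area_ha": [1.0], "dni_m": [1.0], "dm_m": [1.0]}, index=["other"]
        )
        with pytest.raises(ValueError, match="do not match"):
            build_pair_table(tiny_matrix, attrs, jaccard(tiny_matrix), jaccard(tiny_matrix))


class TestGroupSummary:
    def test_constant_values_zero_width_ci(self):
        values = pd.Series([5.0] * 6)
        classes = pd.Series(["a"] * 3 + ["b"] * 3)
        out = group_summary(values, classes)
        assert out.loc["a", "mean"] == 5.0
        assert out.loc["a", "ci_low"] == out.loc["a", "ci_high"] == 5.0

    def test_singleton_class_flagged(self):
        out = group_summary(pd.Series([1.0, 2.0, 3.0]), pd.Series(["a", "b", "b"]))
        assert bool(out.loc["a", "ci_omitted"])
        assert not bool(out.loc["b", "ci_omitted"])

    def test_straddling_pairs_excluded(self):
        pairs = pd.DataFrame({"island_a": ["A", "A", "B"], "island_b": ["B", "C", "C"]})
        groups = pd.DataFrame({"size_class": ["large", "large", "small"]}, index=list("ABC"))
        cls = pair_classes(pairs, groups, "size_class")
        assert cls.tolist() == ["large", None, None]
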