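"""Detection filter, BH, differential expression and PCA contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from mirnet import expression as expr
from mirnet import synthdata as sd
from mirnet.errors import InputError


def _matrix(values, groups, nc_rows=()):
    frame = pd.DataFrame(values)
    frame.index = [f"m{i}" for i in range(frame.shape[0] - len(nc_rows))] + \
                  [f"nc{i}" for i in range(len(nc_rows))]
    frame.columns = [f"s{i}" for i in range(frame.shape[1])]
    mask = pd.Series([False] * (frame.shape[0] - len(nc_rows))
                     + [True] * len(nc_rows), index=frame.index)
    return expr.ExpressionMatrix(
        frame, pd.Series(groups, index=frame.columns), mask)


class TestExpressionMatrix:
    def test_duplicate_row_ids_rejected(self):
        frame = pd.DataFrame(np.zeros((2, 4)), index=["a", "a"],
                             columns=list("wxyz"))
        with pytest.raises(InputError, match="duplicate"):
            expr.ExpressionMatrix(
                frame, pd.Series(["case", "case", "control", "control"],
                                 index=frame.columns),
                pd.Series(False, index=frame.index))

    def test_group_of_size_one_rejected(self):
        with pytest.raises(InputError, match="fewer than 2"):
            _matrix(np.zeros((2, 3)), ["case", "case", "control"])

    def test_tsv_roundtrip(self, tmp_path, small_truth):
        matrix, _ = small_truth
        matrix.to_tsv(tmp_path / "x.tsv", tmp_path / "s.tsv")
        back = expr.ExpressionMatrix.from_tsv(tmp_path / "x.tsv",
                                              tmp_path / "s.tsv")
        pd.testing.assert_frame_equal(matrix.values, back.values)
        assert (matrix.negative_control_mask
                == back.negative_control_mask).all()


class TestDetectionFilter:
    def test_no_negative_controls_is_error(self):
        m = _matrix(np.ones((3, 4)), ["case"] * 2 + ["control"] * 2)
        with pytest.raises(InputError, match="negative-control"):
            expr.detection_filter(m)

    def test_always_above_retained_never_above_removed(self):
        groups = ["case"] * 2 + ["control"] * 2
        values = np.vstack([np.full(4, 8.0),    # well above controls
                            np.full(4, 0.0),    # below
                            np.full(4, 4.0)])   # the control row
        m = _matrix(values, groups, nc_rows=(2,))
        kept = expr.detection_filter(m, min_sample_frac=0.5)
        assert list(kept.values.index) == ["m0"]
        assert not kept.negative_control_mask.any()

    def test_retained_set_equals_brute_force_count(self, small_truth):
        """Oracle: per-row count of entries above the per-sample threshold."""
        matrix, _ = small_truth
        frac, q = 0.5, 0.9
        kept = expr.detection_filter(matrix, frac, q)
        nc = matrix.values.loc[matrix.negative_control_mask.values]
        expected = []
        for mid, row in matrix.values.loc[
                ~matrix.negative_control_mask.values].iterrows():
            n_above = sum(row[s] > np.quantile(nc[s], q)
                          for s in matrix.values.columns)
            if n_above >= frac * matrix.values.shape[1]:
                expected.append(mid)
        assert list(kept.values.index) == expected
        assert 0 < len(expected) < matrix.values.shape[0]


class TestBenjaminiHochberg:
    def test_hand_evaluated_cases(self):
        assert expr.benjamini_hochberg([0.03]) == pytest.approx([0.03])
        np.testing.assert_allclose(
            expr.benjamini_hochberg([0.01, 0.02, 0.03, 0.04]),
            [0.04, 0.04, 0.04, 0.04])
        np.testing.assert_allclose(expr.benjamini_hochberg([1.0] * 5),
                                   [1.0] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            expr.benjamini_hochberg([0.5, 1.5])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=60))
    def test_matches_statsmodels_and_dominates_p(self, pvals):
        q = expr.benjamini_hochberg(pvals)
        expected = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(q, expected, atol=1e-12)
        assert (q >= np.asarray(pvals) - 1e-12).all()

    def test_invariant_to_permutation(self):
        rng = np.random.default_rng(0)
        p = rng.random(40)
        perm = rng.permutation(40)
        q = expr.benjamini_hochberg(p)
        assert np.allclose(expr.benjamini_hochberg(p[perm]), q[perm])


class TestDifferentialExpression:
    def test_identical_groups_have_zero_fc_and_no_calls(self):
        block = np.tile(np.linspace(5, 9, 8), (4, 1)).T
        m = _matrix(np.hstack([block, block]),
                    ["case"] * 4 + ["control"] * 4)
        table = expr.differential_expression(m)
        assert np.allclose(table["log2fc"], 0)
        assert not table["passes_cutoffs"].any()

    def test_small_group_rejected(self):
        values = np.arange(12.0).reshape(4, 3)
        frame = pd.DataFrame(values, index=list("abcd"),
                             columns=["s0", "s1", "s2"])
        m = expr.ExpressionMatrix.__new__(expr.ExpressionMatrix)
        # bypass the constructor's >=2-per-group check to hit the op's own
        m.values = frame
        m.groups = pd.Series(["case", "case", "control"], index=frame.columns)
        m.negative_control_mask = pd.Series(False, index=frame.index)
        with pytest.raises(InputError, match=">= 2 samples"):
            expr.differential_expression(m)

    def test_passes_cutoffs_equals_set_logic_oracle(self, small_truth):
        matrix, _ = small_truth
        table = expr.differential_expression(
            expr.detection_filter(matrix))
        independent = (set(table.index[table["q_value"] < 0.05])
                       & set(table.index[table["log2fc"].abs() > 0.5])
                       & set(table.index[table["mean_expression"] > 5]))
        assert set(table.index[table["passes_cutoffs"]]) == independent

    def test_mannwhitney_branch_runs(self, small_truth):
        matrix, truth = small_truth
        table = expr.differential_expression(
            expr.detection_filter(matrix), method="mannwhitney")
        called = set(table.index[table["passes_cutoffs"]])
        # nonparametric test at n=19/19 still recovers most planted effects
        assert len(called & truth.de_mirna_ids) > 0.8 * len(truth.de_mirna_ids)

    def test_direction_labels_match_sign(self, small_truth):
        matrix, truth = small_truth
        table = expr.differential_expression(expr.detection_filter(matrix))
        for mid, fc in truth.de_log2fc.items():
            if mid in table.index and table.loc[mid, "passes_cutoffs"]:
                assert table.loc[mid, "direction"] == \
                       ("up" if fc > 0 else "down")


class TestProbeCollapse:
    def test_median_collapse(self):
        groups = ["case"] * 2 + ["control"] * 2
        values = np.array([[1.0, 2, 3, 4], [3.0, 4, 5, 6], [9.0, 9, 9, 9]])
        m = _matrix(values, groups)
        mapping = pd.Series({"m0": "mirX", "m1": "mirX"})
        collapsed = expr.collapse_probes(m, mapping)
        assert list(collapsed.values.loc["mirX"]) == [2.0, 3.0, 4.0, 5.0]
        assert "m2" in collapsed.values.index


class TestPCA:
    def test_identical_samples_identical_scores(self):
        rng = np.random.default_rng(1)
        col = rng.normal(7, 1, size=20)
        values = np.column_stack([col, col, col + 1, col + 1])
        m = _matrix(values, ["case"] * 2 + ["control"] * 2)
        result = expr.pca(m, k=2)
        np.testing.assert_allclose(result.scores.iloc[0],
                                   result.scores.iloc[1], atol=1e-9)

    def test_variance_fractions_monotone_and_sum_to_one_at_full_rank(self):
        rng = np.random.default_rng(2)
        m = _matrix(rng.normal(size=(10, 5)),
                    ["case"] * 3 + ["control"] * 2)
        result = expr.pca(m, k=4)  # rank is n_samples - 1 after centering
        evr = result.explained_variance_ratio
        assert (np.diff(evr) <= 1e-12).all()
        assert evr.sum() == pytest.approx(1.0)

    def test_two_point_matches_closed_form_eigendecomposition(self):
        # two distinct sample profiles (0,0) and (2,4), duplicated so each
        # group has two samples; centered rows (-1,-2) and (1,2) have norm
        # sqrt(5), the sole principal direction -> scores +-sqrt(5) on PC1
        values = np.array([[0.0, 0.0, 2.0, 2.0], [0.0, 0.0, 4.0, 4.0]])
        m = _matrix(values, ["case", "case", "control", "control"])
        result = expr.pca(m, k=2)
        np.testing.assert_allclose(np.abs(result.scores["PC1"]),
                                   [np.sqrt(5)] * 4, atol=1e-9)
        assert result.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_k_too_large_rejected(self):
        m = _matrix(np.zeros((3, 4)), ["case"] * 2 + ["control"] * 2)
        with pytest.raises(InputError, match="k="):
            expr.pca(m, k=4)

    def test_case_control_separation_on_planted_data(self, small_truth):
        matrix, _ = small_truth
        result = expr.pca(expr.detection_filter(matrix), k=2)
        case = result.scores.loc[(matrix.groups == "case").values, "PC1"]
        ctrl = result.scores.loc[(matrix.groups == "control").values, "PC1"]
        # planted DE structure separates groups along the leading component
        assert min(case.mean(), ctrl.mean()) + 1e-9 < \
               max(case.mean(), ctrl.mean())
        gap = abs(case.mean() - ctrl.mean())
        spread = np.sqrt(case.var() + ctrl.var())
        assert gap > spread


class TestSeriesMatrixReader:
    def test_reads_geo_layout(self, tmp_path):
        text = ("!Series_title\t\"x\"\n"
                "!series_matrix_table_begin\n"
                "ID_REF\tGSM1\tGSM2\n"
                "probeA\t1.5\t2.5\n"
                "probeB\t3.0\t4.0\n"
                "!series_matrix_table_end\n")
        path = tmp_path / "series.txt"
        path.write_text(text)
        table = expr.read_series_matrix(path)
        assert table.shape == (2, 2)
        assert table.loc["probeB", "GSM2"] == 4.0

    def test_missing_markers_is_error(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("no markers here\n")
        with pytest.raises(InputError, match="markers"):
            expr.read_series_matrix(path)
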