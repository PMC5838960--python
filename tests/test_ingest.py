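import numpy as np
import pandas as pd
import pytest

from mixqc.design import build_manifest, make_default_design
from mixqc.ingest import (
    ExpressionTable,
    cq_to_log2,
    detect_filter,
    normalize_median_total,
    read_expression_table,
    to_log2,
)

from conftest import make_table


@pytest.fixture()
def manifest3():
    return build_manifest(make_default_design(), 3, "full")


class TestReadExpressionTable:
    def _write(self, tmp_path, manifest, sep=","):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(
            rng.integers(0, 100, (3, len(manifest))),
            index=["mir-a", "mir-b", "mir-c"],
            columns=manifest.sample_ids,
        )
        path = tmp_path / "t.txt"
        frame.to_csv(path, sep=sep, index_label="mirna_id")
        return path, frame

    @pytest.mark.parametrize("sep", [",", "\t"])
    def test_round_trip_with_delimiter_detection(self, tmp_path, manifest3, sep):
        path, frame = self._write(tmp_path, manifest3, sep)
        table = read_expression_table(path, "counts", manifest3)
        assert table.values.shape == (3, 15)
        np.testing.assert_allclose(table.values.to_numpy(), frame.to_numpy())

    def test_missing_manifest_sample_named(self, tmp_path, manifest3):
        path, frame = self._write(tmp_path, manifest3)
        frame.drop(columns=["mix2_rep3"]).to_csv(path, index_label="mirna_id")
        with pytest.raises(ValueError, match="mix2_rep3"):
            read_expression_table(path, "counts", manifest3)

    def test_duplicate_mirna_id_rejected(self, tmp_path, manifest3):
        path, frame = self._write(tmp_path, manifest3)
        dup = pd.concat([frame, frame.iloc[[0]]])
        dup.to_csv(path, index_label="mirna_id")
        with pytest.raises(ValueError, match="duplicated"):
            read_expression_table(path, "counts", manifest3)

    def test_non_numeric_cell_located(self, tmp_path, manifest3):
        path, frame = self._write(tmp_path, manifest3)
        frame = frame.astype(object)
        frame.iloc[1, 2] = "oops"
        frame.to_csv(path, index_label="mirna_id")
        with pytest.raises(ValueError, match="mir-b"):
            read_expression_table(path, "counts", manifest3)

    def test_negative_counts_rejected(self, tmp_path, manifest3):
        path, frame = self._write(tmp_path, manifest3)
        frame.iloc[0, 0] = -1
        frame.to_csv(path, index_label="mirna_id")
        with pytest.raises(ValueError, match="nonnegative"):
            read_expression_table(path, "counts", manifest3)


class TestDetectFilter:
    def test_single_count_in_one_sample_is_detected(self, default_design):
        values = np.zeros((2, 5))
        values[0, -1] = 1.0
        table = make_table(values, default_design)
        out = detect_filter(table)
        assert out.mirna_ids == ["m0"]
        assert out.provenance["detect_filter"] == {
            "threshold": 1.0, "retained": 1, "removed": 1,
        }

    def test_engineered_zero_rows_removed(self, default_design):
        rng = np.random.default_rng(1)
        values = rng.integers(1, 50, (10, 5)).astype(float)
        zero_rows = [1, 4, 5, 8]
        values[zero_rows] = 0.0
        table = make_table(values, default_design)
        out = detect_filter(table)
        # oracle: direct scan of the stated predicate
        expected = [f"m{i}" for i in range(10) if values[i].max() >= 1]
        assert out.mirna_ids == expected
        assert len(out.mirna_ids) == 6

    def test_idempotent(self, default_design):
        rng = np.random.default_rng(2)
        values = rng.poisson(0.5, (20, 5)).astype(float)
        table = make_table(values, default_design)
        once = detect_filter(table)
        twice = detect_filter(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_all_removed_warns_not_raises(self, default_design):
        table = make_table(np.zeros((3, 5)), default_design)
        with pytest.warns(UserWarning, match="every miRNA"):
            out = detect_filter(table)
        assert len(out.mirna_ids) == 0


class TestNormalizeMedianTotal:
    def test_scale_factors_from_median_total(self, default_design):
        # three columns with totals 100, 200, 400 -> factors 2.0, 1.0, 0.5
        three = build_manifest(default_design, 1, "full").subset(
            ["liver_rep1", "brain_rep1", "placenta_rep1"]
        )
        frame = pd.DataFrame(
            {"liver_rep1": [60.0, 40.0], "brain_rep1": [150.0, 50.0],
             "placenta_rep1": [300.0, 100.0]},
            index=["m0", "m1"],
        )
        table = ExpressionTable(frame, "counts", three)
        out = normalize_median_total(table)
        factors = out.provenance["normalize_median_total"]["scale_factors"]
        assert factors == {"liver_rep1": 2.0, "brain_rep1": 1.0, "placenta_rep1": 0.5}
        np.testing.assert_allclose(out.values.sum(axis=0), 200.0)

    def test_equal_totals_is_identity(self, default_design):
        values = np.full((4, 5), 10.0)
        table = make_table(values, default_design)
        out = normalize_median_total(table)
        np.testing.assert_allclose(out.values.to_numpy(), values)

    def test_preserves_within_column_order_and_cross_ratios(self, default_design):
        rng = np.random.default_rng(3)
        values = rng.gamma(2.0, 50.0, (30, 5))
        table = make_table(values, default_design)
        out = normalize_median_total(table)
        for col in out.values.columns:
            assert (
                out.values[col].rank() == table.values[col].rank()
            ).all()

    def test_zero_total_column_identified(self, default_design):
        values = np.ones((3, 5))
        values[:, 2] = 0.0
        table = make_table(values, default_design)
        with pytest.raises(ValueError, match="placenta_rep1"):
            normalize_median_total(table)


class TestLog2Transforms:
    @pytest.mark.parametrize("value,pc,expected", [(8.0, 0.0, 3.0), (0.0, 1.0, 0.0)])
    def test_pointwise_values(self, default_design, value, pc, expected):
        table = make_table(np.full((1, 5), value), default_design)
        out = to_log2(table, pc)
        assert out.values.iloc[0, 0] == pytest.approx(expected)
        assert out.provenance["log2"]["pseudocount"] == pc

    def test_zero_with_zero_pseudocount_errors(self, default_design):
        table = make_table(np.zeros((1, 5)), default_design)
        with pytest.raises(ValueError, match="positive"):
            to_log2(table, 0.0)

    def test_invertible(self, default_design):
        rng = np.random.default_rng(4)
        values = rng.gamma(1.5, 100.0, (25, 5))
        table = make_table(values, default_design)
        out = to_log2(table, 1.0)
        back = 2.0 ** out.values - 1.0
        np.testing.assert_allclose(back.to_numpy(), values, rtol=1e-9)

    def test_cq_negation(self, default_design):
        values = np.array([[25.0, 24.0, 0.0, 30.0, 31.5]])
        table = make_table(values, default_design, kind="cq")
        out = cq_to_log2(table)
        np.testing.assert_allclose(out.values.to_numpy(), -values)
        # one cycle difference = one log2 unit difference
        assert out.values.iloc[0, 0] - out.values.iloc[0, 1] == pytest.approx(-1.0)

    def test_cq_path_guards(self, default_design):
        counts = make_table(np.ones((1, 5)), default_design)
        with pytest.raises(ValueError, match="cq"):
            cq_to_log2(counts)
        cq = make_table(np.ones((1, 5)), default_design, kind="cq")
        with pytest.raises(ValueError):
            detect_filter(cq)
        with pytest.raises(ValueError):
            normalize_median_total(cq)
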