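import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from emtsig.expression import (
    ExpressionMatrix,
    IngestionError,
    autoscale,
    compute_log_ratios,
    median_reference_scale,
    pca,
    read_expression_matrix,
    write_expression_matrix,
)


def cellline_annotation(samples, units, treatments):
    return pd.DataFrame({
        "sample_id": samples,
        "unit_id": units,
        "treatment": treatments,
        "time_hours": 0.0,
        "phenotype_class": "EMT-responder",
    })


class TestIO:
    def test_shape_follows_file(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("probeset_id\tS1\tS2\nA\t1.0\t2.0\nB\t3.5\t4.5\nC\t5\t6\n")
        m = read_expression_matrix(p)
        assert m.shape == (3, 2)
        assert m.probeset_ids == ["A", "B", "C"]

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.lists(st.floats(allow_nan=False, allow_infinity=False,
                              width=64), min_size=6, max_size=6))
    def test_write_read_roundtrip_bit_exact(self, tmp_path_factory, values):
        vals = pd.DataFrame(np.array(values).reshape(3, 2),
                            index=["A", "B", "C"], columns=["S1", "S2"])
        m = ExpressionMatrix(vals)
        p = tmp_path_factory.mktemp("rt") / "m.tsv"
        write_expression_matrix(m, p)
        back = read_expression_matrix(p)
        assert np.array_equal(back.values.to_numpy(), m.values.to_numpy())
        assert back.probeset_ids == m.probeset_ids
        assert back.sample_ids == m.sample_ids

    def test_duplicate_probeset_id_named(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("probeset_id\tS1\nA\t1.0\nA\t2.0\n")
        with pytest.raises(IngestionError, match="A"):
            read_expression_matrix(p)

    def test_duplicate_sample_id_named(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("probeset_id\tS1\tS1\nA\t1.0\t2.0\n")
        with pytest.raises(IngestionError, match="S1"):
            read_expression_matrix(p)

    def test_non_numeric_cell_located(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("probeset_id\tS1\tS2\nA\t1.0\t2.0\nB\tfoo\t4.0\n")
        with pytest.raises(IngestionError, match=r"'B'.*'S1'"):
            read_expression_matrix(p)

    def test_gene_mapping_with_missing_sentinel(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("probeset_id\tS1\nA\t1.0\nB\t2.0\n")
        g = tmp_path / "map.tsv"
        g.write_text("probeset_id\tgene_symbol\nA\tTP53\n")
        m = read_expression_matrix(p, g)
        assert m.gene_symbols["A"] == "TP53"
        assert m.gene_symbols["B"] == ""

    def test_missing_value_rejected(self):
        vals = pd.DataFrame([[1.0, np.nan]], index=["A"], columns=["S1", "S2"])
        with pytest.raises(IngestionError, match="missing"):
            ExpressionMatrix(vals)


class TestMedianReferenceScale:
    def test_common_median_is_identity(self, tiny_matrix):
        shifted = tiny_matrix.values.sub(tiny_matrix.values.median(axis=0), axis=1)
        m = ExpressionMatrix(shifted)
        out = median_reference_scale(m)
        assert np.allclose(out.values, m.values)

    def test_two_sample_shift(self):
        vals = pd.DataFrame({"S1": [4.0, 5.0, 6.0], "S2": [6.0, 7.0, 8.0]},
                            index=["A", "B", "C"])
        out = median_reference_scale(ExpressionMatrix(vals))
        assert np.allclose(out.values["S1"], [4.0, 5.0, 6.0])
        assert np.allclose(out.values["S2"], [4.0, 5.0, 6.0])

    def test_idempotent(self, tiny_matrix):
        once = median_reference_scale(tiny_matrix)
        twice = median_reference_scale(once)
        assert np.allclose(once.values, twice.values)

    def test_single_sample_warns_unchanged(self, caplog):
        vals = pd.DataFrame({"S1": [1.0, 2.0]}, index=["A", "B"])
        with caplog.at_level("WARNING"):
            out = median_reference_scale(ExpressionMatrix(vals))
        assert np.allclose(out.values, vals)
        assert "single-sample" in caplog.text


class TestLogRatios:
    def test_ratio_against_control_mean(self):
        vals = pd.DataFrame({"U1": [5.0], "U2": [5.2], "T1": [6.1]}, index=["P"])
        ann = cellline_annotation(["U1", "U2", "T1"], ["L"] * 3,
                                  ["untreated", "untreated", "treated"])
        out = compute_log_ratios(ExpressionMatrix(vals), ann)
        assert out.values.loc["P", "T1"] == pytest.approx(1.0)
        # an untreated control is ratioed against the same mean
        assert out.values.loc["P", "U1"] == pytest.approx(-0.1)

    def test_identical_samples_give_zero(self):
        vals = pd.DataFrame({"U1": [3.0], "T1": [3.0]}, index=["P"])
        ann = cellline_annotation(["U1", "T1"], ["L", "L"], ["untreated", "treated"])
        out = compute_log_ratios(ExpressionMatrix(vals), ann)
        assert np.allclose(out.values, 0.0)

    def test_control_mean_maps_to_zero_vector(self):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(rng.normal(8, 1, (10, 4)),
                            index=[f"P{i}" for i in range(10)],
                            columns=["U1", "U2", "T1", "T2"])
        ann = cellline_annotation(list(vals.columns), ["L"] * 4,
                                  ["untreated", "untreated", "treated", "treated"])
        out = compute_log_ratios(ExpressionMatrix(vals), ann)
        assert np.allclose(out.values[["U1", "U2"]].mean(axis=1), 0.0, atol=1e-12)

    def test_unit_without_controls_errors(self):
        vals = pd.DataFrame({"T1": [3.0]}, index=["P"])
        ann = cellline_annotation(["T1"], ["LX"], ["treated"])
        with pytest.raises(IngestionError, match="LX"):
            compute_log_ratios(ExpressionMatrix(vals), ann)


class TestAutoscale:
    def test_rows_have_zero_mean_unit_sd(self, tiny_matrix):
        out = autoscale(tiny_matrix)
        assert np.allclose(out.values.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(out.values.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_constant_row_dropped_with_warning(self, caplog):
        vals = pd.DataFrame([[4.0, 4.0, 4.0], [1.0, 2.0, 3.0]],
                            index=["K", "V"], columns=["a", "b", "c"])
        with caplog.at_level("WARNING"):
            out = autoscale(ExpressionMatrix(vals))
        assert out.probeset_ids == ["V"]
        assert "K" in caplog.text

    def test_idempotent(self, tiny_matrix):
        once = autoscale(tiny_matrix)
        twice = autoscale(once)
        assert np.allclose(once.values, twice.values, atol=1e-12)

    def test_total_variance_equals_row_count(self, tiny_matrix):
        out = autoscale(tiny_matrix)
        total = out.values.var(axis=1, ddof=1).sum()
        assert total == pytest.approx(out.shape[0], abs=1e-6)


class TestPCA:
    def _random_autoscaled(self, seed, shape=(30, 12)):
        rng = np.random.default_rng(seed)
        vals = pd.DataFrame(rng.normal(0, 1, shape),
                            index=[f"P{i}" for i in range(shape[0])],
                            columns=[f"S{i}" for i in range(shape[1])])
        return autoscale(ExpressionMatrix(vals))

    def test_loadings_orthonormal_and_variance_ordered(self):
        m = self._random_autoscaled(1)
        res = pca(m, 5)
        G = res.loadings.to_numpy().T @ res.loadings.to_numpy()
        assert np.allclose(G, np.eye(5), atol=1e-8)
        assert np.all(np.diff(res.pct_variance) <= 1e-12)
        assert res.pct_variance.sum() <= 100 + 1e-9
        assert np.all(res.pct_variance >= 0)

    def test_scores_are_projection_of_data(self):
        m = self._random_autoscaled(2)
        res = pca(m, 3)
        X = m.values.to_numpy().T
        assert np.allclose(res.scores.to_numpy(), X @ res.loadings.to_numpy())

    def test_rank_one_matrix_fully_captured_by_pc1(self):
        load = np.array([1.0, -2.0, 0.5, 1.5])
        score = np.array([3.0, -1.0, 0.5, 2.0, -2.5])
        vals = pd.DataFrame(np.outer(load, score),
                            index=list("ABCD"), columns=[f"S{i}" for i in range(5)])
        res = pca(ExpressionMatrix(vals), 1)
        assert res.pct_variance[0] == pytest.approx(100.0)

    def test_sample_permutation_equivariance(self):
        m = self._random_autoscaled(3)
        res = pca(m, 2)
        perm = list(m.sample_ids[::-1])
        m2 = ExpressionMatrix(m.values[perm], m.gene_symbols)
        res2 = pca(m2, 2)
        assert np.allclose(res2.loadings, res.loadings)
        assert np.allclose(res2.scores.loc[m.sample_ids], res.scores)

    def test_pc1_recovers_planted_latent_axis(self):
        rng = np.random.default_rng(7)
        z = rng.normal(0, 1, 60)
        signs = rng.choice([-1.0, 1.0], 40)
        vals = pd.DataFrame(np.outer(signs, z) + rng.normal(0, 0.1, (40, 60)),
                            index=[f"P{i}" for i in range(40)],
                            columns=[f"S{i}" for i in range(60)])
        res = pca(autoscale(ExpressionMatrix(vals)), 1)
        r = np.corrcoef(res.scores["PC1"], z)[0, 1]
        assert abs(r) > 0.99

    def test_too_many_components_rejected(self, tiny_matrix):
        with pytest.raises(ValueError):
            pca(tiny_matrix, 4)
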