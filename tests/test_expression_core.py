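import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exprland.expression_core import (ExpressionProfile, RawCountsMatrix,
                                      absolute_expression, compute_tpm,
                                      pseudobulk, qc_filter, quantile_bins,
                                      quantile_normalize, read_expression_tsv,
                                      relative_expression, rescale_context,
                                      sex_stratify, tmm_norm_factors,
                                      top_fraction_genes)


def df(values, genes=None, contexts=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    contexts = contexts or [f"c{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=contexts)


class TestTPM:
    def test_single_gene_rescales_to_one_million(self):
        raw = RawCountsMatrix(df([[7.0]]), pd.Series([2.0], index=["g0"]))
        tpm = rescale_context(compute_tpm(raw))
        assert tpm.iloc[0, 0] == pytest.approx(1e6)

    def test_two_gene_hand_computation(self):
        # reads {10, 30}, lengths {1, 2} kb, 40 mapped reads
        raw = RawCountsMatrix(df([[10.0], [30.0]]),
                              pd.Series([1.0, 2.0], index=["g0", "g1"]))
        tpm = compute_tpm(raw)
        assert tpm["c0"].tolist() == pytest.approx([250_000.0, 375_000.0])
        scaled = rescale_context(tpm)
        assert scaled["c0"].tolist() == pytest.approx([400_000.0, 600_000.0])

    def test_zero_read_sample_errors(self):
        raw = RawCountsMatrix(df([[0.0], [0.0]]),
                              pd.Series([1.0, 1.0], index=["g0", "g1"]))
        with pytest.raises(ValueError, match="c0"):
            compute_tpm(raw)

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError, match="g0"):
            RawCountsMatrix(df([[1.0]]), pd.Series([-1.0], index=["g0"]))


class TestRescale:
    def test_proportions_preserved(self):
        out = rescale_context(df([[1.0], [3.0]]))
        assert out["c0"].tolist() == pytest.approx([250_000.0, 750_000.0])

    def test_idempotent(self):
        scaled = rescale_context(df([[2.0], [2.0], [2.0], [2.0]]))
        again = rescale_context(scaled)
        pd.testing.assert_frame_equal(scaled, again)
        assert (scaled["c0"] == 250_000.0).all()

    def test_all_zero_context_errors(self):
        with pytest.raises(ValueError, match="c0"):
            rescale_context(df([[0.0], [0.0]]))

    @given(st.lists(st.floats(0.01, 1e5), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_column_sums_exactly_one_million(self, values):
        out = rescale_context(df(np.array(values)[:, None]))
        assert out.sum(axis=0).iloc[0] == pytest.approx(1e6, rel=1e-6)


class TestQCFilter:
    def _meta(self, n_samples, exclude=None):
        meta = pd.DataFrame({"n_samples": n_samples})
        if exclude is not None:
            meta["exclude"] = exclude
        return meta

    def test_small_context_dropped_at_boundary(self):
        tpm = df([[1.0, 2.0], [3.0, 4.0]])
        meta = self._meta(pd.Series([99, 100], index=["c0", "c1"]))
        out, log = qc_filter(tpm, meta)
        assert list(out.columns) == ["c1"]
        assert log["contexts_dropped_small"] == ["c0"]

    def test_silent_and_noncoding_genes_dropped(self):
        tpm = df([[1.0, 2.0], [0.0, 0.0], [5.0, 6.0]])
        meta = self._meta(pd.Series([200, 200], index=["c0", "c1"]))
        biotype = pd.Series(["protein_coding", "protein_coding", "lincRNA"],
                            index=["g0", "g1", "g2"])
        out, _ = qc_filter(tpm, meta, gene_biotype=biotype)
        assert list(out.index) == ["g0"]

    def test_tagged_context_dropped_and_identity_otherwise(self):
        tpm = df([[1.0, 2.0, 3.0]])
        meta = self._meta(pd.Series([150, 150, 150], index=["c0", "c1", "c2"]),
                          exclude=pd.Series([False, True, False],
                                            index=["c0", "c1", "c2"]))
        out, _ = qc_filter(tpm, meta)
        assert list(out.columns) == ["c0", "c2"]


class TestAbsoluteRelative:
    @pytest.mark.parametrize("tpm,expected", [(0.0, 0.0), (1.0, 1.0), (3.0, 2.0)])
    def test_absolute_log2(self, tpm, expected):
        assert absolute_expression(df([[tpm]])).iloc[0, 0] == expected

    def test_relative_rows(self):
        A = df([[2.0, 2.0], [1.0, 3.0], [0.0, 5.0], [0.0, 0.0]])
        R = relative_expression(A)
        assert R.loc["g0"].tolist() == pytest.approx([0.5, 0.5])
        assert R.loc["g1"].tolist() == pytest.approx([0.25, 0.75])
        assert R.loc["g2"].tolist() == pytest.approx([0.0, 1.0])
        assert R.loc["g3"].isna().all()  # undefined, flagged not erroneous

    def test_relative_invariant_to_row_scaling(self, rng):
        A = df(rng.uniform(0.1, 8, size=(20, 5)))
        R1 = relative_expression(A)
        R2 = relative_expression(A * 7.5)
        pd.testing.assert_frame_equal(R1, R2)

    def test_profile_layers_consistent(self, rng):
        prof = ExpressionProfile(df(rng.uniform(0, 100, size=(30, 4))))
        defined = prof.r_defined
        sums = prof.R[defined].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
        assert (prof.A.values >= 0).all()


class TestQuantileNormalize:
    def test_rank_mean_by_hand(self):
        mat = df(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
        out = quantile_normalize(mat)
        expected = [2.5, 3.5, 4.5]
        assert out["c0"].tolist() == pytest.approx(expected)
        assert out["c1"].tolist() == pytest.approx(expected)

    def test_identical_columns_unchanged(self):
        mat = df(np.array([[1.0, 1.0], [5.0, 5.0], [2.0, 2.0]]))
        out = quantile_normalize(mat)
        pd.testing.assert_frame_equal(out, mat)

    def test_columns_share_sorted_vector(self, rng):
        mat = df(rng.uniform(0, 50, size=(40, 6)))
        out = quantile_normalize(mat).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 6):
            assert np.allclose(np.sort(out[:, j]), ref)

    def test_permutation_invariance(self, rng):
        mat = df(rng.uniform(0, 50, size=(25, 3)))
        out1 = quantile_normalize(mat)
        perm = rng.permutation(25)
        mat2 = mat.iloc[perm]
        out2 = quantile_normalize(mat2)
        pd.testing.assert_frame_equal(out1.iloc[perm], out2)

    def test_single_sample_warns_identity(self):
        mat = df([[1.0], [2.0]])
        with pytest.warns(UserWarning):
            out = quantile_normalize(mat)
        pd.testing.assert_frame_equal(out, mat)


class TestQuantileBins:
    def test_top_bin_holds_ten_largest(self, rng):
        vals = pd.Series(rng.permutation(np.arange(1.0, 101.0)),
                         index=[f"g{i}" for i in range(100)])
        qb = quantile_bins(vals)
        assert qb.top_decile_set == set(vals.nlargest(10).index)

    def test_zeros_go_to_bin_one(self, rng):
        v = rng.uniform(1, 10, 50)
        v[:12] = 0.0
        vals = pd.Series(v, index=[f"g{i}" for i in range(50)])
        qb = quantile_bins(vals)
        assert (qb.bin[vals == 0] == 1).all()
        assert (qb.bin[vals > 0] >= 2).all()

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            quantile_bins(pd.Series(np.zeros(30)))

    def test_tie_block_stays_together(self):
        # 100 expressed genes; ranks 86..95 tied, straddling the 90% cut
        v = np.arange(1.0, 101.0)
        v[85:95] = 90.0
        vals = pd.Series(v, index=[f"g{i}" for i in range(100)])
        qb = quantile_bins(vals)
        tied_bins = qb.bin[vals == 90.0].unique()
        assert len(tied_bins) == 1
        # mean rank 90.5 -> decile 10 -> bin 11
        assert tied_bins[0] == 11

    def test_bin_sizes_near_equal(self, rng):
        vals = pd.Series(rng.uniform(0.1, 5, 997))
        qb = quantile_bins(vals)
        sizes = qb.bin.value_counts()
        expressed_sizes = sizes[sizes.index >= 2]
        assert expressed_sizes.max() - expressed_sizes.min() <= 1

    def test_top_fraction_matches_sort(self, rng):
        vals = pd.Series(rng.permutation(np.arange(100.0)),
                         index=[f"g{i}" for i in range(100)])
        assert top_fraction_genes(vals, 0.10) == set(vals.nlargest(10).index)


class TestPseudobulk:
    def _cells(self, counts, types):
        genes = [f"g{i}" for i in range(counts.shape[0])]
        cells = [f"cell{i}" for i in range(counts.shape[1])]
        mat = pd.DataFrame(counts, index=genes, columns=cells)
        return mat, pd.Series(types, index=cells)

    def test_one_cell_per_type_is_identity(self):
        mat, labels = self._cells(np.array([[5, 1], [3, 7]]), ["t0", "t1"])
        pb = pseudobulk(mat, labels)
        assert pb.counts["t0"].tolist() == [5, 3]
        assert pb.counts["t1"].tolist() == [1, 7]
        assert pb.n_cells.tolist() == [1, 1]

    def test_identical_types_get_unit_factors(self, rng):
        block = rng.integers(0, 50, size=(30, 1))
        mat, labels = self._cells(np.hstack([block, block]), ["t0", "t1"])
        pb = pseudobulk(mat, labels)
        assert np.allclose(pb.norm_factor, 1.0)
        pd.testing.assert_series_equal(pb.cpm_abs["t0"], pb.cpm_abs["t1"],
                                       check_names=False)

    def test_cpm_invariant_to_uniform_scaling(self, rng):
        counts = rng.integers(1, 100, size=(40, 3))
        mat, labels = self._cells(counts, ["t0", "t1", "t2"])
        pb1 = pseudobulk(mat, labels)
        mat2 = mat.copy()
        mat2.iloc[:, 1] *= 2  # double every count of one cell type
        pb2 = pseudobulk(mat2, labels)
        pd.testing.assert_frame_equal(pb1.cpm_abs, pb2.cpm_abs, atol=1e-8)

    def test_layers_satisfy_invariants(self, rng):
        counts = rng.integers(0, 60, size=(50, 8))
        types = ["t0", "t0", "t1", "t1", "t2", "t2", "t3", "t3"]
        mat, labels = self._cells(counts, types)
        pb = pseudobulk(mat, labels)
        assert np.allclose(pb.cpm_abs.sum(axis=0), 1e6, rtol=1e-6)
        spec = pb.cell_specificity
        nonzero = pb.counts.sum(axis=1) > 0
        assert np.allclose(spec[nonzero].sum(axis=1), 1.0)
        assert ((spec.fillna(0) >= 0) & (spec.fillna(0) <= 1)).all().all()


class TestTMMFactors:
    def test_matches_edger_reference_values(self, rng):
        """Frozen oracle: edgeR::calcNormFactors on this exact matrix."""
        gen = np.random.default_rng(42)
        m = gen.negative_binomial(5, 0.1, size=(300, 4)).astype(float)
        m[:, 1] *= 3
        m[:50, 2] *= 8
        counts = pd.DataFrame(m.astype(int).astype(float),
                              columns=list("ABCD"))
        f = tmm_norm_factors(counts)
        expected = [1.157212, 1.161744, 0.655278, 1.135143]
        assert f.tolist() == pytest.approx(expected, abs=1e-5)


class TestSexStratify:
    def _data(self):
        samples = [f"s{i}" for i in range(6)]
        tpm = pd.DataFrame(
            [[0.0, 0.0, 0.0, 4.0, 4.0, 4.0]], index=["g0"], columns=samples)
        meta = pd.DataFrame({"context": ["liver"] * 6,
                             "sex": ["M", "M", "M", "F", "F", "F"]},
                            index=samples)
        return tpm, meta

    def test_constant_expression_hand_values(self):
        tpm, meta = self._data()
        out = sex_stratify(tpm, meta)
        assert out["M"].A.loc["g0", "liver"] == 0.0
        assert out["F"].A.loc["g0", "liver"] == pytest.approx(np.log2(5))

    def test_identical_sexes_identical_profiles(self, rng):
        samples = [f"s{i}" for i in range(8)]
        vals = np.tile(rng.uniform(0, 10, size=(5, 4)), (1, 2))
        tpm = pd.DataFrame(vals, index=[f"g{i}" for i in range(5)],
                           columns=samples)
        meta = pd.DataFrame({"context": ["a", "a", "b", "b"] * 2,
                             "sex": ["M"] * 4 + ["F"] * 4}, index=samples)
        out = sex_stratify(tpm, meta)
        pd.testing.assert_frame_equal(out["M"].tpm, out["F"].tpm)

    def test_median_midpoint_rule(self):
        samples = ["s0", "s1", "s2", "s3"]
        tpm = pd.DataFrame([[1.0, 3.0, 10.0, 20.0]], index=["g0"],
                           columns=samples)
        meta = pd.DataFrame({"context": ["t"] * 4, "sex": ["M"] * 4},
                            index=samples)
        out = sex_stratify(tpm, meta)
        assert out["M"].tpm.loc["g0", "t"] == pytest.approx((3 + 10) / 2)


class TestIO:
    def test_tsv_round_trip(self, tmp_path, rng):
        mat = df(rng.uniform(0, 100, size=(10, 3)))
        path = tmp_path / "expr.tsv"
        mat.to_csv(path, sep="\t", index_label="gene_id")
        back = read_expression_tsv(path)
        pd.testing.assert_frame_equal(mat, back)

    def test_gct_header_skipped(self, tmp_path):
        path = tmp_path / "expr.gct"
        path.write_text("#1.2\n2\t2\nNAME\tc0\tc1\ng0\t1.0\t2.0\ng1\t3.0\t4.0\n")
        back = read_expression_tsv(path)
        assert back.shape == (2, 2)
        assert back.loc["g1", "c1"] == 4.0
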