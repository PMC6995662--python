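"""I/O and preprocessing: parsing, filters, transforms, promoter aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pandas.testing import assert_frame_equal

from smokesig.containers import OmicsMatrix
from smokesig.preprocess import (
    ParseError,
    aggregate_promoter_me,
    filter_genes,
    filter_samples,
    impute_train_mean,
    intersect_common_genes,
    inverse_transform_cnv,
    load_omics,
    load_sample_table,
    transform_cnv,
    transform_ge,
    write_omics,
)


def _om(layer, data, genes, samples, transformed=False):
    return OmicsMatrix(
        layer,
        pd.DataFrame(data, index=pd.Index(genes, name="symbol"), columns=samples, dtype=float),
        transformed,
    )


class TestLoadOmics:
    def test_na_token_becomes_masked_cell(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("symbol\tS1\tS2\nA\t1.5\t2.0\nB\tNA\t0.5\nC\t3\t4\n")
        m = load_omics(p, "GE")
        assert m.shape == (3, 2)
        assert m.missing_mask.to_numpy().sum() == 1
        assert m.missing_mask.loc["B", "S1"]

    def test_empty_file_is_parse_error(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with pytest.raises(ParseError):
            load_omics(p, "GE")

    def test_duplicate_symbols_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("symbol\tS1\nA\t1\nA\t2\n")
        with pytest.raises(ParseError, match="A"):
            load_omics(p, "GE")

    def test_non_numeric_cell_named(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("symbol\tS1\tS2\nA\t1\t2\nB\toops\t3\n")
        with pytest.raises(ParseError, match=r"'B'.*'S1'"):
            load_omics(p, "GE")

    def test_round_trip_preserves_values_and_mask(self, tmp_path, small_cohort):
        _, (ge, *_r) = small_cohort
        p = write_omics(ge, tmp_path / "ge.tsv")
        back = load_omics(p, "GE")
        assert_frame_equal(ge.values, back.values)
        assert_frame_equal(ge.missing_mask, back.missing_mask)


class TestFilterGenes:
    def test_all_missing_gene_dropped_partially_missing_kept(self):
        m = _om("GE", [[np.nan, np.nan], [np.nan, 2.0], [1.0, 2.0]], list("ABC"), ["S1", "S2"])
        out = filter_genes(m)
        assert out.gene_symbols == ["B", "C"]

    def test_unknown_symbols_removed(self):
        m = _om("GE", [[1.0], [2.0], [3.0]], list("ABC"), ["S1"])
        out = filter_genes(m, valid_symbols={"A", "C"})
        assert out.gene_symbols == ["A", "C"]

    def test_identity_when_everything_valid(self):
        m = _om("GE", [[1.0], [2.0]], list("AB"), ["S1"])
        out = filter_genes(m, valid_symbols={"A", "B"})
        assert_frame_equal(out.values, m.values)


class TestIntersect:
    def test_overlapping_lists_reduce_to_intersection(self):
        t = _om("GE", [[1.0], [2.0], [3.0]], list("ABC"), ["S1"])
        v = _om("GE", [[4.0], [5.0], [6.0]], list("BCD"), ["T1"])
        t2, v2 = intersect_common_genes(t, v)
        assert t2.gene_symbols == v2.gene_symbols == ["B", "C"]
        assert t2.sample_ids == ["S1"] and v2.sample_ids == ["T1"]

    def test_identical_lists_are_identity(self):
        t = _om("GE", [[1.0], [2.0]], list("AB"), ["S1"])
        t2, v2 = intersect_common_genes(t, t)
        assert_frame_equal(t2.values, t.values)

    def test_disjoint_lists_error(self):
        t = _om("GE", [[1.0]], ["A"], ["S1"])
        v = _om("GE", [[1.0]], ["B"], ["T1"])
        with pytest.raises(ValueError, match="no genes shared"):
            intersect_common_genes(t, v)


class TestTransforms:
    def test_cnv_diploid_identities(self):
        m = _om("CNV", [[2.0], [4.0], [1.0]], list("ABC"), ["S1"])
        out = transform_cnv(m)
        assert out.values["S1"].tolist() == [0.0, 1.0, -1.0]
        assert out.transformed

    def test_nonpositive_cnv_errors_listing_genes(self):
        m = _om("CNV", [[2.0], [0.0]], list("AB"), ["S1"])
        with pytest.raises(ValueError, match="B"):
            transform_cnv(m)

    def test_ge_log2_plus_one_tolerates_zero(self):
        m = _om("GE", [[0.0], [3.0]], list("AB"), ["S1"])
        out = transform_ge(m)
        assert out.values["S1"].tolist() == [0.0, 2.0]

    def test_mask_preserved_through_transform(self):
        m = _om("CNV", [[2.0, np.nan]], ["A"], ["S1", "S2"])
        out = transform_cnv(m)
        assert out.missing_mask.loc["A", "S2"]

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1e6), min_size=1, max_size=8))
    def test_cnv_transform_inverse_is_identity(self, vals):
        m = _om("CNV", [[v] for v in vals], [f"G{i}" for i in range(len(vals))], ["S1"])
        back = inverse_transform_cnv(transform_cnv(m))
        assert np.allclose(back.values.to_numpy(), m.values.to_numpy(), rtol=1e-12, atol=1e-12)


class TestPromoterAggregation:
    @pytest.fixture()
    def fixture(self):
        ann = pd.DataFrame(
            {
                "chromosome": ["chr1", "chr1", "chr2"],
                "arm": ["p", "p", "q"],
                "start": [5000, 20000, 5000],
                "end": [9000, 30000, 9000],
                "promoter_start": [3500, 18500, 3500],
                "promoter_end": [5500, 20500, 5500],
            },
            index=pd.Index(["A", "B", "C"], name="symbol"),
        )
        pos = pd.DataFrame(
            {
                "chromosome": ["chr1"] * 6 + ["chr2"] * 4,
                "position": [3600, 5000, 9000, 19000, 20400, 30500, 100, 200, 300, 400],
            },
            index=pd.Index([f"p{i}" for i in range(10)], name="probe"),
        )
        vals = pd.DataFrame(
            np.linspace(0.05, 0.95, 20).reshape(10, 2),
            index=pos.index,
            columns=["S1", "S2"],
        )
        return vals, pos, ann

    def test_matches_brute_force_interval_scan(self, fixture):
        vals, pos, ann = fixture
        out = aggregate_promoter_me(vals, pos, ann)
        # independent brute-force oracle over probe-in-interval membership
        for g, row in ann.iterrows():
            hits = [
                p
                for p in pos.index
                if pos.loc[p, "chromosome"] == row["chromosome"]
                and row["promoter_start"] <= pos.loc[p, "position"] <= row["promoter_end"]
            ]
            if hits:
                expected = vals.loc[hits].mean(axis=0)
                assert np.allclose(out.values.loc[g], expected)
            else:
                assert g not in out.gene_symbols
        assert "C" not in out.gene_symbols  # no promoter probes on chr2 near 3500-5500

    def test_simple_mean_of_in_promoter_probes(self):
        ann = pd.DataFrame(
            {
                "chromosome": ["chr1"], "arm": ["p"], "start": [1000], "end": [2000],
                "promoter_start": [500], "promoter_end": [1500],
            },
            index=pd.Index(["A"], name="symbol"),
        )
        pos = pd.DataFrame(
            {"chromosome": ["chr1", "chr1", "chr1"], "position": [600, 1400, 5000]},
            index=pd.Index(["p0", "p1", "p2"], name="probe"),
        )
        vals = pd.DataFrame(
            {"S1": [0.2, 0.4, 0.9]}, index=pos.index
        )
        out = aggregate_promoter_me(vals, pos, ann)
        assert out.values.loc["A", "S1"] == pytest.approx(0.3)

    def test_missing_probe_values_excluded_from_mean(self):
        ann = pd.DataFrame(
            {
                "chromosome": ["chr1"], "arm": ["p"], "start": [1000], "end": [2000],
                "promoter_start": [500], "promoter_end": [1500],
            },
            index=pd.Index(["A"], name="symbol"),
        )
        pos = pd.DataFrame(
            {"chromosome": ["chr1", "chr1"], "position": [600, 1400]},
            index=pd.Index(["p0", "p1"], name="probe"),
        )
        vals = pd.DataFrame({"S1": [0.2, np.nan]}, index=pos.index)
        out = aggregate_promoter_me(vals, pos, ann)
        assert out.values.loc["A", "S1"] == pytest.approx(0.2)

    def test_permutation_invariant_in_probe_order(self, fixture):
        vals, pos, ann = fixture
        out1 = aggregate_promoter_me(vals, pos, ann)
        perm = np.random.default_rng(0).permutation(len(vals))
        out2 = aggregate_promoter_me(vals.iloc[perm], pos.iloc[perm], ann)
        assert_frame_equal(out1.values, out2.values)


class TestFilterSamples:
    @pytest.fixture()
    def table(self):
        return pd.DataFrame(
            {
                "smoking": ["never", "current", "never", "current"],
                "age": [60, 70, np.nan, 55],
                "gender": ["male", "female", "male", "female"],
                "stage": ["I", None, "II", "III"],
                "vital_status": ["alive", "dead", "alive", "dead"],
            },
            index=pd.Index(["S1", "S2", "S3", "S4"], name="sample_id"),
        )

    def test_sample_lacking_any_clinical_field_removed_everywhere(self, table):
        m = _om("GE", np.arange(8.0).reshape(2, 4), list("AB"), list(table.index))
        kept, m2 = filter_samples(table, m)
        assert list(kept.index) == ["S1", "S4"]
        assert m2.sample_ids == ["S1", "S4"]

    def test_complete_table_is_identity_and_order_preserved(self, table):
        full = table.fillna({"age": 1, "stage": "I"})
        kept, = filter_samples(full)
        assert list(kept.index) == list(full.index)


def test_impute_uses_training_means_only():
    train = pd.DataFrame([[1.0, 3.0], [np.nan, 4.0]], index=["A", "B"], columns=["S1", "S2"])
    val = pd.DataFrame([[np.nan], [np.nan]], index=["A", "B"], columns=["T1"])
    tr, va = impute_train_mean(train, val)
    assert tr.loc["B", "S1"] == 4.0
    assert va.loc["A", "T1"] == 2.0 and va.loc["B", "T1"] == 4.0


def test_sample_table_round_trip(tmp_path, small_cohort):
    _, (_ge, _me, _cnv, samples, *_r) = small_cohort
    p = tmp_path / "samples.tsv"
    samples.to_csv(p, sep="\t")
    back = load_sample_table(p)
    assert list(back.index) == list(samples.index)
    assert (back["smoking"] == samples["smoking"]).all()
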