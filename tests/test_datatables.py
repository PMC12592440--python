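import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coabund.datatables import (
    AbundanceTable,
    FeatureTable,
    TaxonomyMap,
    aggregate_to_rank,
    filter_taxa_by_prevalence,
    intersect_samples,
    qc_features,
    read_abundance_table,
    read_feature_table,
    write_abundance_table,
    write_feature_table,
)


class TestAbundanceIO:
    def test_parse_small_table(self, tmp_path, small_abundance):
        path = tmp_path / "ab.tsv"
        write_abundance_table(small_abundance, path)
        table = read_abundance_table(path, rank="genus")
        assert table.n_samples == 3 and table.n_taxa == 2
        np.testing.assert_allclose(table.values, [[0.1, 0.9], [0.5, 0.5], [0.0, 1.0]])

    def test_negative_value_rejected_with_location(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sample_id\ttA\ttB\ns1\t-0.1\t0.5\n")
        with pytest.raises(ValueError, match="tA"):
            read_abundance_table(path)

    def test_round_trip_full_precision(self, tmp_path, rng):
        df = pd.DataFrame(
            rng.random((5, 4)), index=[f"s{i}" for i in range(5)],
            columns=[f"t{i}" for i in range(4)],
        )
        t = AbundanceTable(df)
        path = tmp_path / "rt.tsv"
        write_abundance_table(t, path)
        back = read_abundance_table(path)
        np.testing.assert_array_equal(back.values, t.values)

    def test_duplicate_ids_rejected(self):
        df = pd.DataFrame([[0.1, 0.2]], index=["s1"], columns=["t", "t"])
        with pytest.raises(ValueError, match="duplicated"):
            AbundanceTable(df)

    def test_nan_abundance_rejected(self):
        df = pd.DataFrame([[np.nan, 0.2], [0.1, 0.3]], index=["a", "b"],
                          columns=["t1", "t2"])
        with pytest.raises(ValueError, match="zeros encode absence"):
            AbundanceTable(df)


class TestAggregation:
    def test_species_sum_to_genus(self, small_taxonomy):
        df = pd.DataFrame(
            [[0.1, 0.2, 0.7]], index=["x"], columns=["s1", "s2", "s3"]
        )
        table = AbundanceTable(df, rank="species")
        out = aggregate_to_rank(table, small_taxonomy, "genus")
        assert out.taxon_ids == ["g1", "g2"]
        np.testing.assert_allclose(out.values, [[0.3, 0.7]])

    def test_same_rank_is_identity(self, small_taxonomy):
        df = pd.DataFrame([[0.4, 0.6]], index=["x"], columns=["s1", "s2"])
        table = AbundanceTable(df, rank="species")
        out = aggregate_to_rank(table, small_taxonomy, "species")
        np.testing.assert_array_equal(out.values, table.values)

    def test_per_sample_mass_conserved(self, rng, small_taxonomy):
        df = pd.DataFrame(
            rng.random((6, 3)), index=[f"x{i}" for i in range(6)],
            columns=["s1", "s2", "s3"],
        )
        table = AbundanceTable(df, rank="species")
        out = aggregate_to_rank(table, small_taxonomy, "family")
        np.testing.assert_allclose(out.values.sum(axis=1), table.values.sum(axis=1),
                                   rtol=0, atol=1e-14)

    def test_orphan_taxa_error(self, small_taxonomy):
        df = pd.DataFrame([[0.5, 0.5]], index=["x"], columns=["s1", "unknown"])
        with pytest.raises(KeyError, match="unknown"):
            aggregate_to_rank(AbundanceTable(df, rank="species"), small_taxonomy, "genus")

    def test_inconsistent_lineage_rejected(self):
        lin = pd.DataFrame(
            {"genus": ["g1", "g1"], "family": ["f1", "f2"]},
            index=pd.Index(["a", "b"], name="taxon_id"),
        )
        with pytest.raises(ValueError, match="inconsistent"):
            TaxonomyMap(lin)


class TestPrevalenceFilter:
    @staticmethod
    def _table(prevalences, n=10):
        cols = {}
        for i, p in enumerate(prevalences):
            col = np.zeros(n)
            col[: int(round(p * n))] = 0.5
            cols[f"t{i}"] = col
        return AbundanceTable(pd.DataFrame(cols, index=[f"s{j}" for j in range(n)]))

    def test_threshold_keeps_expected_count(self):
        out = filter_taxa_by_prevalence(self._table([0.6, 0.4, 0.0]), 0.5)
        assert out.taxon_ids == ["t0"]

    def test_boundary_prevalence_kept(self):
        out = filter_taxa_by_prevalence(self._table([0.5, 0.4]), 0.5)
        assert "t0" in out.taxon_ids

    def test_tiny_threshold_keeps_all_nonzero(self):
        out = filter_taxa_by_prevalence(self._table([0.6, 0.4, 0.0]), 1e-9)
        assert out.taxon_ids == ["t0", "t1"]

    def test_no_survivor_errors(self):
        with pytest.raises(ValueError, match="no taxa"):
            filter_taxa_by_prevalence(self._table([0.1, 0.1]), 0.9)

    @given(st.floats(min_value=0.05, max_value=1.0))
    @settings(max_examples=20, deadline=None)
    def test_idempotent(self, threshold):
        table = self._table([0.1, 0.3, 0.5, 0.8, 1.0])
        try:
            once = filter_taxa_by_prevalence(table, threshold)
        except ValueError:
            return
        twice = filter_taxa_by_prevalence(once, threshold)
        assert once.taxon_ids == twice.taxon_ids


class TestFeatureQC:
    @staticmethod
    def _features(cols, types):
        n = max(len(v) for v in cols.values())
        df = pd.DataFrame(cols, index=[f"s{i}" for i in range(n)])
        return FeatureTable(df, types)

    def test_rare_binary_dropped(self):
        vals = np.zeros(100)
        vals[:3] = 1  # minor-class frequency 0.03 < 0.05
        ft = self._features({"b": vals}, {"b": "binary"})
        out, report = qc_features(ft, min_binary_freq=0.05)
        assert out.feature_ids == []
        assert report.loc[report.feature == "b", "action"].item() == "dropped"

    def test_missingness_dropped(self):
        vals = np.r_[np.full(60, np.nan), np.ones(40)]
        ft = FeatureTable(
            pd.DataFrame({"m": vals}, index=[f"s{i}" for i in range(100)]),
            {"m": "continuous"},
        )
        out, report = qc_features(ft, max_missing_frac=0.5)
        assert report.loc[report.feature == "m", "action"].item() == "dropped"

    def test_outlier_category_merged_into_nearest(self):
        # 500 zeros, 430 ones, 8 sevens: coded mean 0.518, sd 0.780 so the
        # category 7 sits 8.3 sd out and merges into category 1
        vals = np.r_[np.zeros(500), np.ones(430), np.full(8, 7.0)]
        ft = FeatureTable(
            pd.DataFrame({"c": vals}, index=[f"s{i}" for i in range(938)]),
            {"c": "categorical"},
        )
        out, report = qc_features(ft, outlier_sd=3.0)
        assert report.loc[report.feature == "c", "action"].item() == "merged"
        merged = out.data["c"]
        assert set(merged.unique()) == {0.0, 1.0}
        assert (merged == 1.0).sum() == 438

    def test_report_partitions_features(self):
        vals = np.r_[np.zeros(500), np.ones(430), np.full(8, 7.0)]
        n = 938
        ft = FeatureTable(
            pd.DataFrame(
                {"c": vals, "ok": np.tile([0.0, 1.0], n // 2),
                 "miss": np.full(n, np.nan)},
                index=[f"s{i}" for i in range(n)],
            ),
            {"c": "categorical", "ok": "binary", "miss": "continuous"},
        )
        out, report = qc_features(ft)
        assert sorted(report.feature) == ["c", "miss", "ok"]
        assert report.feature.is_unique


def test_intersect_samples_aligns_order(small_abundance, feature_table):
    ab = AbundanceTable(
        small_abundance.data.rename(index={"s1": "s0", "s2": "s1", "s3": "s2"})
    )
    a2, f2 = intersect_samples(ab, feature_table)
    assert a2.sample_ids == f2.sample_ids


def test_feature_sidecar_round_trip(tmp_path, feature_table):
    p, tp = tmp_path / "f.tsv", tmp_path / "ft.tsv"
    write_feature_table(feature_table, p, tp)
    back = read_feature_table(p, tp)
    assert back.feature_types == feature_table.feature_types
    np.testing.assert_allclose(back.data.to_numpy(), feature_table.data.to_numpy())
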