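"""Scat data model, CSV I/O and occurrence tabulation."""

import numpy as np
import pandas as pd
import pytest

import scatniche as sn
from scatniche.scat_data import SchemaError


class TestReadScats:
    def test_rows_sharing_scat_id_group_into_one_record(self, scats_csv):
        path = scats_csv([("s1", "R", 2015, "catfish"), ("s1", "R", 2015, "crab")])
        coll = sn.read_scats(path)
        assert len(coll) == 1
        assert set(coll.records[0].items) == {"catfish", "crab"}

    def test_identical_rows_collapse_to_presence_with_warning(self, scats_csv):
        path = scats_csv([("s1", "R", 2015, "catfish"), ("s1", "R", 2015, "catfish")])
        with pytest.warns(UserWarning, match="duplicate taxon"):
            coll = sn.read_scats(path)
        assert coll.records[0].items == ("catfish",)

    def test_header_only_file_is_an_error(self, scats_csv):
        path = scats_csv([])
        with pytest.raises(SchemaError, match="header only"):
            sn.read_scats(path)

    def test_missing_column_is_a_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"scat_id": ["s1"], "river": ["R"]}).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="missing required column"):
            sn.read_scats(path)

    def test_conflicting_group_labels_within_a_scat_rejected(self, scats_csv):
        path = scats_csv([("s1", "R", 2015, "a"), ("s1", "Q", 2015, "b")])
        with pytest.raises(SchemaError, match="conflicting river"):
            sn.read_scats(path)

    def test_blank_taxon_means_empty_scat(self, scats_csv):
        path = scats_csv([("s1", "R", 2015, ""), ("s2", "R", 2015, "a")])
        coll = sn.read_scats(path)
        by_id = {r.scat_id: r for r in coll}
        assert by_id["s1"].items == ()
        assert by_id["s2"].items == ("a",)


class TestScatRecord:
    def test_duplicate_items_rejected_by_constructor(self):
        with pytest.raises(ValueError, match="duplicate taxon"):
            sn.ScatRecord("s1", "R", 2015, ("a", "a"))

    def test_nonpositive_year_rejected(self):
        with pytest.raises(ValueError, match="year"):
            sn.ScatRecord("s1", "R", 0, ("a",))

    def test_duplicate_scat_ids_rejected_in_collection(self):
        recs = [sn.ScatRecord("s1", "R", 2015, ("a",)), sn.ScatRecord("s1", "R", 2015, ("b",))]
        with pytest.raises(ValueError, match="duplicate scat_id"):
            sn.ScatCollection(recs)


class TestTabulateOccurrences:
    @pytest.mark.parametrize(
        "river, year, taxon, n_records, pct_records",
        [
            ("Pasion", 2015, "Pterygoplichthys spp", 36, 49.3),
            ("Pasion", 2010, "Pterygoplichthys spp", 14, 9.9),
            ("San Pedro", 2015, "Pterygoplichthys spp", 75, 26.0),
        ],
    )
    def test_armored_catfish_record_percentages(
        self, occurrence, river, year, taxon, n_records, pct_records
    ):
        """Catfish share of diet records per group, to table precision."""
        sub = occurrence.per_taxon
        row = sub[(sub.river == river) & (sub.year == year) & (sub.taxon == taxon)].iloc[0]
        assert row.n_records == n_records
        assert round(row.pct_records, 1) == pct_records

    def test_single_scat_single_item_gives_100_percent(self):
        coll = sn.ScatCollection([sn.ScatRecord("s1", "R", 2015, ("a",))])
        occ = sn.tabulate_occurrences(coll)
        row = occ.per_taxon.iloc[0]
        assert row.pct_scats == 100.0 and row.pct_records == 100.0

    def test_pct_records_sums_to_100_within_each_group(self, occurrence):
        sums = occurrence.per_taxon.groupby(["river", "year"])["pct_records"].sum()
        assert np.allclose(sums, 100.0, atol=0.1)

    def test_invariant_to_record_order_and_id_relabeling(self, table3_collection):
        rng = np.random.default_rng(5)
        recs = list(table3_collection.records)
        rng.shuffle(recs)
        relabeled = [
            sn.ScatRecord(f"x{i}", r.river, r.year, r.items, r.contaminated)
            for i, r in enumerate(recs)
        ]
        occ_a = sn.tabulate_occurrences(table3_collection).per_taxon
        occ_b = sn.tabulate_occurrences(sn.ScatCollection(relabeled)).per_taxon
        pd.testing.assert_frame_equal(occ_a, occ_b)

    def test_round_trip_preserves_occurrence_table(self, table3_collection, tmp_path):
        path = tmp_path / "rt.csv"
        sn.write_scats(table3_collection, path)
        occ_a = sn.tabulate_occurrences(table3_collection).per_taxon
        occ_b = sn.tabulate_occurrences(sn.read_scats(path)).per_taxon
        pd.testing.assert_frame_equal(occ_a, occ_b)

    def test_group_of_empty_scats_omitted_with_warning(self):
        coll = sn.ScatCollection(
            [sn.ScatRecord("s1", "R", 2015, ()), sn.ScatRecord("s2", "Q", 2015, ("a",))]
        )
        with pytest.warns(UserWarning, match="no prey records"):
            occ = sn.tabulate_occurrences(coll)
        assert occ.per_group.river.tolist() == ["Q"]

    def test_empty_collection_is_an_error(self):
        with pytest.raises(SchemaError):
            sn.tabulate_occurrences(sn.ScatCollection([]))


class TestPreyFilter:
    def test_length_threshold_is_inclusive(self, prey_ref):
        tab = pd.DataFrame(
            {
                "taxon": ["a", "b", "c"],
                "family": ["F"] * 3,
                "ftl": [2.0, 3.0, 4.0],
                "max_total_length_mm": [90.0, 100.0, 250.0],
                "ftl_source": ["x"] * 3,
            }
        )
        out = sn.filter_prey_by_length(sn.PreyReference(tab), 100)
        assert out.taxa() == ["b", "c"]
        assert sn.filter_prey_by_length(sn.PreyReference(tab), 0).taxa() == ["a", "b", "c"]

    def test_missing_lengths_retained_with_warning(self):
        tab = pd.DataFrame(
            {
                "taxon": ["a", "b"],
                "family": ["F", "F"],
                "ftl": [2.0, 3.0],
                "max_total_length_mm": [np.nan, np.nan],
                "ftl_source": ["x", "x"],
            }
        )
        with pytest.warns(UserWarning, match="retained despite"):
            out = sn.filter_prey_by_length(sn.PreyReference(tab), 100)
        assert out.taxa() == ["a", "b"]

    def test_ftl_below_one_rejected(self):
        tab = pd.DataFrame(
            {
                "taxon": ["a"],
                "family": ["F"],
                "ftl": [0.5],
                "max_total_length_mm": [200.0],
                "ftl_source": ["x"],
            }
        )
        with pytest.raises(ValueError, match="FTL must be >= 1"):
            sn.PreyReference(tab)


class TestIsotopeIO:
    def test_positive_d13C_warns_but_loads(self, tmp_path):
        path = tmp_path / "iso.csv"
        pd.DataFrame(
            {
                "scat_id": ["i1", "i2"],
                "river": ["R", "R"],
                "year": [2015, 2015],
                "d15N": [10.0, 11.0],
                "d13C": [1.0, -28.0],
            }
        ).to_csv(path, index=False)
        with pytest.warns(UserWarning, match="d13C >= 0"):
            df = sn.read_isotopes(path)
        assert len(df) == 2

    def test_missing_isotope_column_is_schema_error(self, tmp_path):
        path = tmp_path / "iso.csv"
        pd.DataFrame({"scat_id": ["i1"], "river": ["R"], "year": [2015], "d15N": [10.0]}).to_csv(
            path, index=False
        )
        with pytest.raises(SchemaError, match="d13C"):
            sn.read_isotopes(path)
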