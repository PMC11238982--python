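import io
import textwrap

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from basindiv import occurrences as occ
from basindiv import synthetic
from basindiv.grid import GridSpec

from conftest import make_pam


def _csv(text):
    return io.StringIO(textwrap.dedent(text))


class TestReadOccurrences:
    def test_well_formed(self, tmp_path):
        p = tmp_path / "occ.csv"
        p.write_text(textwrap.dedent("""\
            scientificName,taxonRank,decimalLatitude,decimalLongitude,eventDate
            Aus bus,species,-33.5,-72.5,2001-05-04
            Cus dus,species,-34.5,-71.5,2002-06-05
            Eus fus,species,-35.5,-70.5,2003-07-06
        """))
        rt = occ.read_occurrences(p)
        assert len(rt) == 3
        assert rt["latitude"].tolist() == [-33.5, -34.5, -35.5]

    def test_unparseable_coordinate_becomes_missing(self, tmp_path):
        p = tmp_path / "occ.csv"
        p.write_text("scientificName,decimalLatitude,decimalLongitude\nAus bus,abc,-72.5\n")
        rt = occ.read_occurrences(p)
        assert len(rt) == 1
        assert np.isnan(rt["latitude"].iloc[0])

    def test_missing_name_column_errors(self, tmp_path):
        p = tmp_path / "occ.csv"
        p.write_text("decimalLatitude,decimalLongitude\n1,2\n")
        with pytest.raises(ValueError, match="scientific name"):
            occ.read_occurrences(p)

    def test_synthetic_row_count_preserved(self, tmp_path, clean_records_fixture):
        p = tmp_path / "sim.csv"
        clean_records_fixture.to_csv(p, index=False)
        rt = occ.read_occurrences(p)
        assert len(rt) == len(clean_records_fixture)


class TestCleanRecords:
    def _table(self, rows):
        df = pd.DataFrame(rows, columns=["scientific_name", "taxon_rank", "latitude",
                                         "longitude", "event_date", "depth_min",
                                         "depth_max"])
        return occ.record_table_from_frame(df)

    def test_zero_coords_dropped(self):
        rt = self._table([("Aus bus", "species", 0.0, 0.0, "2000-01-01", 10, 10)])
        out, rep = occ.clean_records(rt)
        assert len(out) == 0
        assert rep.dropped == {"zero_coords": 1}

    def test_missing_coords_rule_first(self):
        rt = self._table([("Aus bus", "species", None, 0.0, "2000-01-01", 10, 10)])
        _, rep = occ.clean_records(rt)
        assert rep.dropped == {"missing_coords": 1}

    def test_duplicates_keep_first(self):
        row = ("Aus bus", "species", -33.5, -72.5, "2000-01-01", 10.0, 10.0)
        rt = self._table([row, row])
        out, rep = occ.clean_records(rt)
        assert len(out) == 1
        assert rep.dropped == {"duplicate": 1}

    def test_depth_window(self):
        rt = self._table([
            ("Aus bus", "species", -33.5, -72.5, "2000-01-01", 10.0, 10.0),
            ("Aus bus", "species", -33.5, -72.4, "2000-01-01", 250.0, 260.0),
            ("Aus bus", "species", -33.5, -72.3, "2000-01-01", None, None),
        ])
        out, rep = occ.clean_records(rt)
        assert len(out) == 2
        assert rep.dropped == {"outside_depth": 1}

    def test_period_window(self):
        rt = self._table([
            ("Aus bus", "species", -33.5, -72.5, "1980-01-01", 10.0, 10.0),
            ("Aus bus", "species", -33.5, -72.4, "2000-01-01", 10.0, 10.0),
        ])
        out, rep = occ.clean_records(rt)
        assert len(out) == 1
        assert rep.dropped == {"outside_period": 1}

    def test_non_species_rank(self):
        rt = self._table([
            ("Aus", "genus", -33.5, -72.5, "2000-01-01", 10.0, 10.0),
            ("Aus bus", "species", -33.5, -72.4, "2000-01-01", 10.0, 10.0),
        ])
        out, rep = occ.clean_records(rt)
        assert len(out) == 1
        assert rep.dropped == {"non_species_rank": 1}

    def test_rank_heuristic_when_missing(self):
        rt = self._table([
            ("Aus bus", None, -33.5, -72.5, "2000-01-01", 10.0, 10.0),
            ("Aus", None, -33.5, -72.4, "2000-01-01", 10.0, 10.0),
        ])
        with pytest.warns(UserWarning, match="heuristic"):
            out, rep = occ.clean_records(rt)
        assert len(out) == 1

    def test_land_mask(self):
        land = box(-73.0, -34.0, -72.0, -33.0)
        rt = self._table([
            ("Aus bus", "species", -33.5, -72.5, "2000-01-01", 10.0, 10.0),  # on land
            ("Aus bus", "species", -35.5, -75.5, "2000-01-01", 10.0, 10.0),
        ])
        out, rep = occ.clean_records(rt, occ.CleaningRules(land_mask=land))
        assert len(out) == 1
        assert rep.dropped == {"on_land": 1}

    def test_land_mask_required_but_absent(self):
        rt = self._table([("Aus bus", "species", -33.5, -72.5, "2000-01-01", 10, 10)])
        with pytest.raises(ValueError, match="on_land"):
            occ.clean_records(rt, occ.CleaningRules(require_land_mask=True))

    def test_basin_polygon(self):
        basin = box(-80.0, -40.0, -70.0, -30.0)
        rt = self._table([
            ("Aus bus", "species", -33.5, -72.5, "2000-01-01", 10.0, 10.0),
            ("Aus bus", "species", 10.5, 10.5, "2000-01-01", 10.0, 10.0),
        ])
        out, rep = occ.clean_records(rt, occ.CleaningRules(basin_polygon=basin))
        assert len(out) == 1
        assert rep.dropped == {"outside_basin": 1}

    def test_conservation_invariant(self, dirty_records):
        rt = occ.record_table_from_frame(dirty_records)
        out, rep = occ.clean_records(rt)
        assert rep.n_input == rep.n_output + sum(rep.dropped.values())
        assert rep.n_output == len(out)


class TestHarmonize:
    def test_identity_map_unchanged(self):
        rt = occ.record_table_from_frame(pd.DataFrame({
            "scientific_name": ["Paracalanus indicus"], "latitude": [1.0],
            "longitude": [1.0]}))
        out, unmatched = occ.harmonize_taxonomy(rt, {"Paracalanus indicus": "Paracalanus indicus"})
        assert out["scientific_name"].tolist() == ["Paracalanus indicus"]
        assert unmatched == 0

    def test_synonyms_collapse_to_one_presence(self, small_grid):
        df = pd.DataFrame({
            "scientific_name": ["Aus bus", "Aus cus"],
            "taxon_rank": ["species", "species"],
            "latitude": [-33.5, -33.4],
            "longitude": [-72.5, -72.4],
            "event_date": ["2000-01-01", "2000-01-02"],
        })
        rt = occ.record_table_from_frame(df)
        rt, _ = occ.harmonize_taxonomy(rt, {"Aus cus": "Aus bus"})
        cleaned, _ = occ.clean_records(rt)
        pam = occ.build_pam(occ.assign_cells(cleaned, small_grid))
        assert pam.species == ["Aus bus"]
        assert pam.counts.sum() == 2

    def test_chain_resolution(self):
        rt = occ.record_table_from_frame(pd.DataFrame({
            "scientific_name": ["A a"], "latitude": [1.0], "longitude": [1.0]}))
        out, _ = occ.harmonize_taxonomy(rt, {"A a": "B b", "B b": "C c"})
        assert out["scientific_name"].iloc[0] == "C c"

    def test_cycle_errors(self):
        rt = occ.record_table_from_frame(pd.DataFrame({
            "scientific_name": ["A a"], "latitude": [1.0], "longitude": [1.0]}))
        with pytest.raises(ValueError, match="cyclic"):
            occ.harmonize_taxonomy(rt, {"A a": "B b", "B b": "A a"})

    def test_random_map_species_count(self, pool):
        """Mapping the synthetic pool through a random synonym table leaves
        exactly the accepted-name count."""
        rng = np.random.default_rng(0)
        names = pool.names
        accepted = [n for n in names if rng.random() < 0.5] or names[:1]
        table = {n: accepted[rng.integers(len(accepted))] for n in names
                 if n not in accepted}
        table.update({a: a for a in accepted})
        df = pd.DataFrame({"scientific_name": names,
                           "latitude": np.ones(len(names)),
                           "longitude": np.ones(len(names))})
        out, _ = occ.harmonize_taxonomy(occ.record_table_from_frame(df), table)
        assert out["scientific_name"].nunique() == len(set(table.values()))


class TestAssignCells:
    def test_floor_convention(self):
        rt = occ.record_table_from_frame(pd.DataFrame({
            "scientific_name": ["Aus bus"], "latitude": [-33.2], "longitude": [-70.5]}))
        g = occ.assign_cells(rt)
        assert g["cell_x"].iloc[0] == -71.0
        assert g["cell_y"].iloc[0] == -34.0

    def test_dateline_wrap(self):
        rt = occ.record_table_from_frame(pd.DataFrame({
            "scientific_name": ["Aus bus"], "latitude": [10.5], "longitude": [180.0]}))
        g = occ.assign_cells(rt)
        assert g["cell_x"].iloc[0] == -180.0

    def test_idempotent(self, gridded_records, small_grid):
        again = occ.assign_cells(gridded_records, small_grid)
        pd.testing.assert_series_equal(again["cell_id"], gridded_records["cell_id"])

    def test_matches_generator_cells(self, gridded_records):
        assert (gridded_records["cell_id"] == gridded_records["true_cell_id"]).all()


class TestBuildPam:
    def test_single_record(self):
        rt = occ.record_table_from_frame(pd.DataFrame({
            "scientific_name": ["Aus bus"], "latitude": [-33.2], "longitude": [-70.5]}))
        pam = occ.build_pam(occ.assign_cells(rt))
        assert pam.n_cells == pam.n_species == 1
        assert pam.counts[0, 0] == 1

    def test_count_conservation(self, pam, gridded_records):
        assert pam.counts.sum() == len(gridded_records)

    def test_matches_generator_presence(self, pam, gridded_records):
        """read -> clean -> grid -> PAM reproduces the realized presences."""
        realized = gridded_records.groupby(["cell_id", "scientific_name"]).size()
        frame = pam.to_frame()
        for (c, s), n in realized.items():
            assert frame.loc[c, s] == n
        assert frame.to_numpy().sum() == realized.sum()

    def test_no_all_zero_species(self, pam):
        assert (pam.counts.sum(axis=0) > 0).all()


class TestFilterCells:
    def test_identity(self, pam):
        out = occ.filter_cells(pam, min_richness=0)
        assert out.cells == pam.cells

    def test_all_removed_warns_not_raises(self, pam):
        with pytest.warns(UserWarning, match="every cell"):
            out = occ.filter_cells(pam, min_richness=10_000)
        assert out.n_cells == 0

    def test_matches_brute_force(self, pam):
        out = occ.filter_cells(pam, min_richness=5)
        expected = [c for c, r in zip(pam.cells, pam.richness()) if r >= 5]
        assert out.cells == expected

    def test_lon_band_exclusion(self):
        pam = make_pam(np.eye(4, dtype=int),
                       cells=["-120_0", "-150_0", "-100_0", "10_0"])
        out = occ.filter_cells(pam, excluded_lon_band=(-110, -170))
        assert out.cells == ["-100_0", "10_0"]

    def test_triplet_roundtrip(self, pam, tmp_path):
        p = tmp_path / "pam.csv"
        trip = pam.to_triplets(p)
        back = pd.read_csv(p)
        assert back["count"].sum() == pam.counts.sum()
        assert len(trip) == (pam.counts > 0).sum()
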