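"""Occurrence parsing, filtering, gridding and the bipartite incidence."""

import numpy as np
import pytest

import bioregions as br
from bioregions.errors import ConfigurationError, ParameterError
from bioregions.gridding import aggregate_name


def write_csv(path, text):
    path.write_text(text)
    return path


class TestReadOccurrences:
    def test_well_formed_rows_become_records(self, tmp_path):
        p = write_csv(
            tmp_path / "occ.csv",
            "species,x,y,precision\nA,100,200,5\nB,300,400,2\nA,500,600,\n",
        )
        recs = br.read_occurrences(p)
        assert len(recs) == 3
        assert recs[0].species == "A" and recs[0].x == 100.0
        assert recs[2].precision_m is None

    def test_unparseable_coordinates_are_dropped(self, tmp_path):
        p = write_csv(tmp_path / "occ.csv", "species,x,y\nA,1,2\nB,,3\nC,4,notanumber\n")
        assert len(br.read_occurrences(p)) == 1

    def test_header_only_file_yields_empty_list(self, tmp_path):
        p = write_csv(tmp_path / "occ.csv", "species,x,y\n")
        assert br.read_occurrences(p) == []

    def test_missing_required_column_raises(self, tmp_path):
        p = write_csv(tmp_path / "occ.csv", "taxon,x,y\nA,1,2\n")
        with pytest.raises(ConfigurationError):
            br.read_occurrences(p)

    def test_tab_delimiter_is_sniffed(self, tmp_path):
        p = write_csv(tmp_path / "occ.tsv", "species\tx\ty\nA\t1\t2\n")
        assert len(br.read_occurrences(p)) == 1

    def test_column_map_renames(self, tmp_path):
        p = write_csv(tmp_path / "occ.csv", "taxon,east,north\nA,1,2\n")
        recs = br.read_occurrences(
            p, column_map={"species": "taxon", "x": "east", "y": "north"}
        )
        assert recs[0].species == "A"


class TestFilterRecords:
    def rec(self, species="A", precision=5.0):
        return br.OccurrenceRecord(species=species, x=0.0, y=0.0, precision_m=precision)

    def test_precision_threshold_is_strict(self):
        records = [self.rec(precision=15.0), self.rec(precision=10.0), self.rec(precision=9.9)]
        kept = br.filter_records(records, max_precision_m=10.0)
        assert [r.precision_m for r in kept] == [9.9]

    def test_missing_precision_kept_by_default_dropped_with_flag(self):
        records = [self.rec(precision=None)]
        assert len(br.filter_records(records)) == 1
        assert br.filter_records(records, drop_missing_precision=True) == []

    def test_excluded_species_removed(self):
        records = [self.rec("Rubus sp."), self.rec("Silene nutans")]
        kept = br.filter_records(records, exclusion_list={"Rubus sp."})
        assert [r.species for r in kept] == ["Silene nutans"]

    @pytest.mark.parametrize(
        "raw,parent",
        [
            ("X subsp. y", "X"),
            ("Genus epithet var. thing", "Genus epithet"),
            ("Genus epithet", "Genus epithet"),
            ("Genus epithet subsp. a b c", "Genus epithet"),
        ],
    )
    def test_subtaxon_aggregation_truncates_at_binomial(self, raw, parent):
        assert aggregate_name(raw) == parent

    def test_synonym_map_overrides_truncation(self):
        assert aggregate_name("Odd name", {"Odd name": "Fixed name"}) == "Fixed name"

    def test_aggregated_record_keeps_original_label_as_subtaxon(self):
        kept = br.filter_records([self.rec("X subsp. y")])
        assert kept[0].species == "X" and kept[0].subtaxon == "X subsp. y"

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ParameterError):
            br.filter_records([self.rec()], max_precision_m=0)


class TestBuildGrid:
    def recs(self, coords):
        return [br.OccurrenceRecord("A", x, y, 1.0) for x, y in coords]

    def test_bounding_box_determines_shape(self):
        grid = br.build_grid(self.recs([(0, 0), (9900, 9900)]), side_l=5000)
        assert (grid.n_rows, grid.n_cols) == (2, 2)

    def test_boundary_point_goes_to_upper_cell(self):
        grid = br.build_grid(self.recs([(0, 0), (9900, 9900)]), side_l=5000)
        assert grid.cell_of(5000.0, 5000.0) == (1, 1)

    def test_single_record_gives_1x1(self):
        grid = br.build_grid(self.recs([(123, 456)]), side_l=5000)
        assert (grid.n_rows, grid.n_cols) == (1, 1)

    def test_origin_snaps_to_multiple_of_l(self):
        grid = br.build_grid(self.recs([(5600, 12100)]), side_l=5000)
        assert (grid.origin_x, grid.origin_y) == (5000.0, 10000.0)

    def test_invalid_side_raises(self):
        with pytest.raises(ParameterError):
            br.build_grid(self.recs([(0, 0)]), side_l=0)
        with pytest.raises(ParameterError):
            br.build_grid([], side_l=5000)


class TestRasterize:
    def recs(self, triples):
        return [br.OccurrenceRecord(sp, x, y, 1.0) for sp, x, y in triples]

    def test_duplicates_collapse_to_binary_presence(self):
        records = self.recs([("A", 100, 100)] * 4)
        grid = br.build_grid(records, side_l=5000)
        inc = br.rasterize_to_bipartite(records, grid)
        assert inc.presence.toarray().tolist() == [[1]]

    def test_hand_counted_degrees(self):
        # c1 hosts {A, B}, c2 hosts {B}
        records = self.recs([("A", 100, 100), ("B", 200, 100), ("B", 5500, 100)])
        grid = br.build_grid(records, side_l=5000)
        inc = br.rasterize_to_bipartite(records, grid)
        assert inc.richness.tolist() == [2, 1]
        assert dict(zip(inc.species, inc.occupancy.tolist())) == {"A": 1, "B": 2}

    def test_record_outside_grid_raises(self):
        records = self.recs([("A", 100, 100)])
        grid = br.build_grid(records, side_l=5000)
        with pytest.raises(ValueError):
            br.rasterize_to_bipartite(self.recs([("A", 100, 9999999)]), grid)

    def test_links_equal_sum_of_occupancies(self):
        rng = np.random.default_rng(0)
        records = self.recs(
            [
                (f"sp{rng.integers(20)}", rng.uniform(0, 50000), rng.uniform(0, 50000))
                for _ in range(300)
            ]
        )
        grid = br.build_grid(records, side_l=5000)
        inc = br.rasterize_to_bipartite(records, grid)
        assert inc.n_links == inc.occupancy.sum() == inc.richness.sum()

    def test_rasterization_is_idempotent_under_duplication(self):
        rng = np.random.default_rng(1)
        records = self.recs(
            [
                (f"sp{rng.integers(10)}", rng.uniform(0, 30000), rng.uniform(0, 30000))
                for _ in range(100)
            ]
        )
        grid = br.build_grid(records, side_l=5000)
        inc1 = br.rasterize_to_bipartite(records, grid)
        inc2 = br.rasterize_to_bipartite(records + records, grid)
        assert (inc1.presence != inc2.presence).nnz == 0

    def test_translation_by_one_cell_relabels_only(self):
        rng = np.random.default_rng(2)
        records = self.recs(
            [
                (f"sp{rng.integers(10)}", rng.uniform(0, 30000), rng.uniform(0, 30000))
                for _ in range(100)
            ]
        )
        l = 5000.0
        grid = br.build_grid(records, side_l=l, origin=(0.0, 0.0))
        shifted = [
            br.OccurrenceRecord(r.species, r.x + l, r.y + l, r.precision_m)
            for r in records
        ]
        grid_s = br.build_grid(shifted, side_l=l, origin=(0.0, 0.0))
        inc, inc_s = (
            br.rasterize_to_bipartite(records, grid),
            br.rasterize_to_bipartite(shifted, grid_s),
        )
        rc = np.array([grid.rowcol_of(c) for c in inc.cell_ids])
        rc_s = np.array([grid_s.rowcol_of(c) for c in inc_s.cell_ids])
        assert np.array_equal(rc + 1, rc_s)
        assert (inc.presence != inc_s.presence).nnz == 0

    def test_roundtrip_through_files(self, tmp_path):
        records = self.recs([("A", 100, 100), ("B", 5500, 100)])
        grid = br.build_grid(records, side_l=5000)
        inc = br.rasterize_to_bipartite(records, grid)
        inc.to_files(tmp_path / "inc")
        back = br.BipartiteIncidence.from_files(tmp_path / "inc")
        assert back.species == inc.species
        assert (back.presence != inc.presence).nnz == 0
        assert back.grid.side_l == 5000


class TestDegreeDistributions:
    def test_hand_example_means(self):
        records = [
            br.OccurrenceRecord("A", 100, 100, 1.0),
            br.OccurrenceRecord("B", 200, 100, 1.0),
            br.OccurrenceRecord("B", 5500, 100, 1.0),
        ]
        grid = br.build_grid(records, side_l=5000)
        dd = br.degree_distributions(br.rasterize_to_bipartite(records, grid))
        assert dd.species_per_cell.mean() == pytest.approx(1.5)

    def test_saturated_matrix_constant_richness(self):
        records = [
            br.OccurrenceRecord(f"sp{j}", 100 + 5000 * i, 100, 1.0)
            for i in range(3)
            for j in range(4)
        ]
        grid = br.build_grid(records, side_l=5000)
        dd = br.degree_distributions(br.rasterize_to_bipartite(records, grid))
        assert set(dd.species_per_cell.tolist()) == {4}
        summary = dd.summary()
        assert set(summary["distribution"]) == {"species_per_cell", "cells_per_species"}
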