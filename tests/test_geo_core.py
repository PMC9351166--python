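import json

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, Polygon

from urbanscan import synth
from urbanscan.geo_core import (
    AreaTable,
    ConfigurationError,
    DataError,
    PointEvents,
    aggregate_events,
    build_weights,
    centroid_distances,
    read_areas,
    read_events,
    write_areas,
    write_events,
)

X0, Y0 = 300_000.0, 4_800_000.0


def square(x0, y0, s=1000.0):
    return Polygon([(x0, y0), (x0 + s, y0), (x0 + s, y0 + s), (x0, y0 + s)])


def make_areas(geoms, pops=None, cov=None):
    n = len(geoms)
    ids = np.array([f"A{i}" for i in range(n)], dtype=object)
    return AreaTable(
        area_id=ids,
        geometry=geoms,
        population=np.array(pops if pops is not None else [1000.0] * n),
        covariates=cov if cov is not None else pd.DataFrame(index=pd.Index(ids)),
    )


class TestAreaIO:
    def test_round_trip_preserves_ids_population_covariates(self, tmp_path, lattice_5x5):
        synth.simulate_covariates(lattice_5x5, ["v1", "v2"], range_m=2000.0, seed=1)
        path = tmp_path / "areas.geojson"
        write_areas(lattice_5x5, path)
        back = read_areas(path, "area_id", "population")
        assert list(back.area_id) == list(lattice_5x5.area_id)
        np.testing.assert_array_equal(back.population, lattice_5x5.population)
        pd.testing.assert_frame_equal(
            back.covariates, lattice_5x5.covariates, check_names=False
        )

    def test_missing_field_is_configuration_error(self, tmp_path, lattice_5x5):
        path = tmp_path / "areas.geojson"
        write_areas(lattice_5x5, path)
        with pytest.raises(ConfigurationError, match="missing"):
            read_areas(path, "area_id", "no_such_field")

    def test_unit_square_centroid_at_centre(self):
        areas = make_areas([square(X0, Y0, 1000.0)] * 1 + [square(X0 + 2000, Y0)])
        assert areas.centroids[0] == pytest.approx([X0 + 500.0, Y0 + 500.0])

    def test_l_shape_centroid_matches_decomposition_oracle(self):
        # L = 2000x1000 bottom rectangle + 1000x1000 block on its left top
        l_shape = Polygon(
            [
                (X0, Y0),
                (X0 + 2000, Y0),
                (X0 + 2000, Y0 + 1000),
                (X0 + 1000, Y0 + 1000),
                (X0 + 1000, Y0 + 2000),
                (X0, Y0 + 2000),
            ]
        )
        areas = make_areas([l_shape, square(X0 + 5000, Y0)])
        # area-weighted mean of the two constituent rectangles
        r1_c, r1_a = (X0 + 1000, Y0 + 500), 2000 * 1000
        r2_c, r2_a = (X0 + 500, Y0 + 1500), 1000 * 1000
        cx = (r1_c[0] * r1_a + r2_c[0] * r2_a) / (r1_a + r2_a)
        cy = (r1_c[1] * r1_a + r2_c[1] * r2_a) / (r1_a + r2_a)
        assert areas.centroids[0] == pytest.approx([cx, cy])

    def test_lonlat_looking_coordinates_refused(self):
        with pytest.raises(DataError, match="lon/lat"):
            make_areas([square(0.0, 0.0, 0.01), square(1.0, 0.0, 0.01)])

    def test_invalid_polygon_rejected_not_repaired(self):
        bowtie = Polygon([(X0, Y0), (X0 + 1000, Y0 + 1000), (X0 + 1000, Y0), (X0, Y0 + 1000)])
        with pytest.raises(DataError, match="invalid"):
            make_areas([bowtie, square(X0 + 5000, Y0)])


class TestEventIO:
    def test_csv_round_trip_and_period_filter(self, tmp_path):
        ev = PointEvents(
            x=np.array([X0 + 10, X0 + 20, X0 + 30]),
            y=np.array([Y0 + 10, Y0 + 20, Y0 + 30]),
            year=np.array([2012, 2015, 2030]),
        )
        path = tmp_path / "events.csv"
        write_events(ev, path)
        all_back = read_events(path)
        assert all_back.n == 3
        filtered = read_events(path, study_period=(2012, 2021))
        assert filtered.n == 2
        assert set(filtered.year) == {2012, 2015}

    def test_empty_file_gives_empty_events(self, tmp_path):
        path = tmp_path / "events.csv"
        path.write_text("x,y,year\n")
        ev = read_events(path, study_period=(2012, 2021))
        assert ev.n == 0

    def test_non_numeric_coordinate_names_row(self, tmp_path):
        path = tmp_path / "events.csv"
        path.write_text("x,y,year\n300010,4800010,2015\nfoo,4800020,2016\n")
        with pytest.raises(DataError, match="row 1"):
            read_events(path)


class TestWeights:
    def test_2x2_queen_complete_adjacency(self):
        areas = make_areas([square(X0 + i * 1000, Y0 + j * 1000) for j in range(2) for i in range(2)])
        w = build_weights(areas, "queen", row_standardize=False)
        assert all(len(nb) == 3 for nb in w.neighbours)

    def test_3x3_rook_matches_shared_edge_oracle(self):
        geoms = [square(X0 + i * 1000, Y0 + j * 1000) for j in range(3) for i in range(3)]
        areas = make_areas(geoms)
        w = build_weights(areas, "rook", row_standardize=False)
        # brute-force pairwise shared-boundary-length test
        for i in range(9):
            expected = sorted(
                j
                for j in range(9)
                if j != i and geoms[i].intersection(geoms[j]).length > 0
            )
            assert list(w.neighbours[i]) == expected
        assert len(w.neighbours[4]) == 4  # centre
        for corner in (0, 2, 6, 8):
            assert len(w.neighbours[corner]) == 2

    def test_row_standardized_rows_sum_to_one(self, lattice_5x5):
        w = build_weights(lattice_5x5, "queen", row_standardize=True)
        for wi in w.weights:
            assert wi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_queen_pattern_symmetry(self, lattice_5x5):
        w = build_weights(lattice_5x5, "queen", row_standardize=True)
        for i, nb in enumerate(w.neighbours):
            for j in nb:
                assert i in w.neighbours[j]

    def test_all_isolated_is_error(self):
        areas = make_areas([square(X0, Y0), square(X0 + 9000, Y0)])
        with pytest.raises(DataError, match="isolated"):
            build_weights(areas, "queen")


class TestAggregation:
    def test_single_interior_event(self, lattice_5x5):
        c = lattice_5x5.centroids[7]
        ev = PointEvents(x=np.array([c[0]]), y=np.array([c[1]]), year=np.array([2012]))
        panel = aggregate_events(ev, lattice_5x5, [2012])
        assert panel.counts[7, 0] == 1
        assert panel.total == 1
        assert panel.unassigned == 0

    def test_boundary_event_assigned_once_and_conserved(self, lattice_5x5):
        # point on the shared edge of areas 0 and 1
        ev = PointEvents(
            x=np.array([X0 + 1000.0]), y=np.array([Y0 + 500.0]), year=np.array([2012])
        )
        panel = aggregate_events(ev, lattice_5x5, [2012])
        assert panel.total + panel.unassigned == 1
        assert panel.counts.sum() == 1
        assert panel.counts[0, 0] == 1  # first-containing in stable order

    def test_scattered_points_match_containment_oracle(self, rng):
        geoms = [square(X0 + i * 1000, Y0 + j * 1000, 1000.0) for j in range(2) for i in range(2)]
        areas = make_areas(geoms)
        x = rng.uniform(X0, X0 + 2000, 100)
        y = rng.uniform(Y0, Y0 + 2000, 100)
        ev = PointEvents(x=x, y=y, year=np.full(100, 2012))
        panel = aggregate_events(ev, areas, [2012])
        oracle = np.zeros(4, dtype=int)
        for px, py in zip(x, y):
            for i, g in enumerate(geoms):
                if g.covers(Point(px, py)):
                    oracle[i] += 1
                    break
        np.testing.assert_array_equal(panel.counts[:, 0], oracle)
        assert panel.total + panel.unassigned == 100

    def test_outside_event_goes_to_unassigned(self, lattice_5x5):
        ev = PointEvents(
            x=np.array([X0 - 5000.0]), y=np.array([Y0 - 5000.0]), year=np.array([2012])
        )
        panel = aggregate_events(ev, lattice_5x5, [2012])
        assert panel.unassigned == 1
        assert panel.total == 0


class TestDistances:
    def test_3_4_5_triangle(self):
        areas = make_areas([square(X0, Y0, 3000.0), square(X0 + 3000, Y0 + 4000, 3000.0)])
        D = centroid_distances(areas)
        assert D[0, 1] == pytest.approx(5000.0)

    def test_symmetric_zero_diagonal_matches_loop_oracle(self, rng):
        geoms = [
            square(X0 + rng.uniform(0, 50000), Y0 + rng.uniform(0, 50000), 10.0)
            for _ in range(5)
        ]
        areas = make_areas(geoms)
        D = centroid_distances(areas)
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_array_equal(np.diag(D), 0.0)
        c = areas.centroids
        for i in range(5):
            for j in range(5):
                d = np.hypot(c[i, 0] - c[j, 0], c[i, 1] - c[j, 1])
                assert D[i, j] == pytest.approx(d)
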