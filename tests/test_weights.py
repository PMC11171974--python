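"""Spatial weight matrices: constructors vs brute-force oracles, GAL IO."""

import itertools

import numpy as np
import pytest
from shapely.geometry import Polygon

from spatqol.weights import (
    AreaGeometry,
    WeightMatrix,
    distance_band,
    min_connecting_band,
    neighbour_summary,
    queen_contiguity,
    read_gal,
    read_geojson,
    write_gal,
    write_geojson,
)
from tests.conftest import point_areas, square


def brute_force_queen(areas, decimals=9):
    """Independent oracle: pairwise vertex-set intersection."""
    verts = [
        {tuple(np.round(xy, decimals)) for xy in np.asarray(a.polygon.exterior.coords)}
        for a in areas
    ]
    nbrs = {a.area_id: set() for a in areas}
    for i, j in itertools.combinations(range(len(areas)), 2):
        if verts[i] & verts[j]:
            nbrs[areas[i].area_id].add(areas[j].area_id)
            nbrs[areas[j].area_id].add(areas[i].area_id)
    return nbrs


def brute_force_band(areas, band):
    """Independent oracle: O(n^2) centroid distance threshold."""
    nbrs = {a.area_id: set() for a in areas}
    for i, j in itertools.combinations(range(len(areas)), 2):
        d = np.hypot(
            areas[i].centroid[0] - areas[j].centroid[0],
            areas[i].centroid[1] - areas[j].centroid[1],
        )
        if 0 < d <= band:
            nbrs[areas[i].area_id].add(areas[j].area_id)
            nbrs[areas[j].area_id].add(areas[i].area_id)
    return nbrs


def neighbour_ids(W):
    return {W.ids[j]: {W.ids[k] for k in W.neighbours[j]} for j in range(W.n)}


def lattice(nr, nc):
    return [square(f"A{r}_{c}", c, r) for r in range(nr) for c in range(nc)]


class TestQueen:
    def test_2x2_all_mutual_through_centre_vertex(self, grid_2x2):
        W = queen_contiguity(grid_2x2)
        assert W.neighbour_counts().tolist() == [3, 3, 3, 3]

    def test_1x3_chain(self):
        W = queen_contiguity(lattice(1, 3))
        assert W.neighbour_counts().tolist() == [1, 2, 1]

    def test_3x3_corner_edge_centre(self, grid_3x3):
        W = queen_contiguity(grid_3x3)
        assert W.neighbour_counts().tolist() == [3, 5, 3, 5, 8, 5, 3, 5, 3]

    @pytest.mark.parametrize("nr,nc", [(1, 2), (2, 2), (2, 3), (3, 3), (3, 4), (4, 3)])
    def test_matches_brute_force_on_small_lattices(self, nr, nc):
        areas = lattice(nr, nc)
        assert neighbour_ids(queen_contiguity(areas)) == brute_force_queen(areas)

    def test_symmetric_zero_diagonal(self, grid_3x3):
        W = queen_contiguity(grid_3x3)
        A = W.to_sparse().toarray()
        assert (A == A.T).all()
        assert np.diagonal(A).sum() == 0

    def test_duplicate_ids_rejected(self):
        areas = [square("X", 0, 0), square("X", 1, 0)]
        with pytest.raises(ValueError, match="duplicate"):
            queen_contiguity(areas)

    def test_degenerate_polygon_rejected(self):
        bad = AreaGeometry("B", Polygon([(0, 0), (1, 1), (0, 0), (1, 1)]), (0.5, 0.5))
        with pytest.raises(ValueError, match="degenerate"):
            queen_contiguity([square("A", 0, 0), bad])


class TestDistanceBand:
    def test_collinear_chain(self):
        areas = point_areas([(0, 0), (1, 0), (2, 0), (3, 0)])
        W = distance_band(areas, 1.0)
        assert W.neighbour_counts().tolist() == [1, 2, 2, 1]
        assert W.kind == "distance_band" and W.band_km == 1.0

    def test_wide_band_gives_complete_graph(self, rng):
        areas = point_areas(rng.uniform(0, 5, size=(6, 2)))
        W = distance_band(areas, 100.0)
        assert (W.neighbour_counts() == 5).all()

    def test_matches_brute_force_on_scatter(self, rng):
        xy = rng.uniform(0, 10, size=(10, 2))
        areas = point_areas(xy)
        d = np.hypot(*(xy[:, None, :] - xy[None, :, :]).transpose(2, 0, 1))
        np.fill_diagonal(d, np.inf)
        band = 1.5 * d.min(axis=1).mean()
        assert neighbour_ids(distance_band(areas, band)) == brute_force_band(areas, band)

    def test_neighbourhoods_monotone_in_band(self, rng):
        areas = point_areas(rng.uniform(0, 10, size=(12, 2)))
        bands = [1.0, 2.0, 4.0, 8.0]
        prev = None
        for b in bands:
            with np.errstate(all="ignore"):
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cur = neighbour_ids(distance_band(areas, b))
            if prev is not None:
                assert all(prev[a] <= cur[a] for a in cur)
            prev = cur

    def test_isolated_area_warns(self):
        areas = point_areas([(0, 0), (1, 0), (50, 0)])
        with pytest.warns(UserWarning, match="isolated"):
            W = distance_band(areas, 2.0)
        assert W.isolated() == ["P2"]


class TestMinConnectingBand:
    def test_line_example(self):
        assert min_connecting_band(point_areas([(0, 0), (1, 0), (3, 0)])) == 2.0

    def test_equilateral_triangle(self):
        s = 2.5
        tri = point_areas([(0, 0), (s, 0), (s / 2, s * np.sqrt(3) / 2)])
        assert min_connecting_band(tri) == pytest.approx(s)

    def test_matches_nested_loop_oracle(self, rng):
        xy = rng.uniform(0, 100, size=(20, 2))
        areas = point_areas(xy)
        best = -np.inf
        for i in range(20):
            nearest = min(
                np.hypot(*(xy[i] - xy[k])) for k in range(20) if k != i
            )
            best = max(best, nearest)
        assert min_connecting_band(areas) == pytest.approx(best)

    def test_band_is_tight(self, rng):
        import warnings

        areas = point_areas(rng.uniform(0, 10, size=(15, 2)))
        b = min_connecting_band(areas)
        assert distance_band(areas, b).neighbour_counts().min() >= 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            below = distance_band(areas, b * (1 - 1e-6))
        assert below.neighbour_counts().min() == 0


class TestNeighbourSummary:
    def test_chain_of_four(self):
        W = distance_band(point_areas([(i, 0) for i in range(4)]), 1.0)
        s = neighbour_summary(W)
        assert (s.mean, s.median, s.min, s.max) == (1.5, 1.5, 1, 2)

    def test_complete_graph_on_five(self, rng):
        W = distance_band(point_areas(rng.uniform(0, 1, size=(5, 2))), 10.0)
        s = neighbour_summary(W)
        assert s.mean == s.median == s.min == s.max == 4
        assert s.sd == 0.0

    def test_3x3_queen_summary(self, grid_3x3):
        s = neighbour_summary(queen_contiguity(grid_3x3))
        assert s.mean == pytest.approx(40 / 9)
        assert (s.min, s.max) == (3, 8)


class TestGalIO:
    def test_round_trip_chain(self, tmp_path):
        W = distance_band(point_areas([(0, 0), (1, 0), (2, 0)]), 1.0)
        path = tmp_path / "w.gal"
        write_gal(W, path)
        W2 = read_gal(path)
        assert neighbour_ids(W2) == neighbour_ids(W)

    def test_asymmetric_file_rejected(self, tmp_path):
        path = tmp_path / "bad.gal"
        path.write_text("2\nA 1\nB\nB 0\n")
        with pytest.raises(ValueError, match="symmetr"):
            read_gal(path)

    def test_unknown_id_rejected(self, tmp_path):
        path = tmp_path / "bad.gal"
        path.write_text("0 2 synthetic area_id\nA 1\nZ\nB 1\nA\n")
        with pytest.raises(ValueError, match="unknown id"):
            read_gal(path)

    def test_geoda_header_2x2_queen(self, tmp_path, grid_2x2):
        W = queen_contiguity(grid_2x2)
        path = tmp_path / "q.gal"
        write_gal(W, path)
        assert path.read_text().startswith("0 4 ")
        assert read_gal(path).neighbour_counts().tolist() == [3, 3, 3, 3]


class TestGeoJSON:
    def test_round_trip(self, tmp_path, grid_2x2):
        path = tmp_path / "areas.geojson"
        write_geojson(grid_2x2, path)
        back = read_geojson(path)
        assert [a.area_id for a in back] == [a.area_id for a in grid_2x2]
        W = queen_contiguity(back)
        assert W.neighbour_counts().tolist() == [3, 3, 3, 3]


class TestWeightMatrixValidation:
    def test_asymmetric_structure_rejected(self):
        with pytest.raises(ValueError, match="asymmetric"):
            WeightMatrix(
                ids=["a", "b"], neighbours=[[1], []], weights=[[1.0], []], kind="custom"
            )

    def test_self_neighbour_rejected(self):
        with pytest.raises(ValueError, match="own neighbour"):
            WeightMatrix(ids=["a"], neighbours=[[0]], weights=[[1.0]], kind="custom")
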