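"""Mesh geometry: geodesics, borders, distance segments, smoothing."""

import numpy as np
import pytest

from mdsurf import (
    Parcellation,
    SmoothingSpec,
    distance_segments,
    extract_borders,
    geodesic_distance,
    make_mesh,
    smooth_map,
)
from mdsurf.geometry import SurfaceMesh

from conftest import grid_mesh, strip_mesh


def oracle_shortest_paths(graph, source: int) -> np.ndarray:
    """Dijkstra with the priority queue replaced by repeated linear scans."""
    g = graph.tocsr()
    n = g.shape[0]
    dist = np.full(n, np.inf)
    dist[source] = 0.0
    done = np.zeros(n, dtype=bool)
    for _ in range(n):
        cand = np.where(done, np.inf, dist)
        u = int(np.argmin(cand))
        if not np.isfinite(cand[u]):
            break
        done[u] = True
        row = g[u]
        for v, w in zip(row.indices, row.data):
            if dist[u] + w < dist[v]:
                dist[v] = dist[u] + w
    return dist


class TestGeodesicDistance:
    def test_planar_grid_corner_to_corner(self):
        # 3x3 unit grid with sqrt(2) diagonals: shortest edge path = 2*sqrt(2)
        m = grid_mesh(3)
        d = geodesic_distance(m, [0])
        assert d[8] == pytest.approx(2 * np.sqrt(2), abs=1e-12)

    def test_all_sources_zero(self, sphere_mesh):
        d = geodesic_distance(sphere_mesh, np.arange(sphere_mesh.n_vertices))
        assert np.all(d == 0)

    def test_matches_linear_scan_dijkstra_oracle(self):
        rng = np.random.default_rng(7)
        for rep in range(5):
            m = make_mesh("icosphere", 2, two_hemispheres=False)
            # perturb geometry so edge weights differ between replicates
            coords = m.vertex_coords * (1.0 + 0.05 * rng.normal(size=(m.n_vertices, 1)))
            m = SurfaceMesh(vertex_coords=coords, triangles=m.triangles)
            src = int(rng.integers(m.n_vertices))
            d = geodesic_distance(m, [src])
            expected = oracle_shortest_paths(m.geodesic_graph(), src)
            np.testing.assert_allclose(d, expected, atol=1e-9)

    def test_singleton_symmetry(self, sphere_mesh):
        da = geodesic_distance(sphere_mesh, [3])
        db = geodesic_distance(sphere_mesh, [100])
        assert da[100] == pytest.approx(db[3], abs=1e-12)

    def test_unreachable_component_flagged(self, bihemi_mesh):
        comp = np.asarray(bihemi_mesh.component_id)
        d = geodesic_distance(bihemi_mesh, [0])  # vertex 0 is in "L"
        assert np.isinf(d[comp == "R"]).all()
        assert np.isfinite(d[comp == "L"]).all()

    def test_empty_sources_error(self, sphere_mesh):
        with pytest.raises(ValueError):
            geodesic_distance(sphere_mesh, [])


class TestExtractBorders:
    def test_strip_two_areas(self):
        m = strip_mesh(6)
        # bottom row 0..5, top row 6..11; label columns AAABBB
        lab = np.asarray(list("AAABBB" * 2), dtype=object)
        bs = extract_borders(m, Parcellation(area_label=lab))
        # border = last A column and first B column (both rows)
        assert set(bs.border_vertices.tolist()) == {2, 3, 8, 9}
        assert bs.adjacent_pairs == [("A", "B")]

    def test_uniform_label_empty(self, sphere_mesh):
        lab = np.full(sphere_mesh.n_vertices, "X", dtype=object)
        bs = extract_borders(sphere_mesh, Parcellation(area_label=lab))
        assert bs.border_vertices.size == 0
        assert bs.pair_index == {}

    def test_pair_index_matches_edge_scan(self, bihemi_mesh, bihemi_parc, bihemi_borders):
        labels = bihemi_parc.area_label
        expected_pairs = set()
        for a, b in bihemi_mesh.edges():
            if labels[a] != labels[b]:
                expected_pairs.add(tuple(sorted((labels[a], labels[b]))))
        assert set(bihemi_borders.pair_index) == expected_pairs

    def test_stable_under_relabeling(self, bihemi_mesh, bihemi_parc, bihemi_borders):
        perm = {a: f"Z{i}" for i, a in enumerate(reversed(bihemi_parc.areas))}
        relabeled = Parcellation(
            area_label=np.asarray([perm[a] for a in bihemi_parc.area_label], dtype=object)
        )
        bs2 = extract_borders(bihemi_mesh, relabeled)
        np.testing.assert_array_equal(bs2.border_vertices, bihemi_borders.border_vertices)

    def test_every_border_vertex_has_foreign_neighbor(self, bihemi_mesh, bihemi_parc, bihemi_borders):
        labels = bihemi_parc.area_label
        for v in bihemi_borders.border_vertices:
            nbr = bihemi_mesh.neighbors(int(v))
            assert (labels[nbr] != labels[v]).any()


@pytest.fixture(scope="module")
def strip_setup():
    m = strip_mesh(21)
    # columns 0-10 are A (11 columns), 11-20 are B (10 columns)
    col = np.tile(np.arange(21), 2)
    lab = np.where(col <= 10, "A", "B").astype(object)
    parc = Parcellation(area_label=lab)
    borders = extract_borders(m, parc)
    return m, parc, borders


class TestDistanceSegments:
    def test_equal_sizes(self, strip_setup):
        m, parc, borders = strip_setup
        seg = distance_segments(m, parc, borders, ("A", "B"), 5)
        b_sizes = [np.sum(seg[parc.vertices_of("B")] == s) for s in range(1, 6)]
        assert b_sizes == [4, 4, 4, 4, 4]

    def test_uneven_extra_goes_nearest(self, strip_setup):
        m, parc, borders = strip_setup
        seg = distance_segments(m, parc, borders, ("A", "B"), 5)
        # area A has 22 vertices -> sizes (5,5,4,4,4) nearest-first
        a_sizes = [np.sum(seg[parc.vertices_of("A")] == s) for s in range(1, 6)]
        assert a_sizes == [5, 5, 4, 4, 4]

    def test_matches_sort_and_chunk_oracle(self, strip_setup):
        m, parc, borders = strip_setup
        seg = distance_segments(m, parc, borders, ("A", "B"), 5)
        d = geodesic_distance(m, borders.pair_vertices("A", "B"))
        for area in ("A", "B"):
            verts = parc.vertices_of(area)
            order = verts[np.lexsort((verts, d[verts]))]
            k, r = divmod(verts.size, 5)
            sizes = [k + 1] * r + [k] * (5 - r)
            start = 0
            for s, size in enumerate(sizes, start=1):
                assert np.all(seg[order[start : start + size]] == s)
                start += size

    def test_segment_ordering_follows_distance(self, strip_setup):
        m, parc, borders = strip_setup
        seg = distance_segments(m, parc, borders, ("A", "B"), 5)
        d = geodesic_distance(m, borders.pair_vertices("A", "B"))
        for area in ("A", "B"):
            verts = parc.vertices_of(area)
            for s in range(1, 5):
                assert d[verts[seg[verts] == s]].max() <= d[
                    verts[seg[verts] == s + 1]
                ].min() + 1e-12

    def test_partition_and_spread(self, bihemi_mesh, bihemi_parc, bihemi_borders):
        pair = bihemi_borders.adjacent_pairs[0]
        seg = distance_segments(bihemi_mesh, bihemi_parc, bihemi_borders, pair, 3)
        for area in pair:
            verts = bihemi_parc.vertices_of(area)
            assert np.all(seg[verts] >= 1)
            sizes = np.bincount(seg[verts])[1:]
            assert sizes.max() - sizes.min() <= 1

    def test_border_vertices_included(self, strip_setup):
        m, parc, borders = strip_setup
        seg = distance_segments(m, parc, borders, ("A", "B"), 5)
        assert np.all(seg[borders.pair_vertices("A", "B")] == 1)

    def test_non_adjacent_pair_error(self, bihemi_mesh, bihemi_parc, bihemi_borders):
        with pytest.raises(KeyError):
            distance_segments(
                bihemi_mesh, bihemi_parc, bihemi_borders, ("L00", "R00"), 5
            )


class TestSmoothMap:
    def test_constant_map_unchanged(self, sphere_mesh):
        v = np.full(sphere_mesh.n_vertices, 3.7)
        out = smooth_map(sphere_mesh, v, SmoothingSpec(fwhm_mm=12.0))
        np.testing.assert_allclose(out, v, rtol=1e-10)

    def test_zero_fwhm_identity(self, sphere_mesh):
        rng = np.random.default_rng(0)
        v = rng.normal(size=sphere_mesh.n_vertices)
        out = smooth_map(sphere_mesh, v, SmoothingSpec(fwhm_mm=0.0))
        np.testing.assert_array_equal(out, v)

    def test_impulse_matches_analytic_gaussian(self):
        m = grid_mesh(49)
        center = 24 * 49 + 24
        v = np.zeros(m.n_vertices)
        v[center] = 1.0
        out = smooth_map(m, v, SmoothingSpec(fwhm_mm=12.0))
        sigma = 12.0 / (2 * np.sqrt(2 * np.log(2)))
        d = np.linalg.norm(m.vertex_coords - m.vertex_coords[center], axis=1)
        g = np.exp(-(d**2) / (2 * sigma**2)) / (2 * np.pi * sigma**2)
        sel = d < 20
        nrms = np.sqrt(np.mean((out[sel] - g[sel]) ** 2)) / g.max()
        assert nrms < 0.05

    def test_area_weighted_conservation(self, sphere_mesh):
        rng = np.random.default_rng(1)
        v = rng.normal(size=sphere_mesh.n_vertices)
        a = sphere_mesh.vertex_areas()
        out = smooth_map(sphere_mesh, v, SmoothingSpec(fwhm_mm=15.0))
        before = float(a @ v)
        after = float(a @ out)
        assert abs(after - before) <= 1e-8 * max(1.0, abs(before))

    def test_linearity(self, sphere_mesh):
        rng = np.random.default_rng(2)
        u = rng.normal(size=sphere_mesh.n_vertices)
        v = rng.normal(size=sphere_mesh.n_vertices)
        spec = SmoothingSpec(fwhm_mm=10.0)
        lhs = smooth_map(sphere_mesh, 2.0 * u - 3.0 * v, spec)
        rhs = 2.0 * smooth_map(sphere_mesh, u, spec) - 3.0 * smooth_map(
            sphere_mesh, v, spec
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_monotone_nonnegative(self, sphere_mesh):
        rng = np.random.default_rng(3)
        v = np.abs(rng.normal(size=sphere_mesh.n_vertices))
        out = smooth_map(sphere_mesh, v, SmoothingSpec(fwhm_mm=20.0))
        assert np.all(out >= -1e-14)

    def test_no_leakage_across_mask(self, sphere_mesh):
        mask = np.zeros(sphere_mesh.n_vertices, dtype=bool)
        mask[: sphere_mesh.n_vertices // 2] = True
        v = np.ones(sphere_mesh.n_vertices)
        v[~mask] = 100.0
        out = smooth_map(sphere_mesh, v, SmoothingSpec(fwhm_mm=12.0), mask=mask)
        np.testing.assert_array_equal(out[~mask], v[~mask])  # untouched outside
        # masked region never sees the 100s
        assert out[mask].max() < 2.0

    def test_empty_mask_error(self, sphere_mesh):
        with pytest.raises(ValueError):
            smooth_map(
                sphere_mesh,
                np.zeros(sphere_mesh.n_vertices),
                SmoothingSpec(fwhm_mm=4.0),
                mask=np.zeros(sphere_mesh.n_vertices, dtype=bool),
            )


class TestMeshInvariants:
    def test_manifold_edges(self, bihemi_mesh):
        tri = bihemi_mesh.triangles
        pairs = np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
        _, counts = np.unique(np.sort(pairs, axis=1), axis=0, return_counts=True)
        assert counts.max() <= 2

    def test_homolog_map_symmetric_cross_component(self, bihemi_mesh):
        comp = np.asarray(bihemi_mesh.component_id)
        for a, b in bihemi_mesh.homolog_map.items():
            assert bihemi_mesh.homolog_map[b] == a
            assert comp[a] != comp[b]

    def test_invalid_triangle_index_rejected(self):
        with pytest.raises(ValueError):
            SurfaceMesh(
                vertex_coords=np.zeros((3, 3)) + np.eye(3),
                triangles=np.array([[0, 1, 5]]),
            )
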