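import numpy as np
import pytest
from scipy import stats

from anatomap.geometry import make_sheet, mirror_layer, offset_layer, subdivided_copy
from anatomap.layers import SurfaceLayer, place_neurons, point_from_uv
from anatomap.mapping import (
    MappingChain,
    MappingError,
    MappingStep,
    closest_point_on_layer,
    map_euclidean,
    map_normal,
    map_random,
    map_topological,
    traverse_chain,
)
from tests.conftest import sphere_band


class TestTopological:
    def test_verbatim_copy_is_identity(self, unit_sheet):
        copy = unit_sheet.copy("copy")
        p = point_from_uv(unit_sheet, (0.3, 0.7))
        q = map_topological(unit_sheet, copy, p)
        assert np.allclose(q.xyz, p.xyz)
        assert q.tri_index == p.tri_index

    def test_mirror_negates_axis(self, unit_sheet):
        m = mirror_layer(unit_sheet, 0)
        p = point_from_uv(unit_sheet, (0.3, 0.7))
        q = map_topological(unit_sheet, m, p)
        assert np.allclose(q.xyz, (-p.xyz[0], p.xyz[1], p.xyz[2]))

    def test_offset_sheet_shifts_z(self, unit_sheet):
        off = offset_layer(unit_sheet, 0.4)
        p = point_from_uv(unit_sheet, (0.2, 0.9))
        q = map_topological(unit_sheet, off, p)
        assert np.allclose(q.xyz, np.asarray(p.xyz) + (0, 0, 0.4), atol=1e-12)

    def test_round_trip_is_identity(self, unit_sheet):
        off = offset_layer(unit_sheet, 0.4)
        p = point_from_uv(unit_sheet, (0.61, 0.13))
        q = map_topological(off, unit_sheet, map_topological(unit_sheet, off, p))
        assert np.allclose(q.xyz, p.xyz, atol=1e-12)
        assert q.tri_index == p.tri_index

    def test_topology_mismatch_names_offender(self, unit_sheet):
        other = subdivided_copy(unit_sheet, 1)
        p = point_from_uv(unit_sheet, (0.5, 0.5))
        with pytest.raises(MappingError, match="topology mismatch"):
            map_topological(unit_sheet, other, p)


class TestNormal:
    def test_parallel_planes_preserve_xy(self, parallel_sheets):
        a, b = parallel_sheets
        p = point_from_uv(a, (0.37, 0.81))
        q = map_normal(a, b, p)
        assert abs(q.xyz[0] - p.xyz[0]) < 1e-9
        assert abs(q.xyz[1] - p.xyz[1]) < 1e-9
        assert q.xyz[2] == pytest.approx(0.5, abs=1e-9)

    def test_target_displaced_to_the_side_misses(self, unit_sheet):
        side = unit_sheet.copy("side")
        side.vertices = side.vertices + np.array([5.0, 0.0, 1.0])
        side._cache.clear()
        p = point_from_uv(unit_sheet, (0.5, 0.5))
        assert map_normal(unit_sheet, side, p) is None

    def test_concentric_spheres_project_radially(self, spheres):
        inner, outer = spheres
        rng = np.random.default_rng(2)
        for _ in range(25):
            uv = rng.random(2) * 0.9 + 0.05
            p = point_from_uv(inner, uv)
            q = map_normal(inner, outer, p)
            assert q is not None
            expected = 2.0 * np.asarray(p.xyz) / np.linalg.norm(p.xyz)
            assert np.linalg.norm(np.asarray(q.xyz) - expected) < 0.02 * 2.0

    def test_normal_offset_copy_recovers_offset_image(self):
        s = sphere_band(1.0, "s", 64, 32)
        off = offset_layer(s, 0.25)
        p = point_from_uv(s, (0.4, 0.6))
        q = map_normal(s, off, p)
        expected = np.asarray(p.xyz) * 1.25
        assert np.linalg.norm(np.asarray(q.xyz) - expected) < 5e-3


class TestEuclidean:
    def test_plane_target_gives_orthogonal_foot(self, unit_sheet):
        src = offset_layer(unit_sheet, 2.0, "src")
        p = point_from_uv(src, (0.44, 0.27))
        q = map_euclidean(src, unit_sheet, p)
        assert np.allclose(q.xyz, (p.xyz[0], p.xyz[1], 0.0), atol=1e-12)

    def test_matches_exhaustive_search_on_random_queries(self):
        tgt = sphere_band(1.0, "tgt", 24, 12)
        rng = np.random.default_rng(3)
        pts = rng.normal(scale=2.0, size=(500, 3))
        tri_p, xyz_p, d_p = closest_point_on_layer(tgt, pts)
        tri_e, xyz_e, d_e = closest_point_on_layer(tgt, pts, exhaustive=True)
        assert np.array_equal(tri_p, tri_e)
        assert np.allclose(xyz_p, xyz_e)
        assert np.allclose(d_p, d_e)

    def test_distance_bounded_by_vertex_distances(self):
        tgt = sphere_band(1.0, "tgt", 16, 8)
        rng = np.random.default_rng(4)
        pts = rng.normal(scale=1.5, size=(100, 3))
        _, _, d = closest_point_on_layer(tgt, pts)
        for i, p in enumerate(pts):
            assert d[i] <= np.linalg.norm(tgt.vertices - p, axis=1).min() + 1e-12

    def test_equidistant_wedge_tie_breaks_to_lowest_triangle(self):
        # two faces of a symmetric wedge around the y axis
        wedge = SurfaceLayer(
            name="wedge",
            vertices=[[0, 0, 0], [1, 0, 1], [1, 1, 1], [0, 1, 0], [-1, 0, 1], [-1, 1, 1]],
            faces=[(0, 1, 2, 3), (0, 3, 5, 4)],
            uv_corners=[
                np.array([[0, 0], [1, 0], [1, 1], [0, 1]]),
                np.array([[0, 0], [0, 1], [1, 1], [1, 0]]),
            ],
        )
        src = make_sheet(1.0, 1.0, 1, 1, "probe")
        src.vertices = src.vertices + np.array([-0.5, 0.0, 2.0])
        src._cache.clear()
        p = point_from_uv(src, (0.5, 0.5))  # x=0 plane of symmetry
        q = map_euclidean(src, wedge, p)
        assert q.tri_index == 0


class TestRandom:
    def test_single_triangle_target(self):
        tri = SurfaceLayer(
            name="tri",
            vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]],
            faces=[(0, 1, 2)],
            uv_corners=[np.array([[0, 0], [1, 0], [0, 1]])],
        )
        src = make_sheet(1, 1, 1, 1)
        p = point_from_uv(src, (0.5, 0.5))
        rng = np.random.default_rng(0)
        for _ in range(10):
            q = map_random(src, tri, p, rng)
            assert q.tri_index == 0

    def test_area_weighted_face_frequencies(self):
        # two triangles with area ratio 1:3
        tgt = SurfaceLayer(
            name="two",
            vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0], [-3, 0, 0], [0, -3, 0]],
            faces=[(0, 1, 2), (0, 3, 4)],
            uv_corners=[
                np.array([[0.5, 0.5], [1, 0.5], [0.5, 1]]),
                np.array([[0.5, 0.5], [0, 0.5], [0.5, 0]]),
            ],
        )
        src = make_sheet(1, 1, 1, 1)
        p = point_from_uv(src, (0.5, 0.5))
        rng = np.random.default_rng(1)
        n = 10_000
        hits = sum(map_random(src, tgt, p, rng).tri_index == 1 for _ in range(n))
        exp = n * 9 / 10  # areas 0.5 vs 4.5
        assert abs(hits - exp) < 4 * np.sqrt(n * 0.9 * 0.1)

    def test_uniform_over_chart_bins(self, unit_sheet):
        src = make_sheet(1, 1, 1, 1)
        p = point_from_uv(src, (0.5, 0.5))
        rng = np.random.default_rng(7)
        n = 10_000
        uvs = np.array([map_random(src, unit_sheet, p, rng).uv for _ in range(n)])
        h, _, _ = np.histogram2d(uvs[:, 0], uvs[:, 1], bins=8, range=[[0, 1], [0, 1]])
        chi2 = ((h - n / 64) ** 2 / (n / 64)).sum()
        assert stats.chi2.sf(chi2, 63) > 0.01


class TestTraverseChain:
    def test_empty_chain_returns_start(self, unit_sheet):
        p = point_from_uv(unit_sheet, (0.5, 0.5))
        out = traverse_chain({"unit_sheet": unit_sheet}, [], "unit_sheet", p)
        assert out == [p]

    def test_single_step_reduces_to_operator(self, parallel_sheets):
        a, b = parallel_sheets
        layers = {l.name: l for l in (a, b)}
        p = point_from_uv(a, (0.3, 0.3))
        out = traverse_chain(layers, [MappingStep("plane_b", "normal")], "plane_a", p)
        direct = map_normal(a, b, p)
        assert np.allclose(out[-1].xyz, direct.xyz)

    def test_masked_chain_drops_out_of_footprint_neurons(self):
        # soma sheet 1x1; a small mask sheet covering x,y in [0.3, 0.7]
        soma = make_sheet(1.0, 1.0, 4, 4, "soma")
        mask = make_sheet(0.4, 0.4, 2, 2, "mask")
        mask.vertices = mask.vertices + np.array([0.3, 0.3, 0.5])
        mask._cache.clear()
        deformed = offset_layer(mask, 0.5, "deformed")
        sl = make_sheet(1.0, 1.0, 4, 4, "sl")
        sl.vertices = sl.vertices + np.array([0.0, 0.0, 2.0])
        sl._cache.clear()
        layers = {l.name: l for l in (soma, mask, deformed, sl)}
        steps = [
            MappingStep("mask", "normal"),
            MappingStep("deformed", "topological"),
            MappingStep("sl", "euclidean"),
        ]
        inside = point_from_uv(soma, (0.5, 0.5))
        outside = point_from_uv(soma, (0.1, 0.1))
        out_in = traverse_chain(layers, steps, "soma", inside)
        assert out_in is not None and out_in[-1].layer == "sl"
        assert traverse_chain(layers, steps, "soma", outside) is None

    def test_chain_endpoint_mismatch_rejected(self, parallel_sheets):
        a, b = parallel_sheets
        layers = {l.name: l for l in (a, b)}
        pre = place_neurons(a, 3, seed=0)
        post = place_neurons(b, 3, seed=1)
        with pytest.raises(ValueError, match="synaptic layer"):
            MappingChain(
                name="bad", layers=layers, pre_population=pre, post_population=post,
                pre_steps=[MappingStep("plane_b")], post_steps=[MappingStep("plane_a")],
            )
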