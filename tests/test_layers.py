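import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from anatomap.geometry import (
    cone_band_area,
    make_cone_strip,
    make_sheet,
    make_tube_strip,
)
from anatomap.layers import (
    LayerError,
    SurfaceLayer,
    neuron_count_from_density,
    place_neurons,
    point_from_uv,
    read_obj,
    surface_area,
    uv_path_length,
    write_obj,
)

TWO_TRI_SQUARE = """\
v 0 0 0
v 1 0 0
v 1 1 0
v 0 1 0
vt 0 0
vt 1 0
vt 1 1
vt 0 1
f 1/1 2/2 3/3
f 1/1 3/3 4/4
"""


class TestObjIO:
    def test_two_triangle_unit_square(self, tmp_path):
        p = tmp_path / "square.obj"
        p.write_text(TWO_TRI_SQUARE)
        layer = read_obj(p)
        assert len(layer.vertices) == 4
        assert len(layer.faces) == 2
        assert surface_area(layer) == pytest.approx(1.0)

    def test_round_trip_is_bit_identical(self, tmp_path):
        layer = make_cone_strip(0.3, 0.9, 2.0, 0.5, 6, 3)
        p = tmp_path / "strip.obj"
        write_obj(layer, p)
        back = read_obj(p, name=layer.name)
        assert np.array_equal(back.vertices, layer.vertices)
        assert back.faces == layer.faces
        for a, b in zip(back.uv_corners, layer.uv_corners):
            assert np.array_equal(a, b)

    def test_quad_strip_triangulates_to_double_count(self, tmp_path):
        layer = make_tube_strip(1.0, 1.0, 0.5, 8, 4)
        p = tmp_path / "tube.obj"
        write_obj(layer, p)
        back = read_obj(p)
        assert len(back.faces) == 32
        assert len(back.tris) == 64

    def test_missing_vt_reference_is_a_format_error(self, tmp_path):
        p = tmp_path / "bad.obj"
        p.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nvt 0 0\nf 1 2 3\n")
        with pytest.raises(LayerError, match="vt"):
            read_obj(p)


class TestSurfaceArea:
    def test_unit_square(self, unit_sheet):
        assert surface_area(unit_sheet) == pytest.approx(1.0)

    def test_degenerate_triangle_contributes_zero(self):
        layer = SurfaceLayer(
            name="degen",
            vertices=[[0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 1, 0]],
            faces=[(0, 1, 2), (0, 1, 3)],
            uv_corners=[np.array([[0, 0], [0.5, 0], [1, 0]]),
                        np.array([[0, 0], [1, 0], [0, 1]])],
        )
        assert surface_area(layer) == pytest.approx(0.5)

    def test_cylinder_refinement_approaches_analytic(self):
        layer = make_tube_strip(1.0, 1.0, 1.0, 256, 2)
        assert surface_area(layer) == pytest.approx(2 * np.pi, rel=1e-3)

    def test_invariant_under_rigid_motion(self, unit_sheet):
        a0 = surface_area(unit_sheet)
        th = 0.7
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1.0]]
        )
        moved = unit_sheet.copy("moved")
        moved.vertices = unit_sheet.vertices @ R.T + np.array([3.0, -2.0, 5.0])
        moved._cache.clear()
        assert surface_area(moved) == pytest.approx(a0, rel=1e-9)


class TestPointFromUV:
    def test_vertex_corner_maps_to_vertex(self, unit_sheet):
        pt = point_from_uv(unit_sheet, (0.25, 0.5))
        assert np.allclose(pt.xyz, (0.25, 0.5, 0.0))

    def test_center_of_flat_square(self, unit_sheet):
        pt = point_from_uv(unit_sheet, (0.5, 0.5))
        assert np.allclose(pt.xyz, (0.5, 0.5, 0.0), atol=1e-12)

    def test_outside_chart_returns_none(self, unit_sheet):
        assert point_from_uv(unit_sheet, (1.5, 0.5)) is None

    @settings(deadline=None, max_examples=200)
    @given(
        u=st.floats(0.001, 0.999),
        v=st.floats(0.001, 0.999),
    )
    def test_uv_round_trip_on_curved_chart(self, u, v):
        layer = make_cone_strip(0.4, 1.0, 2.0, 0.5, 12, 6)
        pt = point_from_uv(layer, (u, v))
        assert pt is not None
        assert np.allclose(pt.uv, (u, v), atol=1e-9)

    def test_derived_fields_match_barycentric_combination(self):
        layer = make_cone_strip(0.4, 1.0, 2.0, 0.5, 12, 6)
        rng = np.random.default_rng(0)
        for _ in range(50):
            uv = rng.random(2) * 0.998 + 0.001
            pt = point_from_uv(layer, uv)
            tri = layer.tri_xyz[pt.tri_index]
            assert np.allclose(pt.xyz, np.asarray(pt.bary) @ tri, atol=1e-9)


class TestPlaceNeurons:
    def test_half_counts_binomial(self, unit_sheet):
        n = 10_000
        pop = place_neurons(unit_sheet, n, seed=42)
        left = int((pop.uv[:, 0] < 0.5).sum())
        sigma = np.sqrt(n * 0.25)
        assert abs(left - n / 2) < 4 * sigma

    def test_density_zero_half_excludes_it(self, unit_sheet):
        dm = np.ones((32, 32))
        dm[:, :16] = 0.0  # zero weight for u < 0.5
        unit_sheet.density_map = dm
        pop = place_neurons(unit_sheet, 2000, seed=1, use_density=True)
        assert (pop.uv[:, 0] >= 0.47).all()

    def test_cone_band_ratio_matches_area_ratio(self):
        rp, rd, L = 0.25, 1.0, 2.0
        layer = make_cone_strip(rp, rd, L, 0.5, 48, 24)
        n = 100_000
        pop = place_neurons(layer, n, seed=7)
        w = 0.1
        n_prox = int((pop.uv[:, 1] < w).sum())
        n_dist = int((pop.uv[:, 1] > 1 - w).sum())
        expected = cone_band_area(rp, rd, L, 1 - w, 1.0) / cone_band_area(rp, rd, L, 0.0, w)
        ratio = n_dist / n_prox
        se = ratio * np.sqrt(1 / n_dist + 1 / n_prox)
        assert abs(ratio - expected) < 3 * se

    def test_reproducible_and_seed_sensitive(self, unit_sheet):
        a = place_neurons(unit_sheet, 500, seed=3)
        b = place_neurons(unit_sheet, 500, seed=3)
        c = place_neurons(unit_sheet, 500, seed=4)
        assert np.array_equal(a.xyz, b.xyz)
        assert not np.array_equal(a.xyz, c.xyz)

    def test_per_face_counts_multinomial_in_area(self):
        layer = make_cone_strip(0.2, 1.0, 1.0, 0.5, 5, 1)  # 5 quads, unequal areas
        n = 100_000
        pop = place_neurons(layer, n, seed=11)
        face = layer.tri_face[pop.tri_index]
        counts = np.bincount(face, minlength=len(layer.faces))
        areas = np.zeros(len(layer.faces))
        np.add.at(areas, layer.tri_face, layer.tri_areas)
        expected = areas / areas.sum() * n
        chi2 = ((counts - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, len(counts) - 1)
        assert p > 0.01

    def test_zero_weight_errors(self, unit_sheet):
        unit_sheet.density_map = np.zeros((4, 4))
        with pytest.raises(LayerError, match="no admissible surface"):
            place_neurons(unit_sheet, 10, seed=0, use_density=True)


class TestNeuronCount:
    @pytest.mark.parametrize(
        "area,dens,expected", [(2.0, 10.0, 20), (0.0, 50.0, 0), (1.5, 3.0, 4)]
    )
    def test_rounded_product(self, area, dens, expected):
        assert neuron_count_from_density(area, dens) == expected

    def test_mesh_area_consistent_with_analytic(self):
        from anatomap.geometry import cone_strip_area

        layer = make_cone_strip(0.3, 0.9, 2.0, 0.5, 64, 32)
        dens = 125.0
        n_mesh = neuron_count_from_density(surface_area(layer), dens)
        n_analytic = neuron_count_from_density(cone_strip_area(0.3, 0.9, 2.0, 0.5), dens)
        assert abs(n_mesh - n_analytic) <= max(2, 0.01 * n_analytic)


class TestUVPathLength:
    def test_flat_sheet_is_straight_distance(self, unit_sheet):
        d = uv_path_length(unit_sheet, (0.1, 0.2), (0.8, 0.9))
        assert d == pytest.approx(np.hypot(0.7, 0.7), abs=1e-9)

    def test_zero_length(self, unit_sheet):
        assert uv_path_length(unit_sheet, (0.3, 0.3), (0.3, 0.3)) == 0.0

    def test_half_turn_on_cylinder(self):
        layer = make_tube_strip(1.0, 1.0, 0.5, 96, 4)
        d = uv_path_length(layer, (0.0, 0.5), (1.0, 0.5))
        assert d == pytest.approx(np.pi, rel=5e-3)

    def test_symmetry(self):
        layer = make_cone_strip(0.3, 1.0, 2.0, 0.5, 24, 12)
        a, b = (0.1, 0.2), (0.9, 0.8)
        assert uv_path_length(layer, a, b) == pytest.approx(
            uv_path_length(layer, b, a), rel=1e-9
        )

    def test_triangle_inequality_on_flat_sheet(self, unit_sheet):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a, b, c = rng.random((3, 2)) * 0.98 + 0.01
            ab = uv_path_length(unit_sheet, a, b)
            bc = uv_path_length(unit_sheet, b, c)
            ac = uv_path_length(unit_sheet, a, c)
            assert ac <= ab + bc + 1e-9

    def test_path_leaving_chart_errors(self, unit_sheet):
        with pytest.raises(LayerError, match="leaves chart"):
            uv_path_length(unit_sheet, (0.5, 0.5), (1.6, 0.5))
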