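import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphoflow import (
    apply_pure_shear,
    apicobasal_profile,
    ecm_coverage,
    junction_polarity_ratio,
    make_cell_mesh,
    mean_anisotropy,
    mean_elongation,
    mesh_from_labels,
    tissue_shape,
    triangle_elongation,
    triangulate,
)
from morphoflow.morphometry import TissueShape
from morphoflow.synthetic import render_membrane_image, synth_junction_intensities

from conftest import q_oracle


def _equilateral(scale=1.0, angle=0.0, center=(0.0, 0.0)):
    base = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]]) * scale
    c, s = np.cos(angle), np.sin(angle)
    return base @ np.array([[c, s], [-s, c]]) + np.asarray(center)


class TestTriangleElongation:
    @pytest.mark.parametrize("scale,angle", [(1.0, 0.0), (3.7, 0.9), (0.2, 2.4)])
    def test_equilateral_is_isotropic(self, scale, angle):
        q = triangle_elongation(_equilateral(scale, angle))
        assert abs(q.qxx) < 1e-12 and abs(q.qxy) < 1e-12

    def test_pure_shear_gives_exact_log_strain(self):
        tri = _equilateral(2.0, 0.7)
        sheared = tri * np.array([np.exp(0.3), np.exp(-0.3)])
        q = triangle_elongation(sheared)
        assert q.qxx == pytest.approx(0.3, abs=1e-10)
        assert q.qxy == pytest.approx(0.0, abs=1e-10)

    def test_vertex_order_invariance(self):
        tri = np.array([[0.0, 0.0], [2.0, 0.3], [0.7, 1.9]])
        qs = [triangle_elongation(tri[list(p)])
              for p in ((0, 1, 2), (1, 2, 0), (2, 0, 1), (0, 2, 1))]
        for q in qs[1:]:
            assert q.qxx == pytest.approx(qs[0].qxx, abs=1e-12)
            assert q.qxy == pytest.approx(qs[0].qxy, abs=1e-12)

    def test_degenerate_triangle_rejected(self):
        with pytest.raises(ValueError):
            triangle_elongation(np.array([[0, 0], [1, 1], [2, 2]], float))

    def test_agrees_with_eigendecomposition_oracle(self):
        rng = np.random.default_rng(42)
        n_checked = 0
        while n_checked < 1000:
            tri = rng.uniform(-1, 1, size=(3, 2))
            e1, e2 = tri[1] - tri[0], tri[2] - tri[0]
            if abs(e1[0] * e2[1] - e1[1] * e2[0]) < 1e-3:
                continue
            q = triangle_elongation(tri)
            oxx, oxy = q_oracle(tri)
            assert q.qxx == pytest.approx(oxx, abs=1e-10)
            assert q.qxy == pytest.approx(oxy, abs=1e-10)
            n_checked += 1

    @pytest.mark.parametrize("theta_deg", [30.0, 45.0, 90.0])
    def test_rotation_covariance_2theta(self, theta_deg):
        """Rotating a triangle by theta rotates (qxx, qxy) by 2*theta."""
        tri = np.array([[0.0, 0.0], [2.0, 0.3], [0.7, 1.9]])
        q0 = triangle_elongation(tri)
        th = np.radians(theta_deg)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        q1 = triangle_elongation(tri @ R.T)
        c2, s2 = np.cos(2 * th), np.sin(2 * th)
        assert q1.qxx == pytest.approx(c2 * q0.qxx - s2 * q0.qxy, abs=1e-10)
        assert q1.qxy == pytest.approx(s2 * q0.qxx + c2 * q0.qxy, abs=1e-10)


class TestTriangulation:
    def test_one_triangle_per_interior_threefold_vertex(self, hex_mesh):
        tri = triangulate(hex_mesh)
        n_interior = int(
            sum(
                hex_mesh.vertex_interior[v]
                and len(hex_mesh.vertex_cells[v]) == 3
                for v in range(len(hex_mesh.vertex_positions))
            )
        )
        assert len(tri) == n_interior

    def test_triples_are_mutually_adjacent(self, disordered_mesh):
        tri = triangulate(disordered_mesh)
        adj = disordered_mesh.adjacency
        for a, b, c in tri.cell_triples:
            for p, q in ((a, b), (b, c), (a, c)):
                assert (min(p, q), max(p, q)) in adj

    def test_fourfold_vertex_fans_into_two_triangles(self, disordered_mesh):
        from morphoflow.mesh import merge_vertices, t1_candidate_edges

        m = disordered_mesh
        u, v = t1_candidate_edges(m)[0]
        merged = merge_vertices(m, u, v)
        tri0 = triangulate(m)
        tri1 = triangulate(merged)
        # two threefold vertices (2 triangles) became one fourfold (2 triangles)
        assert len(tri1) == len(tri0)
        assert len(merged.vertex_cells[u]) == 4

    def test_empty_triangulation_warns(self):
        m = make_cell_mesh(4, 0.0, seed=0)
        # strip interior flags to force the degenerate path
        m.vertex_interior[:] = False
        with pytest.warns(UserWarning):
            tri = triangulate(m)
        assert len(tri) == 0


class TestMeanElongation:
    def test_sheared_lattice_both_weightings(self, hex_mesh):
        sheared = apply_pure_shear(hex_mesh, 0.3)
        tri = triangulate(sheared)
        for w in ("uniform", "area"):
            q = mean_elongation(tri, weighting=w)
            assert q.qxx == pytest.approx(0.3, abs=1e-7)
            assert q.qxy == pytest.approx(0.0, abs=1e-7)

    def test_magnitude_mean_dominates_mean_magnitude(self, disordered_mesh):
        tri = triangulate(disordered_mesh)
        assert mean_anisotropy(tri) >= mean_elongation(tri).magnitude

    def test_affine_additivity_on_isotropic_lattice(self, hex_mesh):
        q0 = mean_elongation(triangulate(hex_mesh))
        q1 = mean_elongation(triangulate(apply_pure_shear(hex_mesh, 0.25)))
        assert q1.qxx - q0.qxx == pytest.approx(0.25, abs=1e-6)
        assert q1.qxy - q0.qxy == pytest.approx(0.0, abs=1e-6)

    def test_affine_additivity_second_order_on_disordered(self, disordered_mesh):
        """Finite-strain additivity is approximate when qxy != 0: the
        deviation is second order in shear x local anisotropy."""
        q0 = mean_elongation(triangulate(disordered_mesh))
        q1 = mean_elongation(triangulate(apply_pure_shear(disordered_mesh, 0.1)))
        assert q1.qxx - q0.qxx == pytest.approx(0.1, abs=5e-3)

    def test_empty_raises(self):
        from morphoflow.morphometry import Triangulation

        empty = Triangulation(
            cell_triples=np.empty((0, 3), int),
            corners=np.empty((0, 3, 2)),
            areas=np.empty(0),
        )
        with pytest.raises(ValueError):
            mean_elongation(empty)


class TestTissueShape:
    def test_natural_strain_values(self):
        s = TissueShape(l=2.0, h=1.0, area=2.0, l0=1.0, h0=1.0)
        assert s.L == pytest.approx(np.log(2), abs=1e-12)
        assert s.H == 0.0
        assert s.LmH == pytest.approx(0.6931, abs=1e-4)

    def test_pure_shear_doubles_in_LmH(self, disordered_mesh):
        ref = tissue_shape(disordered_mesh)
        sheared = tissue_shape(apply_pure_shear(disordered_mesh, 0.2), ref)
        assert sheared.LmH == pytest.approx(0.4, abs=1e-9)


class TestMeshFromLabels:
    def test_closed_loop_adjacency_and_centroids(self):
        m = make_cell_mesh(64, 0.2, seed=11)
        _, labels = render_membrane_image(m, px_per_unit=32.0, seed=0)
        rec = mesh_from_labels(labels)
        gt_adj = {(a + 1, b + 1) for a, b in m.adjacency}
        assert rec.adjacency == gt_adj
        # centroids within 1 px of the polygon centroids (in px coordinates)
        xmin, ymin, _, _ = m.bounds()
        gt_px = (m.centroids - [xmin - 0.5, ymin - 0.5]) * 32.0 - 0.5
        order = np.argsort(rec.cell_ids)
        err = np.linalg.norm(rec.centroids[order] - gt_px, axis=1)
        assert np.max(err) < 1.0

    def test_too_few_labels_rejected(self):
        with pytest.raises(ValueError):
            mesh_from_labels(np.ones((10, 10), dtype=int))


class TestIntensityMetrics:
    def test_uniform_intensities_give_unit_ratio(self, disordered_mesh):
        ints = {pair: 1.0 for pair in disordered_mesh.adjacency}
        assert junction_polarity_ratio(disordered_mesh, ints) == pytest.approx(1.0)

    def test_doubled_ap_class_gives_two(self, disordered_mesh):
        ints = synth_junction_intensities(disordered_mesh, 2.0, 0.0, seed=0)
        assert junction_polarity_ratio(disordered_mesh, ints) == pytest.approx(2.0)

    def test_noisy_ratio_recovered_within_5pct(self):
        m = make_cell_mesh(300, 0.25, seed=2)
        assert len(m.adjacency) >= 500
        ints = synth_junction_intensities(m, 2.0, 0.1, seed=1)
        r = junction_polarity_ratio(m, ints)
        assert r == pytest.approx(2.0, rel=0.05)

    def test_apicobasal_normalization_invariance(self):
        rng = np.random.default_rng(0)
        lines = [rng.uniform(0.5, 2.0, 40) for _ in range(5)]
        ref = apicobasal_profile(lines)
        scaled = apicobasal_profile([lines[0] * 10.0] + lines[1:])
        assert np.allclose(ref, scaled)
        assert ref.mean() == pytest.approx(1.0)

    def test_apicobasal_preserves_peaks(self):
        x = np.linspace(0, 1, 101)
        line = 1.0 + np.exp(-((x - 0.3) / 0.05) ** 2) + np.exp(-((x - 0.8) / 0.05) ** 2)
        prof = apicobasal_profile([line, 2.0 * line])
        assert abs(int(np.argmax(prof[:50])) - 30) <= 1
        assert abs(int(np.argmax(prof[50:])) + 50 - 80) <= 1

    @given(st.floats(min_value=0.05, max_value=0.95))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_coverage_with_explicit_threshold(self, frac):
        from morphoflow.synthetic import synth_surface_profile

        prof, mask = synth_surface_profile(frac, 800, 10.0, seed=5)
        cov = ecm_coverage(prof, threshold=5.0)
        assert cov == pytest.approx(100.0 * mask.mean(), abs=1.0)

    def test_coverage_extremes(self):
        assert ecm_coverage(np.full(100, 9.0), threshold=5.0) == 100.0
        assert ecm_coverage(np.full(100, 1.0), threshold=5.0) == 0.0
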