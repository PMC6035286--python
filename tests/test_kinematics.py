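import numpy as np
import pytest

from morphoflow.kinematics import (
    ElongationSeries,
    detect_events,
    elongation_rate,
    measure_series,
    natural_strain_series,
    rearrangement_shear,
    shear_rate,
)
from morphoflow.mesh import apply_t1, remove_cell, t1_candidate_edges
from morphoflow.morphometry import TissueShape
from morphoflow.synthetic import plant_event_series


def _shape(l, h):
    return TissueShape(l=l, h=h, area=l * h)


class TestNaturalStrain:
    def test_constant_shapes_give_zero(self):
        L, H, LmH = natural_strain_series([_shape(2, 1)] * 4)
        assert np.allclose(L, 0) and np.allclose(H, 0) and np.allclose(LmH, 0)

    def test_double_and_halve(self):
        _, _, LmH = natural_strain_series([_shape(1, 1), _shape(2, 0.5)])
        assert LmH[-1] == pytest.approx(np.log(4), abs=1e-12)

    def test_log_additivity_under_composition(self):
        shapes = [_shape(1, 1), _shape(1.5, 1 / 1.5), _shape(2.25, 1 / 2.25)]
        _, _, LmH = natural_strain_series(shapes)
        assert LmH[2] == pytest.approx(2 * LmH[1], abs=1e-12)


class TestRates:
    def test_linear_strain_gives_constant_rate(self):
        t = np.linspace(0, 5, 11)
        v = shear_rate(0.2 * t, t)
        assert np.allclose(v, 0.1, atol=1e-12)

    def test_constant_gives_zero(self):
        t = np.linspace(0, 5, 11)
        assert np.allclose(shear_rate(np.ones_like(t), t), 0.0)

    def test_quadratic_matches_analytic_derivative(self):
        t = np.linspace(0, 2, 21)
        v = shear_rate(t**2, t)
        # central differences are exact for quadratics at interior points
        assert np.allclose(v[1:-1], t[1:-1], atol=1e-12)

    def test_decomposition_identity_is_exact(self):
        rng = np.random.default_rng(3)
        t = np.linspace(4, 7, 13)
        series = ElongationSeries(
            times=t, Qxx=rng.normal(size=13), LmH=rng.normal(size=13)
        )
        resid = (
            shear_rate(series.LmH, series.times)
            - elongation_rate(series)
            - rearrangement_shear(series)
        )
        assert np.max(np.abs(resid)) == 0.0


class TestEventDetection:
    def test_single_t1(self, disordered_mesh):
        m = disordered_mesh
        after = apply_t1(m, t1_candidate_edges(m)[0])
        after.frame_time = 1.0
        counts = detect_events([m, after])
        assert (counts.n_T1, counts.n_T2, counts.n_rosette) == (1, 0, 0)
        assert counts.cells_involved == 4

    def test_single_extrusion(self, disordered_mesh):
        m = disordered_mesh
        after = remove_cell(m, 70)
        after.frame_time = 1.0
        counts = detect_events([m, after])
        assert (counts.n_T1, counts.n_T2, counts.n_rosette) == (0, 1, 0)

    @pytest.mark.parametrize("seed", [9, 21])
    def test_mixed_plan_recovered_exactly(self, seed):
        ser = plant_event_series(
            n_cells=150, disorder=0.2, n_frames=8,
            n_t1=4, n_t2=3, n_rosette=3, seed=seed,
        )
        gt = {(e.kind, e.cell_ids) for e in ser.ground_truth.events}
        det = detect_events(ser.frames)
        found = {(e.kind, e.cell_ids) for e in det.events}
        assert found == gt  # precision = recall = 1

    def test_recall_under_centroid_jitter(self):
        """2% of a cell diameter of positional noise must not break the
        topological detection."""
        ser = plant_event_series(
            n_cells=150, disorder=0.2, n_frames=8,
            n_t1=4, n_t2=3, n_rosette=3, jitter_sd=0.02, seed=9,
        )
        gt = {(e.kind, e.cell_ids) for e in ser.ground_truth.events}
        det = {(e.kind, e.cell_ids) for e in detect_events(ser.frames).events}
        assert len(gt & det) / len(gt) >= 0.9

    def test_untracked_series_rejected(self, disordered_mesh):
        with pytest.raises(ValueError):
            detect_events([disordered_mesh])


class TestMeasureSeries:
    def test_reference_frame_strain_zero(self, disordered_mesh):
        from morphoflow import apply_pure_shear

        m2 = apply_pure_shear(disordered_mesh, 0.1)
        m2.frame_time = 1.0
        s = measure_series([disordered_mesh, m2])
        assert s.LmH[0] == 0.0
        assert s.LmH[1] == pytest.approx(0.2, abs=1e-9)
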