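import numpy as np
import pytest

from morphoflow.kinematics import measure_series, rearrangement_shear
from morphoflow.model import ModelParams, qxx_schedule, solve_Qxx_closed, predict_LmH
from morphoflow.synthetic import (
    render_membrane_image,
    simulate_tissue_series,
    synth_elongation_data,
    synth_junction_intensities,
    synth_surface_profile,
)


class TestElongationData:
    def test_zero_noise_is_exact_forward_solution(self, schedule,
                                                  paper_regime_params):
        t = np.linspace(4, 7, 13)
        s = synth_elongation_data(paper_regime_params, schedule, -0.05, 0.0,
                                  t, seed=0)
        assert np.allclose(
            s.Qxx, solve_Qxx_closed(paper_regime_params, -0.05, schedule, t)
        )
        assert np.allclose(
            s.LmH, predict_LmH(paper_regime_params, schedule, t, -0.05)
        )

    def test_reference_strain_pinned_to_zero(self, schedule,
                                             paper_regime_params):
        s = synth_elongation_data(paper_regime_params, schedule, -0.05, 0.05,
                                  np.linspace(4, 7, 13), seed=3)
        assert s.LmH[0] == 0.0

    def test_negative_noise_rejected(self, schedule, paper_regime_params):
        with pytest.raises(ValueError):
            synth_elongation_data(paper_regime_params, schedule, 0.0, -0.1,
                                  np.linspace(4, 7, 13), seed=0)


class TestTissueSeries:
    def test_no_rearrangements_without_lambda(self, schedule):
        ser = simulate_tissue_series(
            schedule, ModelParams(0.5, -0.1, 0.0), Qxx0=-0.05,
            dt=0.5, t_end=6.0, seed=4, n_cells=120,
        )
        assert len(ser.ground_truth.events) == 0
        assert np.allclose(ser.ground_truth.rearrangement_rate, 0.0, atol=1e-9)

    def test_planted_shear_matches_imposed_rate(self, schedule):
        """Cumulative planted rearrangement shear approximates
        lambda * int q dt over the series."""
        lam = 0.1
        ser = simulate_tissue_series(
            schedule, ModelParams(0.5, -0.1, lam), Qxx0=-0.05,
            dt=0.25, t_end=7.0, seed=11,
        )
        t = ser.times
        expected = lam * np.trapezoid(qxx_schedule(t, schedule), t)
        got = float(ser.ground_truth.rearrangement_rate.sum() * 0.25)
        assert got == pytest.approx(expected, rel=0.05)
        assert len(ser.ground_truth.events) > 0

    def test_closed_loop_rearrangement_recovery(self, schedule):
        """The kinematics module recovers the imposed rearrangement shear
        from the mesh series within 10%."""
        ser = simulate_tissue_series(
            schedule, ModelParams(0.5, -0.1, 0.1), Qxx0=-0.05,
            dt=0.25, t_end=7.0, seed=11,
        )
        meas = measure_series(ser.frames)
        rxx = rearrangement_shear(meas)
        cum_meas = float(np.trapezoid(rxx, meas.times))
        cum_gt = float(ser.ground_truth.rearrangement_rate.sum() * 0.25)
        assert cum_meas == pytest.approx(cum_gt, rel=0.10)

    def test_degenerate_parameters_refused(self, schedule):
        with pytest.raises(ValueError):
            simulate_tissue_series(
                schedule, ModelParams(0.5, -2.0, 0.0), Qxx0=0.0,
                dt=0.5, t_end=7.0, seed=0,
            )

    def test_invalid_dt_rejected(self, schedule, paper_regime_params):
        with pytest.raises(ValueError):
            simulate_tissue_series(schedule, paper_regime_params, dt=0.0,
                                   t_end=7.0, seed=0)


class TestRender:
    def test_label_cardinality(self):
        from morphoflow import make_cell_mesh

        m = make_cell_mesh(64, 0.2, seed=11)
        _, labels = render_membrane_image(m, 32.0, 2.0, np.inf, 0)
        assert len(set(np.unique(labels)) - {0}) == 64

    def test_bit_identical_for_fixed_seed(self):
        from morphoflow import make_cell_mesh

        m = make_cell_mesh(36, 0.2, seed=2)
        a, la = render_membrane_image(m, 24.0, 2.0, 8.0, seed=5)
        b, lb = render_membrane_image(m, 24.0, 2.0, 8.0, seed=5)
        assert np.array_equal(a, b) and np.array_equal(la, lb)

    def test_size_cap_enforced(self):
        from morphoflow import make_cell_mesh

        m = make_cell_mesh(36, 0.2, seed=2)
        with pytest.raises(ValueError):
            render_membrane_image(m, 24.0, 2.0, np.inf, 0, max_pixels=1000)


class TestJunctionIntensities:
    def test_unit_ratio_means_uniform_classes(self, disordered_mesh):
        ints = synth_junction_intensities(disordered_mesh, 1.0, 0.0, seed=0)
        vals = np.array(list(ints.values()))
        assert np.allclose(vals, 1.0)

    def test_invalid_ratio_rejected(self, disordered_mesh):
        with pytest.raises(ValueError):
            synth_junction_intensities(disordered_mesh, 0.0, 0.0, seed=0)


class TestSurfaceProfile:
    def test_coverage_fraction_planted_exactly(self):
        prof, mask = synth_surface_profile(0.3, 1000, 10.0, seed=3)
        assert mask.sum() == 300
        assert prof.shape == (1000,)

    def test_covered_runs_are_contiguous(self):
        _, mask = synth_surface_profile(0.4, 500, 10.0, seed=8, max_segments=3)
        runs = np.diff(mask.astype(int))
        assert (runs == 1).sum() <= 3  # at most max_segments rising edges

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            synth_surface_profile(1.2, 100, 10.0, seed=0)
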