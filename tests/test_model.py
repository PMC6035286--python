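import numpy as np
import pytest

from morphoflow.model import (
    ModelParams,
    MyosinSchedule,
    default_tau_grid,
    fit,
    predict_LmH,
    qxx_schedule,
    solve_Qxx_closed,
    solve_Qxx_ode,
)
from morphoflow.synthetic import synth_elongation_data

T = np.linspace(4.0, 8.0, 81)


class TestSchedule:
    def test_plateau_ramp_zero(self, schedule):
        assert qxx_schedule(4.5, schedule) == 1.0
        assert qxx_schedule(5.5, schedule) == 0.5
        assert qxx_schedule(7.0, schedule) == 0.0
        assert qxx_schedule(6.0, schedule) == 0.0  # right-continuity at t2

    def test_before_start_rejected(self, schedule):
        with pytest.raises(ValueError):
            qxx_schedule(3.0, schedule)

    def test_bad_ordering_rejected(self):
        with pytest.raises(ValueError):
            MyosinSchedule(t0=5.0, t1=5.0, t2=6.0)


class TestParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            ModelParams(tau_s=0.0, zeta_over_2K=-0.1, lam=0.1)
        with pytest.raises(ValueError):
            ModelParams(tau_s=0.5, zeta_over_2K=np.nan, lam=0.1)

    def test_derived_viscous_ratio(self):
        p = ModelParams(0.5, -0.1, 0.1)
        assert p.zeta_over_2mu == pytest.approx(-0.2)


class TestSolvers:
    def test_closed_equals_ode_on_regime_grid(self, schedule):
        """Closed form and adaptive integration agree to 1e-6 sup-norm
        across the physiological parameter box."""
        worst = 0.0
        for tau in (0.1, 0.5, 1.0):
            for z2k in (-0.14, -0.10, -0.06):
                for q0 in (-0.1, 0.0, 0.1):
                    p = ModelParams(tau, z2k, 0.1)
                    c = solve_Qxx_closed(p, q0, schedule, T)
                    o = solve_Qxx_ode(p, q0, schedule, T, tol=1e-10)
                    worst = max(worst, float(np.max(np.abs(c - o))))
        assert worst <= 1e-6

    def test_pure_decay_without_active_stress(self, schedule):
        p = ModelParams(0.5, 0.0, 0.0)
        c = solve_Qxx_closed(p, 0.2, schedule, T)
        assert np.allclose(c, 0.2 * np.exp(-(T - 4.0) / 0.5), atol=1e-12)

    def test_stationary_value_under_held_drive(self):
        sched = MyosinSchedule(t0=4.0, t1=200.0, t2=201.0)
        p = ModelParams(0.5, -0.1, 0.0)
        q = solve_Qxx_closed(p, 0.0, sched, np.array([80.0]))
        assert q[0] == pytest.approx(0.1, abs=1e-12)

    def test_linearity_in_active_stress(self, schedule):
        """The particular solution superposes linearly in zeta/2K."""
        base = solve_Qxx_closed(ModelParams(0.5, 0.0, 0.0), 0.0, schedule, T)
        one = solve_Qxx_closed(ModelParams(0.5, 1.0, 0.0), 0.0, schedule, T)
        for z in (-0.14, -0.06, 0.3):
            direct = solve_Qxx_closed(ModelParams(0.5, z, 0.0), 0.0, schedule, T)
            assert np.allclose(direct, base + z * (one - base), atol=1e-12)

    def test_quasi_static_limit(self, schedule):
        """As tau_s -> 0 the elongation adheres to -(zeta/2K) * q(t)."""
        p = ModelParams(0.01, -0.1, 0.0)
        t = np.array([4.5, 5.5, 6.5])
        q = solve_Qxx_closed(p, 0.0, schedule, t)
        expect = 0.1 * qxx_schedule(t, schedule)
        assert np.allclose(q, expect, atol=2e-3)

    def test_invalid_tolerance_rejected(self, schedule, paper_regime_params):
        with pytest.raises(ValueError):
            solve_Qxx_ode(paper_regime_params, 0.0, schedule, T, tol=0.0)


class TestStrainPrediction:
    def test_zero_without_drive(self, schedule):
        lmh = predict_LmH(ModelParams(0.5, 0.0, 0.0), schedule, T, 0.0)
        assert np.allclose(lmh, 0.0, atol=1e-14)

    def test_reference_strain_is_zero(self, schedule, paper_regime_params):
        lmh = predict_LmH(paper_regime_params, schedule, T, -0.05)
        assert lmh[0] == 0.0

    def test_rate_consistency_with_elongation_and_rearrangement(
        self, schedule, paper_regime_params
    ):
        """d(L-H)/dt = 2 (d<Qxx>/dt + lambda*qxx), checked by small-step
        differentiation of the quadrature away from schedule kinks."""
        p, q0 = paper_regime_params, -0.05
        h = 1e-4
        for t in (4.3, 5.4, 6.7):
            tt = np.array([t - h, t, t + h])
            lmh = predict_LmH(p, schedule, tt, q0)
            qq = solve_Qxx_closed(p, q0, schedule, tt)
            dl = (lmh[2] - lmh[0]) / (2 * h)
            dq = (qq[2] - qq[0]) / (2 * h)
            rhs = 2.0 * (dq + p.lam * qxx_schedule(t, schedule))
            assert dl == pytest.approx(rhs, abs=1e-6)

    def test_extension_monotone_while_driven(self, schedule):
        """With contractile AP stress and positive lambda the tissue
        extends along PD while the myosin drive is at full magnitude
        and cell elongation is still building up."""
        p = ModelParams(0.5, -0.1, 0.1)
        t = np.linspace(4.0, 5.0, 21)
        lmh = predict_LmH(p, schedule, t, 0.0)
        assert np.all(np.diff(lmh) > 0)

    def test_misaligned_path_rejected(self, schedule, paper_regime_params):
        with pytest.raises(ValueError):
            predict_LmH(paper_regime_params, schedule, T, 0.0,
                        Qxx_path=np.zeros(3))


class TestFit:
    def test_noiseless_self_consistency(self, schedule, paper_regime_params):
        data = synth_elongation_data(
            paper_regime_params, schedule, -0.05, 0.0,
            np.linspace(4, 7, 13), seed=0,
        )
        res = fit(data, schedule)
        i = int(np.argmin(np.abs(res.tau_grid - 0.5)))
        assert res.zeta_over_2K[i] == pytest.approx(-0.10, abs=1e-4)
        assert res.lam[i] == pytest.approx(0.10, abs=1e-4)
        assert res.best_index == i  # SSE minimal at the true tau_s

    def test_identifiability_design_is_full_rank(self, schedule):
        """Both parameters are identifiable at every grid point: the
        2-column design (sensitivity) matrix is well conditioned, hence
        the SSE Hessian is positive definite."""
        t = np.linspace(4, 7, 13)
        for tau in default_tau_grid():
            q_z = solve_Qxx_closed(ModelParams(tau, 1.0, 0.0), 0.0, schedule, t)
            l_z = predict_LmH(ModelParams(tau, 1.0, 0.0), schedule, t, 0.0)
            l_l = predict_LmH(ModelParams(tau, 0.0, 1.0), schedule, t, 0.0)
            A = np.block([
                [q_z[:, None], np.zeros((len(t), 1))],
                [l_z[:, None], l_l[:, None]],
            ])
            H = A.T @ A
            assert np.all(np.linalg.eigvalsh(H) > 1e-8)

    def test_sequential_mode_close_to_joint_on_noiseless(self, schedule,
                                                         paper_regime_params):
        data = synth_elongation_data(
            paper_regime_params, schedule, -0.05, 0.0,
            np.linspace(4, 7, 13), seed=0,
        )
        j = fit(data, schedule, tau_grid=[0.5], mode="joint")
        s = fit(data, schedule, tau_grid=[0.5], mode="sequential")
        assert s.zeta_over_2K[0] == pytest.approx(j.zeta_over_2K[0], abs=1e-6)
        assert s.lam[0] == pytest.approx(j.lam[0], abs=1e-6)

    def test_nonfinite_data_rejected(self, schedule, paper_regime_params):
        data = synth_elongation_data(
            paper_regime_params, schedule, -0.05, 0.0,
            np.linspace(4, 7, 13), seed=0,
        )
        data.Qxx[3] = np.nan
        with pytest.raises(ValueError):
            fit(data, schedule)

    def test_recovered_values_in_reported_regime(self, schedule):
        """Fits to curves generated in the physiological regime land at
        lambda ~ 0.1/h and zeta/2K in [-0.14, -0.06]."""
        truth = ModelParams(0.5, -0.10, 0.10)
        data = synth_elongation_data(truth, schedule, -0.05, 0.01,
                                     np.linspace(4, 7, 13), seed=7)
        best = fit(data, schedule).best
        assert 0.05 <= best.lam <= 0.15
        assert -0.14 <= best.zeta_over_2K <= -0.06
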