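"""Active continuum model of autonomous tissue convergent extension.

A rectangular tissue under spatially uniform shear: the traceless tissue
shear rate decomposes into cell-elongation change plus cellular
rearrangements, with rearrangements driven by myosin anisotropy q(t) at
rate lambda.  Under free boundaries (zero deviatoric stress), mean cell
elongation obeys

    d<Qxx>/dt = -<Qxx>/tau_s - (zeta/2K)/tau_s * qxx(t),

with tau_s = mu/K the cell-shape relaxation time and zeta/2K the
dimensionless active-stress ratio (negative: AP-contractile, drives PD
extension).  The tissue's natural pure-shear strain follows by
integrating the shear rate:

    (L-H)(t) = -2 * int_{t0}^{t} [ <Qxx>/tau_s
               + ((zeta/2K)/tau_s - lambda) qxx ] dt'.

The myosin anisotropy schedule is piecewise linear: full magnitude on
(t0, t1), a linear ramp to zero on (t1, t2), zero afterwards.

Only the ratios (tau_s, zeta/2K, lambda) are identifiable; given tau_s
the model is affine in (zeta/2K, lambda), so fitting both curves is an
exact two-parameter linear least-squares solve per tau_s grid value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "MyosinSchedule",
    "ModelParams",
    "FitResult",
    "qxx_schedule",
    "solve_Qxx_closed",
    "solve_Qxx_ode",
    "predict_LmH",
    "fit",
    "default_tau_grid",
]


@dataclass(frozen=True)
class MyosinSchedule:
    """Piecewise-linear myosin anisotropy time course (hours APF)."""

    t0: float = 4.0
    t1: float = 5.0
    t2: float = 6.0
    magnitude: float = 1.0

    def __post_init__(self):
        if not (self.t0 < self.t1 < self.t2):
            raise ValueError("schedule requires t0 < t1 < t2")


@dataclass(frozen=True)
class ModelParams:
    """Effective parameters: tau_s [h], zeta/2K [-], lambda [1/h]."""

    tau_s: float
    zeta_over_2K: float
    lam: float

    def __post_init__(self):
        if not (np.isfinite(self.tau_s) and self.tau_s > 0):
            raise ValueError("tau_s must be positive and finite")
        if not np.isfinite(self.zeta_over_2K):
            raise ValueError("zeta_over_2K must be finite")
        if not np.isfinite(self.lam):
            raise ValueError("lam must be finite")

    @property
    def zeta_over_2mu(self) -> float:
        """Derived ratio zeta/2mu = (zeta/2K)/tau_s [1/h]."""
        return self.zeta_over_2K / self.tau_s


def qxx_schedule(t, sched: MyosinSchedule):
    """Myosin anisotropy qxx(t); scalar or array t >= t0.

    Right-continuous at the breakpoints: qxx(t1) starts the ramp at full
    magnitude; qxx(t2) = 0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < sched.t0 - 1e-12):
        raise ValueError(f"schedule undefined before t0={sched.t0}")
    ramp = (sched.t2 - t) / (sched.t2 - sched.t1)
    out = np.where(
        t < sched.t1, 1.0, np.where(t < sched.t2, ramp, 0.0)
    ) * sched.magnitude
    return float(out) if out.ndim == 0 else out


def _segments(sched: MyosinSchedule) -> list[tuple[float, float, float, float]]:
    """(a, b, alpha, beta) per schedule segment with q(t) = alpha + beta*t."""
    m = sched.magnitude
    beta_ramp = -m / (sched.t2 - sched.t1)
    alpha_ramp = m * sched.t2 / (sched.t2 - sched.t1)
    return [
        (sched.t0, sched.t1, m, 0.0),
        (sched.t1, sched.t2, alpha_ramp, beta_ramp),
        (sched.t2, np.inf, 0.0, 0.0),
    ]


def _drive_integral(t: np.ndarray, tau: float, sched: MyosinSchedule) -> np.ndarray:
    """J(t) = int_{t0}^{t} e^{(t'-t)/tau} q(t') dt', exactly per segment.

    The shifted exponent keeps the evaluation overflow-free for small tau.
    For a linear segment q = alpha + beta*t', the antiderivative is
    tau * e^{(t'-t)/tau} * (alpha + beta*t' - tau*beta).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(t)
    for a, b, alpha, beta in _segments(sched):
        lo = np.full_like(t, a)
        hi = np.minimum(t, b)
        active = hi > lo
        if not active.any():
            continue

        def F(x):  # antiderivative evaluated with shifted exponent
            return tau * np.exp((x - t) / tau) * (alpha + beta * x - tau * beta)

        seg = np.where(active, F(hi) - F(lo), 0.0)
        out += seg
    return out


def solve_Qxx_closed(
    params: ModelParams,
    Qxx0: float,
    sched: MyosinSchedule,
    times,
) -> np.ndarray:
    """Closed-form mean cell elongation <Qxx>(t).

    Exact integrating-factor solution: the homogeneous part decays as
    e^{-(t-t0)/tau_s}; the piecewise constant/linear drive integrates in
    closed form against the exponential kernel.
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t < sched.t0 - 1e-12):
        raise ValueError("times must lie at or after the schedule start t0")
    tau = params.tau_s
    hom = Qxx0 * np.exp(-(t - sched.t0) / tau)
    part = -(params.zeta_over_2K / tau) * _drive_integral(t, tau, sched)
    out = hom + part
    return out if np.ndim(times) else out


def solve_Qxx_ode(
    params: ModelParams,
    Qxx0: float,
    sched: MyosinSchedule,
    times,
    tol: float = 1e-9,
) -> np.ndarray:
    """Adaptive numeric integration of the elongation ODE.

    Integrates segment-by-segment between schedule breakpoints so the
    ramp kinks never fall inside an integrator step.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t < sched.t0 - 1e-12):
        raise ValueError("times must lie at or after the schedule start t0")
    tau, z2k = params.tau_s, params.zeta_over_2K

    def rhs(tt, y):
        return [-y[0] / tau - (z2k / tau) * qxx_schedule(min(tt, t[-1] + 1.0), sched)]

    breakpoints = [b for b in (sched.t1, sched.t2) if sched.t0 < b < t.max()]
    knots = np.unique(np.concatenate([[sched.t0], breakpoints, [max(t.max(), sched.t0)]]))
    y0 = float(Qxx0)
    vals = {round(float(sched.t0), 12): y0}
    for a, b in zip(knots[:-1], knots[1:]):
        t_eval = t[(t >= a - 1e-12) & (t <= b + 1e-12)]
        sol = solve_ivp(
            rhs, (a, b), [y0], t_eval=np.unique(np.concatenate([[a], t_eval, [b]])),
            rtol=tol, atol=tol, method="RK45", max_step=(b - a) / 4,
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        for tt, yy in zip(sol.t, sol.y[0]):
            vals[round(float(tt), 12)] = float(yy)
        y0 = float(sol.y[0, -1])
    out = np.array([vals[round(float(tt), 12)] for tt in t])
    return out


# 24-point Gauss-Legendre nodes for the strain quadrature
_GL_X, _GL_W = np.polynomial.legendre.leggauss(24)


def predict_LmH(
    params: ModelParams,
    sched: MyosinSchedule,
    times,
    Qxx0: float,
    Qxx_path: np.ndarray | None = None,
) -> np.ndarray:
    """Tissue natural strain (L-H)(t), with (L-H)(t0) = 0.

    High-order Gauss-Legendre quadrature of the closed-form integrand on
    each inter-timepoint interval, split at the schedule breakpoints.
    ``Qxx_path``, when given, must align with ``times`` (consistency
    check only; the quadrature always uses the closed form).
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if Qxx_path is not None and len(np.atleast_1d(Qxx_path)) != len(t):
        raise ValueError("Qxx_path must align with times")
    if np.any(t < sched.t0 - 1e-12):
        raise ValueError("times must lie at or after the schedule start t0")
    tau, z2k, lam = params.tau_s, params.zeta_over_2K, params.lam

    def integrand(tt):
        q = qxx_schedule(tt, sched)
        Q = solve_Qxx_closed(params, Qxx0, sched, tt)
        return -2.0 * (Q / tau + (z2k / tau - lam) * q)

    knots = np.unique(
        np.concatenate([[sched.t0], t, [b for b in (sched.t1, sched.t2) if b <= t.max()]])
    )
    cum = {knots[0]: 0.0}
    acc = 0.0
    for a, b in zip(knots[:-1], knots[1:]):
        mid, half = 0.5 * (a + b), 0.5 * (b - a)
        nodes = mid + half * _GL_X
        acc += half * float(np.dot(_GL_W, integrand(nodes)))
        cum[b] = acc
    out = np.array([cum[tt] for tt in t])
    return out


def default_tau_grid(n: int = 10, lo: float = 0.1, hi: float = 1.0) -> np.ndarray:
    """Physiologically relevant cell-shape relaxation times, 0.1-1 h."""
    return np.linspace(lo, hi, n)


@dataclass
class FitResult:
    """tau_s-grid fit of (zeta/2K, lambda) to elongation + strain curves."""

    tau_grid: np.ndarray
    zeta_over_2K: np.ndarray
    lam: np.ndarray
    sse: np.ndarray
    converged: np.ndarray
    Qxx0: float
    schedule: MyosinSchedule
    mode: str = "joint"

    @property
    def best_index(self) -> int:
        ok = np.where(self.converged)[0]
        if len(ok) == 0:
            raise ValueError("no converged grid point")
        return int(ok[np.argmin(self.sse[ok])])

    @property
    def best(self) -> ModelParams:
        i = self.best_index
        return ModelParams(
            tau_s=float(self.tau_grid[i]),
            zeta_over_2K=float(self.zeta_over_2K[i]),
            lam=float(self.lam[i]),
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "tau_s": self.tau_grid,
                "zeta_over_2K": self.zeta_over_2K,
                "lam": self.lam,
                "sse": self.sse,
                "converged": self.converged,
            }
        )


def fit(
    data,
    sched: MyosinSchedule,
    tau_grid=None,
    weights: tuple[float, float] | None = None,
    mode: str = "joint",
) -> FitResult:
    """Fit (zeta/2K, lambda) at each tau_s of the grid.

    ``data`` is an ElongationSeries-like object with ``times``, ``Qxx``
    and ``LmH`` arrays.  Qxx0 is pinned to the measured elongation at the
    first timepoint.  Given tau_s the model curves are affine in the two
    parameters, so the inner problem is solved exactly by linear least
    squares on the pooled residuals (equal weighting by default;
    ``weights=(w_Q, w_LmH)`` rescales the two blocks).  ``mode=
    "sequential"`` fits zeta/2K on the Qxx curve alone, then lambda on
    the L-H curve.
    """
    times = np.asarray(data.times, dtype=float)
    qxx_d = np.asarray(data.Qxx, dtype=float)
    lmh_d = np.asarray(data.LmH, dtype=float)
    if len(times) < 4:
        raise ValueError("need at least 4 timepoints")
    if not (np.all(np.isfinite(qxx_d)) and np.all(np.isfinite(lmh_d))):
        raise ValueError("non-finite data")
    if tau_grid is None:
        tau_grid = default_tau_grid()
    tau_grid = np.atleast_1d(np.asarray(tau_grid, dtype=float))
    if len(tau_grid) == 0:
        raise ValueError("empty tau grid")
    Qxx0 = float(qxx_d[0])
    wq, wl = (1.0, 1.0) if weights is None else weights

    z2k_out = np.full(len(tau_grid), np.nan)
    lam_out = np.full(len(tau_grid), np.nan)
    sse_out = np.full(len(tau_grid), np.nan)
    conv = np.zeros(len(tau_grid), dtype=bool)
    for i, tau in enumerate(tau_grid):
        try:
            # affine decomposition via three forward evaluations
            p00 = ModelParams(tau, 0.0, 0.0)
            p10 = ModelParams(tau, 1.0, 0.0)
            p01 = ModelParams(tau, 0.0, 1.0)
            q_base = solve_Qxx_closed(p00, Qxx0, sched, times)
            q_z = solve_Qxx_closed(p10, Qxx0, sched, times) - q_base
            l_base = predict_LmH(p00, sched, times, Qxx0)
            l_z = predict_LmH(p10, sched, times, Qxx0) - l_base
            l_lam = predict_LmH(p01, sched, times, Qxx0) - l_base
            if mode == "joint":
                A = np.block(
                    [
                        [wq * q_z[:, None], np.zeros((len(times), 1))],
                        [wl * l_z[:, None], wl * l_lam[:, None]],
                    ]
                )
                rhs = np.concatenate(
                    [wq * (qxx_d - q_base), wl * (lmh_d - l_base)]
                )
                theta, *_ = np.linalg.lstsq(A, rhs, rcond=None)
                z2k, lam_v = float(theta[0]), float(theta[1])
            elif mode == "sequential":
                z2k = float(np.dot(q_z, qxx_d - q_base) / np.dot(q_z, q_z))
                resid = lmh_d - l_base - z2k * l_z
                lam_v = float(np.dot(l_lam, resid) / np.dot(l_lam, l_lam))
            else:
                raise ValueError(f"unknown fit mode {mode!r}")
            pfit = ModelParams(tau, z2k, lam_v)
            rq = solve_Qxx_closed(pfit, Qxx0, sched, times) - qxx_d
            rl = predict_LmH(pfit, sched, times, Qxx0) - lmh_d
            sse = float(wq**2 * np.sum(rq**2) + wl**2 * np.sum(rl**2))
            z2k_out[i], lam_out[i], sse_out[i] = z2k, lam_v, sse
            conv[i] = np.isfinite(sse)
        except (np.linalg.LinAlgError, FloatingPointError):
            conv[i] = False
    return FitResult(
        tau_grid=tau_grid,
        zeta_over_2K=z2k_out,
        lam=lam_out,
        sse=sse_out,
        converged=conv,
        Qxx0=Qxx0,
        schedule=sched,
        mode=mode,
    )
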