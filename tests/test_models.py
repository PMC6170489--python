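"""Forward-model correctness: closed forms, quadrature and ODE oracles,
nesting, mixing, linearity and the degenerate-eigenvalue limit."""

import numpy as np
import pytest
from scipy.integrate import quad

import fetkin as fk
from fetkin.models import TACModel

from conftest import aif_interpolant, ode_oracle_frames


# -- convolve_monoexp --------------------------------------------------------

def test_convolution_constant_input_closed_form(schedule):
    const = fk.InputFunction(schedule, np.full(schedule.n, 5.0))
    t = np.array([0.5, 2.0, 10.0, 35.0, 40.0])
    out = fk.convolve_monoexp(const, 0.3, t)
    np.testing.assert_allclose(out, 5.0 / 0.3 * (1 - np.exp(-0.3 * t)), rtol=1e-12)


def test_convolution_zero_rate_is_running_integral(schedule, aif_I):
    t = np.array([1.0, 5.0, 20.0, 40.0])
    out = fk.convolve_monoexp(aif_I, 0.0, t)
    ca = aif_interpolant(aif_I)
    # cumulative trapezoid on a grid containing every interpolation knot and
    # evaluation point is exact for the piecewise-linear input
    knots = np.concatenate([[0.0], schedule.midpoints_min, [schedule.ends_min[-1]]])
    fine = np.unique(np.concatenate([np.linspace(0, 40.0, 4001), knots, t]))
    v = ca(fine)
    cum = np.concatenate([[0.0], np.cumsum(np.diff(fine) * 0.5 * (v[1:] + v[:-1]))])
    expected = np.interp(t, fine, cum)
    np.testing.assert_allclose(out, expected, rtol=1e-12)


def test_convolution_matches_quadrature_oracle(schedule, aif_I):
    ca = aif_interpolant(aif_I)
    rate = 0.1
    t_eval = np.array([0.5, 1.0, 5.0, 20.0, 40.0])
    mine = fk.convolve_monoexp(aif_I, rate, t_eval)
    for t, m in zip(t_eval, mine):
        pieces = np.linspace(0, t, 9)
        oracle = sum(
            quad(lambda s: ca(s) * np.exp(-rate * (t - s)), a, b, limit=200)[0]
            for a, b in zip(pieces[:-1], pieces[1:])
        )
        assert abs(m - oracle) <= 1e-6 * abs(oracle)


def test_convolution_rejects_negative_rate_and_bad_grid(aif_I):
    with pytest.raises(ValueError):
        fk.convolve_monoexp(aif_I, -0.1, np.array([1.0]))
    with pytest.raises(ValueError):
        fk.convolve_monoexp(aif_I, 0.1, np.array([45.0]))  # beyond support


def test_convolution_survives_fast_rates(schedule, aif_I):
    # overflow-guarded path: rate*t far beyond the float exponent budget
    out = fk.convolve_monoexp(aif_I, 20.0, np.array([1.0, 40.0]))
    assert np.all(np.isfinite(out)) and np.all(out >= 0)


# -- solvers ----------------------------------------------------------------

def test_1tcm_blood_only_voxel_returns_aif(schedule, aif_I):
    p = fk.KineticParams("1TCM", K1=0.3, k2=0.5, VB=0.999)
    # VB -> 1 limit checked exactly at VB = 1 via the mixing identity
    ctx = TACModel(aif_I, schedule)
    np.testing.assert_allclose(ctx.curve_1tcm(0.3, 0.5, 1.0), aif_I.values, rtol=0, atol=0)
    assert p.VB < 1


def test_1tcm_zero_uptake_is_zero(schedule, aif_I):
    p = fk.KineticParams("s1TCM", K1=0.0, k2=0.3)
    out = fk.solve_1tcm(p, aif_I, schedule)
    np.testing.assert_allclose(out.values, 0.0)


def test_1tcm_matches_ode_oracle(schedule, aif_I):
    p = fk.KineticParams("1TCM", K1=0.085, k2=0.087, VB=0.075)
    mine = fk.solve_1tcm(p, aif_I, schedule).values
    oracle = ode_oracle_frames(p, aif_I, schedule)
    np.testing.assert_allclose(mine, oracle, rtol=1e-4)


def test_2tcm_first_grid_row_matches_ode_oracle(schedule, aif_I):
    p = fk.KineticParams("2TCM", K1=0.10, k2=0.20, k3=0.025, k4=0.05, VB=0.05)
    mine = fk.solve_2tcm(p, aif_I, schedule).values
    oracle = ode_oracle_frames(p, aif_I, schedule)
    np.testing.assert_allclose(mine, oracle, rtol=1e-4)


def test_2tcm_no_exchange_reduces_to_1tcm(schedule, aif_I):
    rng = np.random.default_rng(11)
    for _ in range(20):
        k1, k2 = rng.uniform(0.01, 1.0, 2)
        vb = rng.uniform(0.0, 0.5)
        p2 = fk.KineticParams("2TCM", K1=k1, k2=k2, k3=0.0, k4=0.0, VB=vb)
        p1 = fk.KineticParams("1TCM", K1=k1, k2=k2, VB=vb)
        d = fk.solve_2tcm(p2, aif_I, schedule).values - fk.solve_1tcm(p1, aif_I, schedule).values
        assert np.max(np.abs(d)) < 1e-10


def test_2tcm_pure_blood_signal(schedule, aif_I):
    p = fk.KineticParams("2TCM", K1=0.0, k2=0.3, k3=0.1, k4=0.05, VB=0.05)
    out = fk.solve_2tcm(p, aif_I, schedule)
    np.testing.assert_allclose(out.values, 0.05 * aif_I.values, rtol=1e-12)


def test_2tcm_degenerate_eigenvalues_continuous(schedule, aif_I):
    # k3 = 0, k2 = k4 makes the two eigenrates coincide exactly
    exact = fk.KineticParams("2TCM", K1=0.2, k2=0.2, k3=0.0, k4=0.2, VB=0.05)
    near = fk.KineticParams("2TCM", K1=0.2, k2=0.2, k3=1e-6, k4=0.2, VB=0.05)
    md = fk.solve_2tcm(exact, aif_I, schedule).values
    mn = fk.solve_2tcm(near, aif_I, schedule).values
    np.testing.assert_allclose(md, mn, rtol=1e-4)
    oracle = ode_oracle_frames(exact, aif_I, schedule)
    np.testing.assert_allclose(md, oracle, rtol=1e-4)


def test_solver_model_id_checks(schedule, aif_I):
    p2 = fk.KineticParams("2TCM", K1=0.1, k2=0.2, k3=0.02, k4=0.01, VB=0.05)
    p1 = fk.KineticParams("1TCM", K1=0.1, k2=0.2, VB=0.05)
    with pytest.raises(ValueError):
        fk.solve_1tcm(p2, aif_I, schedule)
    with pytest.raises(ValueError):
        fk.solve_2tcm(p1, aif_I, schedule)


def test_schedule_mismatch_rejected(schedule, aif_I):
    other = fk.FrameSchedule(np.array([0.0, 30.0]), np.array([30.0, 60.0]))
    with pytest.raises(ValueError):
        TACModel(aif_I, other)


# -- algebraic invariants ----------------------------------------------------

def _random_params(rng):
    return fk.KineticParams("2TCM", K1=rng.uniform(0.01, 1), k2=rng.uniform(0.01, 1),
                            k3=rng.uniform(0, 1), k4=rng.uniform(0, 1),
                            VB=rng.uniform(0, 0.9))


def test_linearity_in_input(schedule, aif_I):
    rng = np.random.default_rng(3)
    scaled = fk.InputFunction(schedule, aif_I.values * 3.7)
    for _ in range(10):
        p = _random_params(rng)
        a = fk.solve_2tcm(p, scaled, schedule).values
        b = fk.solve_2tcm(p, aif_I, schedule).values * 3.7
        np.testing.assert_allclose(a, b, rtol=1e-10)


def test_mixing_bounds_and_nonnegativity(schedule, aif_I):
    rng = np.random.default_rng(4)
    for _ in range(15):
        p = _random_params(rng)
        ct_pure = fk.solve_2tcm(
            fk.KineticParams("2TCM", K1=p.K1, k2=p.k2, k3=p.k3, k4=p.k4, VB=0.0),
            aif_I, schedule).values
        mixed = fk.solve_2tcm(p, aif_I, schedule).values
        lo = np.minimum(ct_pure, aif_I.values)
        hi = np.maximum(ct_pure, aif_I.values)
        assert np.all(mixed >= lo - 1e-12) and np.all(mixed <= hi + 1e-12)
        assert np.all(mixed >= 0)


def test_batch_evaluation_matches_scalar(schedule, aif_I):
    rng = np.random.default_rng(5)
    ctx = TACModel(aif_I, schedule)
    X = np.column_stack([rng.uniform(0.01, 1, 8), rng.uniform(0.01, 1, 8),
                         rng.uniform(0, 1, 8), rng.uniform(0, 1, 8),
                         rng.uniform(0, 0.9, 8)])
    batch = ctx.curve_batch("2TCM", X)
    for i in range(8):
        scalar = ctx.curve_2tcm(*X[i])
        np.testing.assert_allclose(batch[i], scalar, rtol=1e-9, atol=1e-12)


# -- frame averaging ---------------------------------------------------------

def test_frame_average_constant_and_linear(schedule):
    assert np.allclose(fk.frame_average(lambda t: np.full_like(t, 3.0), schedule), 3.0)
    first = fk.FrameSchedule(np.array([0.0]), np.array([20.0]))
    # f(t) = t (minutes) averaged over [0, 20 s] -> midpoint 10 s = 1/6 min
    out = fk.frame_average(lambda t: t, first)
    np.testing.assert_allclose(out, [10.0 / 60.0], rtol=1e-12)


def test_frame_average_matches_quadrature(schedule):
    shape = fk.AIFShape()
    # bolus onset on a frame boundary keeps the integrand smooth within frames
    f = lambda t: shape.evaluate(t, 20.0 / 60.0)
    six = fk.FrameSchedule(schedule.starts[:6], schedule.ends[:6])
    mine = fk.frame_average(f, six, n_nodes=48)
    for i in range(6):
        a, b = six.starts_min[i], six.ends_min[i]
        oracle = quad(lambda s: float(f(np.array([s]))[0]), a, b, limit=200)[0] / (b - a)
        assert abs(mine[i] - oracle) <= 1e-6 * max(abs(oracle), 1e-9)


def test_frame_average_sampled_curve_support_check(schedule):
    t = np.linspace(0, 30.0, 50)  # support ends before the last frame (40 min)
    with pytest.raises(ValueError):
        fk.frame_average((t, np.ones_like(t)), schedule)
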