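"""Closed-form forward models for the one- and two-tissue compartment models.

The tissue impulse responses of both models are (sums of) decaying
exponentials, so the tissue curve is a convolution of the arterial input
C_a with exponential kernels:

    1TCM:  C_t(t) = K1 * [C_a (*) exp(-k2 t)](t)
    2TCM:  C_1 + C_2 = K1/(a2-a1) * [ (k3+k4-a1) C_a (*) e^{-a1 t}
                                     + (a2-k3-k4) C_a (*) e^{-a2 t} ]
           a_{1,2} = 0.5 [ (k2+k3+k4) -/+ sqrt((k2+k3+k4)^2 - 4 k2 k4) ]

and the measured voxel signal mixes in fractional blood volume:

    C_T(t) = (1 - VB) C_t(t) + VB C_a(t).

C_a is represented piecewise-linearly between frame midpoints (constant
extension at both ends), which admits *exact* per-segment convolution and
frame-integration formulas — no Riemann sums.  PET frames accumulate decays
over their whole duration, so model curves are frame-averaged by default; a
midpoint-evaluation fallback is provided.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .curves import FrameSchedule, InputFunction, KineticParams, TissueCurve

__all__ = [
    "TACModel",
    "convolve_monoexp",
    "solve_1tcm",
    "solve_2tcm",
    "frame_average",
]

# exponent guard: above this the cumsum trick for the recurrence could overflow
_MAX_EXPONENT = 500.0
# below this x = rate*dt, use Taylor forms of the phi functions
_PHI_TAYLOR_X = 1e-3
# eigenvalue gap below which the confluent (t e^{-at}) limit form is used
_DEGENERATE_GAP = 1e-9


def _phis(x: np.ndarray):
    """Stable helpers phi1 = (1-e^-x)/x, phi2 = (1/2 - ... ), phi3.

    phi1(x) = (1 - e^{-x}) / x
    phi2(x) = (x - 1 + e^{-x}) / x^2
    phi3(x) = (x^2/2 - x + 1 - e^{-x}) / x^3

    with phi1(0) = 1, phi2(0) = 1/2, phi3(0) = 1/6, so a zero rate flows
    through the same code path (running integral of C_a).
    """
    x = np.asarray(x, dtype=float)
    small = x < _PHI_TAYLOR_X
    xs = np.where(small, 0.0, x)  # avoid 0/0 in the exact branch
    with np.errstate(divide="ignore", invalid="ignore"):
        em = -np.expm1(-xs)
        p1 = em / xs
        p2 = (1.0 - p1) / xs
        p3 = (0.5 - p2) / xs
    xt = x  # Taylor branch, |x| < 1e-3 → truncation error < 1e-16 relative
    t1 = 1.0 - xt / 2 + xt**2 / 6 - xt**3 / 24
    t2 = 0.5 - xt / 6 + xt**2 / 24 - xt**3 / 120
    t3 = 1.0 / 6 - xt / 24 + xt**2 / 120 - xt**3 / 720
    return (
        np.where(small, t1, p1),
        np.where(small, t2, p2),
        np.where(small, t3, p3),
    )


@njit(cache=True)
def _conv_frames_kernel(dt, a, b, seg_frame, durations, rates):  # pragma: no cover - jitted
    """Frame-averaged exponential convolutions for a vector of rates.

    Scalar recurrence over segments: y_{j+1} = y_j e^{-x} + g_j with the
    exact per-segment increment and integral of a piecewise-linear input,
    expressed through the stable phi functions (Taylor branch for small x).
    """
    n_rates = rates.size
    n_seg = dt.size
    n_frames = durations.size
    out = np.zeros((n_rates, n_frames))
    for i in range(n_rates):
        r = rates[i]
        y = 0.0
        for j in range(n_seg):
            d = dt[j]
            x = r * d
            e = math.exp(-x)
            if x < 1e-3:
                p1 = 1.0 - x / 2 + x * x / 6 - x * x * x / 24
                p2 = 0.5 - x / 6 + x * x / 24 - x * x * x / 120
                p3 = 1.0 / 6 - x / 24 + x * x / 120 - x * x * x / 720
            else:
                p1 = (1.0 - e) / x
                p2 = (1.0 - p1) / x
                p3 = (0.5 - p2) / x
            f = seg_frame[j]
            if f >= 0:
                out[i, f] += d * (y * p1 + a[j] * d * p2 + b[j] * d * d * p3)
            y = y * e + d * (a[j] * p1 + b[j] * d * p2)
        for k in range(n_frames):
            out[i, k] /= durations[k]
    return out


class TACModel:
    """Precomputed evaluation context binding an input function to a schedule.

    Builds the piecewise-linear representation of C_a on a grid holding the
    interpolation knots (frame midpoints plus constant-extension endpoints)
    and all frame boundaries, so exponential convolutions and their frame
    integrals are evaluated analytically segment by segment.  Reuse one
    instance across many fits of the same (AIF, schedule) pair.
    """

    def __init__(self, input_fn: InputFunction, schedule: FrameSchedule,
                 frame_averaged: bool = True):
        if input_fn.schedule.n != schedule.n or not (
            np.allclose(input_fn.schedule.starts, schedule.starts)
            and np.allclose(input_fn.schedule.ends, schedule.ends)
        ):
            raise ValueError("input function and tissue schedule must match")
        self.input_fn = input_fn
        self.schedule = schedule
        self.frame_averaged = frame_averaged

        mids = schedule.midpoints_min
        vals = input_fn.values.astype(float)
        t_end = schedule.ends_min[-1]
        knots_t = np.concatenate([[0.0], mids, [t_end]])
        knots_v = np.concatenate([[vals[0]], vals, [vals[-1]]])
        if mids[0] == 0.0:  # degenerate zero-width start; cannot occur with valid frames
            knots_t, knots_v = knots_t[1:], knots_v[1:]

        grid = np.unique(np.concatenate([knots_t, schedule.starts_min, schedule.ends_min]))
        self.t = grid
        self.dt = np.diff(grid)
        ca = np.interp(grid, knots_t, knots_v)
        self.ca = ca
        self.a = ca[:-1]                      # segment-start value
        self.b = np.diff(ca) / self.dt        # segment slope

        # map segments -> frames (segment j covers [t_j, t_{j+1}]; -1 = outside)
        seg_mid = grid[:-1] + 0.5 * self.dt
        frame_idx = np.searchsorted(schedule.starts_min, seg_mid, side="right") - 1
        inside = (frame_idx >= 0) & (seg_mid <= schedule.ends_min[np.clip(frame_idx, 0, None)])
        self._seg_frame = np.where(inside, frame_idx, -1).astype(np.int64)
        self.durations_min = schedule.durations_s / 60.0
        self._mid_pos = np.searchsorted(grid, mids)

    # -- exponential convolution machinery ---------------------------------

    def _conv_nodes_and_g(self, rate: float):
        """Node values of y(t) = int_0^t C_a(s) e^{-rate (t-s)} ds and the
        per-segment increments/phi factors needed for frame integrals."""
        if rate < 0:
            raise ValueError("rate must be >= 0")
        x = rate * self.dt
        p1, p2, p3 = _phis(x)
        g = self.dt * (self.a * p1 + self.b * self.dt * p2)
        t = self.t
        span = rate * (t[-1] - t[0])
        if span < _MAX_EXPONENT:
            w = np.exp(rate * t[1:])
            y = np.empty_like(t)
            y[0] = 0.0
            y[1:] = np.cumsum(g * w) / w
        else:  # very fast kernels: O(M) scalar recurrence avoids overflow
            y = np.empty_like(t)
            y[0] = 0.0
            decay = np.exp(-x)
            for j in range(self.dt.size):
                y[j + 1] = y[j] * decay[j] + g[j]
        return y, p1, p2, p3

    def conv_exp_frames_multi(self, rates: np.ndarray) -> np.ndarray:
        """Frame-averaged exponential convolutions for a vector of rates (exact)."""
        rates = np.asarray(rates, dtype=float)
        if np.any(rates < 0):
            raise ValueError("rate must be >= 0")
        return _conv_frames_kernel(self.dt, self.a, self.b, self._seg_frame,
                                   self.durations_min, rates)

    def conv_exp_frames(self, rate: float) -> np.ndarray:
        """Frame-averaged exponential convolution of C_a (exact)."""
        return self.conv_exp_frames_multi(np.array([float(rate)]))[0]

    def conv_exp_midpoints(self, rate: float) -> np.ndarray:
        y, *_ = self._conv_nodes_and_g(rate)
        return y[self._mid_pos]

    def _conv(self, rate: float) -> np.ndarray:
        if self.frame_averaged:
            return self.conv_exp_frames(rate)
        return self.conv_exp_midpoints(rate)

    # -- model curves -------------------------------------------------------

    def _mix(self, ct: np.ndarray, vb: float) -> np.ndarray:
        # measured AIF frames are already frame-integrated data: mix values directly
        return (1.0 - vb) * ct + vb * self.input_fn.values

    def curve_1tcm(self, K1: float, k2: float, VB: float = 0.0) -> np.ndarray:
        return self._mix(K1 * self._conv(k2), VB)

    def curve_2tcm(self, K1: float, k2: float, k3: float, k4: float,
                   VB: float = 0.0) -> np.ndarray:
        theta = k2 + k3 + k4
        disc = theta * theta - 4.0 * k2 * k4
        if disc < 0.0:  # cannot happen for non-negative rates; numerical guard
            disc = 0.0
        root = np.sqrt(disc)
        a1 = 0.5 * (theta - root)
        a2 = 0.5 * (theta + root)
        if a2 - a1 < _DEGENERATE_GAP:
            # confluent limit: kernel e^{-at} + (k3+k4-a) t e^{-at}; the
            # t-weighted convolution is -d/da of the exponential one,
            # evaluated by a symmetric difference well outside the gap
            a = 0.5 * (a1 + a2)
            h = 1e-5
            lo = max(a - h, 0.0)
            f_lo = self._conv(lo)
            f_hi = self._conv(a + h)
            f_mid = self._conv(a)
            conv_t = (f_lo - f_hi) / (a + h - lo)
            ct = K1 * (f_mid + (k3 + k4 - a) * conv_t)
        elif self.frame_averaged:
            c1 = (k3 + k4 - a1) / (a2 - a1)
            c2 = (a2 - k3 - k4) / (a2 - a1)
            f = self.conv_exp_frames_multi(np.array([a1, a2]))
            ct = K1 * (c1 * f[0] + c2 * f[1])
        else:
            c1 = (k3 + k4 - a1) / (a2 - a1)
            c2 = (a2 - k3 - k4) / (a2 - a1)
            ct = K1 * (c1 * self._conv(a1) + c2 * self._conv(a2))
        return self._mix(ct, VB)

    # -- batched evaluation (vectorized over parameter vectors) -------------

    def curve_batch(self, model: str, X: np.ndarray) -> np.ndarray:
        """Model curves for a (B, p) block of parameter vectors -> (B, n).

        The hot path of the simulation study and voxelwise fitting.  Rows
        with (numerically) coincident 2TCM eigenrates are regularized by
        nudging the fast eigenrate a tiny step apart, which is continuous to
        ~1e-6 relative — negligible against acquisition noise.  Requires the
        frame-averaged convention.
        """
        if not self.frame_averaged:
            raise ValueError("curve_batch requires frame_averaged=True")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        B = X.shape[0]
        ca = self.input_fn.values
        if model == "2TCM":
            K1, k2, k3, k4, VB = (X[:, i] for i in range(5))
            theta = k2 + k3 + k4
            disc = np.clip(theta * theta - 4.0 * k2 * k4, 0.0, None)
            root = np.sqrt(disc)
            a1 = 0.5 * (theta - root)
            a2 = np.maximum(0.5 * (theta + root), a1 + _DEGENERATE_GAP)
            f = self.conv_exp_frames_multi(np.concatenate([a1, a2]))
            f1, f2 = f[:B], f[B:]
            s = k3 + k4
            c1 = ((s - a1) / (a2 - a1))[:, None]
            c2 = ((a2 - s) / (a2 - a1))[:, None]
            ct = K1[:, None] * (c1 * f1 + c2 * f2)
        elif model in ("1TCM", "s1TCM"):
            K1, k2 = X[:, 0], X[:, 1]
            VB = X[:, 2] if model == "1TCM" else np.zeros(B)
            ct = K1[:, None] * self.conv_exp_frames_multi(k2)
        else:
            raise ValueError(f"unknown model {model!r}")
        return (1.0 - VB)[:, None] * ct + VB[:, None] * ca[None, :]

    def curve(self, params: KineticParams) -> np.ndarray:
        if params.model == "2TCM":
            return self.curve_2tcm(params.K1, params.k2, params.k3, params.k4, params.VB)
        return self.curve_1tcm(params.K1, params.k2, params.VB)

    def curve_from_array(self, model: str, x: np.ndarray) -> np.ndarray:
        """Unchecked fast path used by the fitter (x in the model's free order)."""
        if model == "2TCM":
            return self.curve_2tcm(x[0], x[1], x[2], x[3], x[4])
        if model == "1TCM":
            return self.curve_1tcm(x[0], x[1], x[2])
        return self.curve_1tcm(x[0], x[1], 0.0)


# ---------------------------------------------------------------------------
# public operations


def convolve_monoexp(input_fn: InputFunction, rate: float,
                     eval_grid: np.ndarray) -> np.ndarray:
    """Exact exponential convolution of the piecewise-linear C_a.

    Returns ``int_0^t C_a(s) exp(-rate (t - s)) ds`` at each time of
    ``eval_grid`` (minutes).  ``rate = 0`` yields the running integral of
    C_a.  Exact for the piecewise-linear input representation.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    eval_grid = np.atleast_1d(np.asarray(eval_grid, dtype=float))
    t_end = input_fn.schedule.ends_min[-1]
    if np.any(eval_grid < 0) or np.any(eval_grid > t_end + 1e-12):
        raise ValueError("eval_grid outside the input function support")

    # reuse the model context on a grid extended with the evaluation points
    ctx = TACModel(input_fn, input_fn.schedule)
    grid = np.unique(np.concatenate([ctx.t, eval_grid]))
    sub = _Sub(grid, np.interp(grid, ctx.t, ctx.ca))
    y = sub.conv_nodes(rate)
    return y[np.searchsorted(grid, eval_grid)]


class _Sub:
    """Minimal piecewise-linear convolution on an explicit grid."""

    def __init__(self, t: np.ndarray, ca: np.ndarray):
        self.t = t
        self.dt = np.diff(t)
        self.a = ca[:-1]
        self.b = np.diff(ca) / self.dt

    def conv_nodes(self, rate: float) -> np.ndarray:
        x = rate * self.dt
        p1, p2, _ = _phis(x)
        g = self.dt * (self.a * p1 + self.b * self.dt * p2)
        y = np.empty_like(self.t)
        y[0] = 0.0
        if rate * (self.t[-1] - self.t[0]) < _MAX_EXPONENT:
            w = np.exp(rate * self.t[1:])
            y[1:] = np.cumsum(g * w) / w
        else:
            decay = np.exp(-x)
            for j in range(self.dt.size):
                y[j + 1] = y[j] * decay[j] + g[j]
        return y


def solve_1tcm(params: KineticParams, input_fn: InputFunction,
               schedule: FrameSchedule, frame_averaged: bool = True) -> TissueCurve:
    """One-tissue compartment model curve (s1TCM when VB = 0)."""
    if params.model not in ("s1TCM", "1TCM"):
        raise ValueError("solve_1tcm expects an s1TCM or 1TCM parameter set")
    ctx = TACModel(input_fn, schedule, frame_averaged=frame_averaged)
    return TissueCurve(schedule, ctx.curve_1tcm(params.K1, params.k2, params.VB))


def solve_2tcm(params: KineticParams, input_fn: InputFunction,
               schedule: FrameSchedule, frame_averaged: bool = True) -> TissueCurve:
    """Two-tissue compartment model curve (bi-exponential analytic solution)."""
    if params.model != "2TCM":
        raise ValueError("solve_2tcm expects a 2TCM parameter set")
    ctx = TACModel(input_fn, schedule, frame_averaged=frame_averaged)
    return TissueCurve(
        schedule, ctx.curve_2tcm(params.K1, params.k2, params.k3, params.k4, params.VB)
    )


def frame_average(curve, schedule: FrameSchedule, n_nodes: int = 32) -> np.ndarray:
    """Per-frame time average of a continuous curve.

    ``curve`` is either a callable ``f(t_minutes) -> activity`` (integrated
    with ``n_nodes``-point Gauss-Legendre per frame) or a ``(t_minutes,
    values)`` pair treated as piecewise-linear (integrated exactly).
    """
    starts, ends = schedule.starts_min, schedule.ends_min
    if callable(curve):
        nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
        mid = 0.5 * (starts + ends)
        half = 0.5 * (ends - starts)
        tt = mid[:, None] + half[:, None] * nodes[None, :]
        vals = np.asarray(curve(tt.ravel()), dtype=float).reshape(tt.shape)
        return (vals * weights[None, :]).sum(axis=1) * 0.5
    t, v = (np.asarray(a, dtype=float) for a in curve)
    if starts[0] < t[0] - 1e-12 or ends[-1] > t[-1] + 1e-12:
        raise ValueError("frame outside curve support")
    out = np.empty(schedule.n)
    for i, (s, e) in enumerate(zip(starts, ends)):
        grid = np.unique(np.concatenate([[s], t[(t > s) & (t < e)], [e]]))
        vv = np.interp(grid, t, v)
        out[i] = np.trapezoid(vv, grid) / (e - s)
    return out
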