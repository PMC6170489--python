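"""Shared fixtures and independent oracles.

The ODE oracle integrates the compartment mass-balance equations directly
with an adaptive stiff solver against the same piecewise-linear arterial
input the analytic solvers use, frame-averaging via an auxiliary cumulative
integral — an independent path to the same quantity.
"""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import fetkin as fk


@pytest.fixture(scope="session")
def schedule():
    return fk.clinical_schedule()


@pytest.fixture(scope="session")
def aif_I(schedule):
    return fk.make_aif("I", peak=100.0, schedule=schedule)


@pytest.fixture(scope="session")
def aif_II(schedule):
    return fk.make_aif("II", peak=100.0, schedule=schedule)


def aif_interpolant(input_fn):
    """The piecewise-linear C_a(t) the solvers assume (t in minutes)."""
    sched = input_fn.schedule
    mids = sched.midpoints_min
    t = np.concatenate([[0.0], mids, [sched.ends_min[-1]]])
    v = np.concatenate([[input_fn.values[0]], input_fn.values, [input_fn.values[-1]]])
    return lambda tt: np.interp(tt, t, v)


def ode_oracle_frames(params, input_fn, schedule, rtol=1e-10):
    """Frame-averaged C_T from direct numerical integration of the model ODEs.

    Blood-volume mixing uses the AIF's frame values, the same convention as
    the analytic solvers (measured AIF frames are frame-integrated data).
    """
    ca = aif_interpolant(input_fn)
    K1, k2, k3, k4 = params.K1, params.k2, params.k3, params.k4

    if params.model == "2TCM":
        def rhs(t, y):
            c1, c2, _ = y
            return [K1 * ca(t) - (k2 + k3) * c1 + k4 * c2,
                    k3 * c1 - k4 * c2,
                    c1 + c2]
    else:
        def rhs(t, y):
            c1, _, _ = y
            return [K1 * ca(t) - k2 * c1, 0.0, c1]

    t_eval = np.unique(np.concatenate([schedule.starts_min, schedule.ends_min]))
    sol = solve_ivp(rhs, (0.0, schedule.ends_min[-1]), [0.0, 0.0, 0.0],
                    t_eval=t_eval, rtol=rtol, atol=1e-13, max_step=0.05,
                    method="LSODA")
    cum = dict(zip(sol.t, sol.y[2]))
    I_start = np.array([cum[t] for t in schedule.starts_min])
    I_end = np.array([cum[t] for t in schedule.ends_min])
    ct = (I_end - I_start) / (schedule.durations_s / 60.0)
    return (1.0 - params.VB) * ct + params.VB * input_fn.values
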