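"""Analytic forward simulation of the one-tissue compartment model.

Between any two consecutive breakpoints (input samples or frame edges) the
input C_a is linear, so the tissue concentration

    dC_t/dt = K1 * C_a(t) - k2 * C_t(t)

admits a closed-form solution and a closed-form time integral.  Frame
values are exact time averages of C_PET = (1 - vb) * C_t + vb * C_a over
each frame interval — no quadrature error.
"""

from __future__ import annotations

import numpy as np

from .types import FrameSchedule, InputFunction, PKParameters, TimeActivityCurve


def _segment_step(C0: float, a: float, b: float, h: float, K1: float, k2: float):
    """Propagate C_t across one segment of length h where C_a(s) = a + b*s.

    Returns (C_t at segment end, integral of C_t over the segment,
    integral of C_a over the segment).
    """
    int_ca = a * h + 0.5 * b * h * h
    if k2 > 0.0:
        # particular solution C_p(s) = K1*(a + b*s)/k2 - K1*b/k2^2
        cp0 = K1 * a / k2 - K1 * b / (k2 * k2)
        cph = K1 * (a + b * h) / k2 - K1 * b / (k2 * k2)
        # expm1 keeps accuracy for small k2*h
        em = -np.expm1(-k2 * h)            # 1 - exp(-k2 h)
        amp = C0 - cp0
        Ch = cph + amp * (1.0 - em)
        int_cp = K1 / k2 * int_ca - K1 * b * h / (k2 * k2)
        int_ct = int_cp + amp * em / k2
    else:
        # pure accumulation: C_t(s) = C0 + K1*(a s + b s^2/2)
        Ch = C0 + K1 * int_ca
        int_ct = C0 * h + K1 * (0.5 * a * h * h + b * h * h * h / 6.0)
    return Ch, int_ct, int_ca


def solve_tissue_curve(params: PKParameters, input_fn: InputFunction,
                       breakpoints: np.ndarray):
    """Integrate the tissue ODE exactly across the given breakpoints.

    Parameters must define a piecewise-linear input over each interval
    (breakpoints must include every input sample time in range).

    Returns (C_t at each breakpoint, per-interval integrals of C_t,
    per-interval integrals of C_a).
    """
    t = np.asarray(breakpoints, dtype=float)
    ca = input_fn(t)
    n = t.size
    ct = np.zeros(n)
    int_ct = np.zeros(n - 1)
    int_ca = np.zeros(n - 1)
    for i in range(n - 1):
        h = t[i + 1] - t[i]
        if h <= 0:
            continue
        a = ca[i]
        b = (ca[i + 1] - ca[i]) / h
        ct[i + 1], int_ct[i], int_ca[i] = _segment_step(
            ct[i], a, b, h, params.K1, params.k2
        )
    return ct, int_ct, int_ca


def _merged_breakpoints(schedule: FrameSchedule, input_fn: InputFunction) -> np.ndarray:
    t_end = float(schedule.end_times[-1])
    pts = np.concatenate([
        [0.0],
        schedule.start_times,
        schedule.end_times,
        input_fn.sample_times[input_fn.sample_times <= t_end],
    ])
    return np.unique(pts)


def simulate_tac(params: PKParameters, input_fn: InputFunction,
                 schedule: FrameSchedule, label: str = "model") -> TimeActivityCurve:
    """Simulate the frame-averaged PET signal for one-tissue kinetics.

    C_PET(t) = (1 - vb) * C_t(t) + vb * C_a(t); each frame value is the
    exact time average of C_PET over the frame interval.
    """
    if schedule.n_frames == 0:
        raise ValueError("empty frame schedule")
    bp = _merged_breakpoints(schedule, input_fn)
    _, int_ct, int_ca = solve_tissue_curve(params, input_fn, bp)
    cum_ct = np.concatenate([[0.0], np.cumsum(int_ct)])
    cum_ca = np.concatenate([[0.0], np.cumsum(int_ca)])
    i0 = np.searchsorted(bp, schedule.start_times)
    i1 = np.searchsorted(bp, schedule.end_times)
    dur = schedule.durations
    mean_ct = (cum_ct[i1] - cum_ct[i0]) / dur
    mean_ca = (cum_ca[i1] - cum_ca[i0]) / dur
    activity = (1.0 - params.vb) * mean_ct + params.vb * mean_ca
    return TimeActivityCurve(schedule, activity, label=label)


def frame_average_input(input_fn: InputFunction,
                        schedule: FrameSchedule) -> np.ndarray:
    """Exact frame-averaged input function values (blood-only signal)."""
    zero = PKParameters(K1=0.0, k2=0.0, vb=1.0)
    return simulate_tac(zero, input_fn, schedule).activity
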