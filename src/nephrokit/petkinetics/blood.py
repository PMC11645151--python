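"""Blood-input preparation: calibration and metabolite correction.

The image-derived blood curve (descending-aorta ROI) is scaled to a venous
calibration sample and corrected for labelled metabolites to yield the
parent-tracer arterial input function.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .types import CalibrationSample, InputFunction, TimeActivityCurve


def _tac_interpolator(tac: TimeActivityCurve) -> Callable[[np.ndarray], np.ndarray]:
    """Piecewise-linear evaluation of a frame TAC at its frame mid-times."""
    mids = tac.schedule.mid_times
    vals = tac.activity

    def evaluate(t):
        return np.interp(np.asarray(t, dtype=float), mids, vals)

    return evaluate


def calibrate_input(blood_tac: TimeActivityCurve,
                    sample: CalibrationSample) -> TimeActivityCurve:
    """Scale the image-derived blood curve to a venous blood sample.

    The scale is sample activity divided by the piecewise-linear value of
    the image curve at the sample time; it is recorded on the returned
    curve as ``calibration_scale``.
    """
    t0 = float(blood_tac.schedule.start_times[0])
    t1 = float(blood_tac.schedule.end_times[-1])
    if not t0 <= sample.time <= t1:
        raise ValueError(
            f"calibration sample time {sample.time} min outside scan window "
            f"[{t0}, {t1}]"
        )
    image_value = float(_tac_interpolator(blood_tac)(sample.time))
    if image_value <= 0:
        raise ValueError(
            "cannot calibrate: image-derived blood activity at sample time "
            f"{sample.time} min is {image_value} <= 0"
        )
    scale = sample.activity / image_value
    out = blood_tac.scaled(scale)
    out.calibration_scale = scale  # provenance
    return out


def metabolite_correct(blood_tac: TimeActivityCurve,
                       parent_fraction: Callable[[np.ndarray], np.ndarray] | float = 1.0
                       ) -> InputFunction:
    """Apply a parent-fraction curve to the whole-blood curve.

    ``parent_fraction`` is a callable of time (minutes) returning fractions
    in [0, 1], or a constant; the default 1.0 is the neutral identity (no
    metabolite model).  The product is evaluated at frame mid-times and
    stored as the input-function sample points.
    """
    mids = blood_tac.schedule.mid_times
    if callable(parent_fraction):
        frac = np.asarray(parent_fraction(mids), dtype=float)
    else:
        frac = np.full(mids.shape, float(parent_fraction))
    if np.any(frac < 0) or np.any(frac > 1):
        raise ValueError("parent fraction must lie in [0, 1] everywhere")
    return InputFunction(mids, blood_tac.activity * frac)
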