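"""Hyperinsulinemic-euglycemic clamp quantification.

The M-value is the steady-state glucose infusion rate (GIR) during the
high-dose insulin stage, an index of whole-body insulin sensitivity;
NEFA suppression during the low-dose stage indexes adipose insulin
sensitivity.  Steady state defaults to the final 30 minutes of a stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_STEADY_MINUTES = 30.0


@dataclass
class ClampRecord:
    """One participant's clamp stage.

    stage : insulin infusion rate, 8 or 40 mU/m^2/min.
    gir_times / gir_values : GIR samples (min, mg/kg/min).
    steady_window : (start, end) minutes; default = final 30 min.
    """

    stage: float
    gir_times: np.ndarray
    gir_values: np.ndarray
    weight_kg: float
    lean_mass_kg: float
    glucose_series: np.ndarray | None = None
    insulin_steady: float | None = None
    nefa_baseline: float | None = None
    nefa_steady: float | None = None
    steady_window: tuple[float, float] | None = None

    def __post_init__(self):
        self.gir_times = np.asarray(self.gir_times, dtype=float)
        self.gir_values = np.asarray(self.gir_values, dtype=float)
        if self.gir_times.shape != self.gir_values.shape:
            raise ValueError("GIR times and values must align")
        if self.weight_kg <= 0 or self.lean_mass_kg <= 0:
            raise ValueError("weight and lean mass must be positive")
        if self.steady_window is None:
            t_end = float(self.gir_times[-1])
            self.steady_window = (t_end - DEFAULT_STEADY_MINUTES, t_end)


def m_value(record: ClampRecord, normalization: str = "total") -> float:
    """Steady-state GIR (mg/kg/min), total- or lean-mass normalized.

    The mean GIR over the steady window; ``normalization='lean'``
    rescales by weight / lean mass to mg/lean kg/min.
    """
    w0, w1 = record.steady_window
    in_window = (record.gir_times >= w0) & (record.gir_times <= w1)
    if in_window.sum() < 3:
        raise ValueError("need at least 3 GIR samples inside the steady window")
    m = float(record.gir_values[in_window].mean())
    if normalization == "total":
        return m
    if normalization == "lean":
        return m * record.weight_kg / record.lean_mass_kg
    raise ValueError(f"unknown normalization {normalization!r}")


def nefa_suppression(baseline_uM: float, steady_uM: float) -> float:
    """Percent suppression of NEFA under insulin: 100*(base - steady)/base.

    Negative values (a rise under insulin) are allowed.
    """
    if baseline_uM <= 0:
        raise ValueError("baseline NEFA must be > 0")
    return 100.0 * (baseline_uM - steady_uM) / baseline_uM


def muscle_mass(appendicular_lean_kg: float, multiplier: float = 1.13,
                offset: float = -0.63) -> float:
    """Muscle mass (kg) from DXA appendicular lean mass (arms + legs).

    Linear form multiplier * ALM + offset; the offset default is -0.63 kg
    and the multiplier is configuration (the published equation family
    this follows is not fully pinned down, so the coefficients are always
    explicit in reports).
    """
    if appendicular_lean_kg <= 0:
        raise ValueError("appendicular lean mass must be positive")
    return multiplier * appendicular_lean_kg + offset
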