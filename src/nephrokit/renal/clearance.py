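"""Urinary clearance of iohexol (GFR) and PAH (RPF) from timed collections.

Per collection period U_x: urine flow = urine volume / collection time;
clearance = urine concentration x flow / mean plasma concentration, where
the mean plasma concentration is (P1 + P2)/2 over the period.  PAH
clearance is converted to renal plasma flow by dividing by the PAH
extraction ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np


@dataclass(frozen=True)
class ClearancePeriod:
    """One timed urine collection with bracketing plasma samples.

    urine_volume in mL, duration in minutes, urine_conc and the plasma
    concentrations P1 (start) / P2 (end) in ug/mL of the same marker.
    """

    urine_volume: float
    duration: float
    urine_conc: float
    plasma_start: float
    plasma_end: float

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("collection duration must be > 0")
        for name in ("urine_volume", "urine_conc", "plasma_start", "plasma_end"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.plasma_start + self.plasma_end <= 0:
            raise ValueError("mean plasma concentration must be > 0")


def period_clearance(period: ClearancePeriod) -> tuple[float, float]:
    """Urine flow (mL/min) and marker clearance (mL/min) for one period."""
    flow = period.urine_volume / period.duration
    mean_plasma = 0.5 * (period.plasma_start + period.plasma_end)
    clearance = period.urine_conc * flow / mean_plasma
    return flow, clearance


def aggregate_clearance(periods: Sequence[ClearancePeriod],
                        outlier_fraction: float = 0.30):
    """Mean clearance across collection periods.

    Returns (mean clearance, per-period clearances, outlier flags); a
    period is flagged (not excluded) when its clearance deviates from the
    median of all periods by more than ``outlier_fraction``.
    """
    if len(periods) == 0:
        raise ValueError("at least one clearance period is required")
    values = np.array([period_clearance(p)[1] for p in periods])
    med = float(np.median(values))
    if med > 0:
        flags = np.abs(values - med) / med > outlier_fraction
    else:
        flags = np.zeros(values.size, dtype=bool)
    return float(values.mean()), values, flags


def rpf_from_pah(pah_clearance: float, gfr: float | None = None,
                 pah_extraction: float | Callable[[float], float] = 0.85) -> float:
    """Renal plasma flow from PAH clearance.

    RPF = PAH clearance / e_PAH.  ``pah_extraction`` is either a constant
    (default 0.85) or a callable of GFR implementing a GFR-dependent
    extraction adjustment.
    """
    if pah_clearance < 0:
        raise ValueError("PAH clearance must be >= 0")
    if callable(pah_extraction):
        if gfr is None:
            raise ValueError("GFR is required for a GFR-dependent extraction")
        e = float(pah_extraction(gfr))
    else:
        e = float(pah_extraction)
    if not 0.0 < e <= 1.0:
        raise ValueError(f"PAH extraction ratio {e} outside (0, 1]")
    return pah_clearance / e


def albumin_excretion(urine_albumin_mg_L: float, urine_volume_mL: float,
                      duration_h: float,
                      urine_creatinine_mg_dL: float | None = None):
    """24-hour albumin excretion rate and albumin-to-creatinine ratio.

    AER (mg/24 h) scales the collected amount to a 24-hour equivalent.
    UACR (mg/g) = urine albumin / urine creatinine; requires creatinine.
    Returns (AER, UACR) with UACR None when creatinine is not supplied.
    """
    if duration_h <= 0:
        raise ValueError("collection duration must be > 0")
    amount_mg = urine_albumin_mg_L * urine_volume_mL / 1000.0
    aer = amount_mg * 24.0 / duration_h
    uacr = None
    if urine_creatinine_mg_dL is not None:
        if urine_creatinine_mg_dL <= 0:
            raise ValueError("urine creatinine must be > 0 for UACR")
        # mg/L albumin over mg/dL creatinine -> mg/g: (alb/10) / (cr/100) g
        albumin_mg_dL = urine_albumin_mg_L / 10.0
        uacr = albumin_mg_dL / urine_creatinine_mg_dL * 1000.0
    return aer, uacr
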