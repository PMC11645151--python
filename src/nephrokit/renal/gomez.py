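"""Intraglomerular hemodynamics from the Gomez framework.

From measured GFR, RPF, mean arterial pressure, hematocrit, and total
plasma protein, the framework estimates intraglomerular pressure and the
afferent/efferent arteriolar resistances under its classical assumptions:
a fixed Bowman's-space pressure, a fixed gross filtration coefficient
K_FG, and filtration-equilibrium plasma protein handling.

    FF      = GFR / RPF
    RBF     = RPF / (1 - Hct)
    dP_F    = GFR[mL/s] / K_FG                      (filtration pressure)
    C_M     = (TP / FF) * ln(1 / (1 - FF))          (glomerular protein)
    pi_G    = 5 * (C_M - 2)                         (oncotic pressure)
    P_GLO   = dP_F + P_Bow + pi_G
    R_A     = ((MAP - P_GLO) / RBF[mL/s]) * 1328
    R_E     = (GFR / (K_FG * (RBF - GFR))) * 1328   (flows in mL/s)
    RVR     = MAP / RBF[mL/min]

Resistances are reported in dyne*s*cm^-5 via the conventional conversion
factor 1328 from mmHg*s/mL.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass(frozen=True)
class GomezConstants:
    """Constants of the Gomez framework (all configurable).

    P_Bow : Bowman's space hydrostatic pressure, mmHg.
    K_FG : gross filtration coefficient, mL/s/mmHg.
    resistance_conversion : mmHg*s/mL -> dyne*s*cm^-5.
    pah_extraction : default PAH extraction ratio.
    """

    P_Bow: float = 10.0
    K_FG: float = 0.1012
    resistance_conversion: float = 1328.0
    pah_extraction: float = 0.85

    def __post_init__(self):
        for name in ("P_Bow", "K_FG", "resistance_conversion", "pah_extraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class HemodynamicProfile:
    """Full renal hemodynamic profile with intermediates exposed.

    GFR, RPF, RBF in mL/min; pressures in mmHg; C_M in g/dL;
    R_A, R_E in dyne*s*cm^-5; RVR in mmHg*min/mL.
    """

    GFR: float
    RPF: float
    FF: float
    RBF: float
    delta_P_F: float
    C_M: float
    pi_G: float
    P_GLO: float
    R_A: float
    R_E: float
    RVR: float

    def as_dict(self) -> dict:
        return asdict(self)

    def summary(self) -> str:
        d = self.as_dict()
        units = {
            "GFR": "mL/min", "RPF": "mL/min", "FF": "", "RBF": "mL/min",
            "delta_P_F": "mmHg", "C_M": "g/dL", "pi_G": "mmHg",
            "P_GLO": "mmHg", "R_A": "dyn*s/cm^5", "R_E": "dyn*s/cm^5",
            "RVR": "mmHg*min/mL",
        }
        lines = ["Gomez hemodynamic profile", "========================="]
        for k, v in d.items():
            lines.append(f"  {k:10s}: {v:10.4f} {units[k]}")
        return "\n".join(lines)


def gomez_profile(gfr: float, rpf: float, map_pressure: float, hct: float,
                  total_protein: float,
                  constants: GomezConstants = GomezConstants()) -> HemodynamicProfile:
    """Evaluate the Gomez equations for one participant.

    Parameters are GFR and RPF in mL/min, mean arterial pressure in mmHg,
    hematocrit as a fraction, and total plasma protein in g/dL.  Raises
    on physically impossible configurations (FF >= 1, RBF <= GFR,
    MAP <= P_GLO).
    """
    import math

    if gfr < 0 or rpf <= 0:
        raise ValueError("GFR must be >= 0 and RPF > 0")
    if not 0.0 < hct < 1.0:
        raise ValueError("hematocrit must lie in (0, 1)")
    ff = gfr / rpf
    if not 0.0 < ff < 1.0:
        raise ValueError(f"filtration fraction {ff:.3f} outside (0, 1): "
                         "GFR must be positive and below RPF")
    rbf = rpf / (1.0 - hct)
    if rbf <= gfr:
        raise ValueError("renal blood flow must exceed GFR")
    gfr_s = gfr / 60.0
    rbf_s = rbf / 60.0
    dpf = gfr_s / constants.K_FG
    cm = (total_protein / ff) * math.log(1.0 / (1.0 - ff))
    pi_g = 5.0 * (cm - 2.0)
    p_glo = dpf + constants.P_Bow + pi_g
    if map_pressure <= p_glo:
        raise ValueError(
            f"mean arterial pressure {map_pressure} mmHg does not exceed "
            f"glomerular pressure {p_glo:.1f} mmHg: afferent resistance "
            "undefined"
        )
    r_a = ((map_pressure - p_glo) / rbf_s) * constants.resistance_conversion
    r_e = (gfr_s / (constants.K_FG * (rbf_s - gfr_s))) \
        * constants.resistance_conversion
    rvr = compute_rvr(map_pressure, rbf)
    return HemodynamicProfile(gfr, rpf, ff, rbf, dpf, cm, pi_g, p_glo,
                              r_a, r_e, rvr)


def compute_rvr(map_pressure: float, rbf: float) -> float:
    """Renal vascular resistance: MAP / RBF (mmHg*min/mL), RBF in mL/min."""
    if rbf <= 0:
        raise ValueError("renal blood flow must be > 0")
    return map_pressure / rbf
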