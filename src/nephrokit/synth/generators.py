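"""Ground-truth synthetic data generators.

Every generator is deterministic given (configuration, seed) and returns
a ``SyntheticTruth`` recording the generative parameters, so each
estimation stage can be validated by parameter recovery without any
external data.

Noise models: multiplicative Gaussian (CV-parameterized) for PET frames
and MRI signals, matching the roughly signal-proportional error of
reconstructed images; additive Gaussian for tabular series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..petkinetics import (
    DEFAULT_FRAME_SCHEDULE,
    DynamicPETImage,
    FrameSchedule,
    InputFunction,
    LabelMask,
    PKParameters,
    simulate_tac,
)
from ..petkinetics.simulate import frame_average_input
from ..mri import DWISeries, EchoSeries, DEFAULT_B_VALUES
from ..renal import ClearancePeriod


@dataclass(frozen=True)
class SyntheticTruth:
    """Generative record: seed, true parameters, and the noise model."""

    seed: int | None
    parameters: dict = field(default_factory=dict)
    noise_model: str = "none"


# ---------------------------------------------------------------- AIF --

def gen_aif(peak_time: float = 0.5, amplitude: float = 300.0,
            alpha: float = 2.0, duration: float = 30.0,
            sampling_s: float = 1.0, seed: int | None = None
            ) -> tuple[InputFunction, SyntheticTruth]:
    """Gamma-variate arterial input: C_a(t) = A * t^alpha * exp(-t/beta).

    ``peak_time`` (minutes) locates the maximum (= alpha*beta); the curve
    is scaled so the peak equals ``amplitude`` kBq/mL, sampled every
    ``sampling_s`` seconds for ``duration`` minutes, zero at t = 0.  The
    family is deterministic; ``seed`` is recorded for provenance only.
    """
    if peak_time <= 0 or amplitude < 0 or alpha <= 0 or duration <= 0:
        raise ValueError("AIF shape parameters must be positive")
    beta = peak_time / alpha
    t = np.arange(0.0, duration + 1e-9, sampling_s / 60.0)
    with np.errstate(divide="ignore"):
        raw = np.where(t > 0, t ** alpha * np.exp(-t / beta), 0.0)
    peak = raw.max()
    values = amplitude * raw / peak if peak > 0 else raw
    truth = SyntheticTruth(seed, {
        "family": "gamma-variate", "peak_time_min": peak_time,
        "amplitude_kBq_mL": amplitude, "alpha": alpha, "beta": beta,
    })
    return InputFunction(t, values), truth


# ------------------------------------------------------------ phantom --

DEFAULT_REGION_PARAMS = {
    # HC-like cortex/medulla kinetics; aorta carries the blood curve
    "cortex": PKParameters(K1=0.20, k2=0.18, vb=0.10),
    "medulla": PKParameters(K1=0.10, k2=0.18, vb=0.05),
}

_REGION_LABELS = {"background": 0, "cortex": 1, "medulla": 2, "aorta": 3}


def default_phantom_geometry(shape=(8, 8, 4)) -> np.ndarray:
    """Simple block geometry: cortex shell, medulla core, aorta column."""
    labels = np.zeros(shape, dtype=np.int32)
    x = shape[0]
    labels[1:x - 2, 1:-1, :] = _REGION_LABELS["cortex"]
    labels[2:x - 3, 2:-2, 1:-1] = _REGION_LABELS["medulla"]
    labels[x - 1:x, 3:5, :] = _REGION_LABELS["aorta"]
    return labels


def gen_dynamic_phantom(geometry: np.ndarray | None = None,
                        region_params: dict | None = None,
                        aif: InputFunction | None = None,
                        noise_cv: float = 0.0,
                        schedule: FrameSchedule = DEFAULT_FRAME_SCHEDULE,
                        seed: int | None = None):
    """Dynamic PET phantom with known per-region kinetics.

    Each labelled voxel carries the exact frame-averaged model curve of
    its region (aorta voxels carry the frame-averaged blood curve), with
    optional multiplicative Gaussian noise of coefficient of variation
    ``noise_cv``.  Returns (image, mask, truth).
    """
    if geometry is None:
        geometry = default_phantom_geometry()
    if region_params is None:
        region_params = dict(DEFAULT_REGION_PARAMS)
    if aif is None:
        aif, _ = gen_aif()
    unknown = set(region_params) - (set(_REGION_LABELS) - {"background", "aorta"})
    if unknown:
        raise ValueError(f"unknown region labels: {sorted(unknown)}")
    if noise_cv > 0 and seed is None:
        raise ValueError("noisy generation requires an explicit seed")

    legend = {v: k for k, v in _REGION_LABELS.items() if v != 0}
    mask = LabelMask(geometry, legend)
    n_frames = schedule.n_frames
    image = np.zeros(geometry.shape + (n_frames,))
    blood = frame_average_input(aif, schedule)
    for name, params in region_params.items():
        curve = simulate_tac(params, aif, schedule).activity
        image[geometry == _REGION_LABELS[name]] = curve
    image[geometry == _REGION_LABELS["aorta"]] = blood
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        image = image * (1.0 + noise_cv * rng.standard_normal(image.shape))
    truth = SyntheticTruth(seed, {
        "region_params": {k: {"K1": p.K1, "k2": p.k2, "vb": p.vb}
                          for k, p in region_params.items()},
        "noise_cv": noise_cv,
    }, noise_model=f"multiplicative gaussian cv={noise_cv}")
    return DynamicPETImage(image, schedule), mask, truth


# ---------------------------------------------------------------- MRI --

def gen_mri_signals(r2star_pre: float = 30.0, fsoc: float = 5.0,
                    adc: float = 1.5e-3, s0: float = 100.0,
                    te_list=(0.005, 0.010, 0.020, 0.040),
                    b_list=DEFAULT_B_VALUES,
                    noise_cv: float = 0.0, seed: int | None = None):
    """Paired pre/post-furosemide echo series and a DWI series.

    R2*_post = R2*_pre - fsoc, so the FSOC truth is recovered by
    subtracting the two fitted rates.  Returns (echo_pre, echo_post,
    dwi, truth).
    """
    if r2star_pre <= 0 or adc <= 0 or s0 <= 0:
        raise ValueError("truth parameters must be positive")
    if noise_cv > 0 and seed is None:
        raise ValueError("noisy generation requires an explicit seed")
    rng = np.random.default_rng(seed)
    te = np.asarray(te_list, dtype=float)
    b = np.asarray(b_list, dtype=float)

    def noisy(signal):
        if noise_cv > 0:
            return signal * (1.0 + noise_cv * rng.standard_normal(signal.shape))
        return signal

    r2_post = r2star_pre - fsoc
    pre = EchoSeries(te, noisy(s0 * np.exp(-r2star_pre * te)), "pre")
    post = EchoSeries(te, noisy(s0 * np.exp(-r2_post * te)), "post")
    dwi = DWISeries(b, noisy(s0 * np.exp(-adc * b)))
    truth = SyntheticTruth(seed, {
        "r2star_pre": r2star_pre, "r2star_post": r2_post, "fsoc": fsoc,
        "adc": adc, "s0": s0, "noise_cv": noise_cv,
    }, noise_model=f"multiplicative gaussian cv={noise_cv}")
    return pre, post, dwi, truth


# ---------------------------------------------------------- clearance --

def gen_clearance_study(true_gfr: float = 120.0, true_rpf: float = 600.0,
                        n_periods: int = 4, noise_cv: float = 0.0,
                        pah_extraction: float = 0.85,
                        seed: int | None = None):
    """Steady-infusion clearance study with known GFR and RPF.

    Plasma levels are constant at steady state; urine concentrations are
    back-computed so noise-free period clearances equal the truth, then
    perturbed multiplicatively with CV ``noise_cv``.  Returns
    (iohexol_periods, pah_periods, truth).
    """
    if true_gfr <= 0 or true_rpf <= 0:
        raise ValueError("true GFR and RPF must be positive")
    if noise_cv > 0 and seed is None:
        raise ValueError("noisy generation requires an explicit seed")
    rng = np.random.default_rng(seed)
    duration = 30.0                       # minutes per collection
    urine_volume = 300.0                  # mL per collection
    flow = urine_volume / duration
    plasma_iohexol = 120.0                # ug/mL, steady state
    plasma_pah = 15.0
    pah_clear = true_rpf * pah_extraction

    def periods(clearance, plasma):
        urine_conc = clearance * plasma / flow
        out = []
        for _ in range(n_periods):
            conc = urine_conc
            if noise_cv > 0:
                conc = urine_conc * (1.0 + noise_cv * rng.standard_normal())
            out.append(ClearancePeriod(urine_volume, duration, conc,
                                       plasma, plasma))
        return out

    truth = SyntheticTruth(seed, {
        "gfr": true_gfr, "rpf": true_rpf, "pah_clearance": pah_clear,
        "pah_extraction": pah_extraction, "noise_cv": noise_cv,
    }, noise_model=f"multiplicative gaussian cv={noise_cv} on urine conc")
    return periods(true_gfr, plasma_iohexol), periods(pah_clear, plasma_pah), truth


# ------------------------------------------------------------- cohort --

DEFAULT_COHORT_EFFECTS = {
    # printed two-group summaries: mean +- SD (log-normal medians for GBM)
    "m_value": {"t1d": (7.8, 2.6), "hc": (14.3, 4.0)},          # mg/kg/min
    "k2_cortex": {"t1d": (0.16, 0.02), "hc": (0.18, 0.02)},     # 1/min
    "k2_medulla": {"t1d": (0.15, 0.03), "hc": (0.18, 0.02)},    # 1/min
    "gbm_width": {"t1d": (521.5, 0.25), "hc": (446.7, 0.10)},   # nm, median & log-sd
    "m_k2_correlation": 0.42,
}


def gen_cohort(n_t1d: int = 28, n_hc: int = 12,
               effect_config: dict | None = None,
               seed: int | None = None):
    """Two-group cohort table with the configured group summaries.

    M-value and cortical/medullary k2 are Gaussian within group with the
    configured correlation between M and cortical k2; GBM width is
    log-normal (right-skewed, parameterized by median and log-SD).
    Returns (DataFrame, truth).
    """
    if n_t1d < 2 or n_hc < 2:
        raise ValueError("need n >= 2 per group")
    cfg = dict(DEFAULT_COHORT_EFFECTS)
    if effect_config:
        cfg.update(effect_config)
    rho = float(cfg["m_k2_correlation"])
    if not -1.0 < rho < 1.0:
        raise ValueError("correlation must lie in (-1, 1)")
    rng = np.random.default_rng(seed)

    frames = []
    for grp, n in (("T1D", n_t1d), ("HC", n_hc)):
        key = grp.lower()
        m_mu, m_sd = cfg["m_value"][key]
        kc_mu, kc_sd = cfg["k2_cortex"][key]
        km_mu, km_sd = cfg["k2_medulla"][key]
        gbm_med, gbm_lsd = cfg["gbm_width"][key]
        cov = np.array([[m_sd ** 2, rho * m_sd * kc_sd],
                        [rho * m_sd * kc_sd, kc_sd ** 2]])
        mk = rng.multivariate_normal([m_mu, kc_mu], cov, size=n)
        frames.append(pd.DataFrame({
            "group": grp,
            "m_value": mk[:, 0],
            "k2_cortex": mk[:, 1],
            "k2_medulla": rng.normal(km_mu, km_sd, size=n),
            "gbm_width": gbm_med * np.exp(rng.normal(0.0, gbm_lsd, size=n)),
        }))
    table = pd.concat(frames, ignore_index=True)
    units = {"m_value": "mg/kg/min", "k2_cortex": "1/min",
             "k2_medulla": "1/min", "gbm_width": "nm"}
    truth = SyntheticTruth(seed, {"effect_config": cfg, "units": units,
                                  "n_t1d": n_t1d, "n_hc": n_hc},
                           noise_model="gaussian within group")
    return table, truth


# --------------------------------------------------------- pseudotime --

def gen_pseudotime(n_cells_per_group: int = 500, shift: float = 0.5,
                   seed: int | None = None):
    """Two pseudotime samples as bimodal mixtures with a location shift.

    Emulates per-group cell densities along a differentiation trajectory;
    ``shift`` moves the second group along pseudotime.  Returns
    (sample_a, sample_b, truth).
    """
    if n_cells_per_group < 1:
        raise ValueError("need at least one cell per group")
    rng = np.random.default_rng(seed)

    def mixture(n, loc):
        comp = rng.random(n) < 0.6
        early = rng.normal(0.3, 0.15, size=n)
        late = rng.normal(1.2, 0.25, size=n)
        return np.where(comp, early, late) + loc

    a = mixture(n_cells_per_group, 0.0)
    b = mixture(n_cells_per_group, shift)
    truth = SyntheticTruth(seed, {"shift": shift,
                                  "n_per_group": n_cells_per_group},
                           noise_model="two-component gaussian mixture")
    return a, b, truth
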