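"""Monoexponential MRI signal models and map summaries.

Both BOLD R2* and diffusion ADC estimation reduce to the same log-linear
monoexponential fit S(x) = S0 * exp(-rate * x): slope/intercept of
ln S versus the abscissa (echo time in seconds, or b-value in s/mm^2);
the decay rate is minus the slope.  A weighted variant (weights
proportional to signal^2) approximates maximum likelihood under additive
Gaussian noise on the untransformed signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_B_VALUES = (200.0, 300.0, 500.0, 700.0, 1000.0)   # s/mm^2


@dataclass
class EchoSeries:
    """Multi-echo gradient-echo signal for R2* estimation.

    echo_times in seconds; signals in arbitrary units (must be positive
    for log fitting); condition tags pre- or post-furosemide acquisitions.
    """

    echo_times: np.ndarray
    signals: np.ndarray
    condition: str = "pre"

    def __post_init__(self):
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        _check_series(self.echo_times, self.signals, "echo_times")


@dataclass
class DWISeries:
    """Diffusion-weighted signal across b-values for ADC estimation."""

    b_values: np.ndarray
    signals: np.ndarray

    def __post_init__(self):
        self.b_values = np.asarray(self.b_values, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        _check_series(self.b_values, self.signals, "b_values")


def _check_series(x, s, name):
    if x.ndim != 1 or x.shape != s.shape:
        raise ValueError(f"{name} and signals must be equal-length 1-D arrays")
    if np.unique(x).size < 2:
        raise ValueError(f"at least 2 distinct {name} are required")
    if np.any(s <= 0):
        raise ValueError("signals must be positive for log-linear fitting")


@dataclass
class MonoexponentialResults:
    """Decay rate and amplitude from a log-linear monoexponential fit."""

    rate: float          # R2* (1/s) or ADC (mm^2/s)
    S0: float
    floored: bool = False
    flags: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "Monoexponential decay fit",
            f"  rate : {self.rate:.6g}",
            f"  S0   : {self.S0:.6g}",
        ]
        if self.flags:
            lines.append(f"  flags: {', '.join(self.flags)}")
        return "\n".join(lines)


class MonoexponentialModel:
    """Log-linear least squares for S(x) = S0 exp(-rate * x)."""

    def __init__(self, x, signals, weighted: bool = False):
        self.x = np.asarray(x, dtype=float)
        self.signals = np.asarray(signals, dtype=float)
        _check_series(self.x, self.signals, "abscissae")
        self.weighted = weighted

    def fit(self) -> MonoexponentialResults:
        logs = np.log(self.signals)
        w = self.signals ** 2 if self.weighted else np.ones_like(logs)
        W = np.sqrt(w)
        X = np.column_stack([np.ones_like(self.x), self.x])
        beta, *_ = np.linalg.lstsq(X * W[:, None], logs * W, rcond=None)
        intercept, slope = beta
        rate = -float(slope)
        flags: list[str] = []
        floored = False
        if rate < 0:
            flags.append("negative rate floored at 0")
            rate = 0.0
            floored = True
        return MonoexponentialResults(rate, float(np.exp(intercept)),
                                      floored=floored, flags=flags)


def fit_r2star(series: EchoSeries, weighted: bool = False) -> MonoexponentialResults:
    """Estimate R2* (1/s) and S0 from a multi-echo series."""
    return MonoexponentialModel(series.echo_times, series.signals,
                                weighted=weighted).fit()


def fit_adc(series: DWISeries, weighted: bool = False) -> MonoexponentialResults:
    """Estimate ADC (mm^2/s) and S0 from a multi-b diffusion series."""
    return MonoexponentialModel(series.b_values, series.signals,
                                weighted=weighted).fit()


def compute_fsoc(r2star_pre: float, r2star_post: float) -> float:
    """Furosemide-suppressible oxygen consumption: R2*_pre - R2*_post (1/s)."""
    if not (np.isfinite(r2star_pre) and np.isfinite(r2star_post)):
        raise ValueError("R2* values must be finite")
    return float(r2star_pre) - float(r2star_post)


def total_kidney_volume(mask, voxel_size) -> float:
    """Kidney volume in mL from a binary mask and voxel size in mm."""
    mask = np.asarray(mask).astype(bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask: no kidney voxels")
    voxel_mm3 = float(np.prod(np.asarray(voxel_size, dtype=float)))
    if voxel_mm3 <= 0:
        raise ValueError("voxel_size must be positive")
    return n * voxel_mm3 / 1000.0


@dataclass(frozen=True)
class MapSummary:
    roi: str
    statistic: str
    value: float
    n_voxels: int


def summarize_map(map3d, mask, statistic: str = "mean",
                  roi: str = "roi") -> MapSummary:
    """Arithmetic or geometric mean of a parameter map over a mask."""
    map3d = np.asarray(map3d, dtype=float)
    mask = np.asarray(mask).astype(bool)
    values = map3d[mask]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("mask selects no finite map voxels")
    if statistic == "mean":
        value = float(values.mean())
    elif statistic == "geometric_mean":
        if np.any(values <= 0):
            raise ValueError("geometric mean requires positive map values")
        value = float(np.exp(np.mean(np.log(values))))
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return MapSummary(roi, statistic, value, int(values.size))
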