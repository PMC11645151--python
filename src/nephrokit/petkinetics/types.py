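"""Domain containers for dynamic PET kinetic analysis.

Units are minutes and kBq/mL throughout.  All activity curves are assumed
decay-corrected to injection time (standard reconstruction output).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class FrameSchedule:
    """Frame timing of a dynamic acquisition, in minutes post-injection.

    Frames must be contiguous-or-gapped, strictly increasing and
    non-overlapping, with every end > start and first start >= 0.
    """

    start_times: np.ndarray
    end_times: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.start_times, dtype=float)
        end = np.asarray(self.end_times, dtype=float)
        object.__setattr__(self, "start_times", start)
        object.__setattr__(self, "end_times", end)
        if start.ndim != 1 or start.shape != end.shape or start.size == 0:
            raise ValueError("start_times and end_times must be equal-length 1-D arrays")
        if start[0] < 0:
            raise ValueError("first frame start must be >= 0")
        if not np.all(end > start):
            raise ValueError("every frame end must exceed its start")
        if not np.all(start[1:] >= end[:-1]):
            raise ValueError("frames must be non-overlapping and increasing")

    @property
    def n_frames(self) -> int:
        return self.start_times.size

    @property
    def durations(self) -> np.ndarray:
        return self.end_times - self.start_times

    @property
    def mid_times(self) -> np.ndarray:
        return 0.5 * (self.start_times + self.end_times)

    @classmethod
    def from_durations(cls, durations_min, t0: float = 0.0) -> "FrameSchedule":
        d = np.asarray(durations_min, dtype=float)
        end = t0 + np.cumsum(d)
        start = np.concatenate([[t0], end[:-1]])
        return cls(start, end)


def _default_schedule() -> FrameSchedule:
    # 12 x 10 s, 8 x 30 s, 2 x 2 min, 4 x 5 min (26 frames, 30 min scan)
    durations = [10 / 60] * 12 + [30 / 60] * 8 + [2.0] * 2 + [5.0] * 4
    return FrameSchedule.from_durations(durations)


DEFAULT_FRAME_SCHEDULE: FrameSchedule = _default_schedule()


@dataclass
class TimeActivityCurve:
    """Frame-resolved activity concentration (kBq/mL) for an ROI or voxel."""

    schedule: FrameSchedule
    activity: np.ndarray
    label: str = ""
    decay_corrected: bool = True

    def __post_init__(self):
        self.activity = np.asarray(self.activity, dtype=float)
        if self.activity.shape != (self.schedule.n_frames,):
            raise ValueError(
                f"activity length {self.activity.size} != "
                f"frame count {self.schedule.n_frames}"
            )
        if not np.all(np.isfinite(self.activity)):
            raise ValueError("activity must be finite")

    def scaled(self, factor: float, label: str | None = None) -> "TimeActivityCurve":
        return TimeActivityCurve(
            self.schedule,
            self.activity * factor,
            label if label is not None else self.label,
            self.decay_corrected,
        )


@dataclass
class InputFunction:
    """Metabolite-corrected, calibrated arterial input C_a(t).

    Interpolation contract: piecewise-linear between samples, zero before
    the first sample, constant extrapolation of the last sample after the
    last sample time.
    """

    sample_times: np.ndarray
    parent_activity: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.sample_times, dtype=float)
        a = np.asarray(self.parent_activity, dtype=float)
        if t.ndim != 1 or t.shape != a.shape or t.size == 0:
            raise ValueError("sample_times and parent_activity must be equal-length 1-D")
        if not np.all(np.diff(t) > 0):
            raise ValueError("sample_times must be strictly increasing")
        if np.any(a < 0):
            raise ValueError("parent_activity must be nonnegative")
        self.sample_times = t
        self.parent_activity = a

    def __call__(self, times) -> np.ndarray:
        """Evaluate C_a at arbitrary times (piecewise-linear, zero-extended)."""
        times = np.asarray(times, dtype=float)
        out = np.interp(times, self.sample_times, self.parent_activity,
                        left=0.0, right=float(self.parent_activity[-1]))
        # zero extension strictly before the first sample
        out = np.where(times < self.sample_times[0], 0.0, out)
        return out


@dataclass(frozen=True)
class PKParameters:
    """One-tissue model parameters.

    K1 : mL plasma / min / mL tissue
    k2 : 1/min
    vb : unitless blood volume fraction in [0, 1]
    extraction_fraction : unitless, default 0.52 (11C-acetate in kidney)
    """

    K1: float
    k2: float
    vb: float = 0.0
    extraction_fraction: float = 0.52

    def __post_init__(self):
        if self.K1 < 0 or self.k2 < 0:
            raise ValueError("K1 and k2 must be nonnegative")
        if not 0.0 <= self.vb <= 1.0:
            raise ValueError("vb must lie in [0, 1]")
        if not 0.0 < self.extraction_fraction <= 1.0:
            raise ValueError("extraction_fraction must lie in (0, 1]")

    @property
    def F(self) -> float:
        """Blood flow, mL/min/mL tissue: F = K1 / extraction_fraction."""
        return self.K1 / self.extraction_fraction


@dataclass
class DynamicPETImage:
    """4-D dynamic PET image (x, y, z, frame), kBq/mL."""

    voxels: np.ndarray
    schedule: FrameSchedule
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 4:
            raise ValueError("voxels must be 4-D (x, y, z, frame)")
        if self.voxels.shape[3] != self.schedule.n_frames:
            raise ValueError("frame axis length must equal frame count")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]


@dataclass
class LabelMask:
    """Integer label volume aligned with an image grid plus a legend."""

    labels: np.ndarray
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int32)
        present = set(np.unique(self.labels).tolist()) - {0}
        unknown = present - set(self.legend)
        if unknown:
            raise ValueError(f"labels missing from legend: {sorted(unknown)}")

    def region(self, name: str) -> np.ndarray:
        """Boolean mask of the region with the given legend name."""
        for value, label_name in self.legend.items():
            if label_name == name:
                return self.labels == value
        raise KeyError(f"no region named {name!r}")


@dataclass
class ParametricMap:
    """Per-voxel kinetic parameter estimates with fit diagnostics.

    Outside ``valid_mask`` map values hold NaN (the declared missing value).
    """

    K1_map: np.ndarray
    k2_map: np.ndarray
    vb_map: np.ndarray
    fit_error_map: np.ndarray
    valid_mask: np.ndarray
    n_failed: int = 0

    def __post_init__(self):
        m = self.valid_mask
        for arr in (self.K1_map, self.k2_map, self.vb_map, self.fit_error_map):
            if arr.shape != m.shape:
                raise ValueError("all maps must share the mask's shape")
            if not np.all(np.isfinite(arr[m])):
                raise ValueError("maps must be finite inside valid_mask")
        if np.any(self.K1_map[m] < 0) or np.any(self.k2_map[m] < 0):
            raise ValueError("K1 and k2 must be nonnegative inside valid_mask")


@dataclass(frozen=True)
class CalibrationSample:
    """Venous blood sample used to scale the image-derived blood curve."""

    time: float          # minutes post-injection
    activity: float      # kBq/mL

    def __post_init__(self):
        if self.time <= 0:
            raise ValueError("sample time must be > 0")
        if self.activity < 0:
            raise ValueError("sample activity must be >= 0")
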