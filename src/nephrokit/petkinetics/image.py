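"""Image-level helpers: flow estimation, frame averaging, iso-contour ROIs."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .types import DynamicPETImage, LabelMask, PKParameters

DEFAULT_AVG_WINDOW = (40.0 / 60.0, 4.5)   # minutes: 40 s to 4.5 min


def estimate_flow(params: PKParameters | float,
                  extraction_fraction: float | None = None) -> float:
    """Blood flow F = K1 / extraction fraction (mL/min/mL tissue).

    Accepts a ``PKParameters`` (its own extraction fraction is used unless
    overridden) or a bare K1 value with an explicit extraction fraction.
    """
    if isinstance(params, PKParameters):
        K1 = params.K1
        ef = params.extraction_fraction if extraction_fraction is None \
            else extraction_fraction
    else:
        K1 = float(params)
        ef = 0.52 if extraction_fraction is None else extraction_fraction
    if ef <= 0:
        raise ValueError("extraction fraction must be > 0")
    return K1 / ef


def average_image(image: DynamicPETImage,
                  window: tuple[float, float] = DEFAULT_AVG_WINDOW) -> np.ndarray:
    """Duration-weighted mean image over a time window (minutes).

    Frames partially inside the window are weighted by their overlap with
    it, so the result is the exact time average of the frame-wise constant
    signal over the window.
    """
    w0, w1 = float(window[0]), float(window[1])
    if w1 <= w0:
        raise ValueError("window end must exceed start")
    overlap = np.minimum(image.schedule.end_times, w1) - \
        np.maximum(image.schedule.start_times, w0)
    overlap = np.clip(overlap, 0.0, None)
    total = overlap.sum()
    if total <= 0:
        raise ValueError("window does not overlap the frame schedule")
    weights = overlap / total
    return np.tensordot(image.voxels, weights, axes=([3], [0]))


def iso_contour_mask(avg_image: np.ndarray, threshold_fraction: float = 0.5,
                     seed_label: str = "cortex",
                     robust_percentile: float = 99.0) -> LabelMask:
    """Semi-automatic ROI from an iso-contour on an average image.

    Voxels at or above ``threshold_fraction`` x robust maximum (the 99th
    percentile by default) are kept; the largest 26-connected component is
    returned as label 1 under ``seed_label``.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    img = np.asarray(avg_image, dtype=float)
    robust_max = np.percentile(img, robust_percentile)
    mask = img >= threshold_fraction * robust_max
    if not np.any(mask):
        raise ValueError(
            "iso-contour selected no voxels; try a lower threshold_fraction "
            f"(robust max {robust_max:.3g})"
        )
    structure = np.ones((3, 3, 3), dtype=bool)
    labelled, n = ndimage.label(mask, structure=structure)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labelled), labelled,
                                   index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        mask = labelled == keep
    return LabelMask(mask.astype(np.int32), {1: seed_label})
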