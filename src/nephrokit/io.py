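"""File-format helpers: NIfTI volumes, CSV curves and tables, JSON results."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .petkinetics import (
    DynamicPETImage,
    FrameSchedule,
    InputFunction,
    LabelMask,
    ParametricMap,
    TimeActivityCurve,
)
from .renal import ClearancePeriod


def load_dynamic_pet(image_path, schedule_csv) -> DynamicPETImage:
    """4-D NIfTI + frame-schedule CSV (frame_start_min, frame_end_min)."""
    img = nib.load(str(image_path))
    sched = pd.read_csv(schedule_csv)
    schedule = FrameSchedule(sched["frame_start_min"].to_numpy(),
                             sched["frame_end_min"].to_numpy())
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DynamicPETImage(np.asarray(img.dataobj, dtype=float),
                           schedule, voxel_size)


def save_volume(array, path, voxel_size=(1.0, 1.0, 1.0)) -> None:
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.float64), affine),
             str(path))


def load_mask(path, legend: dict[int, str] | None = None) -> LabelMask:
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int32)
    if legend is None:
        legend = {int(v): f"label_{int(v)}" for v in np.unique(labels) if v != 0}
    return LabelMask(labels, legend)


def load_tac(path, label: str = "") -> TimeActivityCurve:
    """CSV with columns frame_start_min, frame_end_min, activity_kBq_mL."""
    df = pd.read_csv(path)
    schedule = FrameSchedule(df["frame_start_min"].to_numpy(),
                             df["frame_end_min"].to_numpy())
    return TimeActivityCurve(schedule, df["activity_kBq_mL"].to_numpy(), label)


def save_tac(tac: TimeActivityCurve, path) -> None:
    pd.DataFrame({
        "frame_start_min": tac.schedule.start_times,
        "frame_end_min": tac.schedule.end_times,
        "activity_kBq_mL": tac.activity,
    }).to_csv(path, index=False)


def load_input_function(path) -> InputFunction:
    """CSV with columns time_min, activity_kBq_mL."""
    df = pd.read_csv(path)
    return InputFunction(df["time_min"].to_numpy(),
                         df["activity_kBq_mL"].to_numpy())


def save_input_function(input_fn: InputFunction, path) -> None:
    pd.DataFrame({
        "time_min": input_fn.sample_times,
        "activity_kBq_mL": input_fn.parent_activity,
    }).to_csv(path, index=False)


def load_clearance_periods(path) -> list[ClearancePeriod]:
    """CSV: one row per period (urine_volume_mL, duration_min,
    urine_conc_ug_mL, plasma_start_ug_mL, plasma_end_ug_mL)."""
    df = pd.read_csv(path)
    return [
        ClearancePeriod(r.urine_volume_mL, r.duration_min, r.urine_conc_ug_mL,
                        r.plasma_start_ug_mL, r.plasma_end_ug_mL)
        for r in df.itertuples()
    ]


def save_parametric_map(pmap: ParametricMap, out_dir,
                        voxel_size=(1.0, 1.0, 1.0)) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_volume(pmap.K1_map, out / "K1.nii.gz", voxel_size)
    save_volume(pmap.k2_map, out / "k2.nii.gz", voxel_size)
    save_volume(pmap.vb_map, out / "vb.nii.gz", voxel_size)
    save_volume(pmap.fit_error_map, out / "fit_error.nii.gz", voxel_size)
    save_volume(pmap.valid_mask.astype(np.int16), out / "valid_mask.nii.gz",
                voxel_size)


def save_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
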