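"""File formats: NIfTI volumes, BIDS-style events TSV, motion text, HR CSV.

BOLD data and label maps travel as NIfTI (via nibabel, voxel size on the
affine diagonal); event schedules as tab-separated onset/duration/trial_type
tables; motion as 6-column whitespace-delimited text (translations in mm,
rotations in radians); HR timecourses as 2-column CSV (time_s, value); and
cohort manifests as CSV.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .events import EventSchedule
from .glm import BOLDDataset, MotionTrace
from .hrf import HRTimecourse


def write_bold(data: BOLDDataset, path: str | Path) -> None:
    affine = np.diag(list(data.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(data.values.astype(np.float32), affine), str(path))


def write_labels(label_map: np.ndarray, voxel_size, path: str | Path) -> None:
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(label_map, dtype=np.int16), affine), str(path))


def read_bold(
    bold_path: str | Path, labels_path: str | Path, tr: float
) -> BOLDDataset:
    img = nib.load(str(bold_path))
    lab = nib.load(str(labels_path))
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return BOLDDataset(
        values=np.asarray(img.dataobj, dtype=float),
        tr=tr,
        label_map=np.asarray(lab.dataobj).astype(np.int16),
        voxel_size=voxel_size,
    )


def read_stat_map(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)


def write_stat_map(values: np.ndarray, voxel_size, path: str | Path) -> None:
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine), str(path))


def write_events(schedule: EventSchedule, path: str | Path) -> None:
    schedule.to_frame().to_csv(path, sep="\t", index=False)


def read_events(path: str | Path, run_length: float) -> EventSchedule:
    frame = pd.read_csv(path, sep="\t")
    return EventSchedule.from_frame(frame, run_length=run_length)


def write_motion(motion: MotionTrace, path: str | Path) -> None:
    np.savetxt(path, motion.params, fmt="%.8f")


def read_motion(path: str | Path) -> MotionTrace:
    return MotionTrace(params=np.loadtxt(path, ndmin=2))


def write_hr(hr: HRTimecourse, path: str | Path) -> None:
    pd.DataFrame({"time_s": hr.times, "value": hr.samples}).to_csv(path, index=False)


def read_hr(path: str | Path) -> HRTimecourse:
    frame = pd.read_csv(path)
    t = frame["time_s"].to_numpy(float)
    dt = float(t[1] - t[0]) if t.size > 1 else 1.0
    return HRTimecourse(samples=frame["value"].to_numpy(float), dt=dt, window=float(t[-1]))
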