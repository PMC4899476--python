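"""Readers and writers for on-disk artifacts.

Volumes and masks travel as NIfTI-1 (RAS+ diagonal affine at the voxel size);
event schedules as BIDS-style tab-separated tables (onset, duration,
trial_type, task, level, object, is_catch, question_onset); pattern sets as a
beta-matrix CSV plus a labels TSV; configuration as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import nibabel as nib
import numpy as np
import pandas as pd

from .bold_sim import BOLDRun, ROISet
from .paradigm import RunDesign, TrialEvent, TASK_OF_RUN
from .trial_betas import TrialPatternSet

PathLike = Union[str, Path]


class FormatError(ValueError):
    """A file could not be parsed in the expected format."""


def save_volume(path: PathLike, data: np.ndarray, voxel_size_mm: float = 2.5) -> None:
    """Write a 3-D or 4-D array as NIfTI-1 with an RAS+ diagonal affine."""
    affine = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def load_volume(path: PathLike) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; returns (data, affine)."""
    try:
        img = nib.load(str(path))
        return np.asarray(img.dataobj), img.affine
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"not a readable NIfTI file: {path}") from exc


def save_bold_run(path: PathLike, run: BOLDRun, voxel_size_mm: float = 2.5) -> None:
    save_volume(path, run.data, voxel_size_mm)


def save_roi_masks(rois: ROISet, out_dir: PathLike) -> None:
    """Write one 0/1 NIfTI mask per ROI plus the insula tuning annotation."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, coords in rois.masks.items():
        vol = np.zeros(rois.shape, dtype=np.uint8)
        vol[coords[:, 0], coords[:, 1], coords[:, 2]] = 1
        save_volume(out / f"mask_{name}.nii.gz", vol, rois.voxel_size_mm)
    for name, ann in rois.signal_annotation.items():
        vol = np.zeros(rois.shape, dtype=np.int8)
        c = rois.masks[name]
        vol[c[:, 0], c[:, 1], c[:, 2]] = ann
        save_volume(out / f"annotation_{name}.nii.gz", vol, rois.voxel_size_mm)


def write_events_tsv(design: RunDesign, path: PathLike) -> None:
    rows = []
    for ev in design.events:
        rows.append(
            {
                "onset": ev.onset_s,
                "duration": ev.duration_s,
                "trial_type": ev.trial_type,
                "task": ev.task,
                "level": ev.level,
                "object": ev.object_label,
                "is_catch": int(ev.is_catch),
                "question_onset": ev.question_onset_s if ev.is_catch else "n/a",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_events_tsv(path: PathLike, run_index: int) -> RunDesign:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"not a readable events table: {path}") from exc
    required = {"onset", "duration", "task", "level", "object", "is_catch"}
    if not required.issubset(df.columns):
        raise FormatError(f"events table {path} lacks columns {sorted(required - set(df.columns))}")
    events = []
    for _, row in df.iterrows():
        is_catch = bool(int(row["is_catch"]))
        events.append(
            TrialEvent(
                onset_s=float(row["onset"]),
                task=str(row["task"]),
                level=int(row["level"]),
                object_label=str(row["object"]),
                is_catch=is_catch,
                question_onset_s=float(row["question_onset"]) if is_catch else None,
            )
        )
    return RunDesign(run_index=run_index, task=TASK_OF_RUN[run_index], events=tuple(events))


def write_pattern_set(p: TrialPatternSet, prefix: PathLike) -> None:
    """Write <prefix>_beta.csv (trials x voxels) and <prefix>_labels.tsv."""
    prefix = Path(prefix)
    pd.DataFrame(p.beta).to_csv(prefix.with_name(prefix.name + "_beta.csv"), index=False)
    p.labels.to_csv(prefix.with_name(prefix.name + "_labels.tsv"), sep="\t", index=False)


def read_pattern_set(prefix: PathLike, roi_name: str, subject_id: str = "") -> TrialPatternSet:
    prefix = Path(prefix)
    try:
        beta = pd.read_csv(prefix.with_name(prefix.name + "_beta.csv")).to_numpy(dtype=float)
        labels = pd.read_csv(prefix.with_name(prefix.name + "_labels.tsv"), sep="\t")
    except Exception as exc:
        raise FormatError(f"not a readable pattern set: {prefix}") from exc
    return TrialPatternSet(beta=beta, labels=labels, roi_name=roi_name, subject_id=subject_id)


def write_json(path: PathLike, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
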