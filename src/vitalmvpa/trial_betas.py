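"""Single-trial response estimation (beta series).

Each trial's response is estimated per voxel from a short window around the
event — the pre-onset volume plus the five volumes following the onset volume
— by a least-squares fit of an HRF-convolved 2 s event regressor and a
constant local baseline.  The jittered 12-16 s inter-stimulus interval
guarantees these windows contain no signal from neighbouring trials.  Betas
are expressed in percent of the voxel's run-mean intensity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .bold_sim import BOLDRun, ROISet, canonical_hrf
from .paradigm import RunDesign, ScanDesign, TrialEvent

#: window volume offsets relative to the onset volume
WINDOW_OFFSETS = (-1, 1, 2, 3, 4, 5)


@dataclass(frozen=True)
class TrialWindow:
    """Volume indices of one trial's 6-volume estimation window."""

    onset_volume: int
    volumes: tuple[int, ...]

    @classmethod
    def for_event(cls, event: TrialEvent, tr_s: float, n_volumes: int) -> "TrialWindow":
        v0 = int(event.onset_s // tr_s)
        vols = tuple(v0 + o for o in WINDOW_OFFSETS)
        if vols[0] < 0 or vols[-1] > n_volumes - 1:
            raise ValueError(
                f"trial at {event.onset_s} s: estimation window truncated by run bounds"
            )
        return cls(onset_volume=v0, volumes=vols)


def _design_matrix(tr_s: float) -> np.ndarray:
    """[event regressor, constant] sampled at the window offsets."""
    kernel = canonical_hrf(tr_s, 2.0)
    reg = np.array([0.0 if o < 0 else kernel[o] for o in WINDOW_OFFSETS])
    return np.column_stack([reg, np.ones_like(reg)])


def estimate_trial_beta(
    run: BOLDRun, event: TrialEvent, voxels: np.ndarray
) -> np.ndarray:
    """Per-voxel response amplitude (% of run mean) for one trial.

    ``voxels`` is an (N, 3) array of voxel coordinates.  The estimator fits
    [HRF regressor, constant] over the 6-volume window by least squares and
    scales the regressor coefficient to percent of the voxel's run mean.
    """
    voxels = np.asarray(voxels)
    win = TrialWindow.for_event(event, run.tr_s, run.n_volumes)
    series = run.data[voxels[:, 0], voxels[:, 1], voxels[:, 2], :]  # (V, T)
    X = _design_matrix(run.tr_s)
    pinv = np.linalg.pinv(X)
    y = series[:, list(win.volumes)].T  # (6, V)
    beta_raw = (pinv @ y)[0]
    run_mean = series.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(run_mean > 0, beta_raw / run_mean * 100.0, 0.0)
    return pct


@dataclass(frozen=True)
class TrialPatternSet:
    """Trials x voxels matrix of per-trial betas with labels.

    One row per non-catch trial, ordered by (run, onset): 45 rows per run,
    180 in total for a 4-run session.
    """

    beta: np.ndarray
    labels: pd.DataFrame  # columns: run_index, task, level, object, onset_s
    roi_name: str
    subject_id: str

    def __post_init__(self) -> None:
        if self.beta.shape[0] != len(self.labels):
            raise ValueError("one label row per beta row required")
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("betas must be finite")
        per_run = self.labels.groupby("run_index").size()
        if not (per_run == 45).all():
            raise ValueError("expected 45 non-catch trials per run")

    def select(self, task: str, level: int, runs: Sequence[int]) -> np.ndarray:
        """Row indices of trials matching (task, level) within the given runs."""
        m = (
            (self.labels["task"] == task)
            & (self.labels["level"] == level)
            & (self.labels["run_index"].isin(list(runs)))
        )
        return np.flatnonzero(m.to_numpy())


def build_pattern_set(
    runs: Sequence[BOLDRun],
    designs: Sequence[RunDesign] | ScanDesign,
    rois: ROISet,
    roi_name: str,
    subject_id: str = "",
) -> TrialPatternSet:
    """Assemble the labeled trials x voxels beta matrix for one ROI.

    Catch trials are excluded; voxel column order follows the ROI mask order.
    """
    design_list = designs.runs if isinstance(designs, ScanDesign) else list(designs)
    if len(runs) != 4 or len(design_list) != 4:
        raise ValueError("a session has exactly 4 runs")
    if roi_name not in rois.masks:
        raise ValueError(f"unknown ROI {roi_name!r}")
    voxels = rois.masks[roi_name]
    by_index = {r.run_index: r for r in runs}
    rows, labels = [], []
    for design in sorted(design_list, key=lambda d: d.run_index):
        run = by_index.get(design.run_index)
        if run is None:
            raise ValueError(f"missing BOLD run {design.run_index}")
        for ev in design.experimental_events:
            rows.append(estimate_trial_beta(run, ev, voxels))
            labels.append(
                (design.run_index, ev.task, ev.level, ev.object_label, ev.onset_s)
            )
    return TrialPatternSet(
        beta=np.vstack(rows),
        labels=pd.DataFrame(
            labels, columns=["run_index", "task", "level", "object", "onset_s"]
        ),
        roi_name=roi_name,
        subject_id=subject_id,
    )
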