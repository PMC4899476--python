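"""End-to-end synthetic cohort pipeline: simulate -> betas -> decode -> group maps.

All stage randomness derives from a single master seed, so a re-run with the
same configuration is byte-identical.  The defaults mirror the study design:
16 subjects, 4 runs of 416 volumes at TR 2 s, 45+5 trials per run, 15 trials
per level, linear SVM with C = 1 over the four alternate-run folds, 1000
permutations, Wilcoxon alpha 0.05, selection fraction 0.5 and FDR q = 0.05.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import io as vio
from .bold_sim import (
    GeometryConfig,
    NoiseConfig,
    ROISet,
    SignalConfig,
    VITALITY_PREFERRING,
    build_geometry,
    simulate_run,
)
from .decoding import (
    cross_task_contrasts,
    decode_contrast,
    make_cv_folds,
    permutation_null,
    wilcoxon_group,
    within_task_contrasts,
)
from .group_maps import (
    binomial_overlap_null,
    group_map_inference,
    group_overlap,
    monte_carlo_overlap_null,
    rank_discriminative_voxels,
    select_top_fraction,
)
from .paradigm import generate_session_design
from .trial_betas import build_pattern_set

log = logging.getLogger("vitalmvpa")

ROI_NAMES = ("left_insula", "right_insula", "ctrl_white_matter", "ctrl_ba21")
INSULAE = ("left_insula", "right_insula")


@dataclass
class PipelineConfig:
    n_subjects: int = 16
    seed: int = 0
    geometry_scale: float = 1.0
    signal: SignalConfig = field(default_factory=SignalConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    svm_cost: float = 1.0
    n_perm: int = 1000
    include_permutations: bool = False
    alpha: float = 0.05
    selection_fraction: float = 0.5  # 0.35 also supported
    q: float = 0.05
    null_method: str = "binomial"  # or "monte_carlo"
    n_iter: int = 10_000
    write_volumes: bool = False
    write_events: bool = True

    def geometry(self) -> GeometryConfig:
        g = GeometryConfig()
        return g if self.geometry_scale == 1.0 else g.scaled(self.geometry_scale)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["signal"] = asdict(self.signal)
        d["noise"] = asdict(self.noise)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "signal" in d:
            d["signal"] = SignalConfig(**d["signal"])
        if "noise" in d:
            d["noise"] = NoiseConfig(**d["noise"])
        return cls(**d)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def _subject_seed(master: int, subject: int) -> int:
    return int(np.random.SeedSequence([master, 100 + subject]).generate_state(1)[0] % (2**31))


@dataclass
class SubjectResult:
    subject_id: str
    rois: ROISet
    patterns: dict  # roi name -> TrialPatternSet
    run_roi_means: dict  # roi name -> {task: mean intensity}
    decodings: list  # DecodingResult


@dataclass
class CohortResult:
    config: PipelineConfig
    subjects: list
    accuracy: pd.DataFrame  # tidy: subject, roi, contrast, fold, accuracy
    group_maps: dict  # insula name -> GroupOverlapMap
    consensus_cluster: dict  # insula name -> boolean array (planted majority)
    summary: dict

    def cohort_mean(self, rois, cross_task: bool) -> float:
        df = self.accuracy
        sub = df[df["roi"].isin(rois) & (df["cross_task"] == cross_task)]
        return float(sub.groupby(["subject", "roi", "contrast"])["accuracy"].mean().mean())


def simulate_subject(
    config: PipelineConfig, subject: int
) -> tuple[ROISet, list, list]:
    """Geometry, session design and the four simulated runs of one subject."""
    sseed = _subject_seed(config.seed, subject)
    rois = build_geometry(config.geometry(), config.signal, seed=sseed)
    session = generate_session_design(f"sub-{subject:02d}", seed=sseed)
    runs = [
        simulate_run(
            d, rois, config.signal, config.noise,
            seed=int(np.random.SeedSequence([sseed, 200 + d.run_index]).generate_state(1)[0] % (2**31)),
        )
        for d in session.runs
    ]
    return rois, list(session.runs), runs


def run_pipeline(config: PipelineConfig, out_dir: Optional[str] = None) -> CohortResult:
    """Execute the full synthetic-cohort analysis; optionally write results."""
    t0 = time.time()
    log.info("pipeline start: seed=%d hash=%s", config.seed, config.config_hash())
    cv = make_cv_folds()
    contrasts = list(cross_task_contrasts()) + list(within_task_contrasts())
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    subjects: list[SubjectResult] = []
    rows = []
    for s in range(config.n_subjects):
        rois, designs, runs = simulate_subject(config, s)
        sid = f"sub-{s:02d}"
        roi_means = {}
        for roi in INSULAE:
            c = rois.masks[roi]
            per_task = {"vitality": [], "velocity": []}
            for run, d in zip(runs, designs):
                per_task[d.task].append(
                    float(run.data[c[:, 0], c[:, 1], c[:, 2], :].mean())
                )
            roi_means[roi] = {k: float(np.mean(v)) for k, v in per_task.items()}
        if out and config.write_events:
            for d in designs:
                vio.write_events_tsv(d, out / f"{sid}_run-{d.run_index}_events.tsv")
        if out and config.write_volumes:
            vio.save_roi_masks(rois, out / "masks" if s == 0 else out / f"{sid}_masks")
            for run in runs:
                vio.save_bold_run(out / f"{sid}_run-{run.run_index}_bold.nii.gz", run)

        patterns = {
            roi: build_pattern_set(runs, designs, rois, roi, subject_id=sid)
            for roi in ROI_NAMES
        }
        del runs
        decs = []
        for roi in ROI_NAMES:
            for c in contrasts:
                res = decode_contrast(patterns[roi], c, cv, svm_cost=config.svm_cost)
                if (
                    config.include_permutations
                    and roi in INSULAE
                    and c.cross_task
                    and config.n_perm > 0
                ):
                    null = permutation_null(
                        patterns[roi], c, cv, n_perm=config.n_perm,
                        seed=_subject_seed(config.seed, 1000 + s),
                        svm_cost=config.svm_cost,
                    )
                    from .decoding import attach_null

                    res = attach_null(res, null)
                decs.append(res)
                for fold, acc in enumerate(res.fold_accuracies):
                    rows.append(
                        (sid, roi, c.name, c.cross_task, fold, acc)
                    )
        subjects.append(SubjectResult(sid, rois, patterns, roi_means, decs))
        log.info("subject %s done (%.1f s elapsed)", sid, time.time() - t0)

    accuracy = pd.DataFrame(
        rows, columns=["subject", "roi", "contrast", "cross_task", "fold", "accuracy"]
    )

    # group discriminative maps per insula, collapsing the cross-task contrasts
    group_maps, consensus = {}, {}
    cross_names = {c.name for c in cross_task_contrasts()}
    for roi in INSULAE:
        maps = []
        for sub in subjects:
            res = [
                d for d in sub.decodings
                if d.roi_name == roi and d.contrast.name in cross_names
            ]
            m = rank_discriminative_voxels(res)
            maps.append(select_top_fraction(m, config.selection_fraction))
        gmap = group_overlap(maps)
        v = maps[0].n_voxels
        if config.null_method == "monte_carlo":
            null = monte_carlo_overlap_null(
                v, config.n_subjects, config.selection_fraction,
                n_iter=config.n_iter, seed=config.seed,
            )
        else:
            null = binomial_overlap_null(config.n_subjects, config.selection_fraction)
        group_maps[roi] = group_map_inference(gmap, null, q=config.q)
        planted = np.stack(
            [s.rois.signal_annotation[roi] == VITALITY_PREFERRING for s in subjects]
        )
        consensus[roi] = planted.mean(axis=0) >= 0.5

    # summary statistics
    summary: dict = {"config_hash": config.config_hash(), "seed": config.seed}
    per_subject = (
        accuracy.groupby(["subject", "roi", "contrast", "cross_task"])["accuracy"]
        .mean()
        .reset_index()
    )
    for (roi, contrast), grp in per_subject.groupby(["roi", "contrast"]):
        accs = grp["accuracy"].to_numpy()
        key = f"{roi}:{contrast}"
        entry = {"mean_accuracy": float(accs.mean())}
        if len(accs) >= 2 and np.any(accs != 0.5):
            entry["wilcoxon_p"] = wilcoxon_group(accs, 0.5)
        summary[key] = entry
    for roi in INSULAE:
        gm = group_maps[roi]
        surv = gm.fdr_mask
        summary[f"group_map:{roi}"] = {
            "n_surviving": int(surv.sum()),
            "min_surviving_overlap": gm.min_surviving_overlap,
            "frac_survivors_in_planted_cluster": (
                float(consensus[roi][surv].mean()) if surv.any() else None
            ),
            "n_surviving_positive": int((gm.group_sign[surv] > 0).sum()),
            "n_surviving_negative": int((gm.group_sign[surv] < 0).sum()),
        }
        vit = [s.run_roi_means[roi]["vitality"] for s in subjects]
        vel = [s.run_roi_means[roi]["velocity"] for s in subjects]
        t, p = stats.ttest_rel(vit, vel)
        summary[f"univariate:{roi}"] = {"t": float(t), "p": float(p)}

    result = CohortResult(config, subjects, accuracy, group_maps, consensus, summary)
    if out:
        accuracy.to_csv(out / "accuracy.csv", index=False)
        for roi, gm in group_maps.items():
            pd.DataFrame(
                {
                    "voxel": np.arange(len(gm.overlap_pos)),
                    "overlap_pos": gm.overlap_pos,
                    "overlap_neg": gm.overlap_neg,
                    "p_value": gm.p_values,
                    "fdr_surviving": gm.fdr_mask.astype(int),
                    "in_planted_cluster": consensus[roi].astype(int),
                }
            ).to_csv(out / f"group_map_{roi}.csv", index=False)
        vio.write_json(out / "summary.json", summary)
        vio.write_json(
            out / "provenance.json",
            {"config": config.to_dict(), "config_hash": config.config_hash()},
        )
    log.info("pipeline done in %.1f s", time.time() - t0)
    return result
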