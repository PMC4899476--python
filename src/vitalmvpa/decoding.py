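"""Linear SVM decoding of task-context contrasts.

Because the two task contexts were acquired in separate runs (vitality: runs
1-2, velocity: runs 3-4), cross-validation uses the four alternate-run splits
(train 1,3 / test 2,4; train 2,4 / test 1,3; train 2,3 / test 1,4; train 1,4 /
test 2,3), so every fold trains and tests on one run of each task.  Each fold
z-scores voxels with training-set statistics, fits a linear soft-margin SVM,
and scores the held-out runs.  Chance level is estimated by refitting under
within-run shuffles of the training labels (test labels intact), and group
significance by an exact one-sided Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.svm import SVC

from .bold_sim import BOLDRun, ROISet
from .paradigm import RunDesign, LEVEL_NAMES
from .trial_betas import TrialPatternSet

_EPS = 1e-12


@dataclass(frozen=True)
class CVScheme:
    """The four alternate-run train/test splits."""

    folds: tuple[tuple[frozenset[int], frozenset[int]], ...]

    def __post_init__(self) -> None:
        for train, test in self.folds:
            if train & test:
                raise ValueError("train and test runs must be disjoint")
            if not ({1, 2} & train and {3, 4} & train):
                raise ValueError("each fold must train on one run of each task")


def make_cv_folds() -> CVScheme:
    """Folds (1,3 vs 2,4), (2,4 vs 1,3), (2,3 vs 1,4), (1,4 vs 2,3)."""
    pairs = [({1, 3}, {2, 4}), ({2, 4}, {1, 3}), ({2, 3}, {1, 4}), ({1, 4}, {2, 3})]
    return CVScheme(tuple((frozenset(a), frozenset(b)) for a, b in pairs))


@dataclass(frozen=True)
class Contrast:
    """A balanced two-class contrast defined by (task, level) selectors."""

    name: str
    class_a: tuple[str, int]
    class_b: tuple[str, int]

    @property
    def cross_task(self) -> bool:
        return self.class_a[0] != self.class_b[0]


def cross_task_contrasts() -> tuple[Contrast, ...]:
    """rude vs fast, neutral vs medium, gentle vs slow."""
    out = []
    for level in (1, 2, 3):
        a, b = LEVEL_NAMES["vitality"][level], LEVEL_NAMES["velocity"][level]
        out.append(Contrast(f"{a}_vs_{b}", ("vitality", level), ("velocity", level)))
    return tuple(out)


def within_task_contrasts() -> tuple[Contrast, ...]:
    """All within-task level pairs (rude vs gentle, fast vs slow, ...)."""
    out = []
    for task in ("vitality", "velocity"):
        for la, lb in combinations((1, 2, 3), 2):
            a, b = LEVEL_NAMES[task][la], LEVEL_NAMES[task][lb]
            out.append(Contrast(f"{a}_vs_{b}", (task, la), (task, lb)))
    return tuple(out)


@dataclass(frozen=True)
class DecodingResult:
    subject_id: str
    roi_name: str
    contrast: Contrast
    fold_accuracies: tuple[float, ...]
    fold_weights: tuple[np.ndarray, ...]  # signed voxel weights per fold
    null_accuracies: Optional[np.ndarray] = None

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def chance_estimate(self) -> float:
        if self.null_accuracies is None:
            raise ValueError("no permutation null attached")
        return float(np.mean(self.null_accuracies))

    @property
    def p_value(self) -> float:
        """Empirical p = (1 + #{null >= observed}) / (n_perm + 1)."""
        null = self.null_accuracies
        if null is None:
            raise ValueError("no permutation null attached")
        return float((1 + np.sum(null >= self.mean_accuracy)) / (len(null) + 1))


def _fold_data(p: TrialPatternSet, c: Contrast, train_runs, test_runs):
    """Standardized train/test features and labels for one fold."""
    parts = {}
    for split, runs in (("train", train_runs), ("test", test_runs)):
        ia = p.select(*c.class_a, runs)
        ib = p.select(*c.class_b, runs)
        if len(ia) != len(ib):
            raise ValueError(
                f"unbalanced classes in {split} runs {sorted(runs)}: {len(ia)} vs {len(ib)}"
            )
        X = np.vstack([p.beta[ia], p.beta[ib]])
        y = np.concatenate([np.ones(len(ia)), -np.ones(len(ib))])
        run_ids = p.labels["run_index"].to_numpy()[np.concatenate([ia, ib])]
        parts[split] = (X, y, run_ids)
    (Xtr, ytr, rtr), (Xte, yte, _) = parts["train"], parts["test"]
    mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
    # z-score with train statistics, then scale by the voxel count so the
    # fixed SVM cost C=1 operates in the strongly regularized soft-margin
    # regime for any ROI size: there the decision function approaches the
    # class-centroid difference, keeping voxel weights proportional to each
    # voxel's condition difference (interpretable discriminative maps) and
    # accuracies comparable across ROIs
    sd = np.where(sd < _EPS, 1.0, sd) * Xtr.shape[1]
    return (Xtr - mu) / sd, ytr, rtr, (Xte - mu) / sd, yte


def _fit_score(Xtr, ytr, Xte, yte, svm_cost):
    clf = SVC(kernel="linear", C=svm_cost)
    clf.fit(Xtr, ytr)
    acc = float(np.mean(clf.predict(Xte) == yte))
    return acc, clf.coef_.ravel().copy()


def decode_contrast(
    p: TrialPatternSet,
    c: Contrast,
    cv: Optional[CVScheme] = None,
    svm_cost: float = 1.0,
) -> DecodingResult:
    """Cross-validated linear SVM accuracy and per-fold signed weight maps.

    Features are z-scored with training-set statistics within each fold; the
    positive weight sign corresponds to class_a (vitality in the cross-task
    contrasts).
    """
    cv = cv or make_cv_folds()
    accs, weights = [], []
    for train_runs, test_runs in cv.folds:
        Xtr, ytr, _, Xte, yte = _fold_data(p, c, train_runs, test_runs)
        acc, w = _fit_score(Xtr, ytr, Xte, yte, svm_cost)
        accs.append(acc)
        weights.append(w)
    return DecodingResult(
        subject_id=p.subject_id,
        roi_name=p.roi_name,
        contrast=c,
        fold_accuracies=tuple(accs),
        fold_weights=tuple(weights),
    )


def permutation_null(
    p: TrialPatternSet,
    c: Contrast,
    cv: Optional[CVScheme] = None,
    n_perm: int = 1000,
    seed: int = 0,
    svm_cost: float = 1.0,
) -> np.ndarray:
    """Permutation null distribution of the fold-mean accuracy.

    Training labels are shuffled (test labels intact), the SVM is refit and
    scored; one fold-mean accuracy is recorded per permutation.  Shuffling is
    stratified within training runs whenever a run contains both classes
    (within-task contrasts); for cross-task contrasts class coincides with
    run, a within-run shuffle would be the identity, so labels are exchanged
    across the whole training set instead.  The chance estimate is the mean
    of the returned array.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cv = cv or make_cv_folds()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xE4]))
    folds = [_fold_data(p, c, tr, te) for tr, te in cv.folds]
    null = np.empty(n_perm)
    for k in range(n_perm):
        accs = []
        for Xtr, ytr, rtr, Xte, yte in folds:
            y_perm = ytr.copy()
            strata = (
                [np.flatnonzero(rtr == run) for run in np.unique(rtr)]
                if not c.cross_task
                else [np.arange(len(ytr))]
            )
            for idx in strata:
                y_perm[idx] = y_perm[rng.permutation(idx)]
            acc, _ = _fit_score(Xtr, y_perm, Xte, yte, svm_cost)
            accs.append(acc)
        null[k] = np.mean(accs)
    return null


def attach_null(result: DecodingResult, null: np.ndarray) -> DecodingResult:
    return replace(result, null_accuracies=np.asarray(null, dtype=float))


def wilcoxon_group(accuracies: Sequence[float], chance: float = 0.5) -> float:
    """Exact one-sided Wilcoxon signed-rank p-value against chance.

    Zeros are discarded (classic convention); ties get average ranks; for
    n <= 20 after zero removal the null distribution of W+ is enumerated
    exactly over all 2^n sign assignments, otherwise the normal approximation
    is used.  Alternative: accuracies > chance.
    """
    d = np.asarray(accuracies, dtype=float) - chance
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    n = d.size
    if n > 20:
        res = stats.wilcoxon(d, alternative="greater", correction=False)
        return float(res.pvalue)
    sums = np.zeros(1)
    for r in ranks:
        sums = np.concatenate([sums, sums + r])
    return float(np.mean(sums >= w_plus - 1e-12))


def univariate_roi_check(
    runs_by_subject: Sequence[Sequence[BOLDRun]],
    rois: ROISet,
    designs_by_subject: Sequence[Sequence[RunDesign]],
    roi_name: str,
) -> tuple[float, float]:
    """Paired t-test of mean ROI signal, vitality runs vs. velocity runs.

    For each subject the mean in-mask intensity is averaged over the two runs
    of each task; the per-subject (vitality - velocity) differences are tested
    across subjects with a paired t-test.  Returns (t, two-sided p).
    """
    if len(runs_by_subject) < 2:
        raise ValueError("need at least 2 subjects")
    coords = rois.masks[roi_name]
    vit, vel = [], []
    for runs, designs in zip(runs_by_subject, designs_by_subject):
        task_of = {d.run_index: d.task for d in designs}
        means = {"vitality": [], "velocity": []}
        for run in runs:
            m = run.data[coords[:, 0], coords[:, 1], coords[:, 2], :].mean()
            means[task_of[run.run_index]].append(m)
        vit.append(np.mean(means["vitality"]))
        vel.append(np.mean(means["velocity"]))
    t, p = stats.ttest_rel(vit, vel)
    return float(t), float(p)
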