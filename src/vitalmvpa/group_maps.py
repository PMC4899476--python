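"""Group discriminative overlap maps with Monte Carlo / binomial nulls and FDR.

Each subject's signed discriminative map averages the linear-SVM voxel
weights over folds (and over the three cross-task contrasts when collapsing);
voxels are ranked by |weight| and the top fraction f (50% or 35%) selected,
with sign + for vitality-preferring and - for velocity-preferring voxels.
The group map counts, per voxel, how many of the S = 16 subjects selected it.
Under the independence null (spatial maps completely unrelated) the overlap
count is Binomial(S, f); the same null is also available as a Monte Carlo
simulation, either per-voxel (pooled across voxels) or as a maximum-overlap
variant, and maps are thresholded by Benjamini-Hochberg FDR at q = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .decoding import DecodingResult


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class SubjectDiscriminativeMap:
    """Per-subject signed voxel weights with ranks and optional selection."""

    subject_id: str
    roi_name: str
    weight: np.ndarray
    rank: np.ndarray  # 1 = largest |weight|; a permutation of 1..V
    selected: Optional[np.ndarray] = None
    selection_fraction: Optional[float] = None

    @property
    def n_voxels(self) -> int:
        return len(self.weight)

    @property
    def sign(self) -> np.ndarray:
        """+1 where the voxel prefers vitality, -1 where it prefers velocity."""
        return np.where(self.weight >= 0, 1, -1)


def rank_discriminative_voxels(
    results: DecodingResult | Sequence[DecodingResult],
) -> SubjectDiscriminativeMap:
    """Fold-averaged (and contrast-collapsed) signed weights, ranked by |w|.

    Pass a single DecodingResult or the three cross-task results of one
    subject/ROI to collapse contrasts by averaging their signed weights before
    ranking.  Ties are broken by voxel id.
    """
    if isinstance(results, DecodingResult):
        results = [results]
    if not results:
        raise ValueError("need at least one decoding result")
    ref = results[0]
    stacks = []
    for r in results:
        if r.roi_name != ref.roi_name or r.subject_id != ref.subject_id:
            raise ValueError("results must share subject and ROI")
        if not r.fold_weights:
            raise ValueError("decoding result has no trained weight maps")
        stacks.append(np.mean(np.vstack(r.fold_weights), axis=0))
    weight = np.mean(np.vstack(stacks), axis=0)
    order = np.lexsort((np.arange(len(weight)), -np.abs(weight)))
    rank = np.empty(len(weight), dtype=int)
    rank[order] = np.arange(1, len(weight) + 1)
    return SubjectDiscriminativeMap(
        subject_id=ref.subject_id, roi_name=ref.roi_name, weight=weight, rank=rank
    )


def select_top_fraction(m: SubjectDiscriminativeMap, f: float) -> SubjectDiscriminativeMap:
    """Select exactly round(f * V) top-ranked voxels."""
    if not (0 < f <= 1):
        raise ValueError("selection fraction must lie in (0, 1]")
    n_sel = _round_half_up(f * m.n_voxels)
    return replace(m, selected=m.rank <= n_sel, selection_fraction=f)


@dataclass(frozen=True)
class GroupOverlapMap:
    """Per-voxel signed subject-overlap counts (optionally with inference)."""

    roi_name: str
    overlap_pos: np.ndarray
    overlap_neg: np.ndarray
    n_subjects: int
    selection_fraction: float
    p_values: Optional[np.ndarray] = None
    fdr_mask: Optional[np.ndarray] = None
    q: float = 0.05

    @property
    def overlap_total(self) -> np.ndarray:
        return self.overlap_pos + self.overlap_neg

    @property
    def group_sign(self) -> np.ndarray:
        """Sign with the larger overlap count (+1 vitality, -1 velocity)."""
        return np.where(self.overlap_pos >= self.overlap_neg, 1, -1)

    @property
    def min_surviving_overlap(self) -> Optional[int]:
        if self.fdr_mask is None or not self.fdr_mask.any():
            return None
        return int(self.overlap_total[self.fdr_mask].min())


def group_overlap(maps: Sequence[SubjectDiscriminativeMap]) -> GroupOverlapMap:
    """Count, per voxel, the subjects selecting it with each sign."""
    if not maps:
        raise ValueError("need at least one subject map")
    v = maps[0].n_voxels
    f = maps[0].selection_fraction
    pos = np.zeros(v, dtype=int)
    neg = np.zeros(v, dtype=int)
    for m in maps:
        if m.selected is None:
            raise ValueError("subject maps must be thresholded first")
        if m.n_voxels != v:
            raise ValueError("subject maps must share the voxel space")
        pos += m.selected & (m.sign > 0)
        neg += m.selected & (m.sign < 0)
    return GroupOverlapMap(
        roi_name=maps[0].roi_name,
        overlap_pos=pos,
        overlap_neg=neg,
        n_subjects=len(maps),
        selection_fraction=f,
    )


@dataclass(frozen=True)
class OverlapNull:
    """Tail probabilities of the subject-overlap count under independence."""

    method: str  # "monte_carlo", "binomial" or "monte_carlo_max"
    n_subjects: int
    selection_fraction: float
    tail: np.ndarray  # tail[k] = P(overlap >= k), k = 0..S
    n_iterations: Optional[int] = None

    def p_value(self, k: np.ndarray | int) -> np.ndarray | float:
        return self.tail[np.asarray(k)] if np.ndim(k) else float(self.tail[int(k)])


def binomial_overlap_pvalue(k: int, s: int, f: float) -> float:
    """Exact P(X >= k) for X ~ Binomial(S, f): the independence null."""
    if not (0 <= k <= s):
        raise ValueError("k must lie in [0, S]")
    return float(binom.sf(k - 1, s, f))


def binomial_overlap_null(s: int, f: float) -> OverlapNull:
    tail = np.array([binomial_overlap_pvalue(k, s, f) for k in range(s + 1)])
    return OverlapNull("binomial", s, f, tail)


def monte_carlo_overlap_null(
    v: int, s: int, f: float, n_iter: int = 10_000, seed: int = 0
) -> OverlapNull:
    """Monte Carlo independence null of the per-voxel overlap count.

    Each iteration draws round(f*V) voxels uniformly without replacement for
    every subject and records the per-voxel overlap; tail probabilities pool
    counts over voxels: tail[k] = (1 + #{voxel-iterations with overlap >= k})
    / (n_iter * V + 1).  The companion maximum-statistic null (tail of the
    map-wise maximum overlap) is returned via ``monte_carlo_max_overlap_null``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not (0 < f <= 1):
        raise ValueError("selection fraction must lie in (0, 1]")
    n_sel = _round_half_up(f * v)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF5]))
    hist = np.zeros(s + 1, dtype=np.int64)
    max_hist = np.zeros(s + 1, dtype=np.int64)
    for _ in range(n_iter):
        u = rng.random((s, v))
        thresh = np.partition(u, n_sel - 1, axis=1)[:, n_sel - 1 : n_sel]
        overlap = (u <= thresh).sum(axis=0)
        hist += np.bincount(overlap, minlength=s + 1)
        max_hist[overlap.max()] += 1
    pooled_ge = np.cumsum(hist[::-1])[::-1]
    tail = (1.0 + pooled_ge) / (n_iter * v + 1.0)
    max_ge = np.cumsum(max_hist[::-1])[::-1]
    max_tail = (1.0 + max_ge) / (n_iter + 1.0)
    null = OverlapNull("monte_carlo", s, f, tail, n_iterations=n_iter)
    object.__setattr__(null, "_max_tail", max_tail)
    return null


def monte_carlo_max_overlap_null(
    v: int, s: int, f: float, n_iter: int = 10_000, seed: int = 0
) -> OverlapNull:
    """Family-wise null: tail of the maximum overlap count across the map."""
    base = monte_carlo_overlap_null(v, s, f, n_iter=n_iter, seed=seed)
    return OverlapNull("monte_carlo_max", s, f, base._max_tail, n_iterations=n_iter)


def fdr_threshold(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up: boolean mask of surviving tests."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("p_values must be non-empty")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def group_map_inference(
    gmap: GroupOverlapMap, null: OverlapNull, q: float = 0.05
) -> GroupOverlapMap:
    """Attach per-voxel overlap p-values and the BH-FDR surviving mask."""
    if null.n_subjects != gmap.n_subjects:
        raise ValueError("null and map disagree on the number of subjects")
    p = np.asarray(null.p_value(gmap.overlap_total), dtype=float)
    mask = fdr_threshold(p, q=q)
    return replace(gmap, p_values=p, fdr_mask=mask, q=q)
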