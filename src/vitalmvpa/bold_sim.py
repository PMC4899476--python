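"""Synthetic event-related BOLD simulation with planted multivoxel task tuning.

The generator stands in for the study's undeposited fMRI data.  It builds a
voxel lattice holding four contiguous ROI blobs (left insula 1533 voxels,
right insula 1346, a white-matter control of 500 and a BA21 control of 750, at
2.5 mm isotropic), annotates insula voxels as vitality-preferring (a common,
spatially clustered population), velocity-preferring (rare, scattered) or
untuned, and synthesizes 416-volume runs at TR 2 s as

    baseline + drift + AR(1) noise + sum_trials amplitude(voxel, trial) * HRF.

Trial amplitudes (in % of the voxel's run-mean intensity) are a common evoked
response shared by every in-mask voxel plus, inside the insula, a task-tuning
pattern scaled by ``delta``, an optional level-specific pattern scaled by
``level_delta`` and trial-level noise.  The tuning pattern is mean-centered
within each ROI, so the planted effect is multivariate (pattern) information
with no univariate task difference in ROI-mean signal, and its trial-to-trial
gain fluctuates (``gain_sd``), which is what bounds decoding accuracy well
below ceiling while leaving single-voxel weight signs consistent.  Control-ROI
voxels carry the common response only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
from scipy.signal import lfilter

from .paradigm import RunDesign, TR_S, N_VOLUMES

DEFAULT_ROI_SIZES = {
    "left_insula": 1533,
    "right_insula": 1346,
    "ctrl_white_matter": 500,
    "ctrl_ba21": 750,
}
INSULA_ROIS = ("left_insula", "right_insula")
#: fractional blob centers within the lattice
_ROI_CENTERS = {
    "left_insula": (0.25, 0.28, 0.5),
    "right_insula": (0.75, 0.28, 0.5),
    "ctrl_white_matter": (0.25, 0.75, 0.5),
    "ctrl_ba21": (0.75, 0.75, 0.5),
}

UNTUNED, VITALITY_PREFERRING, VELOCITY_PREFERRING = 0, 1, 2


@dataclass(frozen=True)
class GeometryConfig:
    shape: tuple[int, int, int] = (32, 36, 24)
    voxel_size_mm: float = 2.5
    roi_sizes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_ROI_SIZES))

    def scaled(self, factor: float) -> "GeometryConfig":
        """A reduced-resolution variant with ROI sizes scaled by ``factor``."""
        sizes = {k: max(8, int(round(v * factor))) for k, v in self.roi_sizes.items()}
        lin = max(0.25, factor ** (1.0 / 3.0))
        shape = tuple(max(10, int(round(s * lin))) for s in self.shape)
        return replace(self, shape=shape, roi_sizes=sizes)


@dataclass(frozen=True)
class SignalConfig:
    """Planted multivoxel signal structure (amplitudes in % signal units)."""

    delta: float = 0.75  # task-contrast amplitude; calibrated by cohort simulation
    frac_vitality_voxels: float = 0.25
    frac_velocity_voxels: float = 0.05
    level_delta: float = 0.0  # 0 reproduces within-task chance decoding
    pattern_jitter_sd: float = 0.2
    gain_sd: float = 2.86  # shared per-trial gain on the tuning pattern
    common_amplitude: float = 1.0
    cluster_displacement_sd_vox: float = 0.25

    def __post_init__(self) -> None:
        if self.delta < 0 or self.level_delta < 0:
            raise ValueError("delta and level_delta must be >= 0")
        if self.frac_vitality_voxels + self.frac_velocity_voxels > 1:
            raise ValueError("tuned-voxel fractions must sum to <= 1")


@dataclass(frozen=True)
class NoiseConfig:
    white_sd: float = 4.0
    ar1_coeff: float = 0.35
    drift_amplitude: float = 6.0
    baseline_level: float = 1000.0

    def __post_init__(self) -> None:
        if not (0 <= self.ar1_coeff < 1):
            raise ValueError("ar1_coeff must lie in [0, 1)")

    @classmethod
    def silent(cls) -> "NoiseConfig":
        """Noise-free configuration (for exact round-trip checks)."""
        return cls(white_sd=0.0, ar1_coeff=0.0, drift_amplitude=0.0)


@dataclass(frozen=True)
class ROISet:
    """ROI geometry plus the per-subject tuning annotation of insula voxels."""

    shape: tuple[int, int, int]
    voxel_size_mm: float
    masks: Mapping[str, np.ndarray]  # name -> (N, 3) int voxel coordinates
    signal_annotation: Mapping[str, np.ndarray]  # insula name -> per-voxel code
    pattern_seed: int  # subject-stable seed for pattern structure

    def mask_flat(self, name: str) -> np.ndarray:
        c = self.masks[name]
        return np.ravel_multi_index((c[:, 0], c[:, 1], c[:, 2]), self.shape)

    @property
    def union_order(self) -> tuple[str, ...]:
        return tuple(self.masks)


def _blob(shape: tuple[int, int, int], center: np.ndarray, n: int) -> np.ndarray:
    """The n lattice voxels nearest ``center`` (a contiguous near-sphere)."""
    grid = np.indices(shape).reshape(3, -1).T
    d2 = ((grid - center) ** 2).sum(axis=1)
    # stable tie-break by flat index keeps blobs deterministic
    idx = np.lexsort((np.arange(len(grid)), d2))[:n]
    return grid[np.sort(idx)]


def build_geometry(
    config: GeometryConfig = GeometryConfig(),
    signal: SignalConfig = SignalConfig(),
    seed: int = 0,
) -> ROISet:
    """Build disjoint ROI blobs and the per-subject tuning annotation.

    Vitality-preferring voxels form a contiguous ("dorso-central") cluster at
    a canonical within-insula location shared across subjects up to a random
    displacement of sd ``cluster_displacement_sd_vox``; velocity-preferring
    voxels are rare and scattered at subject-specific positions.
    """
    shape = tuple(config.shape)
    n_lattice = int(np.prod(shape))
    if sum(config.roi_sizes.values()) > n_lattice:
        raise ValueError("requested mask sizes do not fit in the lattice")
    masks: dict[str, np.ndarray] = {}
    for name, size in config.roi_sizes.items():
        center = np.array([f * (s - 1) for f, s in zip(_ROI_CENTERS[name], shape)])
        masks[name] = _blob(shape, center, size)
    flat = [
        np.ravel_multi_index((m[:, 0], m[:, 1], m[:, 2]), shape) for m in masks.values()
    ]
    allv = np.concatenate(flat)
    if len(np.unique(allv)) != len(allv):
        raise ValueError("ROI masks overlap; enlarge the lattice")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA0]))
    annotation: dict[str, np.ndarray] = {}
    for name in INSULA_ROIS:
        coords = masks[name]
        v = len(coords)
        n_vit = int(round(signal.frac_vitality_voxels * v))
        n_vel = int(round(signal.frac_velocity_voxels * v))
        ann = np.full(v, UNTUNED, dtype=np.int8)
        # canonical cluster center: dorsal (+z) off-center within the mask
        c = coords.mean(axis=0) + np.array([0.0, 0.0, 0.15 * shape[2]])
        c = c + rng.normal(0.0, signal.cluster_displacement_sd_vox, size=3)
        d2 = ((coords - c) ** 2).sum(axis=1)
        order = np.lexsort((np.arange(v), d2))
        ann[order[:n_vit]] = VITALITY_PREFERRING
        rest = np.flatnonzero(ann == UNTUNED)
        ann[rng.choice(rest, size=n_vel, replace=False)] = VELOCITY_PREFERRING
        annotation[name] = ann
    return ROISet(
        shape=shape,
        voxel_size_mm=config.voxel_size_mm,
        masks=masks,
        signal_annotation=annotation,
        pattern_seed=int(seed),
    )


# ---------------------------------------------------------------------------
# hemodynamics
# ---------------------------------------------------------------------------

#: kernel support (s); compact so that with the minimum 14 s onset spacing a
#: trial's estimation window holds no signal from neighbouring trials
HRF_SUPPORT_S = 10.0


def canonical_hrf(tr_s: float = TR_S, duration_s: float = 2.0) -> np.ndarray:
    """Double-gamma HRF convolved with a boxcar of ``duration_s``, at TR.

    The impulse response is the standard double-gamma (peak delay 6 s,
    undershoot delay 16 s, 1:6 ratio), smoothly tapered to zero at 10 s so the
    response to a 2 s event has compact support < 12 s.  The sampled event
    response is normalized to unit peak; its maximum falls near 5 s.
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    if duration_s < 0:
        raise ValueError("duration_s must be >= 0")
    from scipy.stats import gamma

    dt = 0.05
    t = np.arange(0.0, HRF_SUPPORT_S, dt)
    h = gamma.pdf(t, 6.0) - gamma.pdf(t, 16.0) / 6.0
    taper = np.clip((HRF_SUPPORT_S - t) / (HRF_SUPPORT_S - 7.0), 0.0, 1.0)
    h = h * np.where(t < 7.0, 1.0, 0.5 - 0.5 * np.cos(np.pi * taper))
    if duration_s > 0:
        box = np.ones(max(1, int(round(duration_s / dt))))
        resp = np.convolve(h, box) * dt
    else:
        resp = h
    n_out = int(np.ceil((HRF_SUPPORT_S + duration_s) / tr_s))
    samples = resp[(np.arange(n_out) * tr_s / dt).round().astype(int).clip(0, len(resp) - 1)]
    return samples / samples.max()


@dataclass(frozen=True)
class BOLDRun:
    """One simulated 4-D run plus its embedded ground truth."""

    data: np.ndarray  # (x, y, z, t)
    run_index: int
    subject_id: str
    seed: int
    tr_s: float = TR_S
    n_volumes: int = N_VOLUMES
    #: per-trial, per-mask-voxel embedded amplitudes (% of run mean), in the
    #: concatenated mask order of ``truth_rois``
    truth_amplitudes: Optional[np.ndarray] = None
    truth_rois: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.data.shape[-1] != self.n_volumes:
            raise ValueError("time dimension must equal n_volumes")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data must be finite")


def _subject_patterns(rois: ROISet, sig: SignalConfig) -> dict[str, dict[str, np.ndarray]]:
    """Subject-stable tuning and level patterns, zero-mean within each ROI.

    The task-tuning pattern is a push-pull preference axis supported only on
    tuned voxels: +1 on vitality-preferring voxels and -n_vit/n_vel on
    velocity-preferring ones (so the ROI-mean modulation is exactly zero and
    untuned voxels carry no systematic task signal).  Trials modulate this
    axis by +(delta + gain)/2 under the vitality task and -(delta + gain)/2
    under the velocity task.
    """
    rng = np.random.default_rng(np.random.SeedSequence([rois.pattern_seed, 0xB1]))
    out: dict[str, dict[str, np.ndarray]] = {}
    for name in INSULA_ROIS:
        ann = rois.signal_annotation[name]
        p_vit = (ann == VITALITY_PREFERRING).astype(float)
        p_vel = (ann == VELOCITY_PREFERRING).astype(float)
        axis = p_vit.copy()
        if p_vel.sum() > 0:
            axis -= p_vel * (p_vit.sum() / p_vel.sum())
        elif p_vit.sum() > 0:
            axis -= p_vit.mean()
        levels = {
            lvl: rng.choice([-1.0, 1.0], size=len(ann)) for lvl in (1, 2, 3)
        }
        out[name] = {
            "task_axis": axis,
            **{f"level{l}": p - p.mean() for l, p in levels.items()},
        }
    return out


def trial_amplitudes(
    design: RunDesign, rois: ROISet, sig: SignalConfig, seed: int
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Embedded amplitude matrix (n_trials x n_mask_voxels, % of run mean).

    Rows cover all 50 events (catch trials evoke responses too); columns are
    the concatenation of the ROI masks in ``rois.union_order``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC2]))
    patterns = _subject_patterns(rois, sig)
    order = rois.union_order
    sizes = [len(rois.masks[n]) for n in order]
    offsets = dict(zip(order, np.concatenate([[0], np.cumsum(sizes)])))
    n_trials = len(design.events)
    amp = np.full((n_trials, sum(sizes)), float(sig.common_amplitude))

    gains = rng.normal(0.0, sig.gain_sd, size=n_trials)
    task_sign = 1.0 if design.task == "vitality" else -1.0
    for name in INSULA_ROIS:
        sl = slice(offsets[name], offsets[name] + len(rois.masks[name]))
        axis = patterns[name]["task_axis"]
        for i, ev in enumerate(design.events):
            amp[i, sl] += task_sign * (sig.delta + gains[i]) / 2.0 * axis
            if sig.level_delta:
                amp[i, sl] += sig.level_delta * patterns[name][f"level{ev.level}"]
    if sig.pattern_jitter_sd:
        amp += rng.normal(0.0, sig.pattern_jitter_sd, size=amp.shape)
    return amp, order


def _event_regressors(design: RunDesign) -> np.ndarray:
    """(n_volumes x n_trials) matrix of unit-amplitude event responses."""
    kernel = canonical_hrf(design.tr_s, 2.0)
    R = np.zeros((design.n_volumes, len(design.events)))
    for i, ev in enumerate(design.events):
        v0 = ev.onset_volume
        k = kernel[: design.n_volumes - v0]
        R[v0 : v0 + len(k), i] = k
    return R


def simulate_run(
    design: RunDesign,
    rois: ROISet,
    sig: SignalConfig = SignalConfig(),
    noise: NoiseConfig = NoiseConfig(),
    seed: int = 0,
) -> BOLDRun:
    """Simulate one 4-D BOLD run with the planted amplitude structure.

    Amplitudes are defined in % of the voxel's run-mean intensity; the
    baseline is solved per voxel (M = B / (1 - mean evoked mass)) so that with
    noise off the percent-scaled single-trial estimator recovers the embedded
    amplitudes exactly.  Voxels outside every mask stay at zero.
    """
    amp, order = trial_amplitudes(design, rois, sig, seed)
    R = _event_regressors(design)  # (T, n_trials)
    s_pct = R @ amp  # (T, V) evoked % time courses
    mean_mass = s_pct.mean(axis=0)  # per-voxel mean evoked % over the run
    if np.any(mean_mass >= 100.0):
        raise ValueError("evoked mass too large for percent scaling")
    run_mean = noise.baseline_level / (1.0 - mean_mass / 100.0)
    series = noise.baseline_level + run_mean * s_pct / 100.0  # (T, V)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD3]))
    T, V = series.shape
    if noise.white_sd > 0:
        innov = rng.normal(0.0, noise.white_sd, size=(T, V))
        if noise.ar1_coeff > 0:
            innov *= np.sqrt(1.0 - noise.ar1_coeff**2)
            series = series + lfilter([1.0], [1.0, -noise.ar1_coeff], innov, axis=0)
        else:
            series = series + innov
    if noise.drift_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi, size=V)
        t = np.arange(T)[:, None]
        drift = noise.drift_amplitude * np.cos(2 * np.pi * t / T + phase[None, :])
        series = series + (drift - drift.mean(axis=0, keepdims=True))

    data = np.zeros(rois.shape + (design.n_volumes,))
    col = 0
    for name in order:
        c = rois.masks[name]
        n = len(c)
        data[c[:, 0], c[:, 1], c[:, 2], :] = series[:, col : col + n].T
        col += n
    return BOLDRun(
        data=data,
        run_index=design.run_index,
        subject_id="",
        seed=int(seed),
        tr_s=design.tr_s,
        n_volumes=design.n_volumes,
        truth_amplitudes=amp,
        truth_rois=order,
    )
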