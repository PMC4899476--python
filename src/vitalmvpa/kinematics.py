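"""Kinematic analysis of the action stimuli.

The behavioral stimulus set consists of 36 reaching actions (3 objects x 12
execution times, 500-1600 ms) whose 3-D marker velocity was sampled at 100 Hz.
This module generates synthetic stand-ins for those velocity profiles
(minimum-jerk bell curves), compares them with classic dynamic time warping
(DTW), and simulates/fits the logarithmic relation between execution time and
the observers' vitality/velocity judgments on a 1-5 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

SAMPLE_RATE_HZ = 100
OBJECTS = ("bottle", "can", "jar")
#: the 12 execution times used in the behavioral study (ms)
EXEC_TIMES_MS = tuple(range(500, 1601, 100))

# fMRI-level stimuli: execution time (ms) -> path length (m), chosen so that
# mean velocity equals the printed 1.06 / 0.57 / 0.38 m/s
FMRI_PATH_LENGTH_M = {600: 0.636, 1000: 0.570, 1400: 0.532}


@dataclass(frozen=True)
class VelocityTrajectory:
    """Sampled 3-D velocity of one action stimulus.

    ``samples`` is an (n, 3) array of (vx, vy, vz) in m/s at 100 Hz with
    n = round(exec_time_ms / 10).
    """

    samples: np.ndarray
    exec_time_ms: int
    object_label: str
    duration_level: int

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 2 or s.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array")
        if not np.all(np.isfinite(s)):
            raise ValueError("velocity samples must be finite")
        expected = round(self.exec_time_ms / 1000 * SAMPLE_RATE_HZ)
        if s.shape[0] != expected:
            raise ValueError(
                f"expected {expected} samples at {SAMPLE_RATE_HZ} Hz for "
                f"{self.exec_time_ms} ms, got {s.shape[0]}"
            )
        object.__setattr__(self, "samples", s)

    @property
    def speed(self) -> np.ndarray:
        """Modulus of the velocity, |v|, per sample."""
        return np.linalg.norm(self.samples, axis=1)

    def channel(self, mode: str) -> np.ndarray:
        if mode == "modulus":
            return self.speed
        try:
            return self.samples[:, ("vx", "vy", "vz").index(mode)]
        except ValueError:
            raise ValueError(f"unknown channel mode {mode!r}") from None


def duration_level_of(exec_time_ms: int) -> int:
    """Map an execution time on the 500..1600 ms grid to its level 1..12."""
    if exec_time_ms not in EXEC_TIMES_MS:
        raise ValueError(f"{exec_time_ms} ms is not on the 500..1600 ms grid")
    return EXEC_TIMES_MS.index(exec_time_ms) + 1


def generate_velocity_profile(
    exec_time_ms: int,
    path_length_m: float,
    seed: int = 0,
    object_label: str = "bottle",
) -> VelocityTrajectory:
    """Generate a bell-shaped (minimum-jerk) 3-D velocity profile.

    The speed profile is the minimum-jerk form s(tau) = 30 L/T tau^2 (1-tau)^2,
    single-peaked with the peak at mid-movement and near-zero endpoints,
    rescaled so that the sampled mean speed is exactly path_length / duration.
    A small deterministic object-specific modulation and a seeded jitter of the
    movement direction make the three objects distinguishable without changing
    the mean speed.
    """
    if exec_time_ms <= 0 or not (500 <= exec_time_ms <= 1600):
        raise ValueError("exec_time_ms must lie in [500, 1600]")
    if path_length_m <= 0:
        raise ValueError("path_length_m must be positive")
    if object_label not in OBJECTS:
        raise ValueError(f"object_label must be one of {OBJECTS}")

    n = round(exec_time_ms / 1000 * SAMPLE_RATE_HZ)
    duration_s = exec_time_ms / 1000.0
    tau = (np.arange(n) + 0.5) / n
    speed = 30.0 * path_length_m / duration_s * tau**2 * (1.0 - tau) ** 2

    # object-specific shape modulation (a few percent), then renormalize so
    # that mean sampled speed * duration = path length exactly
    obj_idx = OBJECTS.index(object_label)
    speed = speed * (1.0 + 0.03 * (obj_idx - 1) * np.cos(2 * np.pi * tau))
    speed = np.clip(speed, 0.0, None)
    speed *= path_length_m / (speed.mean() * duration_s)

    # direction: predominantly +y reach with a gentle arc; the seed jitters the
    # arc phase only, leaving |v| untouched
    rng = np.random.default_rng(seed)
    phase = 0.1 * rng.standard_normal()
    arc = 0.15 * np.sin(np.pi * tau + phase) + 0.05 * (obj_idx - 1)
    lift = 0.08 * np.sin(2 * np.pi * tau)
    direction = np.stack([arc, np.ones(n), lift], axis=1)
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)

    samples = speed[:, None] * direction
    level = duration_level_of(exec_time_ms) if exec_time_ms in EXEC_TIMES_MS else 1
    return VelocityTrajectory(samples, exec_time_ms, object_label, level)


def generate_stimulus_set(seed: int = 0, mean_speed_m_s: float = 0.57) -> list[VelocityTrajectory]:
    """Generate the full 36-stimulus set (3 objects x 12 execution times).

    All stimuli share the same path length (the same reach performed at
    different speeds), set so the 1000 ms action has the given mean speed.
    """
    path_length = mean_speed_m_s * 1.0
    out = []
    for i, t_ms in enumerate(EXEC_TIMES_MS):
        for j, obj in enumerate(OBJECTS):
            out.append(
                generate_velocity_profile(
                    t_ms, path_length, seed=seed * 1000 + i * 10 + j, object_label=obj
                )
            )
    return out


# ---------------------------------------------------------------------------
# dynamic time warping
# ---------------------------------------------------------------------------

def dtw_distance(a: Sequence[float], b: Sequence[float], normalize: bool = False) -> float:
    """Classic dynamic-programming DTW distance between two 1-D series.

    Local cost |a_i - b_j|; symmetric step pattern (insert, delete, match) with
    no step weights; boundary D(0,0) = cost(0,0); returns the terminal
    cumulative cost, unnormalized by default.  With ``normalize=True`` the
    terminal cost is divided by (len(a) + len(b)).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("series must be non-empty")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("series must be finite")

    cost = np.abs(a[:, None] - b[None, :])
    n, m = cost.shape
    D = np.full((n, m), np.inf)
    D[0, 0] = cost[0, 0]
    D[0, 1:] = np.cumsum(cost[0, 1:]) + cost[0, 0]
    D[1:, 0] = np.cumsum(cost[1:, 0]) + cost[0, 0]
    for i in range(1, n):
        row = D[i - 1]
        prev = D[i, 0]
        ci = cost[i]
        for j in range(1, m):
            prev = ci[j] + min(row[j], row[j - 1], prev)
            D[i, j] = prev
    d = float(D[-1, -1])
    return d / (n + m) if normalize else d


@dataclass(frozen=True)
class DTWDistanceMatrix:
    """Pairwise DTW distances among the 36 stimuli."""

    distances: np.ndarray
    labels: tuple[tuple[str, int], ...]  # (object_label, duration_level)
    mode: str = "modulus"

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if np.any(d < 0) or not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
            raise ValueError("distances must be symmetric, non-negative, zero-diagonal")
        object.__setattr__(self, "distances", d)
        object.__setattr__(self, "labels", tuple(self.labels))


def pairwise_dtw_matrix(
    trajs: Sequence[VelocityTrajectory], mode: str = "modulus", normalize: bool = False
) -> DTWDistanceMatrix:
    """DTW distance matrix over the 36-stimulus set on the selected channel."""
    labels = [(t.object_label, t.duration_level) for t in trajs]
    if len(trajs) != 36:
        raise ValueError(f"expected exactly 36 trajectories, got {len(trajs)}")
    if len(set(labels)) != 36:
        raise ValueError("duplicate (object, duration_level) labels")
    series = [t.channel(mode) for t in trajs]
    d = np.zeros((36, 36))
    for i in range(36):
        for j in range(i + 1, 36):
            d[i, j] = d[j, i] = dtw_distance(series[i], series[j], normalize=normalize)
    return DTWDistanceMatrix(d, tuple(labels), mode=mode)


@dataclass(frozen=True)
class GroupingReport:
    mean_within_level: float
    mean_between_level: float

    @property
    def grouped_by_duration(self) -> bool:
        """True iff same-duration stimuli are mutually closer than different-duration ones."""
        return self.mean_within_level < self.mean_between_level


def duration_grouping_check(m: DTWDistanceMatrix) -> GroupingReport:
    """Compare mean DTW distance within vs. between duration levels."""
    levels = np.array([lvl for _, lvl in m.labels])
    same = levels[:, None] == levels[None, :]
    off = ~np.eye(len(levels), dtype=bool)
    within = m.distances[same & off]
    between = m.distances[~same]
    return GroupingReport(float(within.mean()), float(between.mean()))


# ---------------------------------------------------------------------------
# behavioral judgments
# ---------------------------------------------------------------------------

#: generating parameters reproducing the observed mean scores
#: (velocity judgments shifted above vitality judgments on the 1-5 scale)
DEFAULT_JUDGMENT_PARAMS: Mapping[str, tuple[float, float]] = {
    "vitality": (20.44, -2.58),
    "velocity": (20.61, -2.58),
}


def simulate_judgments(
    params: Mapping[str, tuple[float, float]] | None = None,
    noise_sd: float = 0.4,
    n_subjects: int = 18,
    seed: int = 0,
    exec_times_ms: Iterable[int] = EXEC_TIMES_MS,
) -> pd.DataFrame:
    """Simulate per-subject vitality/velocity judgment scores.

    For each task the deterministic score is clip(a + b*ln(exec_time), 1, 5)
    and subject-level Gaussian noise of sd ``noise_sd`` is added on top.
    Returns a tidy table (subject_id, task, exec_time_ms, score).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    params = dict(DEFAULT_JUDGMENT_PARAMS if params is None else params)
    rng = np.random.default_rng(seed)
    rows = []
    for task, (a, b) in params.items():
        for t_ms in exec_times_ms:
            mu = float(np.clip(a + b * np.log(t_ms), 1.0, 5.0))
            scores = mu + noise_sd * rng.standard_normal(n_subjects)
            for s, sc in enumerate(scores):
                rows.append((s, task, int(t_ms), float(sc)))
    return pd.DataFrame(rows, columns=["subject_id", "task", "exec_time_ms", "score"])


def fit_log_judgment(judgments: pd.DataFrame, task: str) -> tuple[float, float, float]:
    """OLS fit of mean judgment score on ln(execution time).

    Returns (intercept, slope, R^2).  Mean scores are taken per execution time
    across subjects before fitting, which is the regression actually reported
    for the judgment curves.
    """
    sub = judgments[judgments["task"] == task]
    if sub.empty:
        raise ValueError(f"no rows for task {task!r}")
    means = sub.groupby("exec_time_ms")["score"].mean()
    if len(means) < 2:
        raise ValueError("need >=2 distinct execution times to fit")
    x = sm.add_constant(np.log(means.index.to_numpy(dtype=float)))
    fit = sm.OLS(means.to_numpy(), x).fit()
    return float(fit.params[0]), float(fit.params[1]), float(fit.rsquared)
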