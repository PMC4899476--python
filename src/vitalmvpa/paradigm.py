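"""Event-related scan design generation.

One scanning session has four runs: the first two under the vitality task
(judge the action's style: rude / neutral / gentle) and the last two under the
velocity task (judge its speed: fast / medium / slow).  Each run presents 50
video clips of 2 s (45 experimental + 5 catch trials) separated by a jittered
12-16 s fixation interval, within 416 volumes at TR = 2 s.  The 45
experimental trials cover 3 objects x 3 levels x 5 repetitions, so each level
contributes 15 decodable trials per run; catch trials (followed by an explicit
question 0.5 s after the 2 s video) are flagged and excluded from decoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

TR_S = 2.0
N_VOLUMES = 416
INITIAL_FIXATION_S = 12.0
EVENT_DURATION_S = 2.0
ISI_CHOICES_S = (12.0, 14.0, 16.0)
N_EXPERIMENTAL = 45
N_CATCH = 5
TASKS = ("vitality", "velocity")
TASK_OF_RUN = {1: "vitality", 2: "vitality", 3: "velocity", 4: "velocity"}
OBJECTS = ("bottle", "can", "jar")
LEVELS = (1, 2, 3)  # 1 = rude/fast, 2 = neutral/medium, 3 = gentle/slow
LEVEL_NAMES = {
    "vitality": {1: "rude", 2: "neutral", 3: "gentle"},
    "velocity": {1: "fast", 2: "medium", 3: "slow"},
}
#: post-onset volumes needed by the trial estimation window
_WINDOW_POST_VOLUMES = 5


@dataclass(frozen=True)
class TrialEvent:
    onset_s: float
    task: str
    level: int
    object_label: str
    is_catch: bool
    duration_s: float = EVENT_DURATION_S
    question_onset_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError("onset_s must be non-negative")
        if self.duration_s != EVENT_DURATION_S:
            raise ValueError(f"events last {EVENT_DURATION_S} s")
        if self.is_catch != (self.question_onset_s is not None):
            raise ValueError("question_onset_s present iff is_catch")
        if self.is_catch and not np.isclose(
            self.question_onset_s - self.onset_s, EVENT_DURATION_S + 0.5
        ):
            raise ValueError("question follows video onset by 2 s + 0.5 s")

    @property
    def trial_type(self) -> str:
        return LEVEL_NAMES[self.task][self.level]

    @property
    def onset_volume(self) -> int:
        return int(self.onset_s // TR_S)


@dataclass(frozen=True)
class RunDesign:
    run_index: int
    task: str
    events: tuple[TrialEvent, ...]
    tr_s: float = TR_S
    n_volumes: int = N_VOLUMES
    initial_fixation_s: float = INITIAL_FIXATION_S

    def __post_init__(self) -> None:
        if self.task != TASK_OF_RUN[self.run_index]:
            raise ValueError(
                f"run {self.run_index} must be a {TASK_OF_RUN[self.run_index]} run"
            )
        ev = self.events
        n_catch = sum(e.is_catch for e in ev)
        if len(ev) != N_EXPERIMENTAL + N_CATCH or n_catch != N_CATCH:
            raise ValueError("a run has 45 experimental + 5 catch events")
        onsets = np.array([e.onset_s for e in ev])
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("events must be strictly ordered")
        gaps = np.diff(onsets) - EVENT_DURATION_S
        if np.any(gaps < min(ISI_CHOICES_S) - 1e-9) or np.any(gaps > max(ISI_CHOICES_S) + 1e-9):
            raise ValueError("inter-trial intervals must lie in [12, 16] s")
        last = ev[-1].onset_volume + _WINDOW_POST_VOLUMES
        if last > self.n_volumes - 1:
            raise ValueError("last trial window exceeds the run")

    @property
    def experimental_events(self) -> tuple[TrialEvent, ...]:
        return tuple(e for e in self.events if not e.is_catch)


@dataclass(frozen=True)
class ScanDesign:
    subject_id: str
    runs: tuple[RunDesign, ...]
    seed: int

    def __post_init__(self) -> None:
        if tuple(r.run_index for r in self.runs) != (1, 2, 3, 4):
            raise ValueError("a session has runs 1..4 in order")


def _child_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([int(seed), *key]).generate_state(1)[0] % (2**31))


def generate_run_design(run_index: int, task: str, seed: int) -> RunDesign:
    """Generate one run's randomized event schedule.

    Conditions: each (object x level) cell appears 5 times among the 45
    experimental trials; 5 catch trials with random conditions are interleaved
    at slot positions drawn without replacement; ISIs are drawn i.i.d.
    uniformly from {12, 14, 16} s, redrawing the whole schedule if it does not
    fit within the 416 volumes.
    """
    if TASK_OF_RUN.get(run_index) != task:
        raise ValueError(f"run {run_index} cannot be a {task} run")
    rng = np.random.default_rng(seed)

    cells = [(o, l) for o in OBJECTS for l in LEVELS for _ in range(5)]
    order = rng.permutation(len(cells))
    conditions = [cells[i] for i in order]
    catch_slots = set(rng.choice(N_EXPERIMENTAL + N_CATCH, size=N_CATCH, replace=False).tolist())
    catch_conditions = [
        (OBJECTS[rng.integers(3)], LEVELS[rng.integers(3)]) for _ in range(N_CATCH)
    ]

    max_last_onset = (N_VOLUMES - 1 - _WINDOW_POST_VOLUMES) * TR_S
    for _ in range(1000):
        isis = rng.choice(ISI_CHOICES_S, size=N_EXPERIMENTAL + N_CATCH - 1)
        onsets = INITIAL_FIXATION_S + np.concatenate(
            [[0.0], np.cumsum(EVENT_DURATION_S + isis)]
        )
        if onsets[-1] <= max_last_onset:
            break
    else:  # pragma: no cover - p(single failure) ~ 0.04
        raise RuntimeError("could not fit ISI schedule in the run")

    events, exp_iter, catch_iter = [], iter(conditions), iter(catch_conditions)
    for slot, onset in enumerate(onsets):
        is_catch = slot in catch_slots
        obj, level = next(catch_iter) if is_catch else next(exp_iter)
        events.append(
            TrialEvent(
                onset_s=float(onset),
                task=task,
                level=level,
                object_label=obj,
                is_catch=is_catch,
                question_onset_s=float(onset) + EVENT_DURATION_S + 0.5 if is_catch else None,
            )
        )
    return RunDesign(run_index=run_index, task=task, events=tuple(events))


def generate_session_design(subject_id: str, seed: int) -> ScanDesign:
    """Generate the 4-run session (vitality runs 1-2, then velocity runs 3-4)."""
    runs = tuple(
        generate_run_design(r, TASK_OF_RUN[r], _child_seed(seed, r)) for r in (1, 2, 3, 4)
    )
    return ScanDesign(subject_id=subject_id, runs=runs, seed=seed)
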