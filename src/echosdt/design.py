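"""Generative model of the Echobot two-task echolocation experiment.

The experiment this package analyses presented a single loudspeaker click
per trial to a blindfolded listener seated in front of a rail-mounted
reflecting disk. Two tasks were run on separate days: *echo-detection*
(disk reflecting or not — yes/no) and *echo-localization* (reflection from
the left or the right disk). A constant-stimulus design was used: within
every session each of the 10 reflector distances appears exactly
``reps_per_distance_per_session`` times in random order, the reflector
position drawn i.i.d. per trial from task-specific probabilities. The
first day of each task is practice and excluded from analysis.

This module builds that schedule and draws observer responses from the
same Bernoulli observation model the estimation code fits (see
:func:`echosdt.sdt.p_yes`), so simulated tables have exactly the
statistical structure the analysis assumes. Trial tables are plain pandas
DataFrames in long format, one trial per row, with task-native response
labels (yes/no, left/right); signal/response indicator coding happens at
fit time.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .sdt import SdtParams, p_yes

__all__ = [
    "TASK_DETECTION",
    "TASK_LOCALIZATION",
    "TASKS",
    "STIM_LEFT",
    "STIM_RIGHT",
    "STIM_NONE",
    "RESP_YES",
    "RESP_NO",
    "RESP_LEFT",
    "RESP_RIGHT",
    "DEFAULT_DISTANCES_M",
    "TRIAL_COLUMNS",
    "ExperimentDesign",
    "ObserverParams",
    "make_design",
    "schedule_trials",
    "simulate_responses",
    "analysis_subset",
    "simulate_experiment",
    "signal_indicator",
    "response_indicator",
]

TASK_DETECTION = "detection"
TASK_LOCALIZATION = "localization"
TASKS = (TASK_DETECTION, TASK_LOCALIZATION)

STIM_LEFT = "left_reflector"
STIM_RIGHT = "right_reflector"
STIM_NONE = "no_reflector"

RESP_YES = "yes"
RESP_NO = "no"
RESP_LEFT = "left"
RESP_RIGHT = "right"

#: The 10 rail distances of the standard apparatus layout, ears to disk.
DEFAULT_DISTANCES_M = (1.00, 1.36, 1.72, 2.08, 2.44, 2.81, 3.17, 3.53, 3.89, 4.25)

TRIAL_COLUMNS = [
    "participant_id",
    "task",
    "day",
    "session",
    "trial",
    "distance_m",
    "stimulus",
    "response",
]


@dataclass(frozen=True)
class ExperimentDesign:
    """Schedule parameters of the two-task constant-stimulus experiment.

    Defaults reproduce the original design: 10 distances from 1.00 to
    4.25 m, 4 days x 10 sessions x (10 distances x 5 reps) = 2,000 trials
    per task and participant; detection stimulus probabilities
    (left, right, none) = (0.25, 0.25, 0.5); localization (left, right) =
    (0.5, 0.5); day 1 is practice.
    """

    distances_m: tuple[float, ...] = DEFAULT_DISTANCES_M
    days: int = 4
    sessions_per_day: int = 10
    reps_per_distance_per_session: int = 5
    detection_stim_probs: tuple[float, float, float] = (0.25, 0.25, 0.5)
    localization_stim_probs: tuple[float, float] = (0.5, 0.5)
    practice_days: frozenset[int] = field(default_factory=lambda: frozenset({1}))

    def __post_init__(self) -> None:
        d = np.asarray(self.distances_m, dtype=float)
        if d.size == 0 or np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise ValueError("distances_m must be strictly increasing and positive")
        for name in ("days", "sessions_per_day", "reps_per_distance_per_session"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive count")
        for name, probs, k in (
            ("detection_stim_probs", self.detection_stim_probs, 3),
            ("localization_stim_probs", self.localization_stim_probs, 2),
        ):
            p = np.asarray(probs, dtype=float)
            if p.size != k or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be {k} nonnegative values summing to 1")
        object.__setattr__(self, "practice_days", frozenset(self.practice_days))

    @property
    def trials_per_session(self) -> int:
        return len(self.distances_m) * self.reps_per_distance_per_session

    @property
    def analysis_days(self) -> tuple[int, ...]:
        return tuple(d for d in range(1, self.days + 1) if d not in self.practice_days)

    def stimulus_probs(self, task: str) -> dict[str, float]:
        if task == TASK_DETECTION:
            pl, pr, pn = self.detection_stim_probs
            return {STIM_LEFT: pl, STIM_RIGHT: pr, STIM_NONE: pn}
        if task == TASK_LOCALIZATION:
            pl, pr = self.localization_stim_probs
            return {STIM_LEFT: pl, STIM_RIGHT: pr}
        raise ValueError(f"unknown task {task!r}")


def make_design(**overrides) -> ExperimentDesign:
    """Build the default design, optionally overriding individual fields."""
    design = ExperimentDesign()
    if overrides:
        if "distances_m" in overrides:
            overrides["distances_m"] = tuple(overrides["distances_m"])
        design = replace(design, **overrides)
    return design


@dataclass(frozen=True)
class ObserverParams:
    """Generative truth for a simulated observer.

    Two forms mirror the two estimation models:

    * ``categorical`` — an arbitrary per-task d' at each distance plus one
      bias value per task.
    * ``exponential`` — d'(X) = amplitude * exp(rate * X) per task, with a
      distance-constant bias per task. The amplitude is the d' extrapolated
      to distance 0; a negative rate gives the empirically typical decay of
      sensitivity with reflector distance.

    ``lapse_rate`` mixes in stimulus-independent guessing,
    p -> lapse/2 + (1 - lapse) * p. The default 0 matches the observation
    model the estimators fit.
    """

    form: str
    amplitude: Mapping[str, float] | None = None
    rate: Mapping[str, float] | None = None
    bias: Mapping[str, float] = field(default_factory=dict)
    dprime_by_distance: Mapping[str, Mapping[float, float]] | None = None
    lapse_rate: float = 0.0

    @classmethod
    def exponential(
        cls,
        alpha0: float,
        alpha1: float,
        beta0: float,
        beta1: float,
        c0: float,
        c1: float,
        lapse_rate: float = 0.0,
    ) -> "ObserverParams":
        """Observer with d'_det(X) = alpha0*exp(alpha1*X), d'_loc(X) = beta0*exp(beta1*X)."""
        return cls(
            form="exponential",
            amplitude={TASK_DETECTION: alpha0, TASK_LOCALIZATION: beta0},
            rate={TASK_DETECTION: alpha1, TASK_LOCALIZATION: beta1},
            bias={TASK_DETECTION: c0, TASK_LOCALIZATION: c1},
            lapse_rate=lapse_rate,
        )

    @classmethod
    def categorical(
        cls,
        dprime_detection: Mapping[float, float],
        dprime_localization: Mapping[float, float],
        c_detection: float,
        c_localization: float,
        lapse_rate: float = 0.0,
    ) -> "ObserverParams":
        return cls(
            form="categorical",
            dprime_by_distance={
                TASK_DETECTION: dict(dprime_detection),
                TASK_LOCALIZATION: dict(dprime_localization),
            },
            bias={TASK_DETECTION: c_detection, TASK_LOCALIZATION: c_localization},
            lapse_rate=lapse_rate,
        )

    def dprime(self, task: str, distance_m: float) -> float:
        if self.form == "exponential":
            return float(self.amplitude[task] * np.exp(self.rate[task] * distance_m))
        table = self.dprime_by_distance[task]
        try:
            return float(table[distance_m])
        except KeyError:
            raise KeyError(
                f"categorical observer has no d' for task={task!r} at "
                f"distance {distance_m} m (grid: {sorted(table)})"
            ) from None

    def criterion(self, task: str) -> float:
        return float(self.bias[task])


def _child_rng(seed: int, participant_id: str, task: str, day: int, session: int,
               stream: int) -> np.random.Generator:
    """Deterministic per-(participant, task, day, session) generator.

    A single root seed is expanded through a SeedSequence keyed on the
    design coordinates, so any subset of the experiment can be regenerated
    in isolation. ``stream`` separates scheduling (0) from response
    simulation (1).
    """
    pid = zlib.crc32(str(participant_id).encode("utf-8"))
    task_code = TASKS.index(task)
    ss = np.random.SeedSequence([int(seed), pid, task_code, int(day), int(session), stream])
    return np.random.default_rng(ss)


def schedule_trials(
    design: ExperimentDesign, task: str, participant_id: str, seed: int
) -> pd.DataFrame:
    """Lay out one participant's full trial schedule for one task.

    Per session the distance sequence is a uniform shuffle of each design
    distance repeated ``reps_per_distance_per_session`` times; the reflector
    position is drawn i.i.d. per trial from the task's stimulus
    probabilities. Responses are left unset (NA).
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    probs = design.stimulus_probs(task)
    stim_labels = list(probs)
    stim_p = np.array([probs[s] for s in stim_labels])
    base = np.repeat(
        np.asarray(design.distances_m, float), design.reps_per_distance_per_session
    )
    n = base.size

    frames = []
    for day in range(1, design.days + 1):
        for session in range(1, design.sessions_per_day + 1):
            rng = _child_rng(seed, participant_id, task, day, session, stream=0)
            distances = rng.permutation(base)
            stimuli = rng.choice(stim_labels, size=n, p=stim_p)
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": participant_id,
                        "task": task,
                        "day": day,
                        "session": session,
                        "trial": np.arange(1, n + 1),
                        "distance_m": distances,
                        "stimulus": stimuli,
                        "response": pd.Series([pd.NA] * n, dtype="object"),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def signal_indicator(trials: pd.DataFrame) -> np.ndarray:
    """S-coding of the stimulus: detection S=1 iff any reflector was
    presented; localization S=1 iff the left reflector was (left is
    arbitrarily the "signal" side)."""
    det = trials["task"].to_numpy() == TASK_DETECTION
    stim = trials["stimulus"].to_numpy()
    return np.where(det, stim != STIM_NONE, stim == STIM_LEFT).astype(int)


def response_indicator(trials: pd.DataFrame) -> np.ndarray:
    """y-coding of the response: detection y=1 iff "yes"; localization y=1
    iff "left"."""
    det = trials["task"].to_numpy() == TASK_DETECTION
    resp = trials["response"].to_numpy()
    return np.where(det, resp == RESP_YES, resp == RESP_LEFT).astype(int)


def simulate_responses(
    trials: pd.DataFrame, observer: ObserverParams, seed: int
) -> pd.DataFrame:
    """Draw responses for every trial from the Bernoulli observation model.

    Each response is an independent Bernoulli draw at probability
    ``p_yes(d'(task, distance), c(task), S)`` (optionally lapse-mixed),
    mapped back to task-native labels. Deterministic given ``seed``; the
    stream is keyed per (participant, task, day, session) like the
    scheduler's, so sub-tables simulate identically in isolation.
    """
    out = trials.copy()
    lam = float(observer.lapse_rate)
    for (pid, task, day, session), idx in out.groupby(
        ["participant_id", "task", "day", "session"], sort=False
    ).groups.items():
        block = out.loc[idx]
        s = signal_indicator(block)
        p = np.empty(len(block))
        dist = block["distance_m"].to_numpy()
        for x in np.unique(dist):
            params = SdtParams(observer.dprime(task, float(x)), observer.criterion(task))
            mask = dist == x
            p[mask & (s == 1)] = p_yes(params, 1)
            p[mask & (s == 0)] = p_yes(params, 0)
        if lam:
            p = lam / 2.0 + (1.0 - lam) * p
        rng = _child_rng(seed, pid, task, day, session, stream=1)
        y = rng.random(len(block)) < p
        if task == TASK_DETECTION:
            labels = np.where(y, RESP_YES, RESP_NO)
        else:
            labels = np.where(y, RESP_LEFT, RESP_RIGHT)
        out.loc[idx, "response"] = labels
    return out


def simulate_experiment(
    design: ExperimentDesign,
    observer: ObserverParams,
    participant_ids: Iterable[str],
    seed: int,
) -> pd.DataFrame:
    """Schedule and simulate both tasks for each participant (all days)."""
    frames = []
    for pid in participant_ids:
        for task in TASKS:
            trials = schedule_trials(design, task, pid, seed)
            frames.append(simulate_responses(trials, observer, seed))
    return pd.concat(frames, ignore_index=True)


def analysis_subset(trials: pd.DataFrame, design: ExperimentDesign) -> pd.DataFrame:
    """Drop practice-day trials (day 1 by default), keeping analysis days.

    For the default design this leaves 3 days x 10 sessions x 5 reps = 150
    trials per distance, task and participant.
    """
    keep = ~trials["day"].isin(list(design.practice_days))
    return trials.loc[keep].reset_index(drop=True)
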