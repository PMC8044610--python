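"""Trial-table and report I/O.

Trial tables are plain CSV, one trial per row, with a fixed header
(participant_id, task, day, session, trial, distance_m, stimulus,
response). Responses keep their task-native labels — yes/no for detection,
left/right for localization — and distances are serialized at two
decimals, so the files stay human-readable and round-trip byte-identically.
Validation is strict and row-numbered: unknown tokens, responses from the
wrong task, or duplicate trial keys abort the load with the offending line.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .design import (
    RESP_LEFT,
    RESP_NO,
    RESP_RIGHT,
    RESP_YES,
    STIM_LEFT,
    STIM_NONE,
    STIM_RIGHT,
    TASK_DETECTION,
    TASK_LOCALIZATION,
    TASKS,
    TRIAL_COLUMNS,
)

__all__ = [
    "TrialTableError",
    "read_trials",
    "write_trials",
    "load_config",
    "default_config",
    "write_json",
]

_STIMULI = {STIM_LEFT, STIM_RIGHT, STIM_NONE}
_RESPONSES = {
    TASK_DETECTION: {RESP_YES, RESP_NO},
    TASK_LOCALIZATION: {RESP_LEFT, RESP_RIGHT},
}


class TrialTableError(ValueError):
    """Malformed trial table; ``row`` is the 1-based file line number."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        super().__init__(message if row is None else f"row {row}: {message}")


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Serialize a trial table to CSV (stable column order, 2-decimal distances)."""
    out = trials.loc[:, TRIAL_COLUMNS].copy()
    out["distance_m"] = out["distance_m"].map(lambda x: f"{float(x):.2f}")
    for col in ("day", "session", "trial"):
        out[col] = out[col].astype(int)
    out.to_csv(path, index=False, lineterminator="\n")


def read_trials(path: str | Path) -> pd.DataFrame:
    """Load and validate a trial table.

    Raises
    ------
    TrialTableError
        Naming the offending file line for any unknown task/stimulus/
        response token, a response inconsistent with the row's task, a
        non-positive distance, or duplicate
        (participant, task, day, session, trial) keys.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != TRIAL_COLUMNS:
        raise TrialTableError(
            f"header mismatch: expected {TRIAL_COLUMNS}, got {list(df.columns)}"
        )
    # header is file line 1, first data row line 2
    for i, rec in enumerate(df.itertuples(index=False), start=2):
        if rec.task not in TASKS:
            raise TrialTableError(f"unknown task {rec.task!r}", row=i)
        if rec.stimulus not in _STIMULI:
            raise TrialTableError(f"unknown stimulus {rec.stimulus!r}", row=i)
        if rec.task == TASK_LOCALIZATION and rec.stimulus == STIM_NONE:
            raise TrialTableError(
                "localization trials cannot use the no_reflector position", row=i
            )
        if rec.response not in _RESPONSES[rec.task]:
            raise TrialTableError(
                f"response {rec.response!r} is not valid for a {rec.task} trial", row=i
            )
        try:
            if float(rec.distance_m) <= 0:
                raise ValueError
        except ValueError:
            raise TrialTableError(
                f"distance_m must be a positive decimal, got {rec.distance_m!r}", row=i
            ) from None
        for col in ("day", "session", "trial"):
            val = getattr(rec, col)
            if not val.isdigit() or int(val) < 1:
                raise TrialTableError(f"{col} must be a positive integer, got {val!r}", row=i)

    keys = df[["participant_id", "task", "day", "session", "trial"]]
    dup = keys.duplicated()
    if dup.any():
        first = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise TrialTableError("duplicate (participant, task, day, session, trial) key", row=first)

    out = df.copy()
    for col in ("day", "session", "trial"):
        out[col] = out[col].astype(int)
    out["distance_m"] = out["distance_m"].astype(float)
    return out


def default_config() -> dict[str, Any]:
    """Packaged default pipeline configuration.

    Simulates 10 participants through the full default design with a
    shared exponential observer (d'_det = 3*exp(-0.4 X), d'_loc =
    2*exp(-0.6 X), biases 0.1 / -0.2) — a moderately sensitive observer
    whose detection advantage shrinks with distance.
    """
    return {
        "seed": 1,
        "participants": [f"p{i:02d}" for i in range(1, 11)],
        "design": {},
        "observer": {
            "form": "exponential",
            "alpha0": 3.0,
            "alpha1": -0.4,
            "beta0": 2.0,
            "beta1": -0.6,
            "c0": 0.1,
            "c1": -0.2,
        },
        "sampler": {},
    }


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Load a YAML config, filling unspecified sections from the defaults."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config root must be a mapping, got {type(user).__name__}")
        for key, val in user.items():
            if key in ("design", "observer", "sampler") and isinstance(val, dict):
                merged = dict(cfg.get(key, {}))
                merged.update(val)
                cfg[key] = merged
            else:
                cfg[key] = val
    return cfg


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


def write_json(obj: Any, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2)
        fh.write("\n")
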