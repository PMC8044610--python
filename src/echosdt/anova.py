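"""Group-level 2 (Task) x 10 (Distance) repeated-measures ANOVA.

Operates on the grid of per-participant d' point estimates (posterior
medians from the categorical model): a complete participants x tasks x
distances array. The classical fully-within-subject decomposition is used:
each effect is tested against its own effect-by-subject interaction,

    F_effect = MS_effect / MS_(effect x subject),

with partial eta-squared SS_effect / (SS_effect + SS_error). No sphericity
correction is applied (degrees of freedom are reported uncorrected).
Participant exclusion (e.g. a leave-one-out re-analysis) is a caller-side
filter on the grid, not a mode of this function.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["rm_anova"]


def rm_anova(grid: np.ndarray) -> pd.DataFrame:
    """Two-way fully-within-subject ANOVA on a (subjects, tasks, distances) grid.

    Returns a frame with one row per effect (``task``, ``distance``,
    ``task:distance``) and columns ``F, df_num, df_den, partial_eta_sq,
    p_value``. The p-value is the F-distribution tail at the uncorrected
    degrees of freedom.

    Raises
    ------
    ValueError
        On missing (non-finite) cells, fewer than 2 subjects, or zero
        error variance (F undefined).
    """
    x = np.asarray(grid, dtype=float)
    if x.ndim != 3:
        raise ValueError(f"grid must be 3-D (subjects, tasks, distances), got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("grid contains missing or non-finite cells")
    n, t, d = x.shape
    if n < 2:
        raise ValueError(f"need at least 2 participants, got {n}")
    if t < 2 or d < 2:
        raise ValueError("need at least 2 levels per within-subject factor")

    m = x.mean()
    m_s = x.mean(axis=(1, 2))            # subject means
    m_t = x.mean(axis=(0, 2))            # task means
    m_d = x.mean(axis=(0, 1))            # distance means
    m_st = x.mean(axis=2)                # (subject, task)
    m_sd = x.mean(axis=1)                # (subject, distance)
    m_td = x.mean(axis=0)                # (task, distance)

    ss_task = n * d * np.sum((m_t - m) ** 2)
    ss_dist = n * t * np.sum((m_d - m) ** 2)
    ss_td = n * np.sum((m_td - m_t[:, None] - m_d[None, :] + m) ** 2)
    ss_ts = d * np.sum((m_st - m_s[:, None] - m_t[None, :] + m) ** 2)
    ss_ds = t * np.sum((m_sd - m_s[:, None] - m_d[None, :] + m) ** 2)
    resid = (
        x
        - m_st[:, :, None]
        - m_sd[:, None, :]
        - m_td[None, :, :]
        + m_s[:, None, None]
        + m_t[None, :, None]
        + m_d[None, None, :]
        - m
    )
    ss_tds = np.sum(resid**2)

    effects = [
        ("task", ss_task, (t - 1), ss_ts, (t - 1) * (n - 1)),
        ("distance", ss_dist, (d - 1), ss_ds, (d - 1) * (n - 1)),
        ("task:distance", ss_td, (t - 1) * (d - 1), ss_tds, (t - 1) * (d - 1) * (n - 1)),
    ]
    rows = []
    for name, ss_eff, df_num, ss_err, df_den in effects:
        ms_err = ss_err / df_den
        if ms_err <= 0.0:
            raise ValueError(f"zero error variance for effect {name!r}; F is undefined")
        f_val = (ss_eff / df_num) / ms_err
        rows.append(
            {
                "effect": name,
                "F": f_val,
                "df_num": df_num,
                "df_den": df_den,
                "partial_eta_sq": ss_eff / (ss_eff + ss_err),
                "p_value": float(stats.f.sf(f_val, df_num, df_den)),
            }
        )
    return pd.DataFrame(rows)
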