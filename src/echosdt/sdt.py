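"""Closed-form equal-variance signal detection theory.

The yes/no tasks analysed here (echo-detection: "was a reflecting disk
present?"; echo-localization: "was the reflection on the left?") are
summarised by two indices of the standard-normal, equal-variance SDT model:

* ``d'`` (sensitivity): the separation, in common standard-deviation units,
  between the internal-evidence distributions on signal and noise trials.
  ``d' = 0`` is chance; ``d' = 1`` corresponds to 69% correct for an
  unbiased responder.
* ``c`` (criterion / response bias): the placement of the yes/no cutoff
  relative to the midpoint between the two distributions. Negative values
  mean a yes-leaning (liberal) observer, positive a no-leaning
  (conservative) one.

Given hit rate ``H`` (proportion "yes" on signal trials) and false-alarm
rate ``F`` (proportion "yes" on noise trials), the closed forms are

    d' = Phi^-1(H) - Phi^-1(F)
    c  = -(Phi^-1(H) + Phi^-1(F)) / 2

where ``Phi`` is the standard normal CDF. These are undefined at H or F of
exactly 0 or 1, in which case estimation should fall back to the Bayesian
models in :mod:`echosdt.models`, whose priors keep the posterior proper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.special import ndtr, ndtri

__all__ = [
    "BoundaryRateError",
    "RatePair",
    "SdtParams",
    "dprime_from_rates",
    "criterion_from_rates",
    "p_yes",
    "percent_correct_unbiased",
]


class BoundaryRateError(ValueError):
    """Raised when a hit/false-alarm rate of exactly 0 or 1 is transformed.

    The probit transform diverges at the boundary; no continuity correction
    is applied. Use the Bayesian estimators in :mod:`echosdt.models`, which
    remain well defined for all-yes or all-no cells.
    """


@dataclass(frozen=True)
class RatePair:
    """Hit and false-alarm proportions from one (task, distance) cell."""

    hit_rate: float
    false_alarm_rate: float

    def __post_init__(self) -> None:
        for name in ("hit_rate", "false_alarm_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")


@dataclass(frozen=True)
class SdtParams:
    """Sensitivity and bias of an equal-variance SDT observer.

    ``d_prime`` carries no sign constraint: an observer who systematically
    responds against the stimulus (as seen for some participants at far
    distances) has negative sensitivity.
    """

    d_prime: float
    criterion: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.d_prime) and math.isfinite(self.criterion)):
            raise ValueError("d_prime and criterion must be finite")


def _checked_probits(rates: RatePair) -> tuple[float, float]:
    h, f = rates.hit_rate, rates.false_alarm_rate
    if h in (0.0, 1.0) or f in (0.0, 1.0):
        raise BoundaryRateError(
            f"closed-form SDT estimates are undefined at boundary rates "
            f"(H={h}, F={f}); fit the Bayesian model instead"
        )
    return float(ndtri(h)), float(ndtri(f))


def dprime_from_rates(rates: RatePair) -> float:
    """Sensitivity index d' = Phi^-1(H) - Phi^-1(F).

    Raises
    ------
    BoundaryRateError
        If either rate is exactly 0 or 1.
    """
    zh, zf = _checked_probits(rates)
    return zh - zf


def criterion_from_rates(rates: RatePair) -> float:
    """Response bias c = -(Phi^-1(H) + Phi^-1(F)) / 2.

    Raises
    ------
    BoundaryRateError
        If either rate is exactly 0 or 1.
    """
    zh, zf = _checked_probits(rates)
    return -0.5 * (zh + zf)


def p_yes(params: SdtParams, signal_present: int) -> float:
    """Probability of a "yes" (signal) response on a single trial.

    The trialwise Bernoulli probability of the observation model:

        p = (1 - S) * [1 - Phi(c + d'/2)] + S * [1 - Phi(c - d'/2)]

    with ``S = signal_present`` in {0, 1}. On signal trials this is the hit
    probability, on noise trials the false-alarm probability.
    """
    if signal_present not in (0, 1):
        raise ValueError(f"signal_present must be 0 or 1, got {signal_present!r}")
    d, c = params.d_prime, params.criterion
    if signal_present:
        return float(1.0 - ndtr(c - d / 2.0))
    return float(1.0 - ndtr(c + d / 2.0))


def percent_correct_unbiased(d_prime: float) -> float:
    """Percent correct of an unbiased (c = 0) observer, 100 * Phi(d'/2).

    With equal signal/noise presentation this is the average of the hit rate
    and the correct-rejection rate at c = 0; d' = 1 gives ~69%, d' = 0 gives
    exactly 50% (chance).
    """
    if not math.isfinite(d_prime):
        raise ValueError("d_prime must be finite")
    return 100.0 * float(ndtr(d_prime / 2.0))
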