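"""Localization performance metrics: quadrant error and local polar RMS error.

Polar errors are response minus target, wrapped into (-180, 180]. The
quadrant error (QE) is the percentage of responses (or probability mass)
whose absolute polar error exceeds 90 degrees; the local polar RMS error
(PE) summarizes the remaining, non-confused responses. Only responses
within |lateral| <= 30 degrees enter the scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError
from .model import PMV
from .synthetic import ResponseSet, wrap_polar_difference

__all__ = [
    "PerformanceScores",
    "polar_error",
    "actual_scores",
    "predicted_scores",
    "aggregate_scores",
]

LATERAL_LIMIT = 30.0
LOCAL_LIMIT = 90.0  # |error| strictly above this counts as quadrant error


@dataclass(frozen=True)
class PerformanceScores:
    """PE in degrees (NaN when undefined) and QE in percent."""

    pe: float
    qe: float

    def __post_init__(self):
        if not math.isnan(self.pe) and self.pe < 0:
            raise InvalidParameterError("PE must be nonnegative")
        if not 0.0 <= self.qe <= 100.0 + 1e-9:
            raise InvalidParameterError("QE must lie in [0, 100]")

    @property
    def pe_defined(self) -> bool:
        return not math.isnan(self.pe)


def polar_error(target_polar, response_polar):
    """Response minus target polar angle, wrapped into (-180, 180]."""
    return wrap_polar_difference(np.asarray(response_polar, float) - np.asarray(target_polar, float))


def actual_scores(rs: ResponseSet, lateral_limit: float = LATERAL_LIMIT) -> PerformanceScores:
    """Scores of an actual (or simulated) response set.

    QE is the percentage of eligible trials with |polar error| > 90; PE is
    the RMS polar error of the remaining trials (NaN if every trial is a
    quadrant error).
    """
    rs.require_nonempty()
    errors = np.array(
        [
            polar_error(t.polar, r.polar)
            for t, r in rs.trials
            if abs(r.lateral) <= lateral_limit + 1e-9
        ]
    )
    if errors.size == 0:
        raise InvalidParameterError(
            f"no trials within the lateral range of +/-{lateral_limit} deg"
        )
    confused = np.abs(errors) > LOCAL_LIMIT
    qe = 100.0 * confused.sum() / errors.size
    local = errors[~confused]
    pe = float(np.sqrt(np.mean(local**2))) if local.size else math.nan
    return PerformanceScores(pe=pe, qe=float(qe))


def predicted_scores(pmv: PMV, target_polar: float) -> PerformanceScores:
    """Scores implied by a PMV for one target.

    QE is the probability mass outside the local polar range (|error| > 90)
    times 100; PE is the discrete RMS expectancy of the error within the
    local range, renormalized by the local mass.
    """
    errors = polar_error(target_polar, pmv.response_angles)
    local = np.abs(errors) <= LOCAL_LIMIT
    qe = 100.0 * float(pmv.probabilities[~local].sum())
    local_mass = float(pmv.probabilities[local].sum())
    if local_mass > 0:
        pe = float(np.sqrt((pmv.probabilities[local] * errors[local] ** 2).sum() / local_mass))
    else:
        pe = math.nan
    return PerformanceScores(pe=pe, qe=qe)


def aggregate_scores(per_target) -> PerformanceScores:
    """Arithmetic mean of PE and QE across targets.

    Entries with undefined PE are excluded from the PE mean but still count
    toward the QE mean; if no entry defines a PE the aggregate PE is NaN.
    """
    per_target = list(per_target)
    if not per_target:
        raise InvalidParameterError("cannot aggregate an empty score list")
    qes = [s.qe for s in per_target]
    pes = [s.pe for s in per_target if s.pe_defined]
    pe = float(np.mean(pes)) if pes else math.nan
    return PerformanceScores(pe=pe, qe=float(np.mean(qes)))
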