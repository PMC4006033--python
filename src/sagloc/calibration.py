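"""Listener-specific uncertainty calibration.

Sweeps U over a fixed grid (default 0.1 to 4.0 in steps of 0.1), predicts
aggregate PE and QE at each value, and selects the U minimizing the squared
residual between predicted and actual (PE, QE) — PE in degrees and QE in
percent entered as plain, unweighted numbers. Ties resolve to the smaller U.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError
from .metrics import PerformanceScores, actual_scores
from .model import ModelConfig, Predictor
from .synthetic import DTFSet, Direction, ResponseSet

__all__ = ["CalibrationResult", "default_u_grid", "performance_curve", "calibrate_uncertainty"]


def default_u_grid() -> np.ndarray:
    return np.round(np.arange(0.1, 4.0 + 1e-9, 0.1), 10)


@dataclass
class CalibrationResult:
    U_grid: np.ndarray
    residuals: np.ndarray
    U_k: float
    predicted_at_U_k: PerformanceScores
    actual: PerformanceScores

    def to_dict(self) -> dict:
        return {
            "U_grid": [float(u) for u in self.U_grid],
            "residuals": [float(r) for r in self.residuals],
            "U_k": float(self.U_k),
            "predicted": {"PE": self.predicted_at_U_k.pe, "QE": self.predicted_at_U_k.qe},
            "actual": {"PE": self.actual.pe, "QE": self.actual.qe},
            "residual_weighting": "unweighted sum of squared PE (deg) and QE (%) residuals",
        }


def performance_curve(
    listener_dtf: DTFSet,
    targets: list[Direction],
    U_grid: np.ndarray | None = None,
    config: ModelConfig | None = None,
    template_dtf: DTFSet | None = None,
) -> list[tuple[float, PerformanceScores]]:
    """Predicted aggregate (PE, QE) as a function of U over a target list."""
    if U_grid is None:
        U_grid = default_u_grid()
    if len(targets) == 0:
        raise InvalidParameterError("empty target list")
    predictor = Predictor(listener_dtf, template_dtf, config)
    return [(float(U), predictor.predicted_scores(targets, float(U))) for U in U_grid]


def _unique_targets(rs: ResponseSet, lateral_limit: float = 30.0) -> list[Direction]:
    seen, out = set(), []
    for target, response in rs.trials:
        if abs(response.lateral) > lateral_limit + 1e-9:
            continue
        key = (target.lateral, target.polar)
        if key not in seen:
            seen.add(key)
            out.append(target)
    return out


def _target_weights(rs: ResponseSet, lateral_limit: float = 30.0):
    """Unique targets and their trial counts within the lateral range."""
    counts: dict[tuple[float, float], int] = {}
    targets: dict[tuple[float, float], Direction] = {}
    for target, response in rs.trials:
        if abs(response.lateral) > lateral_limit + 1e-9:
            continue
        key = (target.lateral, target.polar)
        counts[key] = counts.get(key, 0) + 1
        targets[key] = target
    keys = list(counts)
    return [targets[k] for k in keys], np.array([counts[k] for k in keys], float)


def _pooled_prediction_curve(
    dtf: DTFSet,
    targets: list[Direction],
    weights: np.ndarray,
    U_grid: np.ndarray,
    config: ModelConfig | None,
    template_dtf: DTFSet | None = None,
) -> list[tuple[float, PerformanceScores]]:
    """Model expectation of the pooled-trial estimators used by
    :func:`sagloc.metrics.actual_scores`.

    QE is the trial-count-weighted mean of per-target QEs; PE pools the
    local second moments, weighted by trial count times local probability
    mass — the quantities the pooled RMS over sampled trials actually
    estimates. Using the same estimator on both sides of the residual keeps
    the calibration free of aggregation bias.
    """
    from .metrics import predicted_scores

    predictor = Predictor(dtf, template_dtf, config)
    out = []
    for U in U_grid:
        qe_acc = pe_num = pe_den = 0.0
        for t, w in zip(targets, weights):
            s = predicted_scores(predictor.pmv(t, float(U)), t.polar)
            qe_acc += w * s.qe
            local_mass = 1.0 - s.qe / 100.0
            if s.pe_defined and local_mass > 0:
                pe_num += w * local_mass * s.pe**2
                pe_den += w * local_mass
        qe = qe_acc / weights.sum()
        pe = float(np.sqrt(pe_num / pe_den)) if pe_den > 0 else float("nan")
        out.append((float(U), PerformanceScores(pe=pe, qe=qe)))
    return out


def calibrate_uncertainty(
    rs: ResponseSet,
    dtf: DTFSet,
    U_grid: np.ndarray | None = None,
    config: ModelConfig | None = None,
) -> CalibrationResult:
    """Fit the listener's uncertainty to an observed response set.

    Predictions are aggregated over the unique target directions present in
    the response set (each evaluated against the PMV of its 20-degree-wide
    lateral segment).
    """
    if U_grid is None:
        U_grid = default_u_grid()
    U_grid = np.asarray(U_grid, dtype=float)
    actual = actual_scores(rs)
    targets, weights = _target_weights(rs)
    if not targets:
        raise InvalidParameterError("no eligible targets in the response set")
    curve = _pooled_prediction_curve(dtf, targets, weights, U_grid, config)
    residuals = np.array(
        [
            (s.pe - actual.pe) ** 2 + (s.qe - actual.qe) ** 2
            if s.pe_defined and actual.pe_defined
            else (s.qe - actual.qe) ** 2
            for _, s in curve
        ]
    )
    best = int(np.argmin(residuals))  # first minimum -> smallest U on ties
    return CalibrationResult(
        U_grid=U_grid,
        residuals=residuals,
        U_k=float(U_grid[best]),
        predicted_at_U_k=curve[best][1],
        actual=actual,
    )
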