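"""Acoustic vs non-acoustic factor analysis.

Permutes DTF sets and uncertainties across a listener group: entry (i, j)
of the permutation grid is the aggregate performance predicted with the
i-th listener's DTF set (feeding both the incoming sound and the template
set — the complete re-calibration condition) and the j-th listener's
uncertainty. Rows and columns are sorted by ascending uncertainty, and the
diagonal reproduces each listener's baseline prediction. Row-wise and
column-wise standard deviations quantify how much each factor moves the
predictions; listener-constant parameterizations are probed via Pearson
correlations with the actual scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError
from .metrics import PerformanceScores
from .model import ModelConfig, Predictor
from .synthetic import Direction, ListenerModel

__all__ = [
    "PermutationGrid",
    "FactorContribution",
    "permutation_grid",
    "relative_performance",
    "factor_sds",
    "constant_parameter_eval",
    "pearson",
]


@dataclass
class PermutationGrid:
    """K x K predicted scores; rows index DTF sets, columns uncertainties,
    both in ascending-U listener order."""

    listener_order: list[str]
    uncertainties: np.ndarray
    PE_matrix: np.ndarray
    QE_matrix: np.ndarray

    def __post_init__(self):
        k = len(self.listener_order)
        for m in (self.PE_matrix, self.QE_matrix):
            if m.shape != (k, k):
                raise InvalidParameterError("matrix shape does not match group size")
            if not np.all(np.isfinite(m)):
                raise InvalidParameterError("non-finite grid entry")
        if np.any(self.QE_matrix < 0) or np.any(self.QE_matrix > 100):
            raise InvalidParameterError("QE outside [0, 100]")

    @property
    def k(self) -> int:
        return len(self.listener_order)

    def baseline(self) -> list[PerformanceScores]:
        return [
            PerformanceScores(pe=float(self.PE_matrix[j, j]), qe=float(self.QE_matrix[j, j]))
            for j in range(self.k)
        ]


@dataclass
class FactorContribution:
    """Per-listener SDs of the grid along each factor axis.

    ``sd_over_U[i]``: SD across row i (own DTF, all uncertainties).
    ``sd_over_D[j]``: SD across column j (own uncertainty, all DTF sets).
    """

    sd_over_U_pe: np.ndarray
    sd_over_U_qe: np.ndarray
    sd_over_D_pe: np.ndarray
    sd_over_D_qe: np.ndarray

    def summary(self) -> dict:
        def stats(a):
            return {"mean": float(np.mean(a)), "sd": float(np.std(a, ddof=1))}

        out = {
            "sd_over_U": {"PE": stats(self.sd_over_U_pe), "QE": stats(self.sd_over_U_qe)},
            "sd_over_D": {"PE": stats(self.sd_over_D_pe), "QE": stats(self.sd_over_D_qe)},
        }
        out["ratio_U_to_D"] = {
            "PE": out["sd_over_U"]["PE"]["mean"] / out["sd_over_D"]["PE"]["mean"],
            "QE": out["sd_over_U"]["QE"]["mean"] / out["sd_over_D"]["QE"]["mean"],
        }
        return out


def permutation_grid(
    group: list[ListenerModel],
    targets: list[Direction],
    config: ModelConfig | None = None,
) -> PermutationGrid:
    """Predicted scores for every (DTF set, uncertainty) combination."""
    if len(group) < 2:
        raise InvalidParameterError("need at least 2 listeners")
    for lm in group:
        if lm.uncertainty is None or lm.uncertainty <= 0:
            raise InvalidParameterError(f"listener {lm.dtf.listener_id} not calibrated")
    order = sorted(range(len(group)), key=lambda i: group[i].uncertainty)
    group = [group[i] for i in order]
    k = len(group)
    us = np.array([lm.uncertainty for lm in group])
    pe = np.empty((k, k))
    qe = np.empty((k, k))
    for i, lm in enumerate(group):
        predictor = Predictor(lm.dtf, config=config)
        for j, u in enumerate(us):
            s = predictor.predicted_scores(targets, float(u))
            pe[i, j], qe[i, j] = s.pe, s.qe
    return PermutationGrid(
        listener_order=[lm.dtf.listener_id for lm in group],
        uncertainties=us,
        PE_matrix=pe,
        QE_matrix=qe,
    )


def relative_performance(grid: PermutationGrid) -> dict:
    """Per-DTF-set performance change relative to the listener-specific
    baseline, averaged over all uncertainties.

    Delta(i, j) = entry(i, j) - diagonal(j); positive means the i-th DTF set
    degrades the group. Returns means and SDs per DTF set.
    """
    out = {}
    for name, m in (("PE", grid.PE_matrix), ("QE", grid.QE_matrix)):
        delta = m - np.diag(m)[None, :]
        out[f"d{name}_mean"] = delta.mean(axis=1)
        out[f"d{name}_sd"] = delta.std(axis=1, ddof=1)
    out["listener_order"] = list(grid.listener_order)
    return out


def factor_sds(grid: PermutationGrid) -> FactorContribution:
    """Row-wise (uncertainty varied) and column-wise (DTF varied) SDs."""
    if grid.k < 2:
        raise InvalidParameterError("need at least 2 listeners")
    return FactorContribution(
        sd_over_U_pe=grid.PE_matrix.std(axis=1, ddof=1),
        sd_over_U_qe=grid.QE_matrix.std(axis=1, ddof=1),
        sd_over_D_pe=grid.PE_matrix.std(axis=0, ddof=1),
        sd_over_D_qe=grid.QE_matrix.std(axis=0, ddof=1),
    )


def pearson(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidParameterError("inputs must be equal-length 1-D vectors")
    if x.size < 3:
        raise InvalidParameterError("need at least 3 points")
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise InvalidParameterError("zero variance in correlation input")
    return float((xc * yc).sum() / denom)


def constant_parameter_eval(
    group: list[ListenerModel],
    mode: tuple[str, object],
    actual: list[PerformanceScores],
    targets: list[Direction],
    config: ModelConfig | None = None,
) -> dict:
    """Predictions with one model parameter held constant across the group.

    ``mode`` is ``("constant_U", value)`` — every listener keeps their own
    DTF set but shares the given uncertainty — or
    ``("constant_DTF", listener_id)`` — every listener keeps their own
    uncertainty but shares the named listener's DTF set. Returns Pearson
    correlations between actual and predicted scores across listeners plus
    the group SDs of the predictions.
    """
    if len(group) < 3:
        raise InvalidParameterError("correlation needs at least 3 listeners")
    if len(actual) != len(group):
        raise InvalidParameterError("one actual score per listener required")
    kind, value = mode
    if kind == "constant_U":
        u_const = float(value)
        preds = [
            Predictor(lm.dtf, config=config).predicted_scores(targets, u_const)
            for lm in group
        ]
    elif kind == "constant_DTF":
        matches = [lm for lm in group if lm.dtf.listener_id == value]
        if not matches:
            raise InvalidParameterError(f"no listener with id {value!r}")
        shared = Predictor(matches[0].dtf, config=config)
        preds = [shared.predicted_scores(targets, lm.uncertainty) for lm in group]
    else:
        raise InvalidParameterError(f"unknown mode {kind!r}")

    pred_pe = np.array([s.pe for s in preds])
    pred_qe = np.array([s.qe for s in preds])
    act_pe = np.array([s.pe for s in actual])
    act_qe = np.array([s.qe for s in actual])
    return {
        "mode": kind,
        "value": value if kind == "constant_DTF" else float(value),
        "r_PE": pearson(act_pe, pred_pe),
        "r_QE": pearson(act_qe, pred_qe),
        "group_sd_PE": float(np.std(pred_pe, ddof=1)),
        "group_sd_QE": float(np.std(pred_qe, ddof=1)),
        "predicted_PE": pred_pe.tolist(),
        "predicted_QE": pred_qe.tolist(),
    }
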