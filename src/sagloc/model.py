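"""Comparison stage and spectral-to-spatial mapping.

The distance between the internal representation of an incoming sound and a
template is the standard deviation of their per-band differences — a metric
insensitive to overall level. A Gaussian of width U (the listener-specific
uncertainty) maps distance to a similarity index per ear; a sigmoid binaural
weighting combines the ears, and normalization over all template angles
yields a probability mass vector (PMV) of response polar angles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidParameterError
from .periphery import (
    FilterbankSpec,
    InternalRepresentation,
    TemplateSet,
    band_magnitudes,
    build_template_set,
)
from .synthetic import DTFSet, Direction

__all__ = [
    "ModelConfig",
    "PMV",
    "interspectral_distance",
    "similarity",
    "binaural_weights",
    "predict_pmv",
    "Predictor",
]


@dataclass(frozen=True)
class ModelConfig:
    """Model-wide configuration.

    ``binaural_width`` is the lateral-angle scale (degrees) of the sigmoid
    binaural weighting; within |lateral| <= 30 results are insensitive to
    moderate changes of it.
    """

    U_default: float = 2.0
    binaural_width: float = 13.3
    lateral_centers: tuple[float, ...] = (-20.0, 0.0, 20.0)
    segment_width: float = 20.0
    filterbank: FilterbankSpec = field(default_factory=FilterbankSpec)

    def __post_init__(self):
        if self.binaural_width <= 0:
            raise InvalidParameterError("binaural_width must be positive")
        if self.U_default <= 0:
            raise InvalidParameterError("U_default must be positive")

    def segment_center(self, lateral: float) -> float:
        """Nearest lateral segment center covering ``lateral``."""
        centers = np.asarray(self.lateral_centers, dtype=float)
        i = int(np.argmin(np.abs(centers - lateral)))
        if abs(centers[i] - lateral) > self.segment_width / 2.0 + 1e-9:
            raise InvalidParameterError(
                f"lateral {lateral} not covered by segments {self.lateral_centers}"
            )
        return float(centers[i])


@dataclass(frozen=True)
class PMV:
    """Probability mass vector over polar response angles for one target."""

    response_angles: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self):
        ang = np.asarray(self.response_angles, dtype=float)
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "response_angles", ang)
        object.__setattr__(self, "probabilities", p)
        if ang.shape != p.shape or ang.ndim != 1:
            raise InvalidParameterError("angles/probabilities shape mismatch")
        if np.any(np.diff(ang) <= 0):
            raise InvalidParameterError("response angles must be sorted")
        if np.any(p < 0):
            raise InvalidParameterError("negative probability")
        if abs(p.sum() - 1.0) > 1e-10:
            raise InvalidParameterError(f"probabilities sum to {p.sum()!r}, not 1")

    def entropy(self) -> float:
        p = self.probabilities[self.probabilities > 0]
        return float(-(p * np.log(p)).sum())


def interspectral_distance(
    target: InternalRepresentation, template: InternalRepresentation, ear: int = 0
) -> float:
    """Sample SD (ddof=1) of the per-band dB differences for one ear."""
    if target.band_centers.shape != template.band_centers.shape or not np.allclose(
        target.band_centers, template.band_centers
    ):
        raise InvalidParameterError("band grids differ between target and template")
    diff = target.for_ear(ear) - template.for_ear(ear)
    return float(np.std(diff, ddof=1))


def similarity(distance, U: float):
    """Gaussian mapping of spectral distance to a similarity index in (0, 1]."""
    if U <= 0:
        raise InvalidParameterError("U must be positive")
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise InvalidParameterError("distance must be nonnegative")
    si = np.exp(-(d**2) / (2.0 * U**2))
    return si if si.ndim else float(si)


def binaural_weights(lateral: float, width: float = 13.3) -> tuple[float, float]:
    """Sigmoid binaural weighting: the contralateral ear's contribution
    shrinks with the lateral angle (positive lateral = left)."""
    if not -90.0 <= lateral <= 90.0:
        raise InvalidParameterError(f"lateral {lateral} outside [-90, 90]")
    w_left = 1.0 / (1.0 + np.exp(-lateral / width))
    return float(w_left), float(1.0 - w_left)


def _distance_matrix(rep_in: np.ndarray, rep_tmp: np.ndarray) -> np.ndarray:
    """(2, n_in, n_tmp) SDs of per-band differences; reps are
    (n, 2, n_bands)."""
    diff = rep_in[:, None, :, :] - rep_tmp[None, :, :, :]  # (n_in, n_tmp, 2, B)
    return np.moveaxis(diff.std(axis=-1, ddof=1), 2, 0)


class Predictor:
    """Caches templates and distance matrices for a (incoming, template) DTF
    pair so PMVs for many targets and uncertainties are cheap.

    With the default single-DTF form (incoming == template) this encodes the
    complete-re-calibration condition used throughout the analyses.
    """

    def __init__(
        self,
        incoming_dtf: DTFSet,
        template_dtf: DTFSet | None = None,
        config: ModelConfig | None = None,
    ):
        self.config = config or ModelConfig()
        self.incoming_dtf = incoming_dtf
        self.template_dtf = template_dtf if template_dtf is not None else incoming_dtf
        self._segments: dict[float, dict] = {}

    def _segment(self, center: float) -> dict:
        if center not in self._segments:
            spec = self.config.filterbank
            tset = build_template_set(
                self.template_dtf, center, spec, self.config.segment_width / 2.0
            )
            if self.incoming_dtf is self.template_dtf:
                rep_in_polar, rep_in = tset.polar_angles, tset.magnitude
            else:
                iset = build_template_set(
                    self.incoming_dtf, center, spec, self.config.segment_width / 2.0
                )
                rep_in_polar, rep_in = iset.polar_angles, iset.magnitude
            dist = _distance_matrix(rep_in, tset.magnitude)
            self._segments[center] = {
                "templates": tset,
                "in_polar": rep_in_polar,
                "dist": dist,  # (2, n_in, n_templates)
            }
        return self._segments[center]

    def pmv_matrix(self, lateral: float, U: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """PMVs for all incoming directions of one segment at uncertainty U.

        Returns ``(incoming_polar, response_angles, P)`` with ``P[i, j]`` the
        probability of responding at ``response_angles[j]`` to the target at
        ``incoming_polar[i]``.
        """
        center = self.config.segment_center(lateral)
        seg = self._segment(center)
        si = similarity(seg["dist"], U)  # (2, n_in, n_tmp)
        w_l, w_r = binaural_weights(lateral, self.config.binaural_width)
        combined = w_l * si[0] + w_r * si[1]
        total = combined.sum(axis=1, keepdims=True)
        if np.any(total <= 0):
            raise InvalidParameterError("all similarity indices underflowed to zero")
        return seg["in_polar"], seg["templates"].polar_angles, combined / total

    def pmv(self, target: Direction, U: float | None = None) -> PMV:
        U = self.config.U_default if U is None else U
        in_polar, angles, P = self.pmv_matrix(target.lateral, U)
        from .synthetic import wrap_polar_difference

        i = int(np.argmin(np.abs(wrap_polar_difference(in_polar - target.polar))))
        return PMV(angles, P[i])

    def predicted_scores(self, targets, U: float | None = None):
        """Aggregate predicted performance over a target list."""
        from .metrics import aggregate_scores, predicted_scores

        U = self.config.U_default if U is None else U
        per_target = []
        for t in targets:
            per_target.append(predicted_scores(self.pmv(t, U), t.polar))
        return aggregate_scores(per_target)


def predict_pmv(
    target_direction: Direction,
    incoming_dtf: DTFSet,
    template_dtf: DTFSet | None = None,
    U: float | None = None,
    config: ModelConfig | None = None,
) -> PMV:
    """Response-probability mass vector for one target.

    Per template angle: per-ear spectral distance -> Gaussian similarity at
    uncertainty U -> binaural combination at the target's lateral angle ->
    normalization over template angles to sum one.
    """
    predictor = Predictor(incoming_dtf, template_dtf, config)
    return predictor.pmv(target_direction, U)
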