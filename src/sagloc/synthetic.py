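"""Virtual listeners: DTF-set synthesis and response simulation.

A virtual listener is a DTF set whose direction-dependent spectral features
(a notch migrating with polar angle, a rear-hemifield shelf, and seeded
ripple) stand in for the across-listener variability of measured ears, plus
a ground-truth uncertainty. Response sets are sampled from the localization
model's own probability mass vectors, so the full calibration and factor
pipeline can run without measured data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import InvalidParameterError
from .periphery import erb_number

__all__ = [
    "Direction",
    "DTFSet",
    "SyntheticListenerParams",
    "ResponseSet",
    "ListenerModel",
    "default_frequency_grid",
    "default_polar_grid",
    "DEFAULT_LATERAL_CENTERS",
    "generate_listener_dtfs",
    "generate_responses",
    "compute_dtf_from_hrtf",
]

DEFAULT_LATERAL_CENTERS = (-20.0, 0.0, 20.0)
#: DTF impulse-response duration in seconds
IR_DURATION_S = 5.33e-3


def wrap_polar_difference(delta):
    """Wrap an angular difference (degrees) into (-180, 180]."""
    d = np.asarray(delta, dtype=float) % 360.0
    d = np.where(d > 180.0, d - 360.0, d)
    return d if d.ndim else float(d)


@dataclass(frozen=True)
class Direction:
    """Interaural-polar direction: lateral angle (positive = left) and polar
    angle within the sagittal plane (-30 = front below eye level, 90 =
    above, 210 = rear below eye level)."""

    lateral: float
    polar: float

    def __post_init__(self):
        if not -90.0 <= self.lateral <= 90.0:
            raise InvalidParameterError(f"lateral {self.lateral} outside [-90, 90]")
        if not -90.0 <= self.polar < 270.0:
            raise InvalidParameterError(f"polar {self.polar} outside [-90, 270)")


@dataclass
class DTFSet:
    """Per-listener directional transfer functions.

    ``magnitude`` is dB, shaped (n_directions, 2, n_freq) with ear axis
    0=left, 1=right. ``impulse_responses``, when present, are minimum-phase
    reconstructions shaped (n_directions, 2, n_samples).
    """

    listener_id: str
    directions: list[Direction]
    freq: np.ndarray
    magnitude: np.ndarray
    sampling_rate: float = 48000.0
    impulse_responses: np.ndarray | None = None

    def __post_init__(self):
        self.freq = np.asarray(self.freq, dtype=float)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        if np.any(np.diff(self.freq) <= 0):
            raise InvalidParameterError("frequency grid must be strictly increasing")
        expected = (len(self.directions), 2, self.freq.size)
        if self.magnitude.shape != expected:
            raise InvalidParameterError(
                f"magnitude shape {self.magnitude.shape} != {expected}"
            )
        if not np.all(np.isfinite(self.magnitude)):
            raise InvalidParameterError("non-finite DTF magnitude")

    @property
    def n_directions(self) -> int:
        return len(self.directions)

    def segment_indices(self, lateral_center: float, half_width: float = 10.0) -> list[int]:
        """Indices of directions within ``half_width`` of a lateral segment
        center, sorted by polar angle."""
        idx = [
            i
            for i, d in enumerate(self.directions)
            if abs(d.lateral - lateral_center) <= half_width + 1e-9
        ]
        idx.sort(key=lambda i: self.directions[i].polar)
        return idx

    def direction_index(self, direction: Direction, half_width: float = 10.0) -> int:
        """Index of the nearest stored direction within the same segment
        (nearest-template assignment for off-grid targets)."""
        best, best_cost = None, np.inf
        for i, d in enumerate(self.directions):
            if abs(d.lateral - direction.lateral) > half_width + 1e-9:
                continue
            cost = abs(wrap_polar_difference(d.polar - direction.polar))
            if cost < best_cost:
                best, best_cost = i, cost
        if best is None:
            raise InvalidParameterError(
                f"no stored direction within {half_width} deg lateral of {direction}"
            )
        return best


@dataclass(frozen=True)
class SyntheticListenerParams:
    """Knobs of the virtual-ear synthesis.

    ``cue_quality`` scales every direction-dependent feature; 0 removes all
    directional information, values above 1 sharpen it.
    """

    notch_depth: float = 25.0  # dB
    notch_freq_front: float = 6000.0  # Hz, notch center at polar -30
    notch_slope: float = 35.0  # Hz per degree of polar angle
    rear_offset: float = 8.0  # dB shelf distinguishing rear from front
    ripple_amplitude: float = 4.0  # dB
    cue_quality: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.notch_depth <= 0:
            raise InvalidParameterError("notch_depth must be positive")
        if not 0.0 <= self.cue_quality <= 1.5:
            raise InvalidParameterError("cue_quality must lie in [0, 1.5]")


@dataclass
class ResponseSet:
    """Localization trials: (target, response) direction pairs."""

    listener_id: str
    trials: list[tuple[Direction, Direction]]

    def __len__(self) -> int:
        return len(self.trials)

    def require_nonempty(self):
        if not self.trials:
            raise InvalidParameterError("response set has no trials")


@dataclass
class ListenerModel:
    """A listener as the model sees it: DTF set plus uncertainty."""

    dtf: DTFSet
    uncertainty: float
    ground_truth_U: float | None = None

    def __post_init__(self):
        if self.uncertainty <= 0:
            raise InvalidParameterError("uncertainty must be positive")


def default_frequency_grid(sampling_rate: float = 48000.0, nfft: int = 2048) -> np.ndarray:
    return np.fft.rfftfreq(nfft, 1.0 / sampling_rate)


def default_polar_grid() -> np.ndarray:
    return np.arange(-30.0, 211.0, 5.0)


def _smooth_ripple(x: np.ndarray, coeffs: np.ndarray, phases: np.ndarray) -> np.ndarray:
    """Low-order cosine series over the normalized ERB axis x in [0, 1]."""
    out = np.zeros_like(x)
    for m, (a, ph) in enumerate(zip(coeffs, phases), start=1):
        out += (a / m) * np.cos(2.0 * np.pi * m * x + ph)
    return out


def generate_listener_dtfs(
    params: SyntheticListenerParams,
    listener_id: str | None = None,
    freq: np.ndarray | None = None,
    polar_grid: np.ndarray | None = None,
    lateral_centers: tuple[float, ...] = DEFAULT_LATERAL_CENTERS,
    sampling_rate: float = 48000.0,
) -> DTFSet:
    """Synthesize a listener-specific DTF set on the default direction grid.

    The frontal notch center migrates linearly with polar angle,
    ``notch_freq_front + notch_slope * (polar + 30)`` for polar <= 90; rear
    directions mirror the front (polar -> 180 - polar) and additionally get
    a high-frequency shelf of ``rear_offset`` dB, so front and rear spectra
    differ whenever ``cue_quality > 0``. A seeded smooth ripple decorrelates
    nearby directions. Deterministic for fixed params.
    """
    if freq is None:
        freq = default_frequency_grid(sampling_rate)
    freq = np.asarray(freq, dtype=float)
    if polar_grid is None:
        polar_grid = default_polar_grid()
    polar_grid = np.asarray(polar_grid, dtype=float)

    # notch trajectory must stay on the grid for every polar angle
    front_polar = np.where(polar_grid <= 90.0, polar_grid, 180.0 - polar_grid)
    fc_traj = params.notch_freq_front + params.notch_slope * (front_polar + 30.0)
    fc_lo, fc_hi = fc_traj.min(), fc_traj.max() * 1.03  # right-ear scaling included
    if fc_lo < freq[1] or fc_hi > freq[-1]:
        raise InvalidParameterError(
            f"notch trajectory [{fc_lo:.0f}, {fc_hi:.0f}] Hz leaves the "
            f"frequency grid [{freq[1]:.0f}, {freq[-1]:.0f}] Hz"
        )

    rng = np.random.default_rng(params.seed)
    directions: list[Direction] = []
    n_dir = len(lateral_centers) * polar_grid.size
    mags = np.empty((n_dir, 2, freq.size))

    # direction-independent base colouration (survives cue_quality = 0)
    base = 3.0 * np.exp(-(((freq - 4000.0) / 4000.0) ** 2))
    # sub-linear feature scaling: measured ears differ far less in cue
    # accessibility than listeners differ in processing efficiency, so a
    # given cue_quality spread should perturb performance only moderately
    cq = float(np.sqrt(params.cue_quality))
    n_lo, n_hi = erb_number(max(freq[1], 100.0)), erb_number(freq[-1])
    x = (erb_number(np.maximum(freq, 100.0)) - n_lo) / (n_hi - n_lo)
    ear_scale = (1.0, 1.03)  # left ear carries the nominal notch trajectory

    k = 0
    for lat in lateral_centers:
        for polar, fc0 in zip(polar_grid, fc_traj):
            directions.append(Direction(lat, polar))
            is_rear = polar > 90.0
            for ear in (0, 1):
                fc = fc0 * ear_scale[ear]
                width = 0.1 * fc
                spec = base - cq * params.notch_depth * np.exp(
                    -0.5 * ((freq - fc) / width) ** 2
                )
                peak_fc = 1.5 * fc
                spec += cq * 0.5 * params.notch_depth * np.exp(
                    -0.5 * ((freq - peak_fc) / (0.15 * peak_fc)) ** 2
                )
                if is_rear:
                    spec -= cq * params.rear_offset / (
                        1.0 + np.exp(-(freq - 9000.0) / 1500.0)
                    )
                coeffs = rng.uniform(-1.0, 1.0, size=3)
                phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
                spec += cq * params.ripple_amplitude * _smooth_ripple(x, coeffs, phases)
                mags[k, ear] = spec
            k += 1

    return DTFSet(
        listener_id=listener_id or f"VL{params.seed:03d}",
        directions=directions,
        freq=freq,
        magnitude=mags,
        sampling_rate=sampling_rate,
    )


def generate_responses(
    listener: ListenerModel,
    n_trials: int,
    seed: int,
    config=None,
    max_lateral: float = 30.0,
) -> ResponseSet:
    """Sample a localization-experiment response set from the model.

    Targets are drawn uniformly over the listener's direction grid within
    ``|lateral| <= max_lateral``; the response polar angle is drawn from the
    model's PMV for that target at the listener's uncertainty; the response
    lateral angle equals the target's (the model predicts the polar
    dimension only). No extra response scatter is added.
    """
    from .model import ModelConfig, Predictor

    if n_trials < 1:
        raise InvalidParameterError("n_trials must be >= 1")
    config = config or ModelConfig()
    predictor = Predictor(listener.dtf, config=config)
    targets = [
        d for d in listener.dtf.directions if abs(d.lateral) <= max_lateral + 1e-9
    ]
    if not targets:
        raise InvalidParameterError("no targets within the lateral range")

    rng = np.random.default_rng(seed)
    picks = rng.integers(0, len(targets), size=n_trials)
    pmv_cache: dict[int, object] = {}
    trials = []
    for i in picks:
        if i not in pmv_cache:
            pmv_cache[i] = predictor.pmv(targets[i], listener.uncertainty)
        pmv = pmv_cache[i]
        resp_polar = float(rng.choice(pmv.response_angles, p=pmv.probabilities))
        trials.append((targets[i], Direction(targets[i].lateral, resp_polar)))
    return ResponseSet(listener_id=listener.dtf.listener_id, trials=trials)


def compute_dtf_from_hrtf(hrtf: DTFSet, export_impulse_responses: bool = False) -> DTFSet:
    """Remove the common transfer function from an HRTF set.

    The CTF is the per-ear mean of the log-magnitude spectra across all
    directions; DTF magnitude = HRTF magnitude - CTF, in dB. Optionally a
    minimum-phase impulse response is reconstructed per direction and ear,
    faded with an asymmetric Tukey window (0.5 ms in, 1 ms out) and
    truncated to 5.33 ms (length rounded up to the next sample).
    """
    if hrtf.n_directions < 1:
        raise InvalidParameterError("HRTF set has no directions")
    ctf = hrtf.magnitude.mean(axis=0, keepdims=True)  # (1, 2, n_freq)
    dtf_mag = hrtf.magnitude - ctf
    irs = None
    if export_impulse_responses:
        from .io import minimum_phase_ir, asymmetric_tukey_window

        fs = hrtf.sampling_rate
        n_out = int(np.ceil(IR_DURATION_S * fs))
        window = asymmetric_tukey_window(n_out, fs)
        nfft = 2 * (hrtf.freq.size - 1)
        irs = np.empty((hrtf.n_directions, 2, n_out))
        for i in range(hrtf.n_directions):
            for ear in (0, 1):
                full = minimum_phase_ir(dtf_mag[i, ear], nfft)
                irs[i, ear] = full[:n_out] * window
    return DTFSet(
        listener_id=hrtf.listener_id,
        directions=list(hrtf.directions),
        freq=hrtf.freq,
        magnitude=dtf_mag,
        sampling_rate=hrtf.sampling_rate,
        impulse_responses=irs,
    )
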