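"""External formats: SOFA HRTF/DTF containers and CSV response tables.

SOFA (SimpleFreeFieldHRIR) files are netCDF-4, i.e. HDF5 underneath, so a
plain h5py reader suffices for the variables this package needs
(``Data.IR``, ``Data.SamplingRate``, ``SourcePosition``). The writer emits
the same layout, which round-trips through the reader and is readable by
h5py-based tooling.
"""

from __future__ import annotations

import csv

import h5py
import numpy as np
import pandas as pd

from .exceptions import DataValidationError, FormatError, InvalidParameterError
from .synthetic import Direction, DTFSet, ResponseSet, default_frequency_grid

__all__ = [
    "vertical_polar_to_interaural",
    "interaural_to_vertical_polar",
    "minimum_phase_ir",
    "asymmetric_tukey_window",
    "load_dtf_sofa",
    "write_dtf_sofa",
    "read_responses_csv",
    "write_responses_csv",
]

RESPONSE_COLUMNS = [
    "listener_id",
    "target_lateral",
    "target_polar",
    "response_lateral",
    "response_polar",
]


def vertical_polar_to_interaural(azimuth: float, elevation: float) -> tuple[float, float]:
    """(azimuth, elevation) in degrees -> (lateral, polar) in degrees.

    Azimuth is counterclockwise from front (positive left), elevation up;
    lateral = asin(y), polar = atan2(z, x) wrapped into [-90, 270).
    """
    az, el = np.deg2rad(azimuth), np.deg2rad(elevation)
    x = np.cos(el) * np.cos(az)
    y = np.cos(el) * np.sin(az)
    z = np.sin(el)
    lateral = np.rad2deg(np.arcsin(np.clip(y, -1.0, 1.0)))
    polar = np.rad2deg(np.arctan2(z, x))
    if polar < -90.0:
        polar += 360.0
    return float(lateral), float(polar)


def interaural_to_vertical_polar(lateral: float, polar: float) -> tuple[float, float]:
    """Inverse of :func:`vertical_polar_to_interaural`; azimuth in [0, 360)."""
    lat, pol = np.deg2rad(lateral), np.deg2rad(polar)
    y = np.sin(lat)
    w = np.cos(lat)
    x = w * np.cos(pol)
    z = w * np.sin(pol)
    azimuth = np.rad2deg(np.arctan2(y, x)) % 360.0
    elevation = np.rad2deg(np.arcsin(np.clip(z, -1.0, 1.0)))
    return float(azimuth), float(elevation)


def minimum_phase_ir(magnitude_db: np.ndarray, nfft: int) -> np.ndarray:
    """Minimum-phase impulse response from a dB magnitude spectrum.

    ``magnitude_db`` must be sampled on the rfft grid of ``nfft`` points
    (nfft//2 + 1 bins). Homomorphic (real-cepstrum) construction; the
    magnitude is clipped at -100 dB before the log.
    """
    mag = np.asarray(magnitude_db, dtype=float)
    if mag.shape != (nfft // 2 + 1,):
        raise InvalidParameterError(
            f"magnitude length {mag.shape} does not match nfft {nfft}"
        )
    amp = np.maximum(10.0 ** (mag / 20.0), 1e-5)
    cep = np.fft.irfft(np.log(amp), nfft)
    fold = np.zeros(nfft)
    fold[0] = 1.0
    fold[1 : nfft // 2] = 2.0
    fold[nfft // 2] = 1.0
    spectrum = np.exp(np.fft.rfft(cep * fold, nfft))
    return np.fft.irfft(spectrum, nfft)


def asymmetric_tukey_window(n: int, fs: float, fade_in_s: float = 0.5e-3,
                            fade_out_s: float = 1.0e-3) -> np.ndarray:
    """Unit window with raised-cosine fade-in and fade-out of given lengths."""
    n_in = int(round(fade_in_s * fs))
    n_out = int(round(fade_out_s * fs))
    if n_in + n_out > n:
        raise InvalidParameterError("window shorter than its fades")
    w = np.ones(n)
    if n_in:
        w[:n_in] = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_in) / n_in))
    if n_out:
        w[n - n_out :] = 0.5 * (1.0 + np.cos(np.pi * np.arange(1, n_out + 1) / n_out))
    return w


def write_dtf_sofa(dtf: DTFSet, path) -> None:
    """Write a DTF set as a SimpleFreeFieldHRIR-layout HDF5 (SOFA) file.

    Uses stored impulse responses when present, otherwise minimum-phase
    reconstructions on the set's frequency grid (unwindowed, so the
    magnitude spectra round-trip exactly through :func:`load_dtf_sofa`).
    """
    if dtf.impulse_responses is not None:
        irs = np.asarray(dtf.impulse_responses, dtype=float)
    else:
        nfft = 2 * (dtf.freq.size - 1)
        irs = np.empty((dtf.n_directions, 2, nfft))
        for i in range(dtf.n_directions):
            for ear in (0, 1):
                irs[i, ear] = minimum_phase_ir(dtf.magnitude[i, ear], nfft)
    positions = np.array(
        [
            [*interaural_to_vertical_polar(d.lateral, d.polar), 1.2]
            for d in dtf.directions
        ]
    )
    with h5py.File(path, "w") as f:
        f.attrs["Conventions"] = "SOFA"
        f.attrs["SOFAConventions"] = "SimpleFreeFieldHRIR"
        f.attrs["SOFAConventionsVersion"] = "1.0"
        f.attrs["DataType"] = "FIR"
        f.attrs["ListenerShortName"] = dtf.listener_id
        f.create_dataset("Data.IR", data=irs)
        f.create_dataset("Data.SamplingRate", data=np.array([dtf.sampling_rate]))
        sp = f.create_dataset("SourcePosition", data=positions)
        sp.attrs["Type"] = "spherical"
        sp.attrs["Units"] = "degree, degree, metre"


def _attr_str(attrs, key):
    v = attrs.get(key)
    if isinstance(v, bytes):
        return v.decode()
    return v


def load_dtf_sofa(path, freq: np.ndarray | None = None) -> DTFSet:
    """Read a SimpleFreeFieldHRIR SOFA file into a DTF set.

    Source coordinates are converted from vertical-polar (azimuth,
    elevation) to interaural-polar; impulse responses are Fourier-
    transformed onto the configured magnitude grid (default rfft grid of
    2048 points at the file's sampling rate).
    """
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise FormatError(f"not a readable SOFA/HDF5 file: {exc}") from exc
    with f:
        conv = _attr_str(f.attrs, "SOFAConventions")
        if conv != "SimpleFreeFieldHRIR":
            raise FormatError(f"unsupported or missing SOFAConventions: {conv!r}")
        for name in ("Data.IR", "Data.SamplingRate", "SourcePosition"):
            if name not in f:
                raise FormatError(f"missing SOFA variable {name!r}")
        sp = f["SourcePosition"]
        pos_type = _attr_str(sp.attrs, "Type")
        if pos_type is not None and pos_type != "spherical":
            raise FormatError(f"unsupported SourcePosition type {pos_type!r}")
        positions = np.asarray(sp)
        irs = np.asarray(f["Data.IR"], dtype=float)
        fs = float(np.asarray(f["Data.SamplingRate"]).reshape(-1)[0])
        listener_id = _attr_str(f.attrs, "ListenerShortName") or "SOFA"
    if irs.ndim != 3 or irs.shape[1] != 2:
        raise FormatError(f"Data.IR must be (M, 2, N), got {irs.shape}")

    if freq is None:
        freq = default_frequency_grid(fs)
    freq = np.asarray(freq, dtype=float)
    nfft = 2 * (freq.size - 1)
    spectra = np.fft.rfft(irs, n=nfft, axis=-1)
    mag = 20.0 * np.log10(np.maximum(np.abs(spectra), 1e-5))
    directions = [
        Direction(*vertical_polar_to_interaural(az, el)) for az, el, _ in positions
    ]
    return DTFSet(
        listener_id=listener_id,
        directions=directions,
        freq=freq,
        magnitude=mag,
        sampling_rate=fs,
        impulse_responses=irs,
    )


def write_responses_csv(rs: ResponseSet, path) -> None:
    rows = [
        {
            "listener_id": rs.listener_id,
            "target_lateral": t.lateral,
            "target_polar": t.polar,
            "response_lateral": r.lateral,
            "response_polar": r.polar,
        }
        for t, r in rs.trials
    ]
    pd.DataFrame(rows, columns=RESPONSE_COLUMNS).to_csv(path, index=False)


def read_responses_csv(path) -> ResponseSet:
    """Read a response table; raises :class:`DataValidationError` naming the
    offending row on missing columns or out-of-range angles."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise DataValidationError("empty file without header") from exc
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"missing column(s): {', '.join(missing)}")
    trials = []
    listener_id = ""
    for i, row in df.iterrows():
        try:
            target = Direction(float(row["target_lateral"]), float(row["target_polar"]))
            response = Direction(
                float(row["response_lateral"]), float(row["response_polar"])
            )
        except (InvalidParameterError, ValueError) as exc:
            raise DataValidationError(f"row {i}: {exc}", row=int(i)) from exc
        listener_id = str(row["listener_id"])
        trials.append((target, response))
    return ResponseSet(listener_id=listener_id, trials=trials)
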