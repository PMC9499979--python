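"""Calibrated audio containers and WAV round-tripping.

A seafloor recorder stores 16-bit PCM counts; analysis works in absolute
sound pressure (µPa).  The mapping between the two is a single full-scale
constant (dB re 1 µPa at digital full scale) plus an optional
frequency-dependent transfer function applied in the spectral domain by the
downstream PSD/LTSA code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import wavfile

#: Default mapping of int16 full scale to peak pressure, dB re 1 µPa.
#: Chosen so a 40 dB re 1 µPa²/Hz instrument noise floor over a 100 kHz band
#: sits ~50 dB above the 16-bit quantisation noise density.
DEFAULT_FULL_SCALE_DB = 140.0

_INT16_FS = 32767.0


@dataclass
class TransferFunction:
    """Frequency-dependent system gain correction.

    ``gain_db[i]`` is the amount to *add* to measured dB levels at
    ``freqs_hz[i]``; values between tabulated points are linearly
    interpolated, ends are held constant.  A flat 0 dB function is the
    identity (perfectly calibrated system).
    """

    freqs_hz: np.ndarray
    gain_db: np.ndarray

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.gain_db = np.asarray(self.gain_db, dtype=float)
        if self.freqs_hz.shape != self.gain_db.shape:
            raise ValueError("freqs_hz and gain_db must have the same shape")
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("freqs_hz must be strictly increasing")

    @classmethod
    def flat(cls) -> "TransferFunction":
        return cls(np.array([0.0, 1e6]), np.array([0.0, 0.0]))

    @classmethod
    def from_csv(cls, path) -> "TransferFunction":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"frequency_hz": self.freqs_hz, "gain_db": self.gain_db}).to_csv(
            path, index=False
        )

    def gain_at(self, freqs_hz: np.ndarray) -> np.ndarray:
        """Interpolated gain (dB) at the requested frequencies."""
        return np.interp(np.asarray(freqs_hz, dtype=float), self.freqs_hz, self.gain_db)

    def linear_power_gain(self, freqs_hz: np.ndarray) -> np.ndarray:
        return 10.0 ** (self.gain_at(freqs_hz) / 10.0)


@dataclass
class CalibratedRecording:
    """Single-channel pressure time series in µPa with UTC provenance."""

    samples: np.ndarray  # instantaneous pressure, µPa
    sample_rate: float  # Hz
    start_utc: pd.Timestamp = field(
        default_factory=lambda: pd.Timestamp("2019-07-01T00:00:00Z")
    )
    transfer_function: TransferFunction = field(default_factory=TransferFunction.flat)
    full_scale_db: float = DEFAULT_FULL_SCALE_DB

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("recording must be single-channel")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.start_utc = pd.Timestamp(self.start_utc)
        if self.start_utc.tzinfo is None:
            self.start_utc = self.start_utc.tz_localize("UTC")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    @property
    def nyquist(self) -> float:
        return self.sample_rate / 2.0

    def time_axis(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate


def full_scale_pressure(full_scale_db: float) -> float:
    """Peak pressure (µPa) corresponding to digital full scale."""
    return 10.0 ** (full_scale_db / 20.0)


def write_wav(rec: CalibratedRecording, path) -> None:
    """Write a recording as mono 16-bit PCM WAV using its full-scale map."""
    fs_pressure = full_scale_pressure(rec.full_scale_db)
    counts = np.round(rec.samples / fs_pressure * _INT16_FS)
    counts = np.clip(counts, -32768, 32767).astype(np.int16)
    wavfile.write(path, int(round(rec.sample_rate)), counts)


def read_wav(
    path,
    start_utc="2019-07-01T00:00:00Z",
    transfer_function: TransferFunction | None = None,
    full_scale_db: float = DEFAULT_FULL_SCALE_DB,
) -> CalibratedRecording:
    """Read a mono 16-bit PCM WAV back into pressure units (µPa)."""
    rate, counts = wavfile.read(path)
    if counts.ndim != 1:
        raise ValueError("expected a mono WAV file")
    if counts.dtype != np.int16:
        raise ValueError("expected 16-bit PCM samples")
    fs_pressure = full_scale_pressure(full_scale_db)
    samples = counts.astype(np.float64) / _INT16_FS * fs_pressure
    return CalibratedRecording(
        samples=samples,
        sample_rate=float(rate),
        start_utc=pd.Timestamp(start_utc),
        transfer_function=transfer_function or TransferFunction.flat(),
        full_scale_db=full_scale_db,
    )
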