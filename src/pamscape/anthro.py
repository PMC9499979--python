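"""Long-term spectral averages and vessel-based signal screening.

The published workflow screened hour-long LTSA panels by eye; the detectors
here are explicit, tunable stand-ins for that analyst: a comb-structure
rule for ultrasonic antifouling (UA) signals, persistent narrowband-energy
rules for 28-kHz and 50-kHz echosounder classes, and a low-frequency
broadband-exceedance rule for vessel engine noise on a decimated mid-band
LTSA.  They are validated against synthetic ground truth only and are not
claimed to replicate analyst judgement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import decimate, find_peaks, welch

from .calib import CalibratedRecording


@dataclass
class LTSA:
    """Long-term spectral average: time-averaged calibrated spectra."""

    time_s: np.ndarray  # start time of each averaging bin
    freq_hz: np.ndarray
    levels_db: np.ndarray  # shape (n_freq, n_time), dB re 1 µPa²/Hz
    t_avg_s: float
    f_res_hz: float

    def __post_init__(self) -> None:
        if self.levels_db.shape != (len(self.freq_hz), len(self.time_s)):
            raise ValueError("levels_db shape inconsistent with axes")
        if np.any(np.diff(self.time_s) <= 0) or np.any(np.diff(self.freq_hz) <= 0):
            raise ValueError("axes must be strictly increasing")


def compute_ltsa(
    rec: CalibratedRecording, t_avg_s: float = 5.0, f_res_hz: float = 100.0
) -> LTSA:
    """Average magnitude-squared spectra over ``t_avg_s`` windows.

    The FFT length is ``sample_rate / f_res_hz`` and must divide evenly;
    each time bin is the mean of the non-overlapped spectra inside it,
    corrected by the recording's transfer function.  Trailing audio that
    does not fill a whole bin is dropped.
    """
    fs = rec.sample_rate
    nfft_f = fs / f_res_hz
    if abs(nfft_f - round(nfft_f)) > 1e-9:
        nearest = fs / round(nfft_f) if round(nfft_f) else float("nan")
        raise ValueError(
            f"frequency resolution {f_res_hz} Hz incompatible with {fs:.0f} Hz "
            f"sampling (FFT length must be integer; nearest valid resolution {nearest:.4g} Hz)"
        )
    nfft = int(round(nfft_f))
    bin_len = int(round(t_avg_s * fs))
    if bin_len < nfft:
        raise ValueError("time average shorter than one FFT")
    n_bins = len(rec.samples) // bin_len
    if n_bins == 0:
        raise ValueError("recording shorter than one LTSA time bin")
    levels = np.empty((nfft // 2 + 1, n_bins))
    freqs = None
    for i in range(n_bins):
        seg = rec.samples[i * bin_len : (i + 1) * bin_len]
        freqs, psd = welch(
            seg, fs=fs, window="hann", nperseg=nfft, noverlap=0, scaling="density"
        )
        levels[:, i] = psd
    levels *= rec.transfer_function.linear_power_gain(freqs)[:, None]
    return LTSA(
        time_s=np.arange(n_bins) * t_avg_s,
        freq_hz=freqs,
        levels_db=10.0 * np.log10(levels + 1e-300),
        t_avg_s=t_avg_s,
        f_res_hz=f_res_hz,
    )


def decimate_recording(rec: CalibratedRecording, factor: int = 20) -> CalibratedRecording:
    """Polyphase anti-aliased decimation (for the mid-band vessel LTSA)."""
    samples = decimate(rec.samples, factor, ftype="fir", zero_phase=True)
    return CalibratedRecording(
        samples=samples,
        sample_rate=rec.sample_rate / factor,
        start_utc=rec.start_utc,
        transfer_function=rec.transfer_function,
        full_scale_db=rec.full_scale_db,
    )


# ---------------------------------------------------------------------------
# Detection rules (analyst stand-ins)
# ---------------------------------------------------------------------------

@dataclass
class UaParams:
    min_freq_hz: float = 18_500.0  # combs of interest start near 19 kHz
    margin_db: float = 6.0
    min_peaks: int = 3
    prominence_db: float = 3.0
    gap_bins: int = 2


@dataclass
class EchoParams:
    bands_hz: dict = field(
        default_factory=lambda: {
            "echosounder_28": (27_000.0, 31_000.0),
            "echosounder_50": (49_000.0, 51_000.0),
        }
    )
    margin_db: float = 6.0
    gap_bins: int = 2
    #: an in-band spectral line is attributed to a UA comb only when another
    #: comb line sits within this spacing (combs are dense; a lone
    #: echosounder line is not)
    max_comb_spacing_hz: float = 5_000.0


@dataclass
class VesselParams:
    max_freq_hz: float = 300.0
    margin_db: float = 6.0
    baseline_db: float | None = None  # fixed baseline; None → rolling median
    baseline_window_bins: int = 120  # 10 min of 5-s bins
    gap_bins: int = 2


def _merge_flags(flags: np.ndarray, time_s: np.ndarray, t_avg_s: float, gap_bins: int) -> pd.DataFrame:
    """Merge flagged LTSA bins (allowing short gaps) into intervals."""
    idx = np.flatnonzero(flags)
    rows = []
    if len(idx):
        start = prev = idx[0]
        for i in idx[1:]:
            if i - prev <= gap_bins + 1:
                prev = i
            else:
                rows.append((time_s[start], time_s[prev] + t_avg_s))
                start = prev = i
        rows.append((time_s[start], time_s[prev] + t_avg_s))
    return pd.DataFrame(rows, columns=["start_s", "end_s"])


def _comb_peaks(ltsa: LTSA, params: UaParams) -> list[np.ndarray]:
    """Per time bin: frequencies of narrowband maxima ≥ margin over the
    local floor above ``min_freq_hz`` (the comb-structure statistic)."""
    floor = np.median(ltsa.levels_db, axis=0)
    sel = ltsa.freq_hz >= params.min_freq_hz
    fsel = ltsa.freq_hz[sel]
    out = []
    for i in range(len(ltsa.time_s)):
        col = ltsa.levels_db[sel, i]
        peaks, _ = find_peaks(
            col, height=floor[i] + params.margin_db, prominence=params.prominence_db
        )
        out.append(fsel[peaks])
    return out


def detect_ua(ltsa: LTSA, params: UaParams | None = None) -> pd.DataFrame:
    """Flag time bins showing a multi-line comb above ~19 kHz."""
    params = params or UaParams()
    counts = np.array([len(p) for p in _comb_peaks(ltsa, params)])
    return _merge_flags(counts >= params.min_peaks, ltsa.time_s, ltsa.t_avg_s, params.gap_bins)


def detect_echosounder(
    ltsa: LTSA,
    params: EchoParams | None = None,
    ua_params: UaParams | None = None,
) -> dict[str, pd.DataFrame]:
    """Flag persistent narrowband energy in each echosounder class band.

    When a bin also shows UA comb structure and a comb line falls inside
    the class band, the band energy is attributed to the comb and the bin
    does not count for that class.  A line is treated as part of the comb
    only when another comb line sits within ``max_comb_spacing_hz`` of it;
    an isolated narrowband line (a genuine echosounder sharing the scene
    with a comb whose components lie elsewhere) still counts.  Bands beyond
    the recording bandwidth yield empty interval tables.
    """
    params = params or EchoParams()
    ua_params = ua_params or UaParams()
    peak_freqs = _comb_peaks(ltsa, ua_params)
    comb = np.array([len(p) for p in peak_freqs]) >= ua_params.min_peaks
    floor = np.median(ltsa.levels_db, axis=0)

    def comb_line_in_band(pf: np.ndarray, lo: float, hi: float) -> bool:
        for f in pf[(pf >= lo) & (pf <= hi)]:
            others = pf[pf != f]
            if len(others) and np.min(np.abs(others - f)) <= params.max_comb_spacing_hz:
                return True
        return False

    out = {}
    for cls, (lo, hi) in params.bands_hz.items():
        if lo >= ltsa.freq_hz[-1]:
            out[cls] = pd.DataFrame(columns=["start_s", "end_s"])
            continue
        sel = (ltsa.freq_hz >= lo) & (ltsa.freq_hz <= hi)
        band_max = ltsa.levels_db[sel, :].max(axis=0)
        veto = np.array(
            [c and comb_line_in_band(pf, lo, hi) for c, pf in zip(comb, peak_freqs)]
        )
        flags = (band_max >= floor + params.margin_db) & ~veto
        out[cls] = _merge_flags(flags, ltsa.time_s, ltsa.t_avg_s, params.gap_bins)
    return out


def detect_vessel(mid_ltsa: LTSA, params: VesselParams | None = None) -> pd.DataFrame:
    """Flag broadband low-frequency exceedances on the mid-band LTSA.

    The band level below ``max_freq_hz`` is compared against a rolling
    per-scene median baseline, or a fixed ``baseline_db`` when the scene is
    too short (or too saturated) for a within-scene baseline to make sense.
    """
    params = params or VesselParams()
    sel = mid_ltsa.freq_hz <= params.max_freq_hz
    band_linear = np.mean(10.0 ** (mid_ltsa.levels_db[sel, :] / 10.0), axis=0)
    band_db = 10.0 * np.log10(band_linear + 1e-300)
    if params.baseline_db is not None:
        baseline = np.full_like(band_db, params.baseline_db)
    else:
        baseline = (
            pd.Series(band_db)
            .rolling(params.baseline_window_bins, min_periods=1, center=True)
            .median()
            .to_numpy()
        )
    flags = band_db >= baseline + params.margin_db
    return _merge_flags(flags, mid_ltsa.time_s, mid_ltsa.t_avg_s, params.gap_bins)


def encounters_from_intervals(
    intervals_by_class: dict[str, pd.DataFrame], start_utc
) -> pd.DataFrame:
    """Stack per-class interval tables into one UTC encounter log."""
    t0 = pd.Timestamp(start_utc)
    if t0.tzinfo is None:
        t0 = t0.tz_localize("UTC")
    rows = []
    for cls, df in intervals_by_class.items():
        for _, row in df.iterrows():
            rows.append(
                {
                    "signal_class": cls,
                    "start_utc": t0 + pd.to_timedelta(row["start_s"], unit="s"),
                    "end_utc": t0 + pd.to_timedelta(row["end_s"], unit="s"),
                }
            )
    log = pd.DataFrame(rows, columns=["signal_class", "start_utc", "end_utc"])
    return log.sort_values(["signal_class", "start_utc"], kind="stable").reset_index(drop=True)
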