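"""Soundscape metrics: 1-Hz/1-s PSD, minute medians, third-octave levels.

The processing chain follows the standard long-term monitoring recipe:
Welch PSD with a window equal to the FFT length and no overlap (one
periodogram per second, 1-Hz bins), per-minute medians taken in linear
power over at least 30 usable seconds, one-third-octave band levels (TOLs)
on exact base-10 IEC 61260 edges for the 39 bands with nominal centres
from ~13 Hz to 80 kHz, the 125-Hz-band vessel-noise indicator converted
back to spectral density, and narrow 200-Hz "proxy" bins that isolate
energy from ultrasonic antifouling combs (19.3–19.5 kHz) and 28-kHz
(29.1–29.3 kHz) and 50-kHz (49.9–50.1 kHz) echosounders.  Seconds that
overlap recorder disk-write bursts are excluded before any statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import periodogram

from .calib import CalibratedRecording

#: Base-10 third-octave band numbers for nominal centres ~13 Hz … 80 kHz.
_TOL_BAND_NUMBERS = np.arange(11, 50)  # 10^(n/10): 12.59 Hz … 79.4 kHz
_NOMINAL_PER_DECADE = [12.5, 16.0, 20.0, 25.0, 31.5, 40.0, 50.0, 63.0, 80.0, 100.0]


def tol_band_table() -> pd.DataFrame:
    """The 39 one-third-octave bands: exact centres, edges and bandwidths."""
    centers = 10.0 ** (_TOL_BAND_NUMBERS / 10.0)
    lower = centers * 10.0 ** (-1.0 / 20.0)
    upper = centers * 10.0 ** (1.0 / 20.0)
    nominal = [
        _NOMINAL_PER_DECADE[(n - 1) % 10] * 10.0 ** ((n - 1) // 10 - 1)
        for n in _TOL_BAND_NUMBERS
    ]
    return pd.DataFrame(
        {
            "band_number": _TOL_BAND_NUMBERS,
            "nominal_hz": nominal,
            "center_hz": centers,
            "lower_hz": lower,
            "upper_hz": upper,
            "bandwidth_hz": upper - lower,
        }
    )


@dataclass
class SoundscapeConfig:
    fft_len_s: float = 1.0  # window = FFT length → one periodogram per second
    minute_min_coverage_s: float = 30.0
    proxy_bands_hz: tuple = ((19_300.0, 19_500.0), (29_100.0, 29_300.0), (49_900.0, 50_100.0))
    coarse_bin_hz: float = 200.0
    exclude_intervals: tuple = ()  # (start_s, end_s) pairs, e.g. disk writes
    clamp_floor_db: float = 40.0  # instrument self-noise floor for dB conversion

    def __post_init__(self) -> None:
        bands = sorted(self.proxy_bands_hz)
        for (a, b), (c, d) in zip(bands, bands[1:]):
            if c < b:
                raise ValueError("proxy bands must not overlap")


@dataclass
class MinuteMetrics:
    """Per-minute medians of the full soundscape-metric set.

    Rows with ``coverage_s`` below the configured minimum carry NaN.
    """

    minute_utc: pd.DatetimeIndex
    coverage_s: np.ndarray
    freqs_hz: np.ndarray
    psd_1hz_db: np.ndarray  # (n_minutes, n_freqs), dB re 1 µPa²/Hz
    coarse_freqs_hz: np.ndarray
    psd_coarse_db: np.ndarray  # (n_minutes, n_coarse), dB re 1 µPa²/Hz
    tol_db: np.ndarray  # (n_minutes, 39), dB re 1 µPa²
    tol125_density_db: np.ndarray  # (n_minutes,), dB re 1 µPa²/Hz
    proxy_db: np.ndarray  # (n_minutes, n_proxy), dB re 1 µPa²/Hz


def welch_psd(
    rec: CalibratedRecording, config: SoundscapeConfig | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-second PSD frames in linear µPa²/Hz at 1-Hz resolution.

    Returns ``(frames, freqs_hz, second_index)`` where frames has one row
    per complete non-overlapping 1-s window (Hann window the full FFT
    length, i.e. a periodogram per second), corrected by the transfer
    function.  A segment shorter than one FFT yields zero frames.
    """
    config = config or SoundscapeConfig()
    fs = rec.sample_rate
    nper = int(round(config.fft_len_s * fs))
    n_frames = len(rec.samples) // nper
    if n_frames == 0:
        return np.empty((0, nper // 2 + 1)), np.arange(nper // 2 + 1) * (fs / nper), np.empty(0, int)
    freqs = None
    frames = np.empty((n_frames, nper // 2 + 1))
    for i in range(n_frames):
        seg = rec.samples[i * nper : (i + 1) * nper]
        freqs, psd = periodogram(seg, fs=fs, window="hann", scaling="density")
        frames[i] = psd
    frames *= rec.transfer_function.linear_power_gain(freqs)[None, :]
    return frames, freqs, np.arange(n_frames)


def usable_seconds(
    second_index: np.ndarray, config: SoundscapeConfig
) -> np.ndarray:
    """Mask of seconds whose [s, s+1) window avoids all excluded intervals."""
    mask = np.ones(len(second_index), dtype=bool)
    for a, b in config.exclude_intervals:
        mask &= ~((second_index < b) & (second_index + 1 > a))
    return mask


def minute_median(
    values: np.ndarray, second_index: np.ndarray, mask: np.ndarray, min_cov: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Median per minute in linear power; minutes under coverage → NaN."""
    minutes = second_index // 60
    uniq = np.unique(minutes)
    out = np.full((len(uniq),) + values.shape[1:], np.nan)
    coverage = np.zeros(len(uniq))
    for i, m in enumerate(uniq):
        sel = (minutes == m) & mask
        coverage[i] = sel.sum()
        if coverage[i] >= min_cov:
            out[i] = np.median(values[sel], axis=0)
    return uniq, coverage, out


def _to_db(linear: np.ndarray, clamp_floor_db: float) -> np.ndarray:
    floor = 10.0 ** (clamp_floor_db / 10.0)
    return 10.0 * np.log10(np.maximum(linear, floor))


def tol_levels(
    frames: np.ndarray, freqs_hz: np.ndarray, config: SoundscapeConfig | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-second third-octave band powers (linear µPa²) for the 39 bands.

    Band power integrates the 1-Hz PSD over half-open [lower, upper) edges;
    bands whose upper edge exceeds the available bandwidth are NaN.
    """
    bands = tol_band_table()
    df_hz = freqs_hz[1] - freqs_hz[0]
    out = np.full((frames.shape[0], len(bands)), np.nan)
    for j, row in bands.iterrows():
        sel = (freqs_hz >= row["lower_hz"]) & (freqs_hz < row["upper_hz"])
        if row["upper_hz"] > freqs_hz[-1] + df_hz / 2.0:
            continue  # insufficient PSD bandwidth for this band
        out[:, j] = frames[:, sel].sum(axis=1) * df_hz
    return out, bands


def tol125_density(tol_db, bandwidth_hz: float | None = None) -> np.ndarray:
    """Convert a nominal-125-Hz band level to spectral density.

    Subtracts 10·log10(bandwidth); with no bandwidth given, the exact
    base-10 bandwidth of the 125-Hz third-octave band (≈29.0 Hz) is used.
    """
    if bandwidth_hz is None:
        bands = tol_band_table()
        bandwidth_hz = float(
            bands.loc[bands["nominal_hz"] == 125.0, "bandwidth_hz"].iloc[0]
        )
    return np.asarray(tol_db, dtype=float) - 10.0 * np.log10(bandwidth_hz)


def coarse_psd(
    frames: np.ndarray, freqs_hz: np.ndarray, bin_hz: float
) -> tuple[np.ndarray, np.ndarray]:
    """Mean PSD density over consecutive ``bin_hz``-wide frequency bins."""
    edges = np.arange(0.0, freqs_hz[-1] + bin_hz, bin_hz)
    centers = (edges[:-1] + edges[1:]) / 2.0
    out = np.empty((frames.shape[0], len(centers)))
    for j, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        sel = (freqs_hz >= lo) & (freqs_hz < hi)
        out[:, j] = frames[:, sel].mean(axis=1)
    return out, centers


def proxy_bin_psd(
    frames: np.ndarray, freqs_hz: np.ndarray, config: SoundscapeConfig
) -> np.ndarray:
    """Per-second mean PSD density within each configured proxy band."""
    out = np.empty((frames.shape[0], len(config.proxy_bands_hz)))
    for j, (lo, hi) in enumerate(config.proxy_bands_hz):
        sel = (freqs_hz >= lo) & (freqs_hz < hi)
        if not sel.any():
            out[:, j] = np.nan
        else:
            out[:, j] = frames[:, sel].mean(axis=1)
    return out


def compute_minute_metrics(
    rec: CalibratedRecording, config: SoundscapeConfig | None = None
) -> MinuteMetrics:
    """Full per-minute soundscape metric set for one recording.

    The 30-s coverage rule is applied identically to the 1-Hz PSD, the
    coarse-bin PSD, the TOLs and the proxy bins: all statistics for a
    minute come from the same set of usable seconds.
    """
    config = config or SoundscapeConfig()
    frames, freqs, seconds = welch_psd(rec, config)
    mask = usable_seconds(seconds, config)
    min_cov = config.minute_min_coverage_s

    uniq, coverage, psd_med = minute_median(frames, seconds, mask, min_cov)
    tol_sec, bands = tol_levels(frames, freqs, config)
    _, _, tol_med = minute_median(tol_sec, seconds, mask, min_cov)
    coarse_sec, coarse_centers = coarse_psd(frames, freqs, config.coarse_bin_hz)
    _, _, coarse_med = minute_median(coarse_sec, seconds, mask, min_cov)
    proxy_sec = proxy_bin_psd(frames, freqs, config)
    _, _, proxy_med = minute_median(proxy_sec, seconds, mask, min_cov)

    clamp = config.clamp_floor_db
    tol_db = 10.0 * np.log10(
        np.maximum(tol_med, 1e-300)
    )  # band levels: clamp only densities
    idx125 = int(np.flatnonzero(bands["nominal_hz"] == 125.0)[0])
    bw125 = float(bands["bandwidth_hz"].iloc[idx125])
    minutes_utc = rec.start_utc + pd.to_timedelta(uniq, unit="min")
    return MinuteMetrics(
        minute_utc=pd.DatetimeIndex(minutes_utc),
        coverage_s=coverage,
        freqs_hz=freqs,
        psd_1hz_db=_to_db(psd_med, clamp),
        coarse_freqs_hz=coarse_centers,
        psd_coarse_db=_to_db(coarse_med, clamp),
        tol_db=tol_db,
        tol125_density_db=tol125_density(tol_db[:, idx125], bw125),
        proxy_db=_to_db(proxy_med, clamp),
    )


def metrics_table(metrics: MinuteMetrics, config: SoundscapeConfig | None = None) -> pd.DataFrame:
    """Flat per-minute CSV-ready table of the headline indicator columns."""
    config = config or SoundscapeConfig()
    cols = {
        "minute_utc": metrics.minute_utc,
        "coverage_s": metrics.coverage_s,
        "tol125_density_db": metrics.tol125_density_db,
    }
    for j, (lo, hi) in enumerate(config.proxy_bands_hz):
        cols[f"proxy_{lo / 1e3:g}_{hi / 1e3:g}_khz_db"] = metrics.proxy_db[:, j]
    return pd.DataFrame(cols)
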