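"""Synthetic source-signal templates for calibrated acoustic scenes.

Each template describes one sound source as received at the hydrophone:
Cuvier's beaked whale FM echolocation pulses, short delphinid-like clicks,
ultrasonic antifouling (UA) pulse combs, narrowband navigational echosounder
pings, low-frequency vessel engine noise, and the recorder's own periodic
disk-write noise.  Levels are *received* levels at the sensor in dB re 1 µPa
— no propagation model is applied.

The beaked whale pulse is modelled as a linear-FM upsweep under a smooth
envelope with two additive low-frequency resonances, reproducing the
species' characteristic features: peak frequency near 40 kHz, secondary
spectral peaks near 17 and 23 kHz, duration above 355 µs, and a steep
upsweep.  ``duration`` on click-like templates always means the −10 dB
Hilbert-envelope width, matching how the feature extractor measures it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.signal import butter, sosfiltfilt
from scipy.signal import hilbert as _hilbert
from scipy.signal.windows import tukey

SOURCE_KINDS = (
    "cuvier_fm",
    "delphinid",
    "ua_comb",
    "echosounder_28",
    "echosounder_50",
    "vessel_lowfreq",
    "disk_write",
)

# −10 dB full width of a Gaussian envelope is 2·sqrt(2·ln(10^0.5))·σ ≈ 3.03σ.
_GAUSS_WIDTH_FACTOR = 2.0 * np.sqrt(2.0 * np.log(10.0 ** 0.5))

# Safety factor on the FM-pulse support when checking Nyquist headroom (the
# envelope width is calibrated numerically and can stretch σ slightly).
_FM_SUPPORT_MARGIN = 3.5


@dataclass(frozen=True)
class SourceTemplate:
    """One sound source as received at the hydrophone."""

    kind: str
    level_db: float  # received level, dB re 1 µPa (RMS; see each maker)
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in SOURCE_KINDS:
            raise ValueError(f"unknown source kind {self.kind!r}")

    def with_params(self, **updates) -> "SourceTemplate":
        merged = dict(self.params)
        merged.update(updates)
        return replace(self, params=merged)

    def with_level(self, level_db: float) -> "SourceTemplate":
        return replace(self, level_db=level_db)


# ---------------------------------------------------------------------------
# Template factories (field-realistic defaults)
# ---------------------------------------------------------------------------

def cuvier_template(level_db: float = 115.0) -> SourceTemplate:
    """Cuvier's beaked whale FM pulse train template.

    Peak 40 kHz, secondary spectral peaks near 17 and 23 kHz, −10 dB
    duration 450 µs, 30 kHz/ms upsweep, inter-pulse interval uniform in
    [0.4, 0.5] s.
    """
    return SourceTemplate(
        kind="cuvier_fm",
        level_db=level_db,
        params={
            "peak_freq_hz": 40_000.0,
            "duration_s": 450e-6,
            "sweep_rate_hz_per_s": 30e6,  # 30 kHz/ms
            "resonance_freqs_hz": (17_000.0, 23_000.0),
            "resonance_rel_amp": 0.18,
            "ipi_range_s": (0.4, 0.5),
        },
    )


def delphinid_template(level_db: float = 115.0) -> SourceTemplate:
    """Short unmodulated delphinid-like click (confuser class).

    Falls inside every FM-pulse deletion criterion: 24 kHz peak (< 32 kHz,
    centroid < 25 kHz), 120 µs duration (< 355 µs) and no sweep.
    """
    return SourceTemplate(
        kind="delphinid",
        level_db=level_db,
        params={
            "peak_freq_hz": 24_000.0,
            "duration_s": 120e-6,
            "ipi_range_s": (0.15, 0.25),
        },
    )


#: UA comb component sets (kHz → Hz below), lowest component ~19.4 kHz.
#: The anchored preset tops out near 42 kHz, the transiting preset near
#: 88 kHz, and the close-range port preset near 166 kHz.
_UA_PRESETS = {
    "anchored": (19.4e3, 22.6e3, 25.8e3, 28.7e3, 31.9e3, 35.2e3, 38.6e3, 42.0e3),
    "transiting": (
        19.4e3, 22.6e3, 25.8e3, 28.7e3, 31.9e3, 35.2e3, 38.6e3, 42.0e3,
        46.5e3, 51.5e3, 57.0e3, 63.0e3, 70.0e3, 78.0e3, 88.0e3,
    ),
    "port": (
        19.4e3, 25.8e3, 31.9e3, 38.6e3, 46.5e3, 57.0e3, 70.0e3, 88.0e3,
        110.0e3, 135.0e3, 166.0e3,
    ),
}


def ua_template(preset: str = "anchored", level_db: float = 110.0) -> SourceTemplate:
    """Ultrasonic antifouling pulse-comb template.

    ``level_db`` is the per-component RMS received level while the pulse is
    on.  Pulse length and repetition period are free parameters (not
    constrained by any published duty cycle); the default is a 0.2 s
    multi-tone pulse every 0.25 s.
    """
    if preset not in _UA_PRESETS:
        raise ValueError(f"unknown UA preset {preset!r}")
    return SourceTemplate(
        kind="ua_comb",
        level_db=level_db,
        params={
            "component_freqs_hz": _UA_PRESETS[preset],
            "pulse_len_s": 0.2,
            "pulse_period_s": 0.25,
            "preset": preset,
        },
    )


def echosounder_template(kind: str = "echosounder_28", level_db: float = 125.0) -> SourceTemplate:
    """Narrowband echosounder ping template (28-kHz or 50-kHz class)."""
    if kind == "echosounder_28":
        params = {
            "peak_freq_hz": 28_800.0,
            "band_hz": (27_000.0, 31_000.0),
            "duration_s": 2e-3,
            "ping_interval_s": 1.1,
        }
    elif kind == "echosounder_50":
        params = {
            "peak_freq_hz": 50_000.0,
            "band_hz": (49_000.0, 51_000.0),
            "duration_s": 2e-3,
            "ping_interval_s": 1.1,
        }
    else:
        raise ValueError(f"unknown echosounder kind {kind!r}")
    return SourceTemplate(kind=kind, level_db=level_db, params=params)


def vessel_template(level_db: float = 100.0) -> SourceTemplate:
    """Continuous vessel engine noise with energy below 300 Hz.

    ``level_db`` is the total band RMS level of the low-frequency noise.
    """
    return SourceTemplate(
        kind="vessel_lowfreq",
        level_db=level_db,
        params={"cutoff_hz": 300.0, "filter_order": 6},
    )


def disk_write_template(elevation_db: float = 20.0) -> SourceTemplate:
    """Recorder disk-write noise: broadband burst above the ambient floor.

    ``level_db`` stores the PSD elevation (dB) over the scene noise floor.
    """
    return SourceTemplate(
        kind="disk_write",
        level_db=elevation_db,
        params={"burst_len_s": 15.0, "cycle_s": 75.0},
    )


# ---------------------------------------------------------------------------
# Waveform synthesis
# ---------------------------------------------------------------------------

def _rms_scale(x: np.ndarray, level_db: float) -> np.ndarray:
    """Scale a snippet so its RMS over its own support equals level_db."""
    rms = np.sqrt(np.mean(x**2))
    if rms == 0:
        raise ValueError("cannot scale an all-zero snippet")
    return x * (10.0 ** (level_db / 20.0) / rms)


def template_max_frequency(template: SourceTemplate) -> float:
    """Highest significant frequency a template emits (for Nyquist checks)."""
    p = template.params
    if template.kind == "cuvier_fm":
        sigma = float(p["duration_s"]) / _GAUSS_WIDTH_FACTOR
        return float(p["peak_freq_hz"]) + float(p["sweep_rate_hz_per_s"]) * _FM_SUPPORT_MARGIN * sigma
    if template.kind == "delphinid":
        sigma_t = float(p["duration_s"]) / _GAUSS_WIDTH_FACTOR
        return float(p["peak_freq_hz"]) + 3.0 / (2.0 * np.pi * sigma_t)
    if template.kind == "ua_comb":
        return max(p["component_freqs_hz"])
    if template.kind in ("echosounder_28", "echosounder_50"):
        return float(p["band_hz"][1])
    if template.kind == "vessel_lowfreq":
        return float(p["cutoff_hz"]) * 2.0
    return 0.0  # disk_write: broadband, shaped to whatever band exists


def make_fm_pulse(template: SourceTemplate, sample_rate: float) -> np.ndarray:
    """Render one upswept polycyclic FM pulse (µPa snippet).

    A linear chirp under a Gaussian envelope — its spectrum is then itself
    Gaussian, peaked exactly at the instantaneous frequency of the envelope
    maximum, with no Fresnel ripple.  Two resonances sharing the envelope
    add the characteristic secondary spectral peaks.  The envelope σ is
    calibrated numerically (two passes) so the measured −10 dB Hilbert
    width equals ``duration_s``.
    """
    if template.kind != "cuvier_fm":
        raise ValueError("make_fm_pulse requires a cuvier_fm template")
    p = template.params
    duration = float(p["duration_s"])
    if duration <= 0:
        raise ValueError("pulse duration must be positive")
    if template_max_frequency(template) >= sample_rate / 2.0:
        raise ValueError(
            "template sweeps above Nyquist "
            f"({template_max_frequency(template):.0f} Hz ≥ {sample_rate / 2:.0f} Hz)"
        )
    f0 = float(p["peak_freq_hz"])
    sweep = float(p["sweep_rate_hz_per_s"])
    rel = float(p.get("resonance_rel_amp", 0.15))
    resonances = tuple(float(f) for f in p.get("resonance_freqs_hz", ()))
    sigma = duration / _GAUSS_WIDTH_FACTOR
    if f0 - sweep * _FM_SUPPORT_MARGIN * sigma <= 0:
        raise ValueError("sweep drives instantaneous frequency below 0 Hz")

    def render(sig: float) -> np.ndarray:
        n = max(int(round(6.0 * sig * sample_rate)), 16)
        t = (np.arange(n) - (n - 1) / 2.0) / sample_rate
        env = np.exp(-(t**2) / (2.0 * sig**2))
        x = env * np.cos(2.0 * np.pi * (f0 * t + 0.5 * sweep * t**2))
        for fr in resonances:
            x += rel * env * np.cos(2.0 * np.pi * fr * t)
        return x

    x = render(sigma)
    for _ in range(2):  # match measured −10 dB width to the nominal duration
        env = np.abs(_hilbert(x))
        above = np.flatnonzero(env >= env.max() * 10.0 ** (-10.0 / 20.0))
        width = (above[-1] - above[0] + 1) / sample_rate
        sigma *= duration / width
        x = render(sigma)
    return _rms_scale(x, template.level_db)


def make_click(template: SourceTemplate, sample_rate: float) -> np.ndarray:
    """Render one short Gaussian-envelope click (delphinid confuser)."""
    if template.kind != "delphinid":
        raise ValueError("make_click requires a delphinid template")
    p = template.params
    duration = float(p["duration_s"])
    if duration <= 0:
        raise ValueError("click duration must be positive")
    if template_max_frequency(template) >= sample_rate / 2.0:
        raise ValueError("click spectrum exceeds Nyquist")
    sigma = duration / _GAUSS_WIDTH_FACTOR
    half = 3.0 * sigma
    n = max(int(round(2.0 * half * sample_rate)), 8)
    t = (np.arange(n) - (n - 1) / 2.0) / sample_rate
    x = np.exp(-(t**2) / (2.0 * sigma**2)) * np.cos(
        2.0 * np.pi * float(p["peak_freq_hz"]) * t
    )
    return _rms_scale(x, template.level_db)


def make_ping(template: SourceTemplate, sample_rate: float) -> np.ndarray:
    """Render one narrowband echosounder ping.

    A Gaussian-windowed tone at the class peak frequency; essentially all
    (≥95%) of the energy falls inside the template's stated band.
    """
    if template.kind not in ("echosounder_28", "echosounder_50"):
        raise ValueError("make_ping requires an echosounder template")
    p = template.params
    lo, hi = (float(v) for v in p["band_hz"])
    if lo >= sample_rate / 2.0:
        raise ValueError("echosounder band lies entirely above Nyquist")
    if hi >= sample_rate / 2.0:
        raise ValueError("echosounder band edge exceeds Nyquist")
    duration = float(p["duration_s"])
    if duration <= 0:
        raise ValueError("ping duration must be positive")
    sigma = duration / _GAUSS_WIDTH_FACTOR
    half = 4.0 * sigma
    n = max(int(round(2.0 * half * sample_rate)), 8)
    t = (np.arange(n) - (n - 1) / 2.0) / sample_rate
    x = np.exp(-(t**2) / (2.0 * sigma**2)) * np.cos(
        2.0 * np.pi * float(p["peak_freq_hz"]) * t
    )
    return _rms_scale(x, template.level_db)


def make_ua_comb(
    template: SourceTemplate, sample_rate: float, duration: float
) -> np.ndarray:
    """Render a repeating multi-frequency UA pulse train of given duration.

    Each pulse is the sum of equal-amplitude tones at the comb component
    frequencies under a short-ramp Tukey envelope; ``level_db`` sets the
    per-component RMS level during the on phase.
    """
    if template.kind != "ua_comb":
        raise ValueError("make_ua_comb requires a ua_comb template")
    p = template.params
    comps = tuple(float(f) for f in p["component_freqs_hz"])
    if len(comps) == 0:
        raise ValueError("UA comb has no components")
    if min(comps) < 1_000.0:
        raise ValueError("lowest comb frequency must be at least 1 kHz")
    if max(comps) >= sample_rate / 2.0:
        raise ValueError("comb component exceeds Nyquist")
    n_total = int(round(duration * sample_rate))
    pulse_len = float(p["pulse_len_s"])
    period = float(p["pulse_period_s"])
    if pulse_len <= 0 or period < pulse_len:
        raise ValueError("need 0 < pulse_len_s <= pulse_period_s")
    amp = np.sqrt(2.0) * 10.0 ** (template.level_db / 20.0)
    out = np.zeros(n_total)
    n_pulse = int(round(pulse_len * sample_rate))
    ramp = tukey(n_pulse, alpha=min(0.1, 2e-3 * sample_rate / n_pulse))
    start = 0
    while start < n_total:
        stop = min(start + n_pulse, n_total)
        seg = slice(start, stop)
        t = np.arange(start, stop) / sample_rate
        pulse = np.zeros(stop - start)
        for f in comps:
            pulse += amp * np.cos(2.0 * np.pi * f * t)
        out[seg] += pulse * ramp[: stop - start]
        start += int(round(period * sample_rate))
    return out


def make_vessel_noise(
    template: SourceTemplate,
    sample_rate: float,
    duration: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render continuous low-frequency vessel engine noise.

    Low-pass-filtered Gaussian noise scaled so its total RMS equals the
    template band level.
    """
    if template.kind != "vessel_lowfreq":
        raise ValueError("make_vessel_noise requires a vessel_lowfreq template")
    rng = rng or np.random.default_rng(0)
    p = template.params
    cutoff = float(p["cutoff_hz"])
    if cutoff >= sample_rate / 2.0:
        raise ValueError("vessel band cutoff exceeds Nyquist")
    n = int(round(duration * sample_rate))
    white = rng.standard_normal(n)
    sos = butter(int(p.get("filter_order", 6)), cutoff, "lowpass", fs=sample_rate, output="sos")
    shaped = sosfiltfilt(sos, white)
    return _rms_scale(shaped, template.level_db)
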