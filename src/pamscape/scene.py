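"""Scene assembly: scheduled source events + shaped noise → calibrated audio.

A :class:`SceneSpec` fully determines a scene (one seeded random stream per
scene; event randomness such as inter-pulse jitter is drawn before the noise
so the ground-truth log does not depend on the noise realisation).  The
output pair is a :class:`~pamscape.calib.CalibratedRecording` plus a
ground-truth table with one row per emitted event, directly comparable to
the encounter logs the detectors produce.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .calib import CalibratedRecording, TransferFunction, full_scale_pressure, DEFAULT_FULL_SCALE_DB
from .synth import (
    SourceTemplate,
    make_click,
    make_fm_pulse,
    make_ping,
    make_ua_comb,
    make_vessel_noise,
    template_max_frequency,
)

logger = logging.getLogger(__name__)

TRUTH_COLUMNS = ["signal_class", "start_s", "end_s", "start_utc", "end_utc", "param_json"]


@dataclass(frozen=True)
class ScheduledEvent:
    """One scheduled source activation inside a scene.

    For click/ping trains ``count`` is the number of pulses; for continuous
    sources (UA comb, vessel noise) ``duration_s`` gives the on-time.
    """

    template: SourceTemplate
    start_s: float
    count: int = 1
    duration_s: float | None = None


@dataclass
class SceneSpec:
    duration_s: float
    sample_rate: float = 200_000.0
    events: list = field(default_factory=list)
    noise_floor_db: float = 40.0  # dB re 1 µPa²/Hz, flat to Nyquist
    seed: int = 0
    start_utc: str = "2019-07-01T00:00:00Z"
    full_scale_db: float = DEFAULT_FULL_SCALE_DB
    disk_write: bool = False
    disk_write_elevation_db: float = 20.0
    disk_write_burst_s: float = 15.0
    disk_write_cycle_s: float = 75.0

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["events"] = [
            {
                "kind": ev.template.kind,
                "level_db": ev.template.level_db,
                "params": dict(ev.template.params),
                "start_s": ev.start_s,
                "count": ev.count,
                "duration_s": ev.duration_s,
            }
            for ev in self.events
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SceneSpec":
        with open(path) as fh:
            payload = json.load(fh)
        events = [
            ScheduledEvent(
                template=SourceTemplate(
                    kind=ev["kind"], level_db=ev["level_db"], params=ev["params"]
                ),
                start_s=ev["start_s"],
                count=ev.get("count", 1),
                duration_s=ev.get("duration_s"),
            )
            for ev in payload.pop("events", [])
        ]
        return cls(events=events, **payload)


def _validate(spec: SceneSpec) -> None:
    if spec.duration_s <= 0:
        raise ValueError("scene duration must be positive")
    for ev in spec.events:
        if not 0 <= ev.start_s < spec.duration_s:
            raise ValueError(f"event start {ev.start_s} s outside [0, {spec.duration_s})")
        fmax = template_max_frequency(ev.template)
        if fmax >= spec.sample_rate / 2.0:
            raise ValueError(
                f"{ev.template.kind} template needs sample rate > {2 * fmax:.0f} Hz"
            )


def _add(target: np.ndarray, snippet: np.ndarray, start_idx: int) -> None:
    stop = min(start_idx + len(snippet), len(target))
    if stop > start_idx >= 0:
        target[start_idx:stop] += snippet[: stop - start_idx]


def assemble_scene(spec: SceneSpec) -> tuple[CalibratedRecording, pd.DataFrame]:
    """Render a scene to pressure samples plus a ground-truth event table.

    Deterministic under a fixed spec (including seed).  If the summed scene
    would clip 16-bit full scale a warning is issued and the waveform is
    rescaled; the applied factor is recorded in ``truth.attrs["scale"]``.
    """
    _validate(spec)
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.sample_rate))
    fs = spec.sample_rate
    x = np.zeros(n)
    rows: list[dict] = []
    t0 = pd.Timestamp(spec.start_utc)
    if t0.tzinfo is None:
        t0 = t0.tz_localize("UTC")

    def log(cls: str, start: float, end: float, params: dict) -> None:
        end = min(end, spec.duration_s)
        rows.append(
            {
                "signal_class": cls,
                "start_s": start,
                "end_s": end,
                "start_utc": t0 + pd.to_timedelta(start, unit="s"),
                "end_utc": t0 + pd.to_timedelta(end, unit="s"),
                "param_json": json.dumps(params, sort_keys=True),
            }
        )

    # Event randomness first (IPI jitter, vessel noise realisation) so the
    # truth log is independent of the ambient-noise draw below.
    for ev in spec.events:
        kind = ev.template.kind
        if kind in ("cuvier_fm", "delphinid"):
            maker = make_fm_pulse if kind == "cuvier_fm" else make_click
            snippet = maker(ev.template, fs)
            ipi_lo, ipi_hi = ev.template.params["ipi_range_s"]
            t = ev.start_s
            for _ in range(ev.count):
                if t >= spec.duration_s:
                    break
                _add(x, snippet, int(round(t * fs)))
                log(
                    kind,
                    t,
                    t + len(snippet) / fs,
                    {"peak_freq_hz": ev.template.params["peak_freq_hz"]},
                )
                t += rng.uniform(ipi_lo, ipi_hi)
        elif kind in ("echosounder_28", "echosounder_50"):
            snippet = make_ping(ev.template, fs)
            interval = float(ev.template.params["ping_interval_s"])
            for k in range(ev.count):
                t = ev.start_s + k * interval
                if t >= spec.duration_s:
                    break
                _add(x, snippet, int(round(t * fs)))
                log(kind, t, t + len(snippet) / fs, {"peak_freq_hz": ev.template.params["peak_freq_hz"]})
        elif kind == "ua_comb":
            dur = ev.duration_s if ev.duration_s is not None else spec.duration_s - ev.start_s
            wav = make_ua_comb(ev.template, fs, dur)
            _add(x, wav, int(round(ev.start_s * fs)))
            log(
                kind,
                ev.start_s,
                ev.start_s + dur,
                {"preset": ev.template.params.get("preset", "custom")},
            )
        elif kind == "vessel_lowfreq":
            dur = ev.duration_s if ev.duration_s is not None else spec.duration_s - ev.start_s
            wav = make_vessel_noise(ev.template, fs, dur, rng=rng)
            _add(x, wav, int(round(ev.start_s * fs)))
            log(kind, ev.start_s, ev.start_s + dur, {"cutoff_hz": ev.template.params["cutoff_hz"]})
        else:
            raise ValueError(f"cannot schedule source kind {kind!r}")

    # Ambient noise shaped to the configured flat spectral floor.
    sigma = np.sqrt(10.0 ** (spec.noise_floor_db / 10.0) * fs / 2.0)
    x += rng.standard_normal(n) * sigma

    # Recorder disk-write artifact: broadband burst over the floor on a
    # fixed duty cycle, detectable so the downstream omission logic is real.
    if spec.disk_write:
        burst_sigma = sigma * np.sqrt(
            10.0 ** (spec.disk_write_elevation_db / 10.0) - 1.0
        )
        t = 0.0
        while t < spec.duration_s:
            i0 = int(round(t * fs))
            i1 = min(int(round((t + spec.disk_write_burst_s) * fs)), n)
            x[i0:i1] += rng.standard_normal(i1 - i0) * burst_sigma
            log("disk_write", t, t + spec.disk_write_burst_s, {})
            t += spec.disk_write_cycle_s

    scale = 1.0
    fs_pressure = full_scale_pressure(spec.full_scale_db)
    peak = np.max(np.abs(x)) if n else 0.0
    if peak > fs_pressure:
        scale = 0.99 * fs_pressure / peak
        warnings.warn(
            f"scene clips 16-bit full scale (peak {peak:.3g} µPa); rescaled by {scale:.3g}",
            stacklevel=2,
        )
        logger.warning("scene rescaled by %.4g to avoid clipping", scale)
        x *= scale

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS).sort_values(
        ["start_s", "signal_class"], kind="stable"
    ).reset_index(drop=True)
    truth.attrs["scale"] = scale
    rec = CalibratedRecording(
        samples=x,
        sample_rate=fs,
        start_utc=t0,
        transfer_function=TransferFunction.flat(),
        full_scale_db=spec.full_scale_db,
    )
    return rec, truth


def example_scene_spec(seed: int = 0) -> SceneSpec:
    """A 3-minute mixed demonstration scene used by the analysis scripts.

    Three beaked-whale click trains (one inside the UA-on segment, where
    comb pulse onsets flood the energy detector and mask the train), a
    delphinid confuser train, an anchored UA comb, a 28-kHz echosounder
    bout and a vessel transit, all over the 40 dB instrument floor.
    """
    from .synth import (
        cuvier_template,
        delphinid_template,
        echosounder_template,
        ua_template,
        vessel_template,
    )

    return SceneSpec(
        duration_s=180.0,
        sample_rate=200_000.0,
        seed=seed,
        events=[
            ScheduledEvent(template=cuvier_template(), start_s=10.0, count=12),
            ScheduledEvent(template=cuvier_template(), start_s=100.0, count=12),
            ScheduledEvent(template=cuvier_template(), start_s=160.0, count=12),
            ScheduledEvent(template=delphinid_template(), start_s=40.0, count=5),
            ScheduledEvent(template=ua_template("anchored"), start_s=75.0, duration_s=75.0),
            ScheduledEvent(
                template=echosounder_template("echosounder_28"), start_s=20.25, count=28
            ),
            ScheduledEvent(template=vessel_template(), start_s=0.0, duration_s=40.0),
        ],
    )


def truth_to_csv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False, columns=TRUTH_COLUMNS)


def truth_from_csv(path) -> pd.DataFrame:
    truth = pd.read_csv(path, parse_dates=["start_utc", "end_utc"])
    return truth
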