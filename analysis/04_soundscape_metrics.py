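#!/usr/bin/env python
"""Compute per-minute soundscape metrics for the demonstration scene.

1-Hz/1-s Welch PSD, per-minute linear-power medians, 39 third-octave band
levels, the 125-Hz vessel-noise density indicator and the three 200-Hz
anthropogenic proxy bins; renders the long-term spectrogram from the
stored minute metrics without recomputation.
"""

import os

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from pamscape import assemble_scene
from pamscape import soundscape
from pamscape.scene import example_scene_spec

os.makedirs("results", exist_ok=True)

rec, _ = assemble_scene(example_scene_spec(seed=0))
metrics = soundscape.compute_minute_metrics(rec)
table = soundscape.metrics_table(metrics)
table.to_csv("results/soundscape_minutes.csv", index=False)
print(table.round(2).to_string(index=False))
print("(Vessel transit lifts the 125-Hz indicator in minute 0; the UA comb "
      "on 75–150 s lifts the 19.3–19.5 kHz proxy in minutes 1–2 and its "
      "pulse splatter brushes the 29.1–29.3 kHz bin. The sparse ping bout "
      "in minute 0 barely moves that minute's median — the proxy medians "
      "respond to persistent sources, not isolated transients.)")

fig, ax = plt.subplots(figsize=(8, 4))
im = ax.pcolormesh(
    range(len(metrics.minute_utc)),
    metrics.coarse_freqs_hz / 1e3,
    metrics.psd_coarse_db.T,
    shading="nearest",
    cmap="viridis",
)
ax.set_xlabel("Minute")
ax.set_ylabel("Frequency (kHz)")
ax.set_title("Long-term spectrogram from per-minute 200-Hz PSD medians")
fig.colorbar(im, ax=ax, label="dB re 1 µPa²/Hz")
fig.tight_layout()
fig.savefig("results/minute_spectrogram.png", dpi=120)
print("Wrote results/soundscape_minutes.csv, results/minute_spectrogram.png")
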