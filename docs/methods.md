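# Methods

This note documents the models, numerical choices and limitations behind
`pamscape`. The package is an independent re-implementation of a standard
long-term passive-acoustic-monitoring workflow — click detection, analyst
screening of long-term spectral averages (LTSAs), soundscape metrics, and a
rank-based comparison of hourly activity across noise conditions —
validated entirely on synthetic scenes with known ground truth.

## Calibration model

Analysis works in absolute pressure (µPa). A single constant,
`full_scale_db` (default 140 dB re 1 µPa at digital full scale), maps
16-bit PCM counts to pressure; with it, the 40 dB re 1 µPa²/Hz instrument
noise floor sits ~50 dB above the 16-bit quantisation noise density, so
WAV round trips are transparent to within one quantisation step. A
frequency-dependent transfer function (CSV of frequency/gain pairs,
linearly interpolated, flat by default) is applied as a power gain in every
spectral product (PSD frames, LTSAs). No propagation model is used:
template levels are *received* levels at the sensor.

## Synthetic sources

**Beaked-whale FM pulse.** A linear-frequency-modulated upsweep under a
Gaussian envelope, plus two additive resonances (17 and 23 kHz, relative
amplitude 0.18) sharing the envelope. The Gaussian envelope is the key
numerical choice: a Gaussian-windowed linear chirp has an exactly Gaussian
magnitude spectrum peaked at the instantaneous frequency of the envelope
maximum, so the measured peak frequency equals the nominal 40 kHz with no
Fresnel ripple (flat-topped envelopes put the spectral argmax on a ripple
up to ±2 kHz off). `duration` means the −10 dB Hilbert-envelope width —
the same convention the feature extractor uses — and the envelope σ is
calibrated in two render passes so the measured width matches the nominal
450 µs (the resonances raise the envelope peak and would otherwise bias
the width a few percent). Defaults: peak 40 kHz, sweep 30 kHz/ms, IPI
uniform in [0.4, 0.5] s, received level 115 dB re 1 µPa (RMS over the
snippet).

**Delphinid confuser.** A 120 µs Gaussian-envelope click at 24 kHz with no
modulation. The peak was placed at 24 kHz so the click falls inside *all
four* deletion criteria (peak < 32 kHz, centroid < 25 kHz, duration
< 355 µs, sweep < 23 kHz/ms) and is removed under either connective;
delphinid clicks genuinely span roughly 20–40+ kHz, so this is a realistic
member of that class rather than a straw man.

**Echosounder pings.** Gaussian-windowed tones (2 ms, −10 dB) at 28.8 kHz
(energy within 27–31 kHz) and 50 kHz (49–51 kHz), repeated every 1.1 s at
125 dB re 1 µPa. The repetition period is deliberately *not* an integer
number of seconds: a ping train phase-locked to the 1-s Hann analysis
frames would always land where the window is near zero and vanish from the
PSD — a measurement artifact, not a property of real echosounders.

**UA comb.** Each pulse is a sum of equal-amplitude tones at the comb
component frequencies (lowest 19.4 kHz; anchored preset up to 42 kHz,
transiting to 88 kHz, close-range port preset to 166 kHz, with a component
at 28.7 kHz mirroring the comb energy that motivates placing the 28-kHz
echosounder proxy at 29.1–29.3 kHz). No published pulse schedule exists,
so the duty cycle is a free parameter: 0.2 s pulses every 0.25 s,
per-component level 110 dB re 1 µPa. The comb's pulse onsets are genuine
broadband transients; they trigger the click detector by design (see
"masking" below).

**Vessel noise.** Gaussian noise low-passed at 300 Hz (6th-order
Butterworth, zero-phase), total band level 100 dB re 1 µPa, continuous.

**Disk-write artifact.** Broadband noise 20 dB over the floor for 15 s of
every 75-s cycle — loud enough that the exclusion logic is testable, with
no claim about the true artifact spectrum.

**Scene assembly.** One seeded generator per scene; event randomness (IPI
jitter, vessel noise realisation) is drawn before the ambient noise so
ground-truth logs are noise-independent. Scenes that would clip 16-bit
full scale are rescaled with a warning and the factor recorded. Identical
specs produce bit-identical WAVs.

## Click detection and classification

The detector high-passes at 10 kHz (4th-order Butterworth, zero-phase),
applies the Teager–Kaiser operator, smooths over 200 µs and thresholds at
median + k·MAD with a 5 ms lockout. k defaults to 18: the smoothed TK
energy of filtered Gaussian noise is heavier-tailed than Gaussian, and
k = 18 yields zero false detections in 600 s of floor-level noise while
clicks at 95 dB re 1 µPa (≈6 dB over the in-band noise RMS) are still
detected with recall 1.0.

Features per candidate: peak = argmax of the zero-padded magnitude
spectrum in the 10 kHz–0.98·Nyquist band; centre = power-weighted spectral
centroid over that band; duration = −10 dB width of the lightly smoothed
Hilbert envelope; sweep rate = weighted least-squares slope of a
short-time ridge, where each 100-µs frame contributes its
parabolic-interpolated spectral argmax within ±15 kHz of the global peak
(keeping the 17/23 kHz resonances out of the fit) at its energy-centroid
time (plain frame centres flatten the slope of short pulses by ~15%).
Measured accuracy on synthetic pulses: peak within ±0.1 kHz, duration
within ±7%, sweep within ±4%.

Deletion criteria and segment rules use strict inequalities throughout
(a tie never deletes, "more than seven" means ≥8, "more than 13%" means
> 0.13 exactly), and both the grammatically conjunctive reading (delete
only when all four criteria hold — the default) and the per-criterion
disjunctive reading are implemented behind one switch. The original
pipeline's expert-system discrimination and manual-analyst review are not
reproducible; the deletion criteria plus the connective switch stand in
for them, and the end-to-end campaign uses the disjunctive logic because
it additionally rejects tonal interferers (echosounder pings and UA pulse
onsets have near-zero sweep rates) the way the expert stages would.

**Masking is modelled, not suppressed.** A UA comb in a segment floods the
energy detector with pulse-onset detections; the retained fraction then
falls below 13% even when a click train is present, so that segment logs
negative. This mirrors the real confound (whales near UA sources are both
quieter and harder to detect) and is why campaign hours with UA rank low
regardless of whether the simulated whale clicked.

## LTSA screening (analyst stand-ins)

The original screening was manual. The detectors here are explicit rules
with tunable margins, validated only against synthetic truth:

- **UA:** a time bin counts when ≥3 narrowband maxima stand ≥6 dB over the
  per-bin median floor above 18.5 kHz (comb structure).
- **Echosounders:** persistent in-band maxima (27–31 or 49–51 kHz) ≥6 dB
  over the floor, unless a comb line falls inside the band — and a line
  only counts as "comb" if another comb line sits within 5 kHz of it, so a
  lone 50-kHz sounder sharing the water with a 19–42 kHz comb is still
  logged while the comb's own 28.7 kHz line is not double-counted as a
  28-kHz sounder.
- **Vessels:** mean band level below 300 Hz on the ×20-decimated mid-band
  LTSA exceeding a baseline by 6 dB. The baseline is a rolling per-scene
  median by default; for snapshots too short (or too saturated) for a
  within-scene baseline, a fixed baseline derived from the known
  instrument floor can be supplied, which is what the campaign does.

Flagged bins merge into intervals across gaps of up to 2 bins; no
published criterion constrains this gap tolerance.

## Soundscape metrics

One Hann periodogram per second (window = FFT length = 1 s of samples, 0%
overlap) gives 1-Hz PSD frames; minutes with ≥30 usable seconds get
linear-power medians, converted to dB afterwards (dB-domain medians
differ). Third-octave bands use exact base-10 centres 10^(n/10) for
n = 11…49 — 39 bands, nominal centres ~13 Hz to 80 kHz — with edges
centre·10^(±1/20); consecutive bands tile frequency exactly, so summed
band powers equal the integrated PSD (Parseval) by construction. The
125-Hz indicator subtracts 10·log₁₀(28.99 Hz) from the nominal-125 Hz band
level. The 200-Hz proxies are the *mean density* over each band per
second, then the per-minute median — this follows the coarse-bin recipe
(mean over frequency, median over time); a median across the 200 1-Hz
bins would report the noise floor whenever the source is a single line.
The 30-s coverage rule and disk-write exclusion are applied to one shared
second mask, so PSD, TOL and proxy outputs flag the same minutes.

Two estimator properties worth knowing: a single 1-Hz periodogram bin is
~χ²(2), so its minute median sits 1.6 dB below the true density — floor
flatness is therefore asserted on the 200-Hz bins, where the median is
effectively unbiased; and a median-based proxy ignores sparse transients
(a 2-ms ping per second barely moves a minute median), responding instead
to persistent sources, which is exactly its purpose. dB conversion clamps
at the configured instrument floor (default 40 dB re 1 µPa²/Hz).

## Statistics

Hours are labelled 1–8 by the presence of UA / echosounder / vessel
encounters (any overlap with the hour counts; minute bins are UTC-aligned
and half-open, so an encounter ending exactly on a boundary does not touch
the next bin). `bw_minutes` counts distinct minute bins with beaked-whale
presence. Kruskal–Wallis (tie-corrected, χ² approximation; scipy) runs
across non-empty groups; post hoc comparisons are Dunn-type z tests on
pooled mean ranks with the tie-corrected variance and Bonferroni
adjustment over all pairs. Comparison intervals are mean rank ±
z_crit·√(S²/2n) at the Bonferroni-adjusted level; for equal group sizes
interval non-overlap coincides with pairwise significance (tested), for
unequal sizes it is the usual approximation.

## Campaign scaling

The end-to-end study is scaled to desk size: each simulated hour is
represented by its first 75 s (one classifier segment) at 125 kHz sampling
— enough bandwidth for the anchored comb (42 kHz), the 50-kHz sounder
class and the clicks — with 2–3 hours per condition. The whale response
model is multiplicative on the per-segment click-train probability
(base 0.97; ×0.05 under UA, ×0.5 under echosounders, ×0.75 under vessel
noise), encoding the ordering the analysis should recover: UA strongest.
With these sizes the pipeline recovers all eight conditions exactly and
every UA condition ranks below the quiet condition.

## What the synthetic scenes do and do not show

The generator reproduces the *cited spectral and temporal features* of
each source class over a flat noise floor. It does not emulate
propagation, multipath, clipping-free dynamic-range effects, biological
chorus, weather noise, overlapping click trains from multiple animals, or
the true UA duty cycle. Passing tests therefore demonstrate that the
pipeline's rules are implemented exactly and behave correctly where truth
is known — not that detection performance on real recordings would match
(the rule-based analyst stand-ins, in particular, replace trained human
judgement). Field-scale quantities that depend on the original multi-year
recordings (total χ², band-level increases in dB, absolute miss rates)
are out of reach by design and are not claimed.
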