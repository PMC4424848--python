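# spindlemp

Matching-pursuit parametrization of EEG transients, applied to automatic
detection of sleep spindles (and other structures such as slow waves) in
single-channel polysomnography.

Classical spindle detectors band-pass filter the EEG, threshold the result
in time, and post-filter the supra-threshold epochs — each step accumulating
the bias of the previous one.  This package instead decomposes the signal
once by **matching pursuit (MP)** over a dictionary of Gabor functions

    g(t) = K · exp(−π((t−u)/s)²) · cos(2πf(t−u) + φ),

which yields an explicit parametrization of every local structure by its
time center `u`, Gaussian-envelope half-width `s` (its duration), frequency
`f`, phase `φ` and amplitude.  Detection then reduces to filtering the
fitted atoms with the textbook definition of the structure: for spindles,
`f` ∈ 11–16 Hz, duration ≥ 0.5 s, and a subject-adaptive minimal
peak-to-peak amplitude

    A = 2√2 · P_RMS,

where `P_RMS` is a chosen percentile of the sigma-band (11–16 Hz) RMS
evaluated in successive 0.2-s windows — the detector's single free
parameter.  Agreement with reference annotations is scored at every signal
sample (sensitivity, PPV, MCC, Cohen's κ, F1), the percentile is optimized
by maximizing MCC, and its out-of-sample behaviour is estimated by repeated
random train/validation splits.

The dictionary itself is controlled by one density parameter ε ("energy
error"): the maximum fraction of energy MP can lose in a single iteration
because the (u, f, s) grid is discrete.  At the production setting ε = 0.04
and 256 Hz sampling, the available envelope widths in the spindle range are
0.53, 0.80, 1.21 and 1.82 s.

The package provides, as both a Python library and a `spindlemp` CLI:
dictionary construction, a fast exact MP engine with plain-text "book"
files, the RMS-percentile threshold, structure filters with spindle /
slow-wave presets, sample-resolution evaluation and cross-validation,
per-epoch EEG profiles (counts and time occupancy), and a seeded synthetic
EEG generator with exact ground truth.

## Worked example

```python
import spindlemp as sp

# 5-minute synthetic recording: 1/f background (15 uV RMS) with
# 15 implanted spindles of 60-80 uV peak-to-peak
cfg = sp.SimulationConfig(duration=300.0, seed=42, spindle_density=3.0,
                          spindle_amplitude=(60.0, 80.0))
signal, truth = sp.generate_recording(cfg)

# decompose in 20-s epochs (50 atoms each), threshold at the 97th RMS
# percentile, keep 11-16 Hz atoms lasting >= 0.5 s
events = sp.detect_spindles(signal, cfg.fs, epsilon=0.04, M=50, percentile=97.0)

for ev in events[:3]:
    print(f"[{ev.start:7.2f}, {ev.end:7.2f}) s  f = {ev.frequency:5.2f} Hz  "
          f"amplitude = {ev.amplitude:5.1f} uV")

detected = sp.events_to_mask(events, cfg.fs, len(signal))
metrics = sp.compute_metrics(sp.confusion_counts(detected, truth.mask(len(signal))))
print({k: round(v, 3) for k, v in metrics.as_dict().items()})
```

prints (16 events detected for the 15 implanted spindles):

```
[  27.40,   28.20) s  f = 14.38 Hz  amplitude =  83.9 uV
[  30.32,   30.85) s  f = 15.75 Hz  amplitude =  81.9 uV
[  63.21,   64.41) s  f = 12.69 Hz  amplitude =  87.9 uV
{'sensitivity': 0.948, 'ppv': 0.938, 'mcc': 0.939, 'kappa': 0.939, 'f1': 0.943}
```

Each event is one fitted Gabor atom that passed all three criteria: its
interval is `u ± duration/2`, its amplitude the peak-to-peak of the fitted
oscillation (here comfortably above the adaptive floor of 53.1 µV that the
97th RMS percentile implies for this recording), and the sample-resolution
scores against the implanted ground truth are all ≈ 0.94.  The same events
summarize into a per-epoch profile:

```python
profile = sp.build_profile(events, cfg.duration)      # 20-s epochs
[p.count for p in profile]            # [0, 2, 0, 2, 1, 2, 2, 1, 0, 2, ...]
[round(p.occupancy_pct, 1) for p in profile]  # [0.0, 6.6, 0.0, 8.7, 9.1, ...]
```

The equivalent shell session:

```bash
spindlemp simulate --duration 300 --density 3 --amplitude 60 80 --seed 42 \
                   --out rec.csv --truth truth.csv
spindlemp detect   --input rec.csv --percentile 97 --out events.csv
spindlemp evaluate --events events.csv --reference truth.csv --duration 300
spindlemp profile  --events events.csv --duration 300
```

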