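"""Synthetic EEG recordings with ground-truth Gabor transients.

The generator produces a colored-noise background (default spectral exponent
1, i.e. 1/f power, a crude but serviceable stand-in for scalp EEG) and
implants Gabor-shaped transients of two classes at non-overlapping random
positions:

* spindles: frequency uniform on 11-16 Hz, envelope half-width uniform on
  0.5-2.0 s, peak-to-peak amplitude uniform on 30-50 uV by default;
* slow waves: 0.2-4 Hz, >= 0.5 s, >= 70 uV.

Every implanted event is recorded with its exact parameters and a half-open
[start, end) interval (start = u - s/2, end = u + s/2), so detector output
can be scored at sample resolution without any external data.  The output is
fully determined by the seed.

The generator emulates the signal classes the detector targets, not the
physiology of sleep: no artifacts, no stage structure, no amplitude
non-stationarity beyond the implanted events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dictionary import support_halfwidth_samples

__all__ = ["SimulationConfig", "TruthEvent", "GroundTruth", "generate_recording"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic recording.

    Densities are events per minute; ranges are uniform-distribution bounds.
    ``background_rms`` is the broadband noise RMS in uV and
    ``background_exponent`` the spectral slope (power ~ 1/f^exponent).
    """

    duration: float
    fs: float = 256.0
    seed: int | None = None
    background_rms: float = 15.0
    background_exponent: float = 1.0
    spindle_density: float = 2.0
    spindle_freq: tuple[float, float] = (11.0, 16.0)
    spindle_width: tuple[float, float] = (0.5, 2.0)
    spindle_amplitude: tuple[float, float] = (30.0, 50.0)
    slow_wave_density: float = 0.0
    slow_wave_freq: tuple[float, float] = (0.2, 4.0)
    slow_wave_width: tuple[float, float] = (0.5, 1.5)
    slow_wave_amplitude: tuple[float, float] = (80.0, 120.0)
    min_gap: float = 1.0  # minimal spacing between implanted intervals, s
    edge_margin: float = 2.0  # keep events away from the recording edges, s

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.fs <= 0:
            raise ValueError("duration and fs must be positive")
        if self.spindle_density < 0 or self.slow_wave_density < 0:
            raise ValueError("densities must be non-negative")
        for lo, hi in (self.spindle_freq, self.spindle_width,
                       self.spindle_amplitude, self.slow_wave_freq,
                       self.slow_wave_width, self.slow_wave_amplitude):
            if not 0 <= lo <= hi:
                raise ValueError(f"invalid range ({lo}, {hi})")


@dataclass(frozen=True)
class TruthEvent:
    """One implanted transient with its exact parameters."""

    kind: str  # "spindle" | "slow_wave"
    u: float
    s: float
    f: float
    phi: float
    amplitude: float  # nominal peak-to-peak, uV

    @property
    def start(self) -> float:
        return self.u - self.s / 2.0

    @property
    def end(self) -> float:
        return self.u + self.s / 2.0


@dataclass
class GroundTruth:
    events: list[TruthEvent]
    config: SimulationConfig

    def of_kind(self, kind: str) -> list[TruthEvent]:
        return [ev for ev in self.events if ev.kind == kind]

    def mask(self, n_samples: int, kind: str | None = None) -> np.ndarray:
        """Per-sample boolean mask of the [start, end) truth intervals."""
        from .events import intervals_to_mask

        events = self.events if kind is None else self.of_kind(kind)
        return intervals_to_mask(
            ((ev.start, ev.end) for ev in events), self.config.fs, n_samples
        )

    def annotation_frame(self, kind: str | None = None) -> pd.DataFrame:
        """Intervals as reference-annotation rows (onset_s, duration_s)."""
        events = self.events if kind is None else self.of_kind(kind)
        return pd.DataFrame(
            {
                "onset_s": [ev.start for ev in events],
                "duration_s": [ev.s for ev in events],
            }
        )


def _colored_noise(rng: np.random.Generator, n: int, fs: float,
                   exponent: float, rms: float) -> np.ndarray:
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    noise = np.fft.irfft(spectrum * shaping, n)
    noise *= rms / np.sqrt(np.mean(noise * noise))
    return noise


def _place_events(rng, config, kind, density, f_rng, s_rng, a_rng,
                  occupied: list[tuple[float, float]]) -> list[TruthEvent]:
    n_events = int(round(density * config.duration / 60.0))
    events = []
    for _ in range(n_events):
        s = rng.uniform(*s_rng)
        f = rng.uniform(*f_rng)
        amp = rng.uniform(*a_rng)
        phi = rng.uniform(0.0, 2.0 * np.pi)
        placed = False
        for _attempt in range(2000):
            lo = config.edge_margin + s / 2.0
            hi = config.duration - config.edge_margin - s / 2.0
            if hi <= lo:
                break
            u = rng.uniform(lo, hi)
            u = round(u * config.fs) / config.fs  # snap to the sample grid
            start, end = u - s / 2.0, u + s / 2.0
            if all(end + config.min_gap <= o_lo or start - config.min_gap >= o_hi
                   for o_lo, o_hi in occupied):
                occupied.append((start, end))
                events.append(TruthEvent(kind=kind, u=u, s=s, f=f, phi=phi,
                                         amplitude=amp))
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not place {n_events} non-overlapping {kind} events in "
                f"{config.duration} s (density too high for min_gap="
                f"{config.min_gap})"
            )
    return events


def generate_recording(config: SimulationConfig) -> tuple[np.ndarray, GroundTruth]:
    """Synthesize one recording and its exact annotation.

    Event counts are deterministic (density * duration / 60, rounded);
    placements, parameters and the noise are drawn from the seeded generator,
    so identical configs give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration * config.fs))
    signal = _colored_noise(rng, n, config.fs, config.background_exponent,
                            config.background_rms)
    occupied: list[tuple[float, float]] = []
    events = _place_events(
        rng, config, "spindle", config.spindle_density, config.spindle_freq,
        config.spindle_width, config.spindle_amplitude, occupied,
    )
    events += _place_events(
        rng, config, "slow_wave", config.slow_wave_density,
        config.slow_wave_freq, config.slow_wave_width,
        config.slow_wave_amplitude, occupied,
    )
    t_all = np.arange(n) / config.fs
    for ev in events:
        h = support_halfwidth_samples(ev.s, config.fs)
        c = int(round(ev.u * config.fs))
        lo, hi = max(c - h, 0), min(c + h + 1, n)
        t = t_all[lo:hi] - ev.u
        signal[lo:hi] += (ev.amplitude / 2.0) * np.exp(
            -np.pi * (t / ev.s) ** 2
        ) * np.cos(2.0 * np.pi * ev.f * t + ev.phi)
    events.sort(key=lambda ev: ev.u)
    return signal, GroundTruth(events=events, config=config)
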