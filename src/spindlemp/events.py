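"""Selection of transient structures (spindles, slow waves) from MP books.

A matching-pursuit book is a database of every waveform fitted to an epoch.
Detection of a transient class is then just filtering that database on the
explicit atom parameters: frequency center, duration (taken as the Gaussian
envelope half-width ``s``, optionally rescaled by a multiplicative factor)
and peak-to-peak amplitude.  A kept atom becomes an event on the recording
timeline spanning ``u - duration/2`` to ``u + duration/2``.

The spindle amplitude criterion is subject-adaptive: ``detect_spindles``
computes it from the sigma-band RMS distribution of the recording (see
:mod:`spindlemp.threshold`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dictionary import (
    AtomParams,
    build_dictionary,
    gabor_waveform,
    support_halfwidth_samples,
)
from .mp import Book, FittedAtom, decompose
from .threshold import amplitude_threshold, rms_windows, sigma_bandpass

__all__ = [
    "StructureCriteria",
    "DetectedEvent",
    "SPINDLE",
    "SLOW_SPINDLE",
    "FAST_SPINDLE",
    "SLOW_WAVE",
    "PRESETS",
    "atom_amplitude",
    "filter_book",
    "detect_spindles",
    "decompose_recording",
    "events_from_books",
    "events_to_mask",
    "intervals_to_mask",
    "merge_events",
]


@dataclass(frozen=True)
class StructureCriteria:
    """Parameter-space filter defining one transient class.

    ``min_amplitude`` is peak-to-peak in signal units; ``None`` means
    "subject-adaptive", i.e. filled in from the RMS-percentile rule by the
    detection pipeline.  ``duration_factor`` rescales the envelope half-width
    before the duration test and the event extent.
    """

    f_min: float
    f_max: float
    min_duration: float
    max_duration: float | None = None
    min_amplitude: float | None = None
    duration_factor: float = 1.0

    def __post_init__(self) -> None:
        if not self.f_min < self.f_max:
            raise ValueError(f"need f_min < f_max, got ({self.f_min}, {self.f_max})")
        if not self.min_duration > 0:
            raise ValueError(f"min_duration must be positive, got {self.min_duration}")
        if not self.duration_factor > 0:
            raise ValueError(
                f"duration_factor must be positive, got {self.duration_factor}"
            )


# Spindles: 11-16 Hz lasting at least 0.5 s (amplitude subject-adaptive).
SPINDLE = StructureCriteria(f_min=11.0, f_max=16.0, min_duration=0.5)
SLOW_SPINDLE = replace(SPINDLE, f_max=13.0)
FAST_SPINDLE = replace(SPINDLE, f_min=13.0)
# Slow waves of deep sleep: 0.2-4 Hz, > 0.5 s, > 70 uV peak-to-peak.
SLOW_WAVE = StructureCriteria(f_min=0.2, f_max=4.0, min_duration=0.5,
                              min_amplitude=70.0)

PRESETS = {
    "spindle": SPINDLE,
    "slow_spindle": SLOW_SPINDLE,
    "fast_spindle": FAST_SPINDLE,
    "slow_wave": SLOW_WAVE,
}


@dataclass(frozen=True)
class DetectedEvent:
    """One detected transient on the recording timeline (seconds)."""

    start: float
    end: float
    center: float
    frequency: float
    amplitude: float
    source_epoch: int = 0

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"need start < end, got [{self.start}, {self.end})")

    @property
    def duration(self) -> float:
        return self.end - self.start


def atom_amplitude(atom: FittedAtom, fs: float, n_samples: int | None = None) -> float:
    """Peak-to-peak amplitude of a fitted atom: ``2 * coeff * max|g|``.

    The fitted oscillation reaches ``coeff * max|g|`` at its envelope peak;
    peak-to-peak doubles it.  For spindle-like atoms (several cycles under
    the envelope) this matches max-minus-min of the reconstructed waveform to
    within a few percent.  With ``n_samples`` the waveform is sampled in the
    epoch window (edge clipping included); otherwise on its own support.
    """
    if atom.coeff == 0.0:
        return 0.0
    p = atom.params
    if n_samples is None:
        h = support_halfwidth_samples(p.s, fs)
        local = AtomParams(u=h / fs, s=p.s, f=p.f, phi=p.phi)
        g = gabor_waveform(local, fs, 2 * h + 1)
    else:
        g = gabor_waveform(p, fs, n_samples)
    return 2.0 * atom.coeff * float(np.max(np.abs(g)))


def filter_book(book: Book, criteria: StructureCriteria) -> list[DetectedEvent]:
    """Events for every atom of ``book`` passing all criteria."""
    if criteria.min_amplitude is None:
        raise ValueError(
            "criteria.min_amplitude is unset; fill it in (e.g. from "
            "amplitude_threshold) before filtering"
        )
    out = []
    for atom in book.atoms:
        if atom.degenerate or atom.coeff == 0.0:
            continue
        p = atom.params
        if not criteria.f_min <= p.f <= criteria.f_max:
            continue
        duration = criteria.duration_factor * p.s
        if duration < criteria.min_duration:
            continue
        if criteria.max_duration is not None and duration > criteria.max_duration:
            continue
        amplitude = atom_amplitude(atom, book.fs, book.n_samples)
        if amplitude < criteria.min_amplitude:
            continue
        center = p.u + book.epoch_start
        out.append(DetectedEvent(
            start=center - duration / 2.0,
            end=center + duration / 2.0,
            center=center,
            frequency=p.f,
            amplitude=amplitude,
            source_epoch=int(round(book.epoch_start / book.epoch_length))
            if book.epoch_length else 0,
        ))
    return out


def decompose_recording(
    signal: np.ndarray,
    fs: float,
    epsilon: float = 0.04,
    M: int = 50,
    epoch_length: float = 20.0,
    freq_range: tuple[float, float] | None = (0.0, 30.0),
    scale_range: tuple[float, float] | None = None,
) -> list[Book]:
    """Decompose a recording in consecutive non-overlapping epochs.

    A trailing segment shorter than one epoch is not decomposed.  The default
    frequency ceiling of 30 Hz covers every sleep transient this package
    filters for (slow waves through fast spindles) at a fraction of the
    full-band cost; pass ``freq_range=None`` for the full 0..fs/2 grid.
    """
    signal = np.asarray(signal, dtype=float)
    dictionary = build_dictionary(
        epsilon, fs, epoch_length, scale_range=scale_range, freq_range=freq_range
    )
    n = dictionary.n_samples
    books = []
    for i in range(len(signal) // n):
        epoch = signal[i * n: (i + 1) * n]
        books.append(decompose(epoch, dictionary, M=M, epoch_start=i * epoch_length))
    if not books:
        raise ValueError(
            f"recording of {len(signal) / fs:.3g} s is shorter than one "
            f"{epoch_length}-s epoch"
        )
    return books


def events_from_books(
    books: list[Book],
    criteria: StructureCriteria,
    record_duration: float | None = None,
) -> list[DetectedEvent]:
    """Filter every book and return events sorted by start time.

    Event intervals are clipped to ``[0, record_duration]`` when a duration
    is given (atoms near the recording edges can nominally extend past it).
    """
    events: list[DetectedEvent] = []
    for book in books:
        events.extend(filter_book(book, criteria))
    if record_duration is not None:
        events = [
            _with_interval(ev, max(ev.start, 0.0), min(ev.end, record_duration))
            for ev in events
            if ev.start < record_duration and ev.end > 0.0
        ]
    return sorted(events, key=lambda ev: (ev.start, ev.end, ev.frequency))


def _with_interval(ev: DetectedEvent, start: float, end: float) -> DetectedEvent:
    return DetectedEvent(start=start, end=end, center=ev.center,
                         frequency=ev.frequency, amplitude=ev.amplitude,
                         source_epoch=ev.source_epoch)


def detect_spindles(
    signal: np.ndarray,
    fs: float,
    epsilon: float = 0.04,
    M: int = 50,
    percentile: float = 97.0,
    *,
    epoch_length: float = 20.0,
    criteria: StructureCriteria = SPINDLE,
    freq_range: tuple[float, float] | None = (0.0, 30.0),
    scale_range: tuple[float, float] | None = None,
    books: list[Book] | None = None,
    merge_gap: float | None = None,
) -> list[DetectedEvent]:
    """End-to-end spindle detection on a single-channel recording.

    Decomposes the recording epoch by epoch, computes the subject-adaptive
    amplitude floor ``2*sqrt(2)`` times the requested percentile of the
    sigma-band windowed RMS over the whole supplied signal, and filters the
    books with the spindle criteria.  Pre-computed ``books`` may be supplied
    to re-detect at a different percentile without re-decomposing.
    """
    signal = np.asarray(signal, dtype=float)
    if books is None:
        books = decompose_recording(
            signal, fs, epsilon=epsilon, M=M, epoch_length=epoch_length,
            freq_range=freq_range, scale_range=scale_range,
        )
    dist = rms_windows(sigma_bandpass(signal, fs), fs)
    floor = amplitude_threshold(dist, percentile)
    if criteria.min_amplitude is None:
        criteria = replace(criteria, min_amplitude=floor)
    else:
        criteria = replace(criteria,
                           min_amplitude=max(criteria.min_amplitude, floor))
    events = events_from_books(books, criteria, record_duration=len(signal) / fs)
    if merge_gap is not None:
        events = merge_events(events, merge_gap)
    return events


def merge_events(events: list[DetectedEvent], gap: float = 0.1) -> list[DetectedEvent]:
    """Merge events separated by less than ``gap`` seconds (or overlapping).

    The merged event keeps the frequency and amplitude of its largest-
    amplitude constituent and spans the union of the intervals.
    """
    if not events:
        return []
    events = sorted(events, key=lambda ev: ev.start)
    merged = [events[0]]
    for ev in events[1:]:
        last = merged[-1]
        if ev.start - last.end < gap:
            lead = last if last.amplitude >= ev.amplitude else ev
            merged[-1] = DetectedEvent(
                start=last.start, end=max(last.end, ev.end), center=lead.center,
                frequency=lead.frequency, amplitude=lead.amplitude,
                source_epoch=lead.source_epoch,
            )
        else:
            merged.append(ev)
    return merged


def intervals_to_mask(
    intervals, fs: float, n_samples: int, tol: float = 1e-9
) -> np.ndarray:
    """Boolean per-sample mask of a union of half-open [start, end) intervals.

    Sample ``i`` is set iff ``i/fs`` lies inside some interval.
    """
    mask = np.zeros(n_samples, dtype=bool)
    limit = n_samples / fs
    for start, end in intervals:
        if start < -tol or end > limit + tol:
            raise ValueError(
                f"interval [{start}, {end}) s outside the recording "
                f"[0, {limit:g}) s"
            )
        i0 = max(int(np.ceil(start * fs - tol)), 0)
        i1 = min(int(np.ceil(end * fs - tol)), n_samples)
        mask[i0:i1] = True
    return mask


def events_to_mask(
    events: list[DetectedEvent], fs: float, n_samples: int
) -> np.ndarray:
    return intervals_to_mask(((ev.start, ev.end) for ev in events), fs, n_samples)
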