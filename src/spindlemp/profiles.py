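"""Per-epoch EEG profiles of detected transients.

A profile summarizes one transient class over a whole recording in fixed
epochs (traditionally 20 s in sleep analysis): how many events fall in each
epoch (counted by their time centers) and what percent of the epoch's time
the union of event intervals covers.  The occupancy percentage is directly
relevant for deep-sleep scoring, where classical criteria define stage 3 by
slow waves covering 20-50% of an epoch and stage 4 by more than 50%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import DetectedEvent

__all__ = ["EpochProfile", "build_profile", "stage_band_flags", "profile_frame"]


@dataclass(frozen=True)
class EpochProfile:
    """Event count and time occupancy of one epoch.

    ``epoch_length`` is the epoch's actual extent: the final epoch of a
    recording may be shorter than the nominal length, and its occupancy is
    relative to that actual extent.
    """

    epoch_index: int
    t_start: float
    epoch_length: float
    count: int
    occupancy_pct: float


def _union_length(intervals: list[tuple[float, float]]) -> float:
    total = 0.0
    end_prev = -np.inf
    for start, end in sorted(intervals):
        if start > end_prev:
            total += end - start
            end_prev = end
        elif end > end_prev:
            total += end - end_prev
            end_prev = end
    return total


def build_profile(
    events: list[DetectedEvent],
    record_duration: float,
    epoch_length: float = 20.0,
) -> list[EpochProfile]:
    """Per-epoch counts and occupancy for a list of timeline events.

    Events are counted in the epoch containing their time center; their
    intervals are clipped to each epoch they touch, and overlapping intervals
    are unioned before occupancy is computed.
    """
    if not epoch_length > 0:
        raise ValueError(f"epoch_length must be positive, got {epoch_length}")
    n_epochs = max(int(np.ceil(record_duration / epoch_length - 1e-9)), 1)
    counts = [0] * n_epochs
    spans: list[list[tuple[float, float]]] = [[] for _ in range(n_epochs)]
    for ev in events:
        ci = min(int(ev.center // epoch_length), n_epochs - 1)
        counts[ci] += 1
        first = max(int(ev.start // epoch_length), 0)
        last = min(int(np.ceil(ev.end / epoch_length - 1e-12)) - 1, n_epochs - 1)
        for ei in range(first, last + 1):
            lo = max(ev.start, ei * epoch_length)
            hi = min(ev.end, (ei + 1) * epoch_length, record_duration)
            if hi > lo:
                spans[ei].append((lo, hi))
    profiles = []
    for ei in range(n_epochs):
        t0 = ei * epoch_length
        length = min(epoch_length, record_duration - t0)
        occ = 100.0 * _union_length(spans[ei]) / length
        profiles.append(EpochProfile(
            epoch_index=ei, t_start=t0, epoch_length=length,
            count=counts[ei], occupancy_pct=occ,
        ))
    return profiles


def stage_band_flags(
    profiles: list[EpochProfile],
    low_pct: float = 20.0,
    high_pct: float = 50.0,
) -> list[str]:
    """Band each epoch's occupancy: "below", "20-50" or "above".

    Pure banding of the occupancy value, not a sleep stager.  An occupancy
    exactly at ``high_pct`` belongs to the upper band (the classical
    "50-100%" range read with an inclusive lower edge); one exactly at
    ``low_pct`` likewise belongs to the middle band.
    """
    if not (0.0 <= low_pct < high_pct <= 100.0):
        raise ValueError(f"invalid thresholds ({low_pct}, {high_pct})")
    mid = f"{low_pct:g}-{high_pct:g}"
    out = []
    for prof in profiles:
        if prof.occupancy_pct >= high_pct:
            out.append("above")
        elif prof.occupancy_pct >= low_pct:
            out.append(mid)
        else:
            out.append("below")
    return out


def profile_frame(profiles: list[EpochProfile]) -> pd.DataFrame:
    """Profiles as a DataFrame (epoch_index, t_start_s, count, occupancy_pct)."""
    return pd.DataFrame(
        {
            "epoch_index": [p.epoch_index for p in profiles],
            "t_start_s": [p.t_start for p in profiles],
            "count": [p.count for p in profiles],
            "occupancy_pct": [p.occupancy_pct for p in profiles],
        }
    )
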