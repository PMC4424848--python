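"""Reading and writing signals, annotations, events and pipeline configs.

Signals travel either as EDF (read through MNE, optional dependency) or as a
single-column CSV whose ``# fs=<Hz>`` header line carries the sampling rate.
Reference annotations are CSV with ``onset_s,duration_s`` columns; detected
events are CSV with ``start_s,end_s,center_s,freq_hz,amp_uV`` columns.
All amplitudes are microvolts.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .events import DetectedEvent

__all__ = [
    "read_signal",
    "write_signal_csv",
    "read_annotations",
    "write_annotations",
    "events_to_frame",
    "write_events",
    "read_events",
    "write_annotation_list",
    "load_config",
    "save_config",
]


def read_signal(path, channel: str | None = None) -> tuple[np.ndarray, float]:
    """Load a single-channel signal; returns (samples in uV, fs in Hz).

    ``.edf`` files are read through MNE (``pip install mne``); ``channel``
    selects the channel by name (first channel by default).  MNE yields
    volts, which are converted to microvolts.  Any other extension is parsed
    as a one-column CSV with a ``# fs=<Hz>`` header line.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover
            raise ImportError(
                "reading EDF requires the optional dependency mne "
                "(pip install spindlemp[edf])"
            ) from exc
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        name = channel if channel is not None else raw.ch_names[0]
        data = raw.get_data(picks=[name])[0] * 1e6
        return np.asarray(data, dtype=float), float(raw.info["sfreq"])

    fs = None
    values = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw_line in enumerate(fh, start=1):
            line = raw_line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("fs"):
                    fs = float(body.partition("=")[2])
                continue
            try:
                values.append(float(line.split(",")[0]))
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: not a numeric sample: {line!r}"
                ) from None
    if fs is None:
        raise ValueError(f"{path}: missing '# fs=<Hz>' header line")
    return np.asarray(values), fs


def write_signal_csv(path, signal: np.ndarray, fs: float) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# fs={fs!r}\n")
        for v in np.asarray(signal, dtype=float):
            fh.write(f"{float(v)!r}\n")


def read_annotations(path) -> np.ndarray:
    """Reference intervals as an (n, 2) array of (onset_s, duration_s)."""
    frame = pd.read_csv(path)
    missing = {"onset_s", "duration_s"}.difference(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return frame[["onset_s", "duration_s"]].to_numpy(dtype=float)


def write_annotations(path, intervals) -> None:
    """``intervals``: rows of (onset_s, duration_s) or a matching DataFrame."""
    if not isinstance(intervals, pd.DataFrame):
        intervals = pd.DataFrame(np.atleast_2d(np.asarray(intervals, dtype=float)),
                                 columns=["onset_s", "duration_s"])
    intervals.to_csv(path, index=False)


def events_to_frame(events: list[DetectedEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "start_s": [ev.start for ev in events],
            "end_s": [ev.end for ev in events],
            "center_s": [ev.center for ev in events],
            "freq_hz": [ev.frequency for ev in events],
            "amp_uV": [ev.amplitude for ev in events],
            "source_epoch": [ev.source_epoch for ev in events],
        }
    )


def write_events(path, events: list[DetectedEvent]) -> None:
    events_to_frame(events).to_csv(path, index=False)


def read_events(path) -> list[DetectedEvent]:
    frame = pd.read_csv(path)
    out = []
    for row in frame.itertuples(index=False):
        out.append(DetectedEvent(
            start=float(row.start_s), end=float(row.end_s),
            center=float(row.center_s), frequency=float(row.freq_hz),
            amplitude=float(row.amp_uV),
            source_epoch=int(getattr(row, "source_epoch", 0)),
        ))
    return out


def write_annotation_list(path, events: list[DetectedEvent],
                          description: str = "spindle") -> None:
    """Minimal EDF+-style annotation text: onset, duration, description."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("onset_s\tduration_s\tdescription\n")
        for ev in events:
            fh.write(f"{ev.start:.6f}\t{ev.duration:.6f}\t{description}\n")


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: expected a mapping at the top level")
    return cfg


def save_config(path, config: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
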