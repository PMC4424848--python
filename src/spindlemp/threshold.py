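"""Subject-adaptive minimal spindle amplitude from the sigma-band RMS.

Sleep spindles have no universally agreed minimal amplitude, so the detector
derives one from the recording itself: the signal is band-pass filtered to
the sigma band (11-16 Hz), the root-mean-square amplitude is evaluated in
successive non-overlapping 0.2-s windows, and a chosen percentile of that RMS
distribution is converted to a peak-to-peak amplitude.  A 0.2-s window spans
roughly one period of a sigma oscillation, so within a window the signal is
well approximated by a constant-amplitude sine, for which

    A_peak-to-peak = 2 * sqrt(2) * RMS

The percentile is the detector's single free parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "RMSDistribution",
    "sigma_bandpass",
    "rms_windows",
    "amplitude_threshold",
]

SIGMA_BAND = (11.0, 16.0)
RMS_WINDOW_S = 0.2
PEAK_TO_PEAK_FACTOR = 2.0 * math.sqrt(2.0)


@dataclass(frozen=True)
class RMSDistribution:
    """Windowed RMS values of a band-passed signal."""

    values: np.ndarray
    window_s: float
    band: tuple[float, float]
    fs: float

    def __len__(self) -> int:
        return len(self.values)


def sigma_bandpass(
    signal: np.ndarray,
    fs: float,
    low: float = SIGMA_BAND[0],
    high: float = SIGMA_BAND[1],
) -> np.ndarray:
    """Zero-phase band-pass filter (2nd-order Butterworth design).

    The filter is applied forward and backward (``filtfilt``), which cancels
    group delay so RMS windows stay aligned with the underlying transients;
    the magnitude response is consequently the squared 2nd-order response.
    """
    if not 0.0 < low < high < fs / 2.0:
        raise ValueError(
            f"band ({low}, {high}) Hz is invalid for sampling rate {fs} Hz"
        )
    sos = sps.butter(2, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(signal, dtype=float))


def rms_windows(
    filtered: np.ndarray, fs: float, window_s: float = RMS_WINDOW_S
) -> RMSDistribution:
    """RMS in successive non-overlapping windows; a trailing partial window
    is discarded.

    Window boundaries are kept at exact multiples of ``window_s`` even when
    that is a non-integer number of samples (0.2 s at 256 Hz is 51.2
    samples): window ``i`` covers samples ``[floor(i*w), floor((i+1)*w))``,
    so a 60-s signal always yields exactly 300 windows.
    """
    filtered = np.asarray(filtered, dtype=float)
    w = window_s * fs
    n_win = int(len(filtered) / w)
    if n_win < 1:
        raise ValueError(
            f"signal of {len(filtered)} samples is shorter than one "
            f"{window_s}-s window ({w:g} samples)"
        )
    edges = np.floor(np.arange(n_win + 1) * w).astype(np.intp)
    csum = np.concatenate([[0.0], np.cumsum(filtered * filtered)])
    sums = csum[edges[1:]] - csum[edges[:-1]]
    values = np.sqrt(sums / np.diff(edges))
    return RMSDistribution(values=values, window_s=window_s,
                           band=SIGMA_BAND, fs=fs)


def amplitude_threshold(dist: RMSDistribution, percentile: float) -> float:
    """Minimal peak-to-peak amplitude ``2*sqrt(2) * P_RMS``.

    ``P_RMS`` is the requested percentile of the windowed RMS distribution
    (linear interpolation between order statistics).
    """
    if not 0.0 <= percentile <= 100.0:
        raise ValueError(f"percentile must lie in [0, 100], got {percentile}")
    if len(dist) == 0:
        raise ValueError("empty RMS distribution")
    return PEAK_TO_PEAK_FACTOR * float(np.percentile(dist.values, percentile))
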