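"""Sample-resolution detector scoring and percentile cross-validation.

Detector and reference scorings are compared at every signal sample, which
is stricter and less ambiguous than window-based event matching.  The
cross-tabulation (TP/TN/FP/FN counts over samples) yields five summary
measures:

    sensitivity = TP / (TP + FN)
    PPV         = TP / (TP + FP)
    MCC         = (TP*TN - FP*FN) / sqrt(P * P' * N * N')
    kappa       = ((TP + TN)/(P + N) - P_e) / (1 - P_e)
    F1          = 2 * PPV * sensitivity / (PPV + sensitivity)

with P = TP+FN, P' = TP+FP, N = FP+TN, N' = FN+TN and random-agreement
probability P_e = (P'*P + N'*N)/(P+N)^2.  A measure whose denominator
vanishes is reported as NaN and flagged, never silently as zero.

The detector's one free parameter — the RMS percentile fixing the minimal
spindle amplitude — is chosen to maximize MCC, and its out-of-sample
performance is estimated by repeated random train/validation splits: on each
iteration the optimal percentile is found for every training recording
separately, the training optima are averaged, and the averaged percentile is
scored on the held-out recordings.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .events import (
    StructureCriteria,
    SPINDLE,
    decompose_recording,
    events_from_books,
    events_to_mask,
    intervals_to_mask,
)
from .threshold import amplitude_threshold, rms_windows, sigma_bandpass

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "METRIC_NAMES",
    "confusion_counts",
    "compute_metrics",
    "PreparedRecording",
    "prepare_recording",
    "optimal_percentile",
    "cross_validate",
    "CrossValidationResult",
    "DEFAULT_PERCENTILE_GRID",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("sensitivity", "ppv", "mcc", "kappa", "f1")

# Percentile sweep covering the useful upper tail of the RMS distribution.
DEFAULT_PERCENTILE_GRID = tuple(np.arange(90.0, 100.0, 0.5))


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-sample cross-tabulation of detector vs. reference masks."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def p(self) -> int:  # reference-positive samples
        return self.tp + self.fn

    @property
    def p_prime(self) -> int:  # detector-positive samples
        return self.tp + self.fp

    @property
    def n(self) -> int:  # reference-negative samples
        return self.fp + self.tn

    @property
    def n_prime(self) -> int:  # detector-negative samples
        return self.fn + self.tn

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class Metrics:
    """The five performance measures; NaN entries are listed in ``undefined``."""

    sensitivity: float
    ppv: float
    mcc: float
    kappa: float
    f1: float
    undefined: frozenset = field(default_factory=frozenset)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def confusion_counts(detected: np.ndarray, reference: np.ndarray) -> ConfusionCounts:
    detected = np.asarray(detected, dtype=bool)
    reference = np.asarray(reference, dtype=bool)
    if detected.shape != reference.shape:
        raise ValueError(
            f"mask lengths differ: detected {detected.shape}, "
            f"reference {reference.shape}"
        )
    tp = int(np.count_nonzero(detected & reference))
    fp = int(np.count_nonzero(detected & ~reference))
    fn = int(np.count_nonzero(~detected & reference))
    tn = detected.size - tp - fp - fn
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    p, pp, n, npr = counts.p, counts.p_prime, counts.n, counts.n_prime
    total = counts.total
    undefined = set()

    def guarded(name: str, num: float, den: float) -> float:
        if den == 0:
            undefined.add(name)
            return math.nan
        return num / den

    sens = guarded("sensitivity", tp, p)
    ppv = guarded("ppv", tp, pp)
    if min(p, pp, n, npr) == 0:
        undefined.add("mcc")
        mcc = math.nan
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(
            float(p) * float(pp) * float(n) * float(npr)
        )
    if total == 0:
        undefined.add("kappa")
        kappa = math.nan
    else:
        p_e = (float(pp) * p + float(npr) * n) / float(total) ** 2
        kappa = guarded("kappa", (tn + tp) / total - p_e, 1.0 - p_e)
    if "sensitivity" in undefined or "ppv" in undefined:
        undefined.add("f1")
        f1 = math.nan
    else:
        f1 = guarded("f1", 2.0 * ppv * sens, ppv + sens)
    return Metrics(sensitivity=sens, ppv=ppv, mcc=mcc, kappa=kappa, f1=f1,
                   undefined=frozenset(undefined))


def _reference_mask(reference, fs: float, n_samples: int) -> np.ndarray:
    """Accept a boolean mask or (onset, duration) interval rows."""
    ref = np.asarray(reference)
    if ref.dtype == bool:
        if ref.shape != (n_samples,):
            raise ValueError(
                f"reference mask has shape {ref.shape}, expected ({n_samples},)"
            )
        return ref
    intervals = [(float(on), float(on) + float(dur)) for on, dur in ref]
    return intervals_to_mask(intervals, fs, n_samples)


class PreparedRecording:
    """One recording decomposed once, re-scorable at any percentile.

    The MP decomposition and the sigma-band RMS distribution do not depend on
    the amplitude percentile, so percentile sweeps and cross-validation reuse
    them and only repeat the (cheap) filtering and scoring stage.
    """

    def __init__(self, signal, reference, fs: float, *, epsilon: float = 0.04,
                 M: int = 50, epoch_length: float = 20.0,
                 criteria: StructureCriteria = SPINDLE,
                 freq_range=(0.0, 30.0), scale_range=None):
        signal = np.asarray(signal, dtype=float)
        self.fs = fs
        self.n_samples = len(signal)
        self.duration = self.n_samples / fs
        self.criteria = criteria
        self.books = decompose_recording(
            signal, fs, epsilon=epsilon, M=M, epoch_length=epoch_length,
            freq_range=freq_range, scale_range=scale_range,
        )
        self.rms = rms_windows(sigma_bandpass(signal, fs), fs)
        self.reference = _reference_mask(reference, fs, self.n_samples)
        self._cache: dict[float, Metrics] = {}

    def metrics_at(self, percentile: float) -> Metrics:
        key = round(float(percentile), 9)
        if key not in self._cache:
            floor = amplitude_threshold(self.rms, percentile)
            crit = self.criteria
            if crit.min_amplitude is None:
                crit = dc_replace(crit, min_amplitude=floor)
            else:
                crit = dc_replace(crit, min_amplitude=max(crit.min_amplitude, floor))
            events = events_from_books(self.books, crit,
                                       record_duration=self.duration)
            mask = events_to_mask(events, self.fs, self.n_samples)
            self._cache[key] = compute_metrics(confusion_counts(mask, self.reference))
        return self._cache[key]

    def mcc_at(self, percentile: float) -> float:
        return self.metrics_at(percentile).mcc


def prepare_recording(signal, reference, fs: float, **kwargs) -> PreparedRecording:
    return PreparedRecording(signal, reference, fs, **kwargs)


def _as_prepared(recordings, fs, kwargs) -> list[PreparedRecording]:
    out = []
    for rec in recordings:
        if isinstance(rec, PreparedRecording):
            out.append(rec)
        else:
            signal, reference = rec
            out.append(PreparedRecording(signal, reference, fs, **kwargs))
    return out


def _best_percentile(prepared: list[PreparedRecording], grid) -> float:
    """Grid percentile maximizing mean MCC; ties go to the lowest value."""
    best_p, best_mcc = None, -math.inf
    for p in grid:
        vals = [r.mcc_at(p) for r in prepared]
        vals = [v for v in vals if not math.isnan(v)]
        if not vals:
            continue
        mean = sum(vals) / len(vals)
        if mean > best_mcc:
            best_p, best_mcc = float(p), mean
    if best_p is None:
        raise ValueError("MCC undefined at every grid percentile")
    return best_p


def optimal_percentile(
    recordings,
    grid=DEFAULT_PERCENTILE_GRID,
    fs: float | None = None,
    **detector_kwargs,
) -> float:
    """Exhaustive sweep: grid percentile maximizing mean MCC over recordings.

    ``recordings`` are (signal, reference) pairs (reference = boolean mask or
    (onset, duration) rows) or already-PreparedRecording objects.
    """
    if len(list(grid)) == 0:
        raise ValueError("empty percentile grid")
    prepared = _as_prepared(recordings, fs, detector_kwargs)
    return _best_percentile(prepared, grid)


@dataclass
class CrossValidationResult:
    """Per-iteration validation metrics plus their summary statistics."""

    iterations: pd.DataFrame  # iteration, percentile, and the five measures
    summary: pd.DataFrame  # median/q1/q3/mean/sd per measure
    n_undefined: int  # metric values excluded from averages


def cross_validate(
    recordings,
    n_iter: int = 100,
    n_train: int = 14,
    seed: int | None = None,
    grid=DEFAULT_PERCENTILE_GRID,
    fs: float | None = None,
    **detector_kwargs,
) -> CrossValidationResult:
    """Random-split cross-validation of the percentile selection.

    Each iteration draws ``n_train`` recordings without replacement, finds
    the MCC-optimal percentile of each training recording separately,
    averages those optima (arithmetic mean), applies the averaged percentile
    to every held-out recording and averages the resulting measures over the
    validation set.  Seeded and reproducible; training and validation sets
    are disjoint by construction and asserted to be so.
    """
    prepared = _as_prepared(recordings, fs, detector_kwargs)
    n_rec = len(prepared)
    if n_train >= n_rec:
        raise ValueError(
            f"n_train={n_train} needs at least {n_train + 1} recordings, "
            f"got {n_rec}"
        )
    rng = np.random.default_rng(seed)
    rows = []
    n_undefined = 0
    for it in range(n_iter):
        train_idx = rng.choice(n_rec, size=n_train, replace=False)
        train = set(int(i) for i in train_idx)
        validation = [i for i in range(n_rec) if i not in train]
        assert not train.intersection(validation)
        optima = [_best_percentile([prepared[i]], grid) for i in sorted(train)]
        p_bar = float(np.mean(optima))
        row = {"iteration": it, "percentile": p_bar}
        for name in METRIC_NAMES:
            vals = [getattr(prepared[i].metrics_at(p_bar), name) for i in validation]
            finite = [v for v in vals if not math.isnan(v)]
            n_undefined += len(vals) - len(finite)
            row[name] = float(np.mean(finite)) if finite else math.nan
        rows.append(row)
    iterations = pd.DataFrame(rows)
    if n_undefined:
        logger.info("cross_validate: %d undefined metric values excluded",
                    n_undefined)
    stats = {}
    for name in ("percentile",) + METRIC_NAMES:
        col = iterations[name].dropna()
        stats[name] = {
            "median": col.median(),
            "q1": col.quantile(0.25),
            "q3": col.quantile(0.75),
            "mean": col.mean(),
            "sd": col.std(),
        }
    summary = pd.DataFrame(stats).T
    return CrossValidationResult(iterations=iterations, summary=summary,
                                 n_undefined=n_undefined)
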