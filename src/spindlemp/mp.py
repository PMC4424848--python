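"""Matching-pursuit decomposition of EEG epochs over a Gabor dictionary.

Matching pursuit greedily expands a signal ``x`` as a weighted sum of
unit-norm atoms: starting from the residual ``R0 = x``, each iteration picks
the dictionary atom with the largest inner product with the current residual,
subtracts its projection, and repeats.  After ``M`` iterations::

    x  ~=  sum_n  <R^n x, g_n> g_n   +   R^M x

The expansion is energy-conserving: ``|x|^2 = sum c_n^2 + |R^M x|^2`` because
each residual update is orthogonal to the atom it removes.

The dictionary grid covers (u, f, s) only; phase is solved in closed form per
candidate by projecting the residual onto the atom's quadrature pair
(envelope*cos, envelope*sin), which is exact and keeps the grid
three-dimensional.  The selection score of a candidate is therefore the
squared norm of that two-dimensional projection, i.e. the energy the atom
would remove at its optimal phase.

Implementation notes
--------------------
Inner products for all frequencies of one (scale, time-center) pair are the
band bins of one windowed FFT of the residual; the quadrature Gram entries
come from an FFT of the squared envelope (shared by all interior time
centers, computed per-center where the support is clipped by the epoch
edges).  Scores are cached and, after each subtraction, recomputed only for
time centers whose support overlaps the subtracted atom, so a decomposition
is exactly equivalent to rescanning the whole grid every iteration.  No
analytic approximations enter the cache: every number is a discrete sum over
samples, which is what makes brute-force oracle tests match atom for atom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dictionary import (
    AtomParams,
    Dictionary,
    gabor_waveform,
    support_halfwidth_samples,
)

__all__ = [
    "FittedAtom",
    "Book",
    "best_match",
    "decompose",
    "reconstruct",
    "write_book",
    "read_book",
]

# Relative determinant threshold below which the quadrature pair is treated
# as collinear (f = 0 or Nyquist) and the fit falls back to the cos template.
_DET_RTOL = 1e-12


@dataclass(frozen=True)
class FittedAtom:
    """One atom fitted by matching pursuit.

    ``coeff`` is the inner product of the residual with the unit-norm atom at
    its optimal phase; it is non-negative (the sign is absorbed into phi).
    """

    params: AtomParams
    coeff: float
    iteration: int
    degenerate: bool = False

    @property
    def energy(self) -> float:
        return self.coeff * self.coeff


@dataclass
class Book:
    """Ordered result of one epoch's decomposition plus bookkeeping."""

    atoms: list[FittedAtom]
    fs: float
    epoch_start: float
    epoch_length: float
    signal_energy: float
    residual_energy: float
    epsilon: float | None = None

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_length * self.fs))


class _ScaleBlock:
    """Cached state for one dictionary scale on one epoch geometry."""

    def __init__(self, grid, fs: float, n: int, pad: int):
        self.s = grid.s
        self.fs = fs
        self.n = n
        self.pad = pad  # left padding of the shared padded-residual buffer
        self.h = support_halfwidth_samples(grid.s, fs)
        self.W = 2 * self.h + 1
        self.N = grid.fft_len
        self.k0 = grid.k0
        self.n_f = grid.n_f
        self.centers = np.round(grid.u_values * fs).astype(np.intp)
        self.u_values = grid.u_values
        self.f_values = grid.f_values
        n_u = len(self.centers)

        tau = (np.arange(self.W) - self.h) / fs
        self.env = np.exp(-np.pi * (tau / grid.s) ** 2)

        ks = self.k0 + np.arange(self.n_f)
        self.twiddle = np.exp(-2j * np.pi * ks * self.h / self.N)
        self.idx2 = (2 * ks) % self.N
        self.twiddle2 = np.exp(-2j * np.pi * (2 * ks) * self.h / self.N)

        # quadrature Gram rows -> precomputed score coefficients qA, qB, qC
        # such that score = qA*rc^2 - 2*qB*rc*rs + qC*rs^2.
        self.qA = np.empty((n_u, self.n_f))
        self.qB = np.empty((n_u, self.n_f))
        self.qC = np.empty((n_u, self.n_f))
        interior = None
        for i, c in enumerate(self.centers):
            lo, hi = c - self.h, c + self.h + 1
            if 0 <= lo and hi <= n:
                if interior is None:
                    interior = self._gram_coeffs(np.ones(self.W, dtype=bool))
                rows = interior
            else:
                valid = np.zeros(self.W, dtype=bool)
                valid[max(0, -lo): self.W - max(0, hi - n)] = True
                rows = self._gram_coeffs(valid)
            self.qA[i], self.qB[i], self.qC[i] = rows

        self.score = np.zeros((n_u, self.n_f))
        self.rc = np.zeros((n_u, self.n_f))
        self.rs = np.zeros((n_u, self.n_f))

    def _gram_coeffs(self, valid: np.ndarray):
        """Score coefficients from the quadrature Gram of one time center."""
        e2 = np.where(valid, self.env * self.env, 0.0)
        s0 = e2.sum()
        spec = np.fft.fft(e2, self.N)
        e2f = np.conj(spec[self.idx2]) * self.twiddle2
        qcc = 0.5 * (s0 + e2f.real)
        qss = 0.5 * (s0 - e2f.real)
        qcs = 0.5 * e2f.imag
        det = qcc * qss - qcs * qcs
        ok = det > _DET_RTOL * qcc * qss
        det_safe = np.where(ok, det, 1.0)
        qA = np.where(ok, qss / det_safe, 1.0 / qcc)
        qB = np.where(ok, qcs / det_safe, 0.0)
        qC = np.where(ok, qcc / det_safe, 0.0)
        return qA, qB, qC

    def refresh(self, padded: np.ndarray, lo: int | None = None, hi: int | None = None):
        """Recompute correlations/scores for centers overlapping [lo, hi)."""
        if lo is None:
            i0, i1 = 0, len(self.centers)
        else:
            i0 = int(np.searchsorted(self.centers, lo - self.h))
            i1 = int(np.searchsorted(self.centers, hi - 1 + self.h, side="right"))
            if i0 >= i1:
                return
        starts = self.centers[i0:i1] + self.pad - self.h
        windows = np.lib.stride_tricks.sliding_window_view(padded, self.W)[starts]
        spec = np.fft.rfft(windows * self.env, self.N, axis=1)
        z = np.conj(spec[:, self.k0: self.k0 + self.n_f]) * self.twiddle
        rc, rs = z.real, z.imag
        self.rc[i0:i1], self.rs[i0:i1] = rc, rs
        self.score[i0:i1] = (
            self.qA[i0:i1] * rc * rc
            - 2.0 * self.qB[i0:i1] * rc * rs
            + self.qC[i0:i1] * rs * rs
        )


class _Engine:
    """Matching-pursuit state for one (dictionary, epoch-length) pair."""

    def __init__(self, dictionary: Dictionary, n: int):
        self.dictionary = dictionary
        self.fs = dictionary.fs
        self.n = n
        pad = max(support_halfwidth_samples(g.s, self.fs) for g in dictionary.grids)
        self.pad = pad
        self.blocks = [_ScaleBlock(g, self.fs, n, pad) for g in dictionary.grids]
        self.padded = np.zeros(n + 2 * pad)

    @property
    def residual(self) -> np.ndarray:
        return self.padded[self.pad: self.pad + self.n]

    def load(self, signal: np.ndarray) -> None:
        self.padded[:] = 0.0
        self.padded[self.pad: self.pad + self.n] = signal
        for b in self.blocks:
            b.refresh(self.padded)

    def select(self):
        """Grid point with the largest projected energy.

        Ties are broken toward the smallest time center, then the smallest
        frequency, then the smallest scale.
        """
        best = None
        for b in self.blocks:  # blocks are in increasing-scale order
            flat = int(np.argmax(b.score))
            iu, jf = divmod(flat, b.n_f)
            sc = b.score[iu, jf]
            if best is None or sc > best[0] or (
                sc == best[0]
                and (b.u_values[iu], b.f_values[jf]) < (best[1], best[2])
            ):
                best = (sc, b.u_values[iu], b.f_values[jf], b)
        _, u, f, b = best
        return float(u), b.s, float(f)

    def fit_exact(self, u: float, s: float, f: float):
        """Direct projection of the residual onto the atom's quadrature pair.

        Returns (params, coeff, unit_waveform_segment, lo, hi).  All sums are
        plain discrete inner products over the truncated support, so the
        subtraction is exactly orthogonal to the fitted atom.
        """
        h = support_halfwidth_samples(s, self.fs)
        c = int(round(u * self.fs))
        lo, hi = max(c - h, 0), min(c + h + 1, self.n)
        t = np.arange(lo, hi) / self.fs - u
        env = np.exp(-np.pi * (t / s) ** 2)
        gc = env * np.cos(2.0 * np.pi * f * t)
        gs = env * np.sin(2.0 * np.pi * f * t)
        r = self.residual[lo:hi]
        qcc, qss, qcs = gc @ gc, gs @ gs, gc @ gs
        rc, rs = r @ gc, r @ gs
        det = qcc * qss - qcs * qcs
        if det > _DET_RTOL * qcc * qss:
            b0 = (qss * rc - qcs * rs) / det
            b1 = (qcc * rs - qcs * rc) / det
        else:
            b0, b1 = (rc / qcc if qcc > 0 else 0.0), 0.0
        g = b0 * gc + b1 * gs
        norm = np.linalg.norm(g)
        if norm == 0.0:
            params = AtomParams(u=u, s=s, f=f, phi=0.0)
            return params, 0.0, np.zeros(hi - lo), lo, hi
        ghat = g / norm
        coeff = float(r @ ghat)
        phi = math.atan2(-b1, b0)
        if coeff < 0.0:  # only reachable through rounding; keep coeff >= 0
            coeff, phi = -coeff, phi + math.pi if phi <= 0 else phi - math.pi
        return AtomParams(u=u, s=s, f=f, phi=phi), coeff, ghat, lo, hi

    def step(self, iteration: int) -> FittedAtom:
        u, s, f = self.select()
        params, coeff, ghat, lo, hi = self.fit_exact(u, s, f)
        if coeff == 0.0:
            return FittedAtom(params=params, coeff=0.0, iteration=iteration,
                              degenerate=True)
        self.padded[self.pad + lo: self.pad + hi] -= coeff * ghat
        for b in self.blocks:
            b.refresh(self.padded, lo, hi)
        return FittedAtom(params=params, coeff=coeff, iteration=iteration)


_ENGINE_CACHE: dict[tuple[Dictionary, int], _Engine] = {}


def _engine_for(dictionary: Dictionary, n: int) -> _Engine:
    key = (dictionary, n)
    if key not in _ENGINE_CACHE:
        if len(_ENGINE_CACHE) >= 3:  # keep the footprint of cached FFT state bounded
            _ENGINE_CACHE.pop(next(iter(_ENGINE_CACHE)))
        _ENGINE_CACHE[key] = _Engine(dictionary, n)
    return _ENGINE_CACHE[key]


def best_match(residual: np.ndarray, dictionary: Dictionary) -> FittedAtom:
    """Single best grid atom for a residual, phase optimized analytically."""
    residual = np.asarray(residual, dtype=float)
    n = dictionary.n_samples
    if residual.shape != (n,):
        raise ValueError(
            f"residual has {residual.shape} samples, dictionary epoch needs ({n},)"
        )
    engine = _engine_for(dictionary, n)
    engine.load(residual)
    u, s, f = engine.select()
    params, coeff, _, _, _ = engine.fit_exact(u, s, f)
    return FittedAtom(params=params, coeff=coeff, iteration=0,
                      degenerate=coeff == 0.0)


def decompose(
    signal: np.ndarray,
    dictionary: Dictionary,
    M: int = 50,
    epoch_start: float = 0.0,
) -> Book:
    """Run ``M`` matching-pursuit iterations on one epoch.

    The returned Book satisfies ``signal_energy == sum(coeff^2) +
    residual_energy`` up to float rounding, and its first atoms are identical
    to those of any longer decomposition of the same epoch.
    """
    if M < 1:
        raise ValueError(f"M must be >= 1, got {M}")
    signal = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal contains non-finite samples")
    n = dictionary.n_samples
    if signal.shape != (n,):
        raise ValueError(
            f"signal has {signal.shape} samples but the dictionary epoch is "
            f"{dictionary.epoch_length} s at {dictionary.fs} Hz ({n} samples)"
        )
    engine = _engine_for(dictionary, n)
    engine.load(signal)
    signal_energy = float(signal @ signal)
    atoms = []
    for it in range(M):
        atom = engine.step(it)
        atoms.append(atom)
        if atom.degenerate:
            break
    residual = engine.residual
    return Book(
        atoms=atoms,
        fs=dictionary.fs,
        epoch_start=epoch_start,
        epoch_length=dictionary.epoch_length,
        signal_energy=signal_energy,
        residual_energy=float(residual @ residual),
        epsilon=dictionary.epsilon,
    )


def reconstruct(book: Book, n_atoms: int | None = None) -> np.ndarray:
    """Sum of the first ``n_atoms`` fitted waveforms, on the epoch's grid."""
    if n_atoms is None:
        n_atoms = len(book.atoms)
    if n_atoms > len(book.atoms):
        raise ValueError(f"book has {len(book.atoms)} atoms, asked for {n_atoms}")
    out = np.zeros(book.n_samples)
    for atom in book.atoms[:n_atoms]:
        if atom.coeff:
            out += atom.coeff * gabor_waveform(atom.params, book.fs, book.n_samples)
    return out


# -- book serialization (plain-text CSV with a '#' header block) -------------

_HEADER_FIELDS = ("fs", "epoch_start", "epoch_length", "signal_energy",
                  "residual_energy", "epsilon", "M")
_COLUMNS = "iteration,u,s,f,phi,coeff,energy"


def write_book(book: Book, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# spindlemp book v1\n")
        values = (book.fs, book.epoch_start, book.epoch_length,
                  book.signal_energy, book.residual_energy,
                  book.epsilon if book.epsilon is not None else "",
                  len(book.atoms))
        for name, value in zip(_HEADER_FIELDS, values):
            fh.write(f"# {name}={value!r}\n".replace("'", ""))
        fh.write(_COLUMNS + "\n")
        for a in book.atoms:
            p = a.params
            fields = (float(p.u), float(p.s), float(p.f), float(p.phi),
                      float(a.coeff), float(a.energy))
            fh.write(",".join([str(a.iteration)] + [repr(v) for v in fields]))
            fh.write("\n")


def read_book(path) -> Book:
    header: dict[str, str] = {}
    atoms: list[FittedAtom] = []
    saw_columns = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    header[key.strip()] = value.strip()
                continue
            if not saw_columns:
                if line != _COLUMNS:
                    raise ValueError(
                        f"{path}: line {lineno}: expected column header "
                        f"{_COLUMNS!r}, got {line!r}"
                    )
                saw_columns = True
                continue
            parts = line.split(",")
            if len(parts) != 7:
                raise ValueError(
                    f"{path}: line {lineno}: expected 7 comma-separated "
                    f"fields, got {len(parts)}"
                )
            try:
                it = int(parts[0])
                u, s, f, phi, coeff, _energy = map(float, parts[1:])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            atoms.append(FittedAtom(
                params=AtomParams(u=u, s=s, f=f, phi=phi),
                coeff=coeff, iteration=it,
            ))
    if not saw_columns:
        raise ValueError(f"{path}: missing column header line")
    try:
        eps = header.get("epsilon", "")
        return Book(
            atoms=atoms,
            fs=float(header["fs"]),
            epoch_start=float(header["epoch_start"]),
            epoch_length=float(header["epoch_length"]),
            signal_energy=float(header["signal_energy"]),
            residual_energy=float(header["residual_energy"]),
            epsilon=float(eps) if eps not in ("", "None") else None,
        )
    except KeyError as exc:
        raise ValueError(f"{path}: missing header field {exc}") from None
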