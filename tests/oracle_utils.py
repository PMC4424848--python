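"""Independent brute-force reference implementations used by the tests.

Everything here is written directly from the definitions (plain loops,
direct summation, numpy least squares) and deliberately shares no code with
the package internals it checks.
"""

import numpy as np


def direct_gabor(u, s, f, phi, fs, n, normalize=True):
    """Direct-summation Gabor sample vector (no truncation)."""
    t = np.arange(n) / fs - u
    g = np.exp(-np.pi * (t / s) ** 2) * np.cos(2 * np.pi * f * t + phi)
    if normalize:
        g = g / np.sqrt(np.sum(g * g))
    return g


def best_projection_energy(residual, u, s, f, fs):
    """Energy removed by the atom at its optimal phase, via least squares."""
    n = len(residual)
    t = np.arange(n) / fs - u
    env = np.exp(-np.pi * (t / s) ** 2)
    gc = env * np.cos(2 * np.pi * f * t)
    gs = env * np.sin(2 * np.pi * f * t)
    basis = np.column_stack([gc, gs])
    coef, *_ = np.linalg.lstsq(basis, residual, rcond=None)
    proj = basis @ coef
    return float(proj @ proj)


def scan_dictionary(residual, dictionary):
    """Exhaustive scan of every (u, s, f) grid point.

    Returns (energy, u, s, f) of the maximizer; ties broken toward the
    smallest u, then f, then s — matching the engine's documented rule.
    The atom waveforms here are truncated exactly like the package's
    synthesis (support radius in samples) so that scores are comparable
    to machine precision.
    """
    from spindlemp.dictionary import support_halfwidth_samples

    fs = dictionary.fs
    n = len(residual)
    best = (-np.inf, np.inf, np.inf, np.inf)
    for grid in dictionary.grids:
        s = grid.s
        h = support_halfwidth_samples(s, fs)
        for u in grid.u_values:
            c = int(round(u * fs))
            lo, hi = max(c - h, 0), min(c + h + 1, n)
            t = np.arange(lo, hi) / fs - u
            env = np.exp(-np.pi * (t / s) ** 2)
            seg = residual[lo:hi]
            for f in grid.f_values:
                gc = env * np.cos(2 * np.pi * f * t)
                gs = env * np.sin(2 * np.pi * f * t)
                basis = np.column_stack([gc, gs])
                coef, *_ = np.linalg.lstsq(basis, seg, rcond=None)
                proj = basis @ coef
                energy = float(proj @ proj)
                cand = (energy, u, f, s)
                if energy > best[0] or (
                    energy == best[0] and (u, f, s) < (best[1], best[2], best[3])
                ):
                    best = cand
    return best


def loop_confusion(detected, reference):
    tp = tn = fp = fn = 0
    for d, r in zip(detected, reference):
        if d and r:
            tp += 1
        elif d and not r:
            fp += 1
        elif not d and r:
            fn += 1
        else:
            tn += 1
    return tp, tn, fp, fn


def formula_metrics(tp, tn, fp, fn):
    """Second, independent coding of the five performance measures."""
    P, Pp, N, Np = tp + fn, tp + fp, fp + tn, fn + tn
    total = P + N
    out = {}
    out["sensitivity"] = tp / P if P else np.nan
    out["ppv"] = tp / Pp if Pp else np.nan
    out["mcc"] = (
        (tp * tn - fp * fn) / np.sqrt(np.prod([float(x) for x in (P, Pp, N, Np)]))
        if min(P, Pp, N, Np) > 0
        else np.nan
    )
    if total:
        pe = (Pp * P + Np * N) / total**2
        out["kappa"] = ((tp + tn) / total - pe) / (1 - pe) if pe != 1 else np.nan
    else:
        out["kappa"] = np.nan
    s, p = out["sensitivity"], out["ppv"]
    out["f1"] = 2 * p * s / (p + s) if (p + s) and not np.isnan(p + s) else np.nan
    return out
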