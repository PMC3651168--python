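"""Independent naive oracles used by the test suite.

Everything here is deliberately written as the dumbest correct
implementation — per-window double loops, exhaustive pair enumeration,
literal refits — so it shares no code path with the library.
"""

from __future__ import annotations

import itertools

import numpy as np


def pad_reflect(a: np.ndarray, h: int) -> np.ndarray:
    return np.pad(a, h, mode="reflect")


def naive_focal_variance(a: np.ndarray, window: int) -> np.ndarray:
    h = window // 2
    p = pad_reflect(a, h)
    out = np.empty_like(a, dtype=float)
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            win = p[i:i + window, j:j + window]
            out[i, j] = np.mean((win - win.mean()) ** 2)
    return out


def naive_focal_entropy(q: np.ndarray, window: int) -> np.ndarray:
    """q must already hold integer gray levels."""
    h = window // 2
    p = pad_reflect(q, h)
    out = np.empty(q.shape, dtype=float)
    for i in range(q.shape[0]):
        for j in range(q.shape[1]):
            win = p[i:i + window, j:j + window].ravel()
            _, counts = np.unique(win, return_counts=True)
            pk = counts / counts.sum()
            out[i, j] = -(pk * np.log(pk)).sum()
    return out


def naive_glcm_contrast(q: np.ndarray, window: int,
                        offsets) -> np.ndarray:
    """Exhaustive pair enumeration within each (reflect-padded) window."""
    h = window // 2
    maxoff = max(max(abs(dr), abs(dc)) for dr, dc in offsets)
    p = pad_reflect(q, h + maxoff)
    out = np.empty(q.shape, dtype=float)
    for i in range(q.shape[0]):
        for j in range(q.shape[1]):
            acc = 0.0
            for dr, dc in offsets:
                tot, npair = 0.0, 0
                for r in range(window):
                    for c in range(window):
                        rr = i + maxoff + r
                        cc = j + maxoff + c
                        r2, c2 = rr + dr, cc + dc
                        # both pixels of the pair inside the window?
                        if (0 <= r + dr < window) and (0 <= c + dc < window):
                            tot += (p[rr, cc] - p[r2, c2]) ** 2
                            npair += 1
                acc += tot / npair
            out[i, j] = acc / len(offsets)
    return out


def naive_zonal(values: np.ndarray, mask: np.ndarray, origin_x: float,
                origin_y: float, cell: float, x: float, y: float,
                radius: float):
    """Full-scan circle membership + moments."""
    sel = []
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            px = origin_x + (j + 0.5) * cell
            py = origin_y - (i + 0.5) * cell
            if mask[i, j] and (px - x) ** 2 + (py - y) ** 2 <= radius ** 2:
                sel.append(values[i, j])
    sel = np.asarray(sel, dtype=float)
    if sel.size == 0:
        return 0, np.nan, np.nan
    sd = np.std(sel, ddof=1) if sel.size > 1 else 0.0
    return sel.size, sel.mean(), sd


def naive_loocv(y: np.ndarray, X: np.ndarray) -> float:
    """Literal leave-one-out refit loop on a prepared design matrix."""
    n = y.size
    errs = []
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        beta, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
        errs.append((y[i] - X[i] @ beta) ** 2)
    return float(np.mean(errs))


def exact_accumulation_mean(incidence: np.ndarray) -> np.ndarray:
    """Mean cumulative richness over all S! sample orderings."""
    inc = np.asarray(incidence, dtype=bool)
    S = inc.shape[0]
    sums = np.zeros(S)
    n_perm = 0
    for order in itertools.permutations(range(S)):
        seen = np.logical_or.accumulate(inc[list(order)], axis=0)
        sums += seen.sum(axis=1)
        n_perm += 1
    return sums / n_perm


def matheron_by_hand(resid: np.ndarray, coords: np.ndarray,
                     edges: np.ndarray):
    """Semivariogram via an explicit pair table."""
    n = resid.size
    n_bins = edges.size - 1
    gamma = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = np.hypot(*(coords[i] - coords[j]))
            if d > edges[-1]:
                continue
            b = min(np.searchsorted(edges, d, side="right") - 1, n_bins - 1)
            b = max(b, 0)
            gamma[b] += (resid[i] - resid[j]) ** 2
            counts[b] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, gamma / (2 * np.maximum(counts, 1)), 0.0)
    return gamma, counts
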