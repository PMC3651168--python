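"""Moving-window image texture: NDVI, first-order variance and entropy,
and second-order (gray-level co-occurrence) contrast.

These are the three texture measures classically used as remotely sensed
surrogates for vegetation structure.  Each is evaluated in a square moving
window of odd side ``w`` and written to the window's central cell:

* first-order variance — population variance (divisor ``n = w**2``) of the
  raw pixel values in the window;
* first-order entropy — Shannon entropy (natural log, nats) of the window's
  gray-level histogram after linear quantization to ``levels`` bins;
* second-order contrast — ``sum_ij p(i,j) * (i - j)**2`` over the window's
  gray-level co-occurrence matrix, averaged over a set of pixel offsets.

All three are computed with integral-image (summed-area table) rectangle
sums, so cost is linear in raster size and independent of window extent.
The naive per-window double loop lives in the test suite as the oracle.

Edge handling: ``reflect`` mirrors the raster at its borders so the output
covers the full grid; ``mask`` marks every window that does not fit
entirely inside the raster as nodata.  Under either policy a window that
contains an invalid (nodata) pixel yields nodata — texture is never
interpolated across data gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raster import Raster

DEFAULT_GRAY_LEVELS = 64
#: symmetric 4-direction offsets at distance one (E, S, SE, SW)
DEFAULT_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass(frozen=True)
class TextureSpec:
    """One texture computation: measure, window extent and discretization."""

    measure: str  # variance | entropy | contrast
    window: int
    gray_levels: int = DEFAULT_GRAY_LEVELS
    offsets: tuple = DEFAULT_OFFSETS
    edge_policy: str = "reflect"

    def __post_init__(self):
        if self.measure not in ("variance", "entropy", "contrast"):
            raise ValueError(f"unknown measure {self.measure!r}")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")
        if self.gray_levels < 2:
            raise ValueError("gray_levels must be >= 2")
        if self.measure == "contrast" and not self.offsets:
            raise ValueError("contrast requires at least one offset")
        if self.edge_policy not in ("reflect", "mask"):
            raise ValueError("edge_policy must be 'reflect' or 'mask'")

    @property
    def label(self) -> str:
        return f"{self.measure}_{self.window}x{self.window}"


def compute_texture(raster: Raster, spec: TextureSpec) -> Raster:
    """Dispatch a :class:`TextureSpec` to the matching focal operation."""
    if spec.measure == "variance":
        return focal_variance(raster, spec.window, spec.edge_policy)
    if spec.measure == "entropy":
        return focal_entropy(raster, spec.window, spec.gray_levels,
                             spec.edge_policy)
    return glcm_contrast(raster, spec.window, spec.gray_levels,
                         spec.offsets, spec.edge_policy)


# ---------------------------------------------------------------------------
# NDVI and quantization

def compute_ndvi(red: Raster, nir: Raster) -> Raster:
    """(NIR - Red) / (NIR + Red), in [-1, 1]; zero-sum pixels become nodata."""
    if red.shape2d != nir.shape2d:
        raise ValueError("red and nir bands differ in shape")
    if (red.origin_x, red.origin_y, red.cell_size) != \
            (nir.origin_x, nir.origin_y, nir.cell_size):
        raise ValueError("red and nir bands are not co-registered")
    r = np.asarray(red.band(0), dtype=np.float64)
    n = np.asarray(nir.band(0), dtype=np.float64)
    denom = r + n
    valid = red.mask & nir.mask & (denom != 0)
    out = np.zeros_like(denom)
    np.divide(n - r, denom, out=out, where=valid)
    return red.like(out, mask=valid)


def quantize(raster: Raster, levels: int) -> Raster:
    """Linear min-max binning of valid pixels into gray levels 0..levels-1.

    The maximum value maps to ``levels - 1``; a constant raster maps wholly
    to level 0 (degenerate but legal).  Nodata propagates.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    vals = np.asarray(raster.band(0), dtype=np.float64)
    if not raster.mask.any():
        raise ValueError("raster has no valid pixels")
    vmin = vals[raster.mask].min()
    vmax = vals[raster.mask].max()
    if vmax == vmin:
        q = np.zeros_like(vals)
    else:
        q = np.floor((vals - vmin) / (vmax - vmin) * levels)
        q = np.clip(q, 0, levels - 1)
    q[~raster.mask] = 0
    return raster.like(q)


def _as_levels(raster: Raster, levels: int) -> np.ndarray:
    """Return integer gray levels, quantizing on the fly if needed."""
    vals = np.asarray(raster.band(0))
    if np.issubdtype(vals.dtype, np.floating) and not np.all(
            np.mod(vals[raster.mask], 1) == 0):
        return quantize(raster, levels).band(0).astype(np.int64)
    v = vals.astype(np.int64)
    if v[raster.mask].min() < 0 or v[raster.mask].max() >= levels:
        return quantize(raster, levels).band(0).astype(np.int64)
    return v


# ---------------------------------------------------------------------------
# integral-image machinery

def _check_window(raster: Raster, window: int) -> None:
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    if window > min(raster.shape2d):
        raise ValueError("window larger than raster")


def _pad(arr: np.ndarray, pad: int, edge_policy: str,
         fill: float = 0.0) -> np.ndarray:
    if edge_policy == "reflect":
        return np.pad(arr, pad, mode="reflect")
    return np.pad(arr, pad, mode="constant", constant_values=fill)


def _integral(arr: np.ndarray, dtype=np.float64) -> np.ndarray:
    s = np.zeros((arr.shape[0] + 1, arr.shape[1] + 1), dtype=dtype)
    s[1:, 1:] = np.asarray(arr, dtype=dtype).cumsum(0).cumsum(1)
    return s


def _rect_sums(S: np.ndarray, top: int, left: int, height: int, width: int,
               out_shape: tuple[int, int]) -> np.ndarray:
    """Rectangle sums: for output cell (r, c), sum of the padded array over
    rows [r+top, r+top+height) and cols [c+left, c+left+width)."""
    nr, nc = out_shape
    i0, i1 = top, top + height
    j0, j1 = left, left + width
    return (S[i1:i1 + nr, j1:j1 + nc] - S[i0:i0 + nr, j1:j1 + nc]
            - S[i1:i1 + nr, j0:j0 + nc] + S[i0:i0 + nr, j0:j0 + nc])


def _window_valid(raster: Raster, window: int, pad: int,
                  edge_policy: str) -> np.ndarray:
    """True where the window at each cell contains no invalid pixel."""
    h = window // 2
    m = _pad(raster.mask.astype(np.float64), pad, edge_policy, fill=0.0)
    counts = _rect_sums(_integral(m), pad - h, pad - h, window, window,
                        raster.shape2d)
    return counts > window * window - 0.5


# ---------------------------------------------------------------------------
# focal texture operations

def focal_variance(raster: Raster, window: int,
                   edge_policy: str = "reflect") -> Raster:
    """Per-window population variance of raw values at the central cell."""
    _check_window(raster, window)
    h = window // 2
    vals = np.asarray(raster.band(0), dtype=np.float64)
    # center on the global mean: variance is shift-invariant and the
    # integral images lose far fewer digits on near-zero-mean data
    center = vals[raster.mask].mean() if raster.mask.any() else 0.0
    p = _pad(np.where(raster.mask, vals - center, 0.0), h, edge_policy)
    n = float(window * window)
    ld = np.longdouble
    s1 = _rect_sums(_integral(p, ld), 0, 0, window, window, raster.shape2d)
    s2 = _rect_sums(_integral(p * p, ld), 0, 0, window, window,
                    raster.shape2d)
    mean = s1 / n
    var = np.asarray(np.maximum(s2 / n - mean * mean, 0.0),
                     dtype=np.float64)
    mask = _window_valid(raster, window, h, edge_policy)
    var[~mask] = 0.0
    return raster.like(var, mask=mask)


def focal_entropy(raster: Raster, window: int,
                  levels: int = DEFAULT_GRAY_LEVELS,
                  edge_policy: str = "reflect") -> Raster:
    """Per-window Shannon entropy (nats) of the gray-level histogram."""
    if levels < 2:
        raise ValueError("levels must be >= 2")
    _check_window(raster, window)
    h = window // 2
    q = _as_levels(raster, levels)
    p = _pad(q, h, edge_policy).astype(np.int64)
    n = float(window * window)
    ent = np.zeros(raster.shape2d, dtype=np.float64)
    for k in np.unique(p):
        counts = _rect_sums(_integral(p == k), 0, 0, window, window,
                            raster.shape2d)
        pk = counts / n
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(pk > 0, -pk * np.log(pk), 0.0)
        ent += term
    mask = _window_valid(raster, window, h, edge_policy)
    ent[~mask] = 0.0
    return raster.like(np.maximum(ent, 0.0), mask=mask)


def glcm_contrast(raster: Raster, window: int,
                  levels: int = DEFAULT_GRAY_LEVELS,
                  offsets: tuple = DEFAULT_OFFSETS,
                  edge_policy: str = "reflect") -> Raster:
    """Per-window GLCM contrast averaged over the configured offsets.

    Co-occurrence is accumulated symmetrically; because contrast weights
    ``(i - j)**2`` are symmetric in the pair, counting each unordered pair
    once and normalizing by the pair count gives the identical statistic.
    """
    if not offsets:
        raise ValueError("at least one offset required")
    _check_window(raster, window)
    h = window // 2
    q = _as_levels(raster, levels).astype(np.float64)
    maxoff = max(max(abs(dr), abs(dc)) for dr, dc in offsets)
    pad = h + maxoff
    p = _pad(q, pad, edge_policy)
    nr, nc = raster.shape2d
    Hp, Wp = p.shape

    total = np.zeros((nr, nc), dtype=np.float64)
    n_used = 0
    for dr, dc in offsets:
        if dr < 0 or (dr == 0 and dc < 0):
            dr, dc = -dr, -dc  # same unordered pair set
        height = window - dr
        width = window - abs(dc)
        if height <= 0 or width <= 0:
            raise ValueError(f"offset ({dr},{dc}) exceeds window span")
        # squared level difference anchored at the pair's first pixel
        D = np.zeros_like(p)
        r_hi = Hp - dr
        if dc >= 0:
            D[:r_hi, :Wp - dc] = (p[:r_hi, :Wp - dc]
                                  - p[dr:, dc:]) ** 2
        else:
            D[:r_hi, -dc:] = (p[:r_hi, -dc:] - p[dr:, :Wp + dc]) ** 2
        left = pad - h + (0 if dc >= 0 else -dc)
        sums = _rect_sums(_integral(D), pad - h, left, height, width,
                          (nr, nc))
        total += sums / float(height * width)
        n_used += 1
    out = total / n_used
    mask = _window_valid(raster, window, pad, edge_policy)
    out[~mask] = 0.0
    return raster.like(np.maximum(out, 0.0), mask=mask)
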