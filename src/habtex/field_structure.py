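"""Field-measured vegetation structure from foliage-height profiles.

A foliage-height profile is the count of vegetation contacts ("hits") on a
vertical pole, tallied in 30-cm height bands from the ground to 12 m
(40 bands).  Sixteen profiles are taken per sample point (4 sub-plots x 4
cardinal directions).  Two indices summarize them:

* foliage-height diversity (FHD) — Shannon diversity (natural log) of the
  hit distribution across height bands, pooled over the 16 profiles.  High
  FHD means vegetation is spread evenly through many height layers.
* horizontal vegetation structure (HVS) — sample standard deviation of the
  16 per-profile canopy heights, where a profile's canopy height is the
  upper edge of its highest occupied band (0 if the profile has no hits).
  High HVS means canopy height varies from place to place.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

N_BANDS = 40
BAND_HEIGHT_M = 0.3
PROFILES_PER_POINT = 16


def foliage_height_diversity(hits: np.ndarray) -> float:
    """Shannon diversity (nats) of pooled hits across height bands.

    ``hits`` is a (16, n_bands) array of per-profile band counts.  Hits
    are pooled across profiles before computing the index.  Returns NaN
    when the point recorded no hits at all (flagged, not an error).
    """
    hits = np.asarray(hits)
    _check_profiles(hits)
    pooled = hits.sum(axis=0).astype(np.float64)
    total = pooled.sum()
    if total <= 0:
        return float("nan")
    p = pooled[pooled > 0] / total
    return float(-(p * np.log(p)).sum())


def horizontal_structure(hits: np.ndarray,
                         band_height: float = BAND_HEIGHT_M) -> float:
    """Sample SD (n-1) of the 16 canopy heights, in metres."""
    hits = np.asarray(hits)
    _check_profiles(hits)
    heights = canopy_heights(hits, band_height)
    return float(np.std(heights, ddof=1))


def canopy_heights(hits: np.ndarray,
                   band_height: float = BAND_HEIGHT_M) -> np.ndarray:
    """Per-profile canopy height: upper edge of the highest occupied band."""
    hits = np.asarray(hits)
    occupied = hits > 0
    # index of highest occupied band, -1 when profile is empty
    top = np.where(occupied.any(axis=1),
                   hits.shape[1] - 1 - np.argmax(occupied[:, ::-1], axis=1),
                   -1)
    return (top + 1) * band_height


def _check_profiles(hits: np.ndarray) -> None:
    if hits.ndim != 2 or hits.shape[0] != PROFILES_PER_POINT:
        raise ValueError(
            f"expected ({PROFILES_PER_POINT}, n_bands) profile array, "
            f"got {hits.shape}")
    if (hits < 0).any():
        raise ValueError("hit counts must be non-negative")


def structure_indices(profiles: pd.DataFrame) -> pd.DataFrame:
    """Compute FHD and HVS per point from a long-format profile table.

    Expects columns ``point_id, subplot, direction, band_1..band_40``
    (one row per profile).  Returns ``point_id, fhd, hvs``.
    """
    band_cols = [c for c in profiles.columns if c.startswith("band_")]
    rows = []
    for pid, grp in profiles.groupby("point_id", sort=False):
        hits = grp[band_cols].to_numpy()
        rows.append({"point_id": pid,
                     "fhd": foliage_height_diversity(hits),
                     "hvs": horizontal_structure(hits)})
    return pd.DataFrame(rows)
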