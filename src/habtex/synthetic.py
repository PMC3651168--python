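"""Synthetic landscape and survey generator with known ground truth.

Emulates the data structure of a three-habitat (grassland / savanna /
woodland) military-installation mosaic surveyed for breeding birds:

* a habitat map built by thresholding smoothed Gaussian noise at
  fraction-matching quantiles (contiguous patches, exact class shares);
* a 1-m single-band "air photo" (bright ground, dark tree crowns) and a
  30-m two-band red/NIR image from which NDVI is computed;
* constrained sample points (minimum separation, exclusion features,
  habitat-edge buffer);
* 16 foliage-height profiles per point whose pooled Shannon diversity
  matches habitat-level targets (defaults 0.53 / 1.51 / 2.70 nats);
* repeated 100-m variable-radius point counts with half-normal
  distance-dependent detection, and a per-point species richness drawn
  from a quadratic response plus Gaussian noise.

Everything is driven by a :class:`TruthConfig` carrying the generating
parameters, so downstream estimators can be checked against known truth.
All generators are deterministic given their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import Raster

GRASSLAND, SAVANNA, WOODLAND = 0, 1, 2
HABITAT_NAMES = {GRASSLAND: "grassland", SAVANNA: "savanna",
                 WOODLAND: "woodland"}
TRUNCATION_M = 100.0
DISC_AREA_HA = np.pi * TRUNCATION_M ** 2 / 1e4

# per-habitat foliage band weights; Shannon entropies 0.527 / 1.510 / 2.708
# nats, matching the grassland/savanna/woodland vertical-structure targets
_GRASS_BANDS = {0: 0.78, 1: 0.22}
_SAV_W = 0.5626 ** np.arange(8)
_SAVANNA_BANDS = {i: w / _SAV_W.sum() for i, w in enumerate(_SAV_W)}
_WOOD_IDX = np.unique(np.linspace(0, 39, 15).round().astype(int))
_WOODLAND_BANDS = {int(i): 1.0 / len(_WOOD_IDX) for i in _WOOD_IDX}


@dataclass
class HabitatReflectance:
    """Fine-grain rendering parameters for one habitat class."""
    background: float
    noise_sd: float
    crown_density: float  # crowns per m^2
    crown_radius: float   # m
    crown_value: float
    red: float            # coarse-grain band means
    nir: float


@dataclass
class TruthConfig:
    """Generating parameters: the ground truth of a synthetic study."""

    extent_m: tuple = (2000.0, 2000.0)
    fractions: tuple = (0.25, 0.35, 0.40)
    patch_scale_m: float = 500.0
    fine_cell_m: float = 1.0
    coarse_cell_m: float = 30.0
    coarse_noise_sd: float = 2.0
    reflectance: dict = field(default_factory=lambda: {
        # grassland: bright, nearly treeless, quiet
        GRASSLAND: HabitatReflectance(180.0, 4.0, 2e-5, 2.0, 60.0,
                                      50.0, 100.0),
        # savanna: bright background with sparse dark crowns -> high
        # local contrast at fine grain
        SAVANNA: HabitatReflectance(170.0, 5.0, 6e-3, 3.0, 60.0,
                                    40.0, 110.0),
        # woodland: dense overlapping crowns on a dark background ->
        # dark with moderate variation
        WOODLAND: HabitatReflectance(100.0, 5.0, 5e-2, 3.0, 60.0,
                                     30.0, 120.0),
    })
    # density model: birds/ha = max(0, b0 + b1*x [+ b2*x^2])
    density_beta: tuple = (6.4, -0.36)
    # half-normal detection scale, one sigma (m) per survey year
    detection_sigma: tuple = (58.0, 55.0, 42.0)
    # richness = round(max(0, c0 + c1*x + c2*x^2 + noise))
    richness_beta: tuple = (7.08, 0.40, -0.0021)
    richness_noise_sd: float = 2.0
    fhd_targets: tuple = (0.53, 1.51, 2.70)
    profile_mean_hits: float = 12.0  # expected hits per profile
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("habitat fractions must sum to 1")
        if any(s <= 0 for s in self.detection_sigma):
            raise ValueError("detection sigma must be positive")
        if self.richness_noise_sd < 0:
            raise ValueError("noise sd must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["reflectance"] = {HABITAT_NAMES[k]: asdict(v) if not
                            isinstance(v, dict) else v
                            for k, v in self.reflectance.items()}
        return d


# ---------------------------------------------------------------------------
# habitat map and reflectance

def generate_habitat_map(extent_m=(2000.0, 2000.0), cell_size: float = 10.0,
                         fractions=(0.25, 0.35, 0.40),
                         patch_scale: float = 300.0,
                         seed: int = 0) -> Raster:
    """Three-class habitat mosaic from quantile-thresholded smoothed noise.

    Smoothing at ``patch_scale`` gives contiguous patches; thresholding the
    smoothed field at the fraction-matching quantiles makes realized class
    shares equal the requested fractions up to ties.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if patch_scale <= cell_size:
        raise ValueError("patch_scale must exceed cell_size")
    ny = int(round(extent_m[1] / cell_size))
    nx = int(round(extent_m[0] / cell_size))
    if ny < 3 or nx < 3:
        raise ValueError("degenerate extent: need at least 3x3 cells")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((ny, nx))
    smooth = ndimage.gaussian_filter(noise, sigma=patch_scale / cell_size
                                     / 4.0, mode="reflect")
    labels = np.full((ny, nx), WOODLAND, dtype=np.int16)
    q_grass = np.quantile(smooth, fractions[0])
    q_sav = np.quantile(smooth, fractions[0] + fractions[1])
    labels[smooth <= q_grass] = GRASSLAND
    labels[(smooth > q_grass) & (smooth <= q_sav)] = SAVANNA
    return Raster(labels, 0.0, extent_m[1], cell_size)


def _resample_nearest(src: Raster, cell_size: float) -> Raster:
    # ceil so the resampled grid always covers the full source extent
    ny = int(np.ceil(src.shape2d[0] * src.cell_size / cell_size - 1e-9))
    nx = int(np.ceil(src.shape2d[1] * src.cell_size / cell_size - 1e-9))
    rr = np.minimum((np.arange(ny) + 0.5) * cell_size / src.cell_size,
                    src.shape2d[0] - 1).astype(int)
    cc = np.minimum((np.arange(nx) + 0.5) * cell_size / src.cell_size,
                    src.shape2d[1] - 1).astype(int)
    return Raster(src.values[np.ix_(rr, cc)], src.origin_x, src.origin_y,
                  cell_size)


def render_reflectance(habitat_map: Raster, grain: str,
                       config: TruthConfig, seed: int = 0) -> Raster:
    """Render the habitat mosaic at fine (1-m, one band) or coarse (30-m,
    red + NIR bands) grain.

    Fine grain draws a noisy per-habitat background and stamps dark
    circular tree crowns at Poisson-distributed densities; coarse grain
    assigns per-habitat red/NIR means plus noise.
    """
    if grain not in ("fine", "coarse"):
        raise ValueError("grain must be 'fine' or 'coarse'")
    labs = np.unique(np.asarray(habitat_map.values, dtype=int))
    unknown = set(labs) - set(config.reflectance)
    if unknown:
        raise ValueError(f"unknown habitat label(s) {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    if grain == "coarse":
        hm = _resample_nearest(habitat_map, config.coarse_cell_m)
        lab = np.asarray(hm.values, dtype=int)
        red = np.zeros(lab.shape)
        nir = np.zeros(lab.shape)
        for h, p in config.reflectance.items():
            red[lab == h] = p.red
            nir[lab == h] = p.nir
        red += rng.normal(0.0, config.coarse_noise_sd, lab.shape)
        nir += rng.normal(0.0, config.coarse_noise_sd, lab.shape)
        return Raster(np.stack([red, nir]), hm.origin_x, hm.origin_y,
                      hm.cell_size)

    hm = _resample_nearest(habitat_map, config.fine_cell_m)
    lab = np.asarray(hm.values, dtype=int)
    ny, nx = lab.shape
    cell = hm.cell_size
    img = np.zeros(lab.shape)
    for h, p in config.reflectance.items():
        sel = lab == h
        img[sel] = p.background
        if p.noise_sd > 0:
            img[sel] += rng.normal(0.0, p.noise_sd, int(sel.sum()))
    # stamp circular crowns, darkest value wins where crowns overlap
    yy_cache = {}
    for h, p in config.reflectance.items():
        sel_rows, sel_cols = np.nonzero(lab == h)
        if sel_rows.size == 0 or p.crown_density <= 0:
            continue
        area_m2 = sel_rows.size * cell * cell
        n_crowns = rng.poisson(p.crown_density * area_m2)
        if n_crowns == 0:
            continue
        idx = rng.integers(0, sel_rows.size, n_crowns)
        rad = max(int(round(p.crown_radius / cell)), 1)
        if rad not in yy_cache:
            yy, xx = np.mgrid[-rad:rad + 1, -rad:rad + 1]
            yy_cache[rad] = (yy * yy + xx * xx) <= rad * rad
        disc = yy_cache[rad]
        for r0, c0 in zip(sel_rows[idx], sel_cols[idx]):
            r1, r2 = max(r0 - rad, 0), min(r0 + rad + 1, ny)
            c1, c2 = max(c0 - rad, 0), min(c0 + rad + 1, nx)
            d = disc[r1 - (r0 - rad):disc.shape[0] - ((r0 + rad + 1) - r2),
                     c1 - (c0 - rad):disc.shape[1] - ((c0 + rad + 1) - c2)]
            patch = img[r1:r2, c1:c2]
            patch[d] = np.minimum(patch[d], p.crown_value)
    return Raster(img, hm.origin_x, hm.origin_y, cell)


# ---------------------------------------------------------------------------
# sample points

def place_sample_points(habitat_map: Raster, n_candidates: int = 400,
                        min_sep: float = 300.0,
                        exclusion_mask: Raster | None = None,
                        exclusion_radius: float = 150.0,
                        edge_buffer: float = 100.0,
                        seed: int = 0) -> pd.DataFrame:
    """Random points at pixel centers honoring three spatial constraints.

    Candidates are drawn sequentially and kept only when at least
    ``min_sep`` from every already-accepted candidate; the accepted set is
    then filtered to points at least ``exclusion_radius`` from any masked
    (e.g. road) pixel and at least ``edge_buffer`` from the nearest pixel
    center of a different habitat class.  Returns ``id, x, y, habitat``
    (possibly empty, with a warning).
    """
    if min_sep < 0 or exclusion_radius < 0 or edge_buffer < 0:
        raise ValueError("distances must be non-negative")
    lab = np.asarray(habitat_map.values, dtype=int)
    ny, nx = lab.shape
    cell = habitat_map.cell_size
    rng = np.random.default_rng(seed)

    # distance (m) from each pixel center to nearest other-class center
    edge_dist = np.zeros(lab.shape)
    for h in np.unique(lab):
        sel = lab == h
        edge_dist[sel] = (ndimage.distance_transform_edt(sel) * cell)[sel]

    if exclusion_mask is not None:
        excl = np.asarray(_resample_nearest(exclusion_mask, cell).values) > 0
        excl_dist = ndimage.distance_transform_edt(~excl) * cell
    else:
        excl_dist = None

    accepted_rc: list[tuple[int, int]] = []
    xs, ys = [], []
    max_tries = 60 * max(n_candidates, 1)
    tries = 0
    while len(accepted_rc) < n_candidates and tries < max_tries:
        tries += 1
        r = int(rng.integers(0, ny))
        c = int(rng.integers(0, nx))
        x, y = habitat_map.rowcol_to_xy(r, c)
        if xs and np.min((np.asarray(xs) - x) ** 2
                         + (np.asarray(ys) - y) ** 2) < min_sep ** 2:
            continue
        accepted_rc.append((r, c))
        xs.append(float(x))
        ys.append(float(y))

    rows = []
    for i, (r, c) in enumerate(accepted_rc):
        if edge_dist[r, c] < edge_buffer:
            continue
        if excl_dist is not None and excl_dist[r, c] < exclusion_radius:
            continue
        rows.append({"id": f"pt{i:03d}", "x": xs[i], "y": ys[i],
                     "habitat": int(lab[r, c])})
    if not rows:
        warnings.warn("no sample point satisfies all constraints")
        return pd.DataFrame(columns=["id", "x", "y", "habitat"])
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# foliage profiles

_BAND_WEIGHTS = {GRASSLAND: _GRASS_BANDS, SAVANNA: _SAVANNA_BANDS,
                 WOODLAND: _WOODLAND_BANDS}


def simulate_foliage_profiles(points: pd.DataFrame, config: TruthConfig,
                              seed: int = 0,
                              band_weights: dict | None = None,
                              n_bands: int = 40) -> pd.DataFrame:
    """Sixteen Poisson foliage-height profiles per point.

    Per profile, hits in band b are Poisson with mean
    ``profile_mean_hits * weight_b``; pooling the 16 profiles gives a
    point-level Shannon diversity close to the entropy of the habitat's
    band-weight vector (0.53 / 1.51 / 2.70 nats by default).
    Long-format rows: point_id, subplot (1-4), direction (1-4),
    band_1..band_{n_bands}.
    """
    rng = np.random.default_rng(seed)
    weights = band_weights or _BAND_WEIGHTS
    rows = []
    for rec in points.itertuples(index=False):
        wvec = np.zeros(n_bands)
        for b, w in weights[int(rec.habitat)].items():
            wvec[b] = w
        lam = config.profile_mean_hits * wvec
        for sub in range(1, 5):
            for direc in range(1, 5):
                hits = rng.poisson(lam)
                row = {"point_id": rec.id, "subplot": sub,
                       "direction": direc}
                row.update({f"band_{b + 1}": int(hits[b])
                            for b in range(n_bands)})
                rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bird surveys and richness

def true_density(covariate: np.ndarray, beta) -> np.ndarray:
    """birds/ha: max(0, b0 + b1*x [+ b2*x^2])."""
    x = np.asarray(covariate, dtype=np.float64)
    lam = beta[0] + beta[1] * x
    if len(beta) > 2:
        lam = lam + beta[2] * x * x
    return np.maximum(lam, 0.0)


def simulate_bird_surveys(points: pd.DataFrame, covariate,
                          truth: TruthConfig, years: int = 3,
                          visits: tuple = (4, 4, 3), seed: int = 0,
                          species: str = "SP1") -> pd.DataFrame:
    """Poisson point counts with half-normal distance-dependent detection.

    Per point and visit, the number of birds present in the 100-m disc is
    Poisson(lambda * disc area); each bird sits at a uniform-in-disc
    radius and is detected with probability exp(-d^2 / 2 sigma_year^2).
    Only detected birds appear, with their true radial distances.
    """
    if any(s <= 0 for s in truth.detection_sigma):
        raise ValueError("detection sigma must be positive")
    rng = np.random.default_rng(seed)
    lam = true_density(covariate, truth.density_beta)
    if np.ndim(visits) == 0:
        visits = tuple([int(visits)] * years)
    sig = list(truth.detection_sigma)
    while len(sig) < years:
        sig.append(sig[-1])
    rows = []
    for yi in range(years):
        sigma = sig[yi]
        for vi in range(visits[yi]):
            n_birds = rng.poisson(lam * DISC_AREA_HA)
            for pid, nb in zip(points["id"], n_birds):
                if nb == 0:
                    continue
                d = TRUNCATION_M * np.sqrt(rng.random(nb))
                p_detect = np.exp(-d * d / (2.0 * sigma * sigma))
                det = rng.random(nb) < p_detect
                for dist in d[det]:
                    rows.append({"point_id": pid, "year": 2007 + yi,
                                 "visit": vi + 1, "species": species,
                                 "distance_m": float(dist)})
    return pd.DataFrame(rows, columns=["point_id", "year", "visit",
                                       "species", "distance_m"])


def simulate_richness(points: pd.DataFrame, covariate, coefficients=None,
                      noise_sd: float = 2.0, seed: int = 0) -> np.ndarray:
    """Per-point species richness: quadratic response + Gaussian noise,
    rounded and clamped non-negative."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    coefficients = coefficients if coefficients is not None \
        else (7.08, 0.40, -0.0021)
    x = np.asarray(covariate, dtype=np.float64)
    rng = np.random.default_rng(seed)
    mu = coefficients[0] + coefficients[1] * x
    if len(coefficients) > 2:
        mu = mu + coefficients[2] * x * x
    r = mu + rng.normal(0.0, noise_sd, x.shape)
    return np.maximum(np.round(r), 0.0).astype(int)
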