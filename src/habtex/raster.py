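"""Minimal in-memory raster container with GeoTIFF round-tripping.

A :class:`Raster` is a 2-D (single band) or 3-D (band, row, col) float array
plus an affine north-up geotransform expressed as ``origin_x, origin_y``
(planar map coordinates of the grid's *upper-left corner*, metres) and a
square ``cell_size``.  Row indices increase southward (y decreasing), the
usual raster convention.  Validity is tracked with an explicit boolean mask
rather than NaN so integer-valued rasters (habitat classes, quantized gray
levels) stay exact.

GeoTIFFs are written through :mod:`tifffile` with the standard
georeferencing tags (ModelPixelScale, ModelTiepoint) and the GDAL nodata
tag, so outputs open correctly in GIS software.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

NODATA = -9999.0

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass
class Raster:
    """Gridded values with a planar geotransform and validity mask."""

    values: np.ndarray
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 1.0
    mask: np.ndarray = field(default=None)  # True where valid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim not in (2, 3):
            raise ValueError("values must be 2-D or (band, row, col) 3-D")
        if self.values.size == 0:
            raise ValueError("values grid is empty")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.mask is None:
            self.mask = np.ones(self.shape2d, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.shape2d:
                raise ValueError("mask shape must match the grid")

    # -- geometry ---------------------------------------------------------

    @property
    def shape2d(self) -> tuple[int, int]:
        return self.values.shape[-2:]

    @property
    def n_bands(self) -> int:
        return 1 if self.values.ndim == 2 else self.values.shape[0]

    def band(self, i: int) -> np.ndarray:
        return self.values if self.values.ndim == 2 else self.values[i]

    def xy_to_rowcol(self, x: float, y: float) -> tuple[int, int]:
        col = int(np.floor((x - self.origin_x) / self.cell_size))
        row = int(np.floor((self.origin_y - y) / self.cell_size))
        return row, col

    def rowcol_to_xy(self, row, col):
        """Planar coordinates of pixel *centers*."""
        x = self.origin_x + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin_y - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def contains(self, x: float, y: float) -> bool:
        nrow, ncol = self.shape2d
        r, c = self.xy_to_rowcol(x, y)
        return 0 <= r < nrow and 0 <= c < ncol

    def like(self, values: np.ndarray, mask: np.ndarray | None = None) -> "Raster":
        """New raster sharing this one's geotransform."""
        return Raster(values, self.origin_x, self.origin_y, self.cell_size,
                      mask=self.mask.copy() if mask is None else mask)

    # -- I/O --------------------------------------------------------------

    def write(self, path) -> None:
        arr = np.asarray(self.values, dtype=np.float32).copy()
        bad = ~self.mask
        if arr.ndim == 2:
            arr[bad] = NODATA
        else:
            arr[:, bad] = NODATA
        extratags = [
            (_TAG_MODEL_PIXEL_SCALE, "d", 3,
             (self.cell_size, self.cell_size, 0.0)),
            (_TAG_MODEL_TIEPOINT, "d", 6,
             (0.0, 0.0, 0.0, self.origin_x, self.origin_y, 0.0)),
            (_TAG_GDAL_NODATA, "s", 0, str(NODATA)),
        ]
        tifffile.imwrite(path, arr, extratags=extratags,
                         photometric="minisblack")

    @classmethod
    def read(cls, path) -> "Raster":
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            arr = tf.asarray()
            tags = page.tags
            cell = 1.0
            ox = oy = 0.0
            if _TAG_MODEL_PIXEL_SCALE in tags:
                cell = float(tags[_TAG_MODEL_PIXEL_SCALE].value[0])
            if _TAG_MODEL_TIEPOINT in tags:
                tp = tags[_TAG_MODEL_TIEPOINT].value
                ox, oy = float(tp[3]), float(tp[4])
            nodata = NODATA
            if _TAG_GDAL_NODATA in tags:
                nodata = float(tags[_TAG_GDAL_NODATA].value)
        arr = np.asarray(arr, dtype=np.float64)
        if arr.ndim == 3 and arr.shape[-1] in (2, 3, 4) and arr.shape[0] > 8:
            arr = np.moveaxis(arr, -1, 0)  # pixel-interleaved -> band-major
        if arr.ndim == 2:
            mask = arr != nodata
        else:
            mask = np.all(arr != nodata, axis=0)
        return cls(arr, ox, oy, cell, mask=mask)
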