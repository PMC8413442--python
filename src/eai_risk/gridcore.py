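"""Raster data model, alignment/resampling, nodata handling and GeoTIFF I/O.

The whole pipeline operates on :class:`Grid` — a single-band 2-D raster with
a boolean missing-data mask, a square cell size and a top-left origin.  The
coordinate convention throughout the package is row 0 = northernmost row,
col 0 = westernmost column, so "northwest" means low row/col indices.

GeoTIFF files are read and written through :mod:`tifffile` using the three
GeoTIFF/GDAL tags the pipeline needs: ``ModelPixelScale`` (33550),
``ModelTiepoint`` (33922) and ``GDAL_NODATA`` (42113).  The CRS is carried
as an opaque string in ``ImageDescription`` and never interpreted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import tifffile
from scipy import ndimage

logger = logging.getLogger("eai_risk")

# GeoTIFF / GDAL tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

DEFAULT_NODATA = -9999.0

#: Factor registry: every factor symbol the quality indices use, with its
#: resampling kind.  Categorical factors carry integer class codes and must
#: never be interpolated.
FACTOR_KINDS: dict[str, str] = {
    # climate (CQI)
    "Pr": "continuous",   # average annual precipitation, mm/yr
    "T": "continuous",    # annual mean temperature, degC
    "Di": "continuous",   # drought index (P/PET), dimensionless
    "Al": "continuous",   # altitude, m
    "Par": "continuous",  # photosynthetically active radiation, MJ/m2
    "At": "continuous",   # accumulated temperature >=10 degC, degree-days
    # soil (SQI)
    "Sd": "continuous",   # soil depth, cm
    "St": "continuous",   # soil texture index
    "Sei": "categorical", # soil erosion intensity class
    "Som": "continuous",  # soil organic matter, %
    "Sm": "continuous",   # soil moisture, m3/m3
    # vegetation (VQI)
    "Vc": "continuous",   # vegetation coverage
    "Vr": "continuous",   # vegetation richness index
    "Vrr": "categorical", # vegetation resistance-to-risk class
    "NPP": "continuous",  # net primary productivity, gC/m2/yr
    "A": "categorical",   # aspect class (sunny..shady)
    # terrain
    "DEM": "continuous",  # digital elevation model, m
}

CLIMATE_FACTORS = ("Pr", "T", "Di", "Al", "Par", "At")
SOIL_FACTORS = ("Sd", "St", "Sei", "Som", "Sm")
VEGETATION_FACTORS = ("Vc", "Vr", "Vrr", "NPP", "A")


class GridError(ValueError):
    """Contract violation on a Grid operation."""


class GridIOError(IOError):
    """Raster file could not be read or written."""


@dataclass
class Grid:
    """A single-band raster: values, nodata mask, geometry.

    Parameters
    ----------
    values:
        2-D float array of cell values.  Values under the mask are
        meaningless and never enter any computation.
    nodata_mask:
        2-D boolean array, same shape; True marks missing cells.
    cell_size:
        Square cell edge length in map units (> 0).
    origin:
        (x, y) map coordinates of the *top-left corner* of cell (0, 0).
    crs_tag:
        Opaque CRS identifier carried through I/O, never interpreted.
    """

    values: np.ndarray
    nodata_mask: np.ndarray = None  # type: ignore[assignment]
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise GridError("Grid values must be 2-D")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise GridError(
                f"mask shape {self.nodata_mask.shape} != values shape "
                f"{self.values.shape}"
            )
        if not self.cell_size > 0:
            raise GridError(f"cell_size must be > 0, got {self.cell_size}")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    # -- basic properties -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_unmasked(self) -> int:
        return int((~self.nodata_mask).sum())

    def unmasked_values(self) -> np.ndarray:
        """1-D array of the values at unmasked cells."""
        return self.values[~self.nodata_mask]

    def copy(self) -> "Grid":
        return Grid(self.values.copy(), self.nodata_mask.copy(),
                    self.cell_size, self.origin, self.crs_tag)

    def with_values(self, values: np.ndarray,
                    mask: np.ndarray | None = None) -> "Grid":
        """New Grid sharing this grid's geometry."""
        return Grid(values, self.nodata_mask.copy() if mask is None else mask,
                    self.cell_size, self.origin, self.crs_tag)

    def same_geometry(self, other: "Grid", tol: float = 1e-9) -> bool:
        return (self.shape == other.shape
                and abs(self.cell_size - other.cell_size) <= tol
                and abs(self.origin[0] - other.origin[0]) <= tol
                and abs(self.origin[1] - other.origin[1]) <= tol)

    # -- mask-propagating arithmetic --------------------------------------
    def _binop(self, other, op) -> "Grid":
        if isinstance(other, Grid):
            if not self.same_geometry(other):
                raise GridError("arithmetic on misaligned grids")
            mask = self.nodata_mask | other.nodata_mask
            vals = op(self.values, other.values)
        else:
            mask = self.nodata_mask.copy()
            vals = op(self.values, other)
        return Grid(vals, mask, self.cell_size, self.origin, self.crs_tag)

    def __add__(self, other): return self._binop(other, np.add)
    def __radd__(self, other): return self._binop(other, lambda a, b: b + a)
    def __sub__(self, other): return self._binop(other, np.subtract)
    def __mul__(self, other): return self._binop(other, np.multiply)
    def __rmul__(self, other): return self._binop(other, lambda a, b: b * a)
    def __truediv__(self, other): return self._binop(other, np.divide)


def _mask_union(grids: Iterable[Grid]) -> np.ndarray:
    """Union of missing cells — the nodata policy at every combination step."""
    mask = None
    for g in grids:
        mask = g.nodata_mask.copy() if mask is None else (mask | g.nodata_mask)
    if mask is None:
        raise GridError("no grids supplied")
    return mask


@dataclass
class FactorStack:
    """Named, mutually aligned factor grids.

    Alignment is checked at construction and on insertion, never assumed.
    Factor names must come from :data:`FACTOR_KINDS`.
    """

    grids: dict[str, Grid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = list(self.grids)
        for name in names:
            self._check_name(name)
        for name in names[1:]:
            self._check_aligned(name, self.grids[name])

    @staticmethod
    def _check_name(name: str) -> None:
        if name not in FACTOR_KINDS:
            raise GridError(
                f"unknown factor {name!r}; registered factors: "
                f"{sorted(FACTOR_KINDS)}"
            )

    def _check_aligned(self, name: str, grid: Grid) -> None:
        ref_name = next(iter(self.grids))
        ref = self.grids[ref_name]
        if not ref.same_geometry(grid):
            raise GridError(
                f"factor {name!r} is not aligned with {ref_name!r}"
            )

    def __getitem__(self, name: str) -> Grid:
        return self.grids[name]

    def __contains__(self, name: str) -> bool:
        return name in self.grids

    def __setitem__(self, name: str, grid: Grid) -> None:
        self._check_name(name)
        if self.grids:
            self._check_aligned(name, grid)
        self.grids[name] = grid

    def factors(self) -> list[str]:
        return list(self.grids)

    def require(self, names: Sequence[str], context: str = "") -> None:
        missing = [n for n in names if n not in self.grids]
        if missing:
            where = f" for {context}" if context else ""
            raise GridError(f"missing factor(s){where}: {', '.join(missing)}")


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------

def read_grid(path: str | Path, band: int = 0) -> Grid:
    """Read one band of a GeoTIFF into a :class:`Grid`.

    The nodata mask comes from the file's ``GDAL_NODATA`` tag; a file with
    no nodata declaration yields an all-False mask and a logged warning.
    NaN cells are always masked.
    """
    path = Path(path)
    try:
        tf = tifffile.TiffFile(path)
    except (OSError, tifffile.TiffFileError, ValueError) as exc:
        raise GridIOError(f"cannot read raster {path}: {exc}") from exc
    with tf:
        if band >= len(tf.pages):
            raise GridIOError(
                f"{path}: band {band} out of range (file has "
                f"{len(tf.pages)} band(s))"
            )
        page = tf.pages[band]
        values = np.asarray(page.asarray(), dtype=np.float64)
        if values.ndim != 2:
            raise GridIOError(f"{path}: band {band} is not a 2-D raster")

        tag = page.tags.get(_TAG_GDAL_NODATA)
        if tag is not None:
            nodata = float(str(tag.value).strip())
            mask = np.isclose(values, nodata, rtol=0.0, atol=1e-6)
        else:
            logger.warning("%s declares no nodata value; assuming all "
                           "cells valid", path)
            mask = np.zeros(values.shape, dtype=bool)
        mask |= np.isnan(values)

        scale = page.tags.get(_TAG_MODEL_PIXEL_SCALE)
        cell_size = float(scale.value[0]) if scale is not None else 1.0
        tie = page.tags.get(_TAG_MODEL_TIEPOINT)
        origin = ((float(tie.value[3]), float(tie.value[4]))
                  if tie is not None else (0.0, 0.0))
        desc = page.tags.get(270)
        crs_tag = str(desc.value) if desc is not None else ""
    return Grid(values, mask, cell_size, origin, crs_tag)


def write_grid(grid: Grid, path: str | Path,
               nodata: float = DEFAULT_NODATA) -> None:
    """Write a :class:`Grid` as a float32 single-band GeoTIFF.

    Masked cells are stored as ``nodata`` and the value is declared in the
    ``GDAL_NODATA`` tag, so ``read_grid(write_grid(g))`` restores the mask
    exactly and unmasked values bit-identically at float32 precision.
    """
    path = Path(path)
    vals = grid.values.astype(np.float32)
    vals = np.where(grid.nodata_mask, np.float32(nodata), vals)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3,
         (float(grid.cell_size), float(grid.cell_size), 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, grid.origin[0], grid.origin[1], 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, repr(float(nodata))),
    ]
    try:
        tifffile.imwrite(path, vals, extratags=extratags,
                         description=grid.crs_tag)
    except OSError as exc:
        raise GridIOError(f"cannot write raster {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Alignment / resampling
# ---------------------------------------------------------------------------

def _cell_centers(grid_like: Grid) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = grid_like.shape
    x0, y0 = grid_like.origin
    cs = grid_like.cell_size
    x = x0 + (np.arange(cols) + 0.5) * cs
    y = y0 - (np.arange(rows) + 0.5) * cs  # row 0 = north, y decreases
    return x, y


def align(grids: Sequence[Grid], target: Grid, method: str = "bilinear",
          names: Sequence[str] | None = None) -> list[Grid]:
    """Resample grids onto the target's geometry.

    method:
        ``nearest`` or ``bilinear``.  If ``names`` is given, each grid is
        checked against the factor-kind registry and bilinear on a
        categorical factor is a contract error (interpolating class codes
        would invent categories).

    Cells whose interpolation stencil touches any masked or out-of-extent
    source cell are masked in the output — nodata never turns finite.
    """
    if method not in ("nearest", "bilinear"):
        raise GridError(f"unknown resampling method {method!r}")
    if names is not None:
        if len(names) != len(grids):
            raise GridError("names and grids length mismatch")
        for n in names:
            if n not in FACTOR_KINDS:
                raise GridError(f"unknown factor {n!r}")
            if method == "bilinear" and FACTOR_KINDS[n] == "categorical":
                raise GridError(
                    f"factor {n!r} is categorical: bilinear resampling is "
                    "not allowed (use nearest)"
                )

    tx, ty = _cell_centers(target)
    out: list[Grid] = []
    for g in grids:
        if g.same_geometry(target):
            out.append(g.with_values(g.values.copy(), g.nodata_mask.copy()))
            continue
        sx0, sy0 = g.origin
        cs = g.cell_size
        # fractional source indices of target cell centers
        cols_idx = (tx - sx0) / cs - 0.5
        rows_idx = (sy0 - ty) / cs - 0.5
        ci, ri = np.meshgrid(cols_idx, rows_idx)
        nr, nc = g.shape
        inside = (ri >= -0.5) & (ri <= nr - 0.5) & \
                 (ci >= -0.5) & (ci <= nc - 0.5)
        if not inside.any():
            raise GridError("grid does not overlap the target extent")
        coords = np.stack([ri.ravel(), ci.ravel()])
        order = 0 if method == "nearest" else 1
        filled = np.where(g.nodata_mask, 0.0, g.values)
        num = ndimage.map_coordinates(filled, coords, order=order,
                                      mode="nearest").reshape(ri.shape)
        valid = ndimage.map_coordinates(
            (~g.nodata_mask).astype(np.float64), coords, order=order,
            mode="nearest").reshape(ri.shape)
        mask = ~inside | (valid < 1.0 - 1e-12)
        vals = np.where(mask, 0.0, num)
        out.append(Grid(vals, mask, target.cell_size, target.origin,
                        g.crs_tag or target.crs_tag))
    return out
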