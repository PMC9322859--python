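"""Raster data model and grid I/O.

Every stage of the pipeline works on simple in-memory rasters: a categorical
land-class grid with six classes (cultivated land, woodland, grassland,
waters, construction land, unused land) and stacks of continuous driver
layers (terrain, socio-economic density surfaces, accessibility distances).
Grids are row-major with the origin at the top-left and are indexed
(row, col).  All rasters participating in one analysis must share shape and
cell size; mixed resolutions are rejected rather than resampled.

Supported on-disk formats are GeoTIFF (via :mod:`tifffile`) and the ESRI
ASCII grid text dialect.  Cells that are nodata in any layer are excluded
from sampling, allocation and area statistics downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "N_CLASSES",
    "CLASS_LABELS",
    "CategoricalRaster",
    "ContinuousRaster",
    "DriverStack",
    "DRIVER_NAMES",
    "read_raster",
    "write_raster",
    "distance_transform",
]

N_CLASSES = 6
#: Canonical class order; codes are 1-based (1 = cultivated ... 6 = unused).
CLASS_LABELS = (
    "cultivated",
    "woodland",
    "grassland",
    "waters",
    "construction",
    "unused",
)

#: Canonical driver layer names, in the order the suitability model uses them.
DRIVER_NAMES = (
    "dem",
    "slope",
    "gdp_density",
    "pop_density",
    "dist_town",
    "dist_river",
    "dist_national_road",
    "dist_provincial_road",
    "dist_railway",
)

DEFAULT_NODATA = -9999


class RasterValidationError(ValueError):
    """Raised when a raster violates its structural invariants."""


@dataclass
class CategoricalRaster:
    """A grid of land-class codes.

    Parameters
    ----------
    values
        Integer grid; valid codes are 1..6, anything equal to
        ``nodata_code`` is treated as missing.
    cell_size
        Edge length of a cell in metres.
    nodata_code
        Integer marking missing cells (default -9999).
    class_labels
        Ordered names for codes 1..6.
    """

    values: np.ndarray
    cell_size: float
    nodata_code: int = DEFAULT_NODATA
    class_labels: tuple[str, ...] = CLASS_LABELS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.all(np.mod(self.values[np.isfinite(self.values)], 1) == 0):
                raise RasterValidationError("categorical raster requires integer codes")
            self.values = self.values.astype(np.int32)
        if self.values.ndim != 2 or min(self.values.shape) < 3:
            raise RasterValidationError(
                f"grid must be 2-D with both dimensions >= 3, got shape {self.values.shape}"
            )
        if self.cell_size <= 0:
            raise RasterValidationError("cell_size must be positive")
        if len(self.class_labels) != N_CLASSES:
            raise RasterValidationError("exactly six class labels required")
        codes = np.unique(self.values)
        bad = codes[(codes != self.nodata_code) & ((codes < 1) | (codes > N_CLASSES))]
        if bad.size:
            raise RasterValidationError(
                f"invalid land-class codes {sorted(int(b) for b in bad)}; "
                f"expected 1..{N_CLASSES} or nodata {self.nodata_code}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return self.values != self.nodata_code

    def class_counts(self) -> np.ndarray:
        """Cell count per class, length 6 (index 0 = class code 1)."""
        v = self.values[self.valid_mask]
        return np.bincount(v, minlength=N_CLASSES + 1)[1:].astype(np.int64)

    def class_areas_km2(self) -> np.ndarray:
        return self.class_counts() * (self.cell_size / 1000.0) ** 2

    def copy(self) -> "CategoricalRaster":
        return replace(self, values=self.values.copy())


@dataclass
class ContinuousRaster:
    """A real-valued grid; NaN cells are nodata."""

    values: np.ndarray
    cell_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 3:
            raise RasterValidationError(
                f"grid must be 2-D with both dimensions >= 3, got shape {self.values.shape}"
            )
        if self.cell_size <= 0:
            raise RasterValidationError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def normalized(self) -> "ContinuousRaster":
        """Min-max scale to [0, 1] over non-nodata cells."""
        v = self.values
        m = self.valid_mask
        lo, hi = np.nanmin(v), np.nanmax(v)
        out = np.full_like(v, np.nan)
        out[m] = 0.0 if hi == lo else (v[m] - lo) / (hi - lo)
        return ContinuousRaster(out, self.cell_size)


@dataclass
class DriverStack:
    """Named, aligned stack of continuous driver layers."""

    layers: dict[str, ContinuousRaster]

    def __post_init__(self) -> None:
        if not self.layers:
            raise RasterValidationError("driver stack is empty")
        shapes = {l.shape for l in self.layers.values()}
        sizes = {l.cell_size for l in self.layers.values()}
        if len(shapes) != 1 or len(sizes) != 1:
            raise RasterValidationError(
                f"driver layers disagree on shape/cell_size: {shapes}, {sizes}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def cell_size(self) -> float:
        return next(iter(self.layers.values())).cell_size

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.layers)

    def __getitem__(self, name: str) -> ContinuousRaster:
        return self.layers[name]

    @property
    def valid_mask(self) -> np.ndarray:
        m = np.ones(self.shape, dtype=bool)
        for layer in self.layers.values():
            m &= layer.valid_mask
        return m

    def normalized(self) -> "DriverStack":
        return DriverStack({k: v.normalized() for k, v in self.layers.items()})

    def as_matrix(self, names: Iterable[str] | None = None) -> np.ndarray:
        """Flattened (n_cells, n_layers) feature matrix in ``names`` order."""
        names = tuple(names) if names is not None else self.names
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"missing driver layer(s): {missing}")
        return np.column_stack([self.layers[n].values.ravel() for n in names])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _format_from_path(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in {"geotiff", "ascii"}:
            raise ValueError(f"unknown raster format {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        return "geotiff"
    if suffix in {".asc", ".txt"}:
        return "ascii"
    raise ValueError(f"cannot infer raster format from {path.name!r}")


def _read_ascii(path: Path) -> tuple[np.ndarray, float, float]:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            parts = fh.readline().split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        values = np.loadtxt(fh)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    values = values.reshape(nrows, ncols)
    return values, header["cellsize"], header.get("nodata_value", DEFAULT_NODATA)


def _write_ascii(path: Path, values: np.ndarray, cell_size: float, nodata: float) -> None:
    nrows, ncols = values.shape
    is_int = np.issubdtype(values.dtype, np.integer)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {cell_size:.6f}\n")
        fh.write(f"NODATA_value {nodata}\n")
        np.savetxt(fh, values, fmt="%d" if is_int else "%.10g")


def _read_geotiff(path: Path) -> tuple[np.ndarray, float, float]:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        meta: dict = {}
        if page.description:
            try:
                meta = json.loads(page.description)
            except (json.JSONDecodeError, TypeError):
                meta = {}
    return values, float(meta.get("cell_size", 1.0)), float(meta.get("nodata", DEFAULT_NODATA))


def _write_geotiff(path: Path, values: np.ndarray, cell_size: float, nodata: float) -> None:
    desc = json.dumps({"cell_size": cell_size, "nodata": nodata})
    tifffile.imwrite(path, values, description=desc)


def read_raster(path: str | Path, kind: str = "continuous",
                fmt: str | None = None) -> CategoricalRaster | ContinuousRaster:
    """Read a GeoTIFF or ESRI ASCII grid.

    ``kind`` is ``"categorical"`` (validated 6-class codes) or
    ``"continuous"`` (nodata mapped to NaN).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _format_from_path(path, fmt)
    if fmt == "ascii":
        values, cell_size, nodata = _read_ascii(path)
    else:
        values, cell_size, nodata = _read_geotiff(path)
    if kind == "categorical":
        values = np.where(values == nodata, DEFAULT_NODATA, values).astype(np.int32)
        return CategoricalRaster(values, cell_size, nodata_code=DEFAULT_NODATA)
    if kind == "continuous":
        values = np.asarray(values, dtype=float)
        values[values == nodata] = np.nan
        return ContinuousRaster(values, cell_size)
    raise ValueError(f"unknown raster kind {kind!r}")


def write_raster(raster: CategoricalRaster | ContinuousRaster, path: str | Path,
                 fmt: str | None = None) -> Path:
    """Write a raster to GeoTIFF or ESRI ASCII; format inferred from suffix."""
    path = Path(path)
    fmt = _format_from_path(path, fmt)
    if isinstance(raster, CategoricalRaster):
        values = raster.values.astype(np.int32)
        nodata: float = raster.nodata_code
    else:
        values = raster.values.astype(np.float64)
        nodata = DEFAULT_NODATA
        values = np.where(np.isfinite(values), values, nodata)
    if fmt == "ascii":
        _write_ascii(path, values, raster.cell_size, nodata)
    else:
        _write_geotiff(path, values, raster.cell_size, nodata)
    return path


# ---------------------------------------------------------------------------
# Distance analysis
# ---------------------------------------------------------------------------

def distance_transform(mask: np.ndarray, cell_size: float) -> ContinuousRaster:
    """Euclidean distance (metres, centre to centre) to the nearest True cell.

    True cells read 0.  Raises on an all-False mask, where the distance is
    undefined.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("distance transform undefined for an all-False mask")
    d = ndimage.distance_transform_edt(~mask, sampling=cell_size)
    return ContinuousRaster(np.asarray(d, dtype=float), cell_size)
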