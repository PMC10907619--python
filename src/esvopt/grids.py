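"""Categorical land-use grids and continuous driver rasters.

Rasters are stored in memory as 2-D numpy arrays and on disk as ESRI
ASCII grids (plain text, single band, explicit nodata), the exchange
format every desktop GIS reads. A :class:`LULCGrid` carries the class
codes, the per-cell area in hectares and minimal georeferencing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

#: canonical 6-class code convention: 1 cultivated, 2 forest, 3 grassland,
#: 4 water, 5 construction, 6 unused
CLASS_NAMES: Mapping[int, str] = {
    1: "cultivated",
    2: "forest",
    3: "grassland",
    4: "water",
    5: "construction",
    6: "unused",
}

DEFAULT_NODATA = -9999


class GeometryError(ValueError):
    """Raised when two rasters that must align do not."""


@dataclass
class LULCGrid:
    """A categorical land-use raster.

    Parameters
    ----------
    values
        2-D integer array of class codes.
    cell_area
        Area of one cell in hm² (hectares); must be positive.
    nodata
        Code marking cells outside the study region.
    xllcorner, yllcorner, cellsize
        Optional georeferencing of the lower-left corner (map units).
    """

    values: np.ndarray
    cell_area: float = 1.0
    nodata: int = DEFAULT_NODATA
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    cellsize: float = 100.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.all(self.values == np.round(self.values)):
                raise ValueError(
                    "categorical grid requires integer class codes; "
                    "use read_ascii_array for continuous rasters")
            self.values = self.values.astype(np.int64)
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return self.values != self.nodata

    def classes(self) -> np.ndarray:
        """Sorted class codes present (nodata excluded)."""
        return np.unique(self.values[self.valid_mask])

    def same_geometry(self, other: "LULCGrid") -> bool:
        return (
            self.shape == other.shape
            and self.cell_area == other.cell_area
            and self.cellsize == other.cellsize
        )

    def require_alignment(self, other: "LULCGrid") -> None:
        if not self.same_geometry(other):
            raise GeometryError(
                f"grid geometries differ: {self.shape}/{other.shape}"
            )

    def with_values(self, values: np.ndarray) -> "LULCGrid":
        """New grid sharing this geometry with different class codes."""
        return replace(self, values=np.asarray(values))


@dataclass
class FactorStack:
    """Named continuous driving-factor rasters on a shared geometry.

    Layers are min–max normalized lazily by :meth:`normalized`; the
    normalization constants are stored so surfaces learned on one epoch
    can score another.
    """

    layers: dict[str, np.ndarray] = field(default_factory=dict)
    norm_constants: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {a.shape for a in self.layers.values()}
        if len(shapes) > 1:
            raise GeometryError(f"factor layers have mixed shapes: {shapes}")
        for name, arr in self.layers.items():
            if np.all(~np.isfinite(arr)):
                raise ValueError(f"layer {name!r} has no finite data")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    def __len__(self) -> int:
        return len(self.layers)

    def normalized(self) -> "FactorStack":
        """Min–max scale every layer to [0, 1], remembering the constants."""
        out, consts = {}, {}
        for name, arr in self.layers.items():
            lo, hi = float(np.nanmin(arr)), float(np.nanmax(arr))
            span = hi - lo if hi > lo else 1.0
            out[name] = (arr - lo) / span
            consts[name] = (lo, span)
        return FactorStack(out, consts)

    def design_matrix(self, flat_index: np.ndarray | None = None) -> np.ndarray:
        """Stack layers into an (n_cells, n_layers) matrix."""
        flats = [arr.ravel() for arr in self.layers.values()]
        X = np.column_stack(flats)
        return X if flat_index is None else X[flat_index]


def write_ascii_grid(path: str | Path, grid: LULCGrid | np.ndarray,
                     nodata: float = DEFAULT_NODATA, cellsize: float = 100.0,
                     fmt: str = "%d") -> Path:
    """Write a single-band raster as an ESRI ASCII grid."""
    if isinstance(grid, LULCGrid):
        arr, nodata, cellsize = grid.values, grid.nodata, grid.cellsize
        xll, yll = grid.xllcorner, grid.yllcorner
    else:
        arr, xll, yll = np.asarray(grid), 0.0, 0.0
        if np.issubdtype(arr.dtype, np.floating):
            fmt = "%.6g"
    path = Path(path)
    header = (
        f"ncols {arr.shape[1]}\nnrows {arr.shape[0]}\n"
        f"xllcorner {xll}\nyllcorner {yll}\n"
        f"cellsize {cellsize}\nNODATA_value {nodata}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, arr, fmt=fmt)
    return path


def _parse_ascii(path: str | Path) -> tuple[np.ndarray, dict[str, float]]:
    meta: dict[str, float] = {}
    with Path(path).open() as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0][0].isalpha():
            meta[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    return np.atleast_2d(np.loadtxt(lines[n_header:])), meta


def read_ascii_array(path: str | Path) -> np.ndarray:
    """Read an ESRI ASCII grid as a raw (possibly continuous) array."""
    data, _ = _parse_ascii(path)
    return data


def read_ascii_grid(path: str | Path, cell_area: float = 1.0) -> LULCGrid:
    """Read an ESRI ASCII grid of integer class codes as a LULCGrid."""
    data, meta = _parse_ascii(path)
    nodata = meta.get("nodata_value", DEFAULT_NODATA)
    return LULCGrid(
        data, cell_area=cell_area, nodata=int(nodata),
        xllcorner=meta.get("xllcorner", 0.0),
        yllcorner=meta.get("yllcorner", 0.0),
        cellsize=meta.get("cellsize", 100.0),
    )


def check_codes(grid: LULCGrid, allowed: Iterable[int]) -> None:
    """Validate that every non-nodata cell uses a declared class code."""
    present = set(grid.classes().tolist())
    extra = present - set(allowed)
    if extra:
        raise ValueError(f"undeclared class codes present: {sorted(extra)}")
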