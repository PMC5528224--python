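"""Aligned covariate rasters and ESRI ASCII grid I/O.

The grid convention is the standard ASCII-raster one: row 0 is the top
row, values are row-major, and the cell centre of (row, col) sits at
``(xllcorner + (col + 0.5) * cell_size,
   yllcorner + (n_rows - row - 0.5) * cell_size)``.
NODATA cells are held as NaN in memory and written back with the
stack's sentinel value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, RasterFormatError

__all__ = ["RasterStack", "read_ascii_grid", "write_ascii_grid"]

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


@dataclass
class RasterStack:
    """One or more aligned covariate grids sharing a geotransform."""

    layers: dict[str, np.ndarray]
    cell_size: float
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if not self.layers:
            raise InputError("a RasterStack needs at least one layer")
        if not self.cell_size > 0:
            raise InputError("cell_size must be positive")
        shapes = {name: arr.shape for name, arr in self.layers.items()}
        first = next(iter(shapes.values()))
        if any(s != first for s in shapes.values()) or len(first) != 2:
            raise InputError(f"layers must share one 2-D shape; got {shapes}")
        self.layers = {
            name: np.asarray(arr, dtype=float) for name, arr in self.layers.items()
        }

    @property
    def n_rows(self) -> int:
        return next(iter(self.layers.values())).shape[0]

    @property
    def n_cols(self) -> int:
        return next(iter(self.layers.values())).shape[1]

    @property
    def layer_names(self) -> tuple[str, ...]:
        return tuple(self.layers)

    @property
    def mask(self) -> np.ndarray:
        """True where any layer is NODATA."""
        m = np.zeros((self.n_rows, self.n_cols), dtype=bool)
        for arr in self.layers.values():
            m |= np.isnan(arr)
        return m

    def layer(self, name: str | None = None) -> np.ndarray:
        if name is None:
            if len(self.layers) != 1:
                raise InputError(
                    f"stack has layers {self.layer_names}; specify one"
                )
            return next(iter(self.layers.values()))
        if name not in self.layers:
            raise InputError(f"no layer named '{name}' (have {self.layer_names})")
        return self.layers[name]

    def add_layer(self, name: str, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_rows, self.n_cols):
            raise InputError(
                f"layer '{name}' shape {values.shape} does not match "
                f"({self.n_rows}, {self.n_cols})"
            )
        self.layers[name] = values

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.xllcorner + (col + 0.5) * self.cell_size,
            self.yllcorner + (self.n_rows - row - 0.5) * self.cell_size,
        )

    def table(self, rows: np.ndarray, cols: np.ndarray) -> pd.DataFrame:
        """Covariate values at the given pixels as a DataFrame."""
        return pd.DataFrame(
            {name: arr[rows, cols] for name, arr in self.layers.items()}
        )


def read_ascii_grid(path, name: str = "layer") -> RasterStack:
    """Read a single-layer ESRI ASCII grid (.asc)."""
    header: dict[str, float] = {}
    nodata = None
    values: list[list[float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    if not lines:
        raise RasterFormatError("empty file", line=1)
    i = 0
    for i, raw in enumerate(lines):
        parts = raw.split()
        if not parts:
            continue
        key = parts[0].lower()
        if key in _HEADER_KEYS or key == "nodata_value":
            if len(parts) != 2:
                raise RasterFormatError(
                    f"header line '{key}' needs exactly one value", line=i + 1
                )
            try:
                val = float(parts[1])
            except ValueError:
                raise RasterFormatError(
                    f"bad numeric value {parts[1]!r} for '{key}'", line=i + 1
                ) from None
            if key == "nodata_value":
                nodata = val
            else:
                header[key] = val
        else:
            break
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise RasterFormatError(f"missing header fields: {missing}", line=i + 1)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    for lineno in range(i, len(lines)):
        parts = lines[lineno].split()
        if not parts:
            continue
        try:
            row = [float(v) for v in parts]
        except ValueError as exc:
            raise RasterFormatError(f"bad cell value: {exc}", line=lineno + 1) from None
        if len(row) != ncols:
            raise RasterFormatError(
                f"expected {ncols} values per row, got {len(row)}", line=lineno + 1
            )
        values.append(row)
    if len(values) != nrows:
        raise RasterFormatError(
            f"expected {nrows} data rows, got {len(values)}", line=len(lines)
        )
    grid = np.asarray(values, dtype=float)
    if nodata is not None:
        grid[grid == nodata] = np.nan
    return RasterStack(
        layers={name: grid},
        cell_size=header["cellsize"],
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        nodata=nodata if nodata is not None else -9999.0,
    )


def _fmt(v: float) -> str:
    if float(v).is_integer() and abs(v) < 1e15:
        return str(int(v))
    return repr(float(v))


def write_ascii_grid(raster: RasterStack, path, layer: str | None = None) -> None:
    """Write one layer as an ESRI ASCII grid; NaN cells get the sentinel."""
    grid = raster.layer(layer)
    out = np.where(np.isnan(grid), raster.nodata, grid)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {raster.n_cols}\n")
        fh.write(f"nrows {raster.n_rows}\n")
        fh.write(f"xllcorner {_fmt(raster.xllcorner)}\n")
        fh.write(f"yllcorner {_fmt(raster.yllcorner)}\n")
        fh.write(f"cellsize {_fmt(raster.cell_size)}\n")
        fh.write(f"NODATA_value {_fmt(raster.nodata)}\n")
        for row in out:
            fh.write(" ".join(_fmt(v) for v in row) + "\n")
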