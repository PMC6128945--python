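"""Minimal raster container with ESRI ASCII grid I/O and a Horn slope operator.

Values are float64 with NaN marking nodata in memory; the nodata sentinel
only appears on disk. Rows are stored north-up (row 0 is the top of the
grid), matching the ASCII grid layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(eq=False)
class Raster:
    values: np.ndarray = field(repr=False)
    cellsize: float = 1.0
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    nodata_value: float = -9999.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("raster values must be a non-empty 2-D array")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def nodata_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def rowcol_from_xy(self, x: float, y: float) -> tuple[int, int]:
        """Grid cell containing map coordinates (x, y)."""
        col = int(np.floor((x - self.xllcorner) / self.cellsize))
        row_from_bottom = int(np.floor((y - self.yllcorner) / self.cellsize))
        row = self.n_rows - 1 - row_from_bottom
        return row, col

    def like(self, values: np.ndarray) -> "Raster":
        return Raster(
            values, self.cellsize, self.xllcorner, self.yllcorner, self.nodata_value
        )


def write_ascii_grid(raster: Raster, path) -> None:
    vals = np.where(raster.nodata_mask, raster.nodata_value, raster.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.n_cols}\n")
        fh.write(f"nrows {raster.n_rows}\n")
        fh.write(f"xllcorner {raster.xllcorner!r}\n")
        fh.write(f"yllcorner {raster.yllcorner!r}\n")
        fh.write(f"cellsize {raster.cellsize!r}\n")
        fh.write(f"NODATA_value {raster.nodata_value!r}\n")
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path) -> Raster:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in (
                "ncols",
                "nrows",
                "xllcorner",
                "yllcorner",
                "xllcenter",
                "yllcenter",
                "cellsize",
                "nodata_value",
            ) and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    if "ncols" not in header or "nrows" not in header:
        raise ValueError("missing ncols/nrows header")
    vals = np.array(rows, dtype=float)
    if vals.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"grid body {vals.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    nodata = header.get("nodata_value", -9999.0)
    vals = np.where(vals == nodata, np.nan, vals)
    cellsize = header.get("cellsize", 1.0)
    # center-registered headers shift the corner by half a cell
    xll = header.get("xllcorner", header.get("xllcenter", 0.5 * cellsize) - 0.5 * cellsize)
    yll = header.get("yllcorner", header.get("yllcenter", 0.5 * cellsize) - 0.5 * cellsize)
    return Raster(vals, cellsize, xll, yll, nodata)


def slope_degrees(elevation: Raster) -> Raster:
    """Slope in degrees by Horn's 3x3 finite-difference operator.

    Edge cells use replicated padding; nodata cells propagate NaN.
    """
    z = elevation.values
    pad = np.pad(z, 1, mode="edge")
    a = pad[:-2, :-2]
    b = pad[:-2, 1:-1]
    c = pad[:-2, 2:]
    d = pad[1:-1, :-2]
    f = pad[1:-1, 2:]
    g = pad[2:, :-2]
    h = pad[2:, 1:-1]
    i = pad[2:, 2:]
    cs = elevation.cellsize
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * cs)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8.0 * cs)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    slope[elevation.nodata_mask] = np.nan
    return elevation.like(slope)
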