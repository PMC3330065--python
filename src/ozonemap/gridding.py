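"""Regular covariate grids, prediction surfaces, and ESRI ASCII raster I/O.

Grids follow the ESRI ASCII convention: row 0 is the northernmost row,
``(xllcorner, yllcorner)`` is the lower-left corner of the lower-left
cell, and predictions are made at cell centers.  Coordinates are planar
projected kilometres; altitudes are metres.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np

DEFAULT_NODATA = -9999.0


@dataclass
class CovariateGrid:
    """A rectangular grid carrying one per-cell covariate (altitude, m)."""

    x_ll: float
    y_ll: float
    cell_size: float
    values: np.ndarray  # 2-D, row 0 = top (north)
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def x_centers(self) -> np.ndarray:
        """Cell-center x coordinates, west to east (length ncols)."""
        return self.x_ll + (np.arange(self.ncols) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        """Cell-center y coordinates for each row, north to south (length nrows)."""
        top = self.y_ll + self.nrows * self.cell_size
        return top - (np.arange(self.nrows) + 0.5) * self.cell_size

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) meshes of cell centers, both shaped like ``values``."""
        return np.meshgrid(self.x_centers(), self.y_centers())

    def valid_mask(self) -> np.ndarray:
        return ~np.isclose(self.values, self.nodata) & np.isfinite(self.values)

    def value_at(self, x: float, y: float) -> float:
        """Covariate of the cell containing the point (x, y)."""
        col = int(np.floor((x - self.x_ll) / self.cell_size))
        row_from_bottom = int(np.floor((y - self.y_ll) / self.cell_size))
        row = self.nrows - 1 - row_from_bottom
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise ValueError(f"point ({x}, {y}) lies outside the grid")
        return float(self.values[row, col])


@dataclass
class PredictionSurface:
    """An interpolated metric surface on the geometry of a CovariateGrid."""

    x_ll: float
    y_ll: float
    cell_size: float
    values: np.ndarray
    metric_name: str = ""
    method: str = ""
    mask_applied: bool = False
    nodata: float = DEFAULT_NODATA

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def valid_mask(self) -> np.ndarray:
        return ~np.isclose(self.values, self.nodata) & np.isfinite(self.values)

    def as_grid(self) -> CovariateGrid:
        return CovariateGrid(self.x_ll, self.y_ll, self.cell_size,
                             self.values.copy(), self.nodata)


def predict_grid(interp, grid: CovariateGrid, metric_name: str = "",
                 method: str = "") -> PredictionSurface:
    """Evaluate a fitted interpolator at every valid cell center.

    ``interp`` must expose ``predict(x, y, altitude=None)`` and a boolean
    attribute ``needs_altitude``.  Altitude-using methods read the
    covariate value of each cell; nodata cells stay nodata.
    """
    mask = grid.valid_mask()
    xg, yg = grid.center_mesh()
    out = np.full(grid.shape, grid.nodata, dtype=float)
    xs, ys = xg[mask], yg[mask]
    if getattr(interp, "needs_altitude", False):
        alts = grid.values[mask]
        pred = interp.predict(xs, ys, alts)
    else:
        pred = interp.predict(xs, ys)
    pred = np.asarray(pred, dtype=float)
    if not np.all(np.isfinite(pred)):
        raise RuntimeError("interpolator produced non-finite predictions")
    out[mask] = pred
    return PredictionSurface(grid.x_ll, grid.y_ll, grid.cell_size, out,
                             metric_name=metric_name, method=method,
                             nodata=grid.nodata)


def apply_mask(surface: PredictionSurface, mask: np.ndarray) -> PredictionSurface:
    """Keep cells where ``mask`` is True; set the rest to nodata.

    Used e.g. to restrict AOT40F surfaces to forested cells.  The mask
    must match the surface geometry exactly.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != surface.values.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match surface {surface.values.shape}")
    values = np.where(mask, surface.values, surface.nodata)
    return dataclasses.replace(surface, values=values, mask_applied=True)


def surface_summary(surface: PredictionSurface) -> dict:
    """Min / max / mean / valid-cell count over valid cells only."""
    valid = surface.values[surface.valid_mask()]
    if valid.size == 0:
        raise ValueError("surface has no valid cells")
    return {
        "min": float(valid.min()),
        "max": float(valid.max()),
        "mean": float(valid.mean()),
        "n_valid": int(valid.size),
    }


def write_ascii_grid(path, grid) -> None:
    """Write a CovariateGrid or PredictionSurface as an ESRI ASCII raster."""
    lines = [
        f"ncols {grid.ncols}",
        f"nrows {grid.nrows}",
        f"xllcorner {grid.x_ll}",
        f"yllcorner {grid.y_ll}",
        f"cellsize {grid.cell_size}",
        f"NODATA_value {grid.nodata}",
    ]
    body = "\n".join(" ".join(format(v, ".6g") for v in row)
                     for row in grid.values)
    Path(path).write_text("\n".join(lines) + "\n" + body + "\n")


def read_ascii_grid(path) -> CovariateGrid:
    """Read an ESRI ASCII raster into a CovariateGrid."""
    text = Path(path).read_text().split("\n")
    header: dict[str, float] = {}
    i = 0
    while i < len(text):
        parts = text[i].split()
        if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value", "xllcenter", "yllcenter"}:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"ASCII grid header missing '{key}'")
    values = np.loadtxt(text[i:].__iter__(), dtype=float)
    values = np.atleast_2d(values)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid body does not match declared dimensions")
    return CovariateGrid(
        x_ll=header["xllcorner"],
        y_ll=header["yllcorner"],
        cell_size=header["cellsize"],
        values=values,
        nodata=header.get("nodata_value", DEFAULT_NODATA),
    )
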