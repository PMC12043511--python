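"""Planar pixel grids and text raster I/O.

The landscape frame is an unprojected metre grid. Pixel ``(i, j)`` of a
:class:`PixelGrid` covers the half-open square
``[x0 + j*s, x0 + (j+1)*s) x [y0 + i*s, y0 + (i+1)*s)`` with ``s`` the pixel
size; row index ``i`` increases northward. Rasters are plain 2-D float arrays
of shape ``(n_rows, n_cols)`` with ``NaN`` marking missing pixels.

Rasters are serialized as ESRI ASCII grids (``.asc``): a text format that
carries the grid origin and cell size in its header, so geometry survives a
round-trip exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

NODATA = -99999.0


@dataclass(frozen=True)
class PixelGrid:
    """Regular square-pixel grid anchored at its south-west corner."""

    x0: float
    y0: float
    pixel_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        s = self.pixel_size
        return (self.x0, self.y0, self.x0 + self.n_cols * s, self.y0 + self.n_rows * s)

    def pixel_bounds(self, i: int, j: int) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of pixel (i, j)."""
        s = self.pixel_size
        return (self.x0 + j * s, self.y0 + i * s, self.x0 + (j + 1) * s, self.y0 + (i + 1) * s)

    def pixel_index(self, x, y):
        """Row/column of the pixel containing (x, y) (half-open convention)."""
        j = np.floor((np.asarray(x) - self.x0) / self.pixel_size).astype(int)
        i = np.floor((np.asarray(y) - self.y0) / self.pixel_size).astype(int)
        return i, j

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-centre coordinate arrays (X, Y), each of grid shape."""
        s = self.pixel_size
        xs = self.x0 + (np.arange(self.n_cols) + 0.5) * s
        ys = self.y0 + (np.arange(self.n_rows) + 0.5) * s
        return np.meshgrid(xs, ys)

    def covers(self, xmin: float, ymin: float, xmax: float, ymax: float) -> bool:
        gx0, gy0, gx1, gy1 = self.extent
        return gx0 <= xmin and gy0 <= ymin and xmax <= gx1 and ymax <= gy1


def resample_to_grid(
    values: np.ndarray,
    source: PixelGrid,
    target: PixelGrid,
    method: str = "nearest",
) -> np.ndarray:
    """Resample ``values`` from ``source`` onto ``target`` pixel centres.

    ``nearest`` replicates the enclosing coarse cell (appropriate for
    class-like soil layers); ``bilinear`` interpolates between coarse cell
    centres and reproduces linear fields exactly.
    """
    from scipy.ndimage import map_coordinates

    values = np.asarray(values, dtype=float)
    if values.shape != source.shape:
        raise ValueError("values shape does not match source grid")
    X, Y = target.centers()
    # fractional source pixel coordinates of the target centres
    col = (X - source.x0) / source.pixel_size - 0.5
    row = (Y - source.y0) / source.pixel_size - 0.5
    if method == "nearest":
        i = np.clip(np.rint(row).astype(int), 0, source.n_rows - 1)
        j = np.clip(np.rint(col).astype(int), 0, source.n_cols - 1)
        return values[i, j]
    if method == "bilinear":
        coords = np.stack([row.ravel(), col.ravel()])
        out = map_coordinates(values, coords, order=1, mode="nearest")
        return out.reshape(target.shape)
    raise ValueError(f"unknown resampling method: {method!r}")


def write_ascii_grid(path: str | Path, values: np.ndarray, grid: PixelGrid) -> None:
    """Write a raster as an ESRI ASCII grid (text). NaN -> NODATA."""
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError("raster shape does not match grid")
    out = np.where(np.isfinite(values), values, NODATA)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.x0!r}\n"
        f"yllcorner {grid.y0!r}\n"
        f"cellsize {grid.pixel_size!r}\n"
        f"NODATA_value {NODATA!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # ESRI convention: first data row is the northernmost
        for row in out[::-1]:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, PixelGrid]:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    path = Path(path)
    meta: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if parts[0][0].isalpha() or parts[0][0] == "N":
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: malformed header line")
                meta[parts[0].lower()] = float(parts[1])
            else:
                try:
                    rows.append([float(v) for v in parts])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed data row") from exc
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    missing = required - meta.keys()
    if missing:
        raise ValueError(f"{path}: missing header keys {sorted(missing)}")
    grid = PixelGrid(
        x0=meta["xllcorner"],
        y0=meta["yllcorner"],
        pixel_size=meta["cellsize"],
        n_rows=int(meta["nrows"]),
        n_cols=int(meta["ncols"]),
    )
    data = np.asarray(rows, dtype=float)
    if data.shape != grid.shape:
        raise ValueError(f"{path}: data shape {data.shape} != header shape {grid.shape}")
    nodata = meta.get("nodata_value", NODATA)
    data = data[::-1]  # back to row 0 = south
    data[data == nodata] = np.nan
    return data, grid
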