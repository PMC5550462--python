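"""Regular equal-area grids and plain-text raster I/O.

All spatial layers live on a shared square-cell grid on an equal-area plane
(kilometre units). Row 0 is the southernmost row; the grid origin is the
lower-left corner of cell (0, 0). Rasters are serialized as ESRI ASCII grids,
which keeps every layer inspectable and diff-able.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np

# Ecosystem-class codes (one class per cell, exhaustive partition).
ECO_LAND_FRESH = 0
ECO_MARINE_SHELF = 1
ECO_MARINE_DEEP = 2
ECOSYSTEM_LABELS = {
    ECO_LAND_FRESH: "land-freshwater",
    ECO_MARINE_SHELF: "marine-shelf",
    ECO_MARINE_DEEP: "marine-deep",
}

# Protected-area class codes.
PA_NONE = 0
PA_STRICT = 1  # IUCN categories I-IV
PA_OTHER = 2  # IUCN V+ / uncategorized
PA_LABELS = {PA_NONE: "unprotected", PA_STRICT: "PA-I-IV", PA_OTHER: "PA-V+"}

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular grid of square cells.

    ``origin`` is the (x, y) of the lower-left corner of the lower-left cell,
    in km on the equal-area plane. Cell (row i, col j) has its center at
    ``origin + ((j + 0.5), (i + 0.5)) * cell_size_km``.
    """

    n_rows: int
    n_cols: int
    cell_size_km: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size_km**2

    @property
    def extent_km(self) -> tuple[float, float]:
        """(width, height) of the grid in km."""
        return (self.n_cols * self.cell_size_km, self.n_rows * self.cell_size_km)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinate arrays, each shaped (n_rows, n_cols)."""
        x = self.origin[0] + (np.arange(self.n_cols) + 0.5) * self.cell_size_km
        y = self.origin[1] + (np.arange(self.n_rows) + 0.5) * self.cell_size_km
        return np.meshgrid(x, y)

    def contains(self, x: float, y: float) -> bool:
        w, h = self.extent_km
        return (
            self.origin[0] <= x <= self.origin[0] + w
            and self.origin[1] <= y <= self.origin[1] + h
        )

    def distance_from(self, x: float, y: float) -> np.ndarray:
        """Euclidean distance (km) from (x, y) to every cell center."""
        cx, cy = self.cell_centers()
        return np.hypot(cx - x, cy - y)


def write_ascii_grid(path: str | Path, field: np.ndarray, spec: GridSpec) -> None:
    """Write a 2-D field as an ESRI ASCII grid.

    Row 0 of ``field`` is the southernmost row; the ASCII format stores rows
    north-to-south, so the array is flipped on output.
    """
    field = np.asarray(field)
    if field.shape != spec.shape:
        raise ValueError(f"field shape {field.shape} != grid shape {spec.shape}")
    buf = io.StringIO()
    buf.write(f"ncols {spec.n_cols}\n")
    buf.write(f"nrows {spec.n_rows}\n")
    buf.write(f"xllcorner {spec.origin[0]!r}\n")
    buf.write(f"yllcorner {spec.origin[1]!r}\n")
    buf.write(f"cellsize {spec.cell_size_km!r}\n")
    buf.write(f"NODATA_value {NODATA!r}\n")
    out = np.flipud(field)
    fmt = "%d" if np.issubdtype(field.dtype, np.integer) else "%.10g"
    np.savetxt(buf, out, fmt=fmt)
    Path(path).write_text(buf.getvalue())


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid, returning (field, GridSpec).

    The returned field has row 0 as the southernmost row.
    """
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    for line in lines[:6]:
        key, val = line.split()
        header[key.lower()] = float(val)
    spec = GridSpec(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        cell_size_km=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
    )
    data = np.loadtxt(io.StringIO("\n".join(lines[6:])))
    data = np.atleast_2d(data)
    if data.shape != spec.shape:
        raise ValueError(f"data shape {data.shape} != declared {spec.shape}")
    field = np.flipud(data)
    if np.allclose(field, np.round(field)) and np.abs(field).max() < 2**31:
        as_int = field.astype(np.int64)
        if np.array_equal(as_int.astype(float), field):
            return as_int, spec
    return field, spec
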