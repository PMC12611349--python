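"""The 1-degree analysis lattice over the Indo-Pacific Convergence Zone.

The study region spans 18°S–25°N and 90°E–165°E. At the default 1°
resolution this yields a 43 × 75 lattice of 3225 cells, each covering a
nominal 12,321 km² under the planar 111 km/degree approximation used
throughout (no equal-area projection; the box is far from the antimeridian,
so no longitude wraparound is needed).

Cells are half-open intervals [x, x+res) on latitude and longitude, except
the outermost row and column, which are closed so that the lattice is an
exact partition of the study box: every in-bounds point belongs to exactly
one cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

KM_PER_DEGREE = 111.0

#: Study-region bounding box (degrees): 18°S–25°N, 90°E–165°E.
DEFAULT_BOUNDS = (-18.0, 25.0, 90.0, 165.0)


@dataclass(frozen=True)
class GridSpec:
    """Rectangular lattice specification.

    Parameters
    ----------
    lat_min, lat_max, lon_min, lon_max
        Study-box edges in decimal degrees.
    resolution
        Cell size in degrees; the box extents must be integer multiples.
    """

    lat_min: float = DEFAULT_BOUNDS[0]
    lat_max: float = DEFAULT_BOUNDS[1]
    lon_min: float = DEFAULT_BOUNDS[2]
    lon_max: float = DEFAULT_BOUNDS[3]
    resolution: float = 1.0

    def __post_init__(self) -> None:
        if not (self.lat_max > self.lat_min and self.lon_max > self.lon_min):
            raise ValueError("empty study box")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        for extent in (self.lat_max - self.lat_min, self.lon_max - self.lon_min):
            ratio = extent / self.resolution
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError(
                    f"extent {extent}° is not an integer multiple of the "
                    f"{self.resolution}° resolution"
                )

    @property
    def n_rows(self) -> int:
        return round((self.lat_max - self.lat_min) / self.resolution)

    @property
    def n_cols(self) -> int:
        return round((self.lon_max - self.lon_min) / self.resolution)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area_km2(self) -> float:
        """Nominal full-cell area under the 111 km/degree approximation."""
        return (self.resolution * KM_PER_DEGREE) ** 2

    # -- cell addressing ----------------------------------------------------

    def cell_id(self, row: int, col: int) -> int:
        """Flat 0-based id, row-major from the south-west corner."""
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"cell ({row}, {col}) outside the lattice")
        return row * self.n_cols + col

    def rowcol(self, cell_id: int) -> tuple[int, int]:
        if not 0 <= cell_id < self.n_cells:
            raise ValueError(f"cell id {cell_id} outside the lattice")
        return divmod(cell_id, self.n_cols)

    def cell_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        """(lat_min, lat_max, lon_min, lon_max) of one cell box."""
        la = self.lat_min + row * self.resolution
        lo = self.lon_min + col * self.resolution
        return la, la + self.resolution, lo, lo + self.resolution


def assign_cell(lat: float, lon: float, spec: GridSpec) -> tuple[int, int] | None:
    """Map a point to its (row, col) cell, or None if outside the study box.

    Points exactly on the north or east outer boundary fall into the
    outermost (closed-edge) row/column.
    """
    if not (np.isfinite(lat) and np.isfinite(lon)):
        return None
    if not (spec.lat_min <= lat <= spec.lat_max and spec.lon_min <= lon <= spec.lon_max):
        return None
    row = min(int((lat - spec.lat_min) / spec.resolution), spec.n_rows - 1)
    col = min(int((lon - spec.lon_min) / spec.resolution), spec.n_cols - 1)
    return row, col


def assign_cells(
    lat: np.ndarray, lon: np.ndarray, spec: GridSpec
) -> np.ndarray:
    """Vectorized cell assignment: flat cell ids, -1 for out-of-bounds points."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    inside = (
        np.isfinite(lat)
        & np.isfinite(lon)
        & (lat >= spec.lat_min)
        & (lat <= spec.lat_max)
        & (lon >= spec.lon_min)
        & (lon <= spec.lon_max)
    )
    row = np.floor((lat - spec.lat_min) / spec.resolution).astype(int)
    col = np.floor((lon - spec.lon_min) / spec.resolution).astype(int)
    np.clip(row, 0, spec.n_rows - 1, out=row)
    np.clip(col, 0, spec.n_cols - 1, out=col)
    ids = row * spec.n_cols + col
    return np.where(inside, ids, -1)


def cell_neighbors(
    cell: tuple[int, int], spec: GridSpec, scheme: str = "queen"
) -> set[tuple[int, int]]:
    """In-bounds lattice neighbors of a cell, focal cell excluded.

    ``queen`` returns up to 8 neighbors (edge + corner contiguity), ``rook``
    up to 4 (edge contiguity only). There is no wraparound.
    """
    if scheme not in ("queen", "rook"):
        raise ValueError(f"unknown contiguity scheme {scheme!r}")
    row, col = cell
    if not (0 <= row < spec.n_rows and 0 <= col < spec.n_cols):
        raise ValueError(f"cell {cell} outside the lattice")
    out: set[tuple[int, int]] = set()
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            if scheme == "rook" and dr != 0 and dc != 0:
                continue
            r, c = row + dr, col + dc
            if 0 <= r < spec.n_rows and 0 <= c < spec.n_cols:
                out.add((r, c))
    return out


def grid_table(spec: GridSpec) -> pd.DataFrame:
    """The full lattice as a table: one row per cell with its bounding box."""
    rows, cols = np.divmod(np.arange(spec.n_cells), spec.n_cols)
    lat0 = spec.lat_min + rows * spec.resolution
    lon0 = spec.lon_min + cols * spec.resolution
    return pd.DataFrame(
        {
            "cell_id": np.arange(spec.n_cells),
            "row": rows,
            "col": cols,
            "lat_min": lat0,
            "lat_max": lat0 + spec.resolution,
            "lon_min": lon0,
            "lon_max": lon0 + spec.resolution,
        }
    )


def grid_geojson(spec: GridSpec) -> dict:
    """The lattice as a GeoJSON FeatureCollection of cell polygons (WGS84)."""
    features = []
    for row in range(spec.n_rows):
        for col in range(spec.n_cols):
            la0, la1, lo0, lo1 = spec.cell_bounds(row, col)
            features.append(
                {
                    "type": "Feature",
                    "properties": {"cell_id": spec.cell_id(row, col), "row": row, "col": col},
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [
                            [[lo0, la0], [lo1, la0], [lo1, la1], [lo0, la1], [lo0, la0]]
                        ],
                    },
                }
            )
    return {"type": "FeatureCollection", "features": features}
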