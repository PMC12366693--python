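"""Georeferenced simulation lattice, coordinate conversions, zones and sampling schemes.

The simulation world is a lattice of square cells (demes) of 100 x 100 km in
the WGS84 Plate Carree (equirectangular) projection, in which one degree of
longitude or latitude maps to a constant ``pi/180 * 6378137`` metres.  Each
cell carries a land/water flag and belongs to one of two competition/admixture
zones split at latitude 43.2 degrees N ("southeast" vs "northwest" continental
route).

Sampling schemes list the paleogenomic population samples to reproduce: a deme
position (Plate Carree metres), a population layer (HG = hunter-gatherers,
FA = farmers), a sample size in individuals and a mean age in years before
present, which is converted to a simulation generation index assuming
25-year generations and a configurable simulation start (default 40,000 BP).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

#: metres per degree in the WGS84 Plate Carree projection
METERS_PER_DEGREE = math.pi / 180.0 * 6_378_137.0

#: latitude separating the "northwest" from the "southeast" continental route
ZONE_BOUNDARY_LATITUDE = 43.2

#: default simulation clock
DEFAULT_START_BP = 40_000
GENERATION_YEARS = 25
DEFAULT_GENERATIONS = 1600


class InvalidCoordinateError(ValueError):
    """Coordinate outside the valid domain (e.g. |lat| > 90)."""


class OutOfBoundsError(ValueError):
    """Point falls outside the world grid."""


class SchemeError(ValueError):
    """Malformed or inconsistent sampling scheme."""


def platecarree_from_lonlat(lon: float, lat: float) -> tuple[float, float]:
    """Project geographic degrees to Plate Carree metres (x = E, y = N)."""
    lat_arr = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat_arr) > 90.0):
        raise InvalidCoordinateError(f"latitude out of range [-90, 90]: {lat}")
    return lon * METERS_PER_DEGREE, lat * METERS_PER_DEGREE


def lonlat_from_platecarree(x: float, y: float) -> tuple[float, float]:
    """Inverse of :func:`platecarree_from_lonlat`; round-trips to < 1e-9 deg."""
    lat = y / METERS_PER_DEGREE
    lat_arr = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat_arr) > 90.0):
        raise InvalidCoordinateError(f"y does not correspond to a valid latitude: {y}")
    return x / METERS_PER_DEGREE, lat


def generation_from_age(
    age_bp: float,
    start_bp: float = DEFAULT_START_BP,
    gen_years: float = GENERATION_YEARS,
) -> int:
    """Generations elapsed from the simulation start to an age in yr BP.

    Half-up rounding, e.g. (40000 - 5368)/25 = 1385.28 -> 1385.
    """
    if age_bp < 0 or age_bp > start_bp:
        raise InvalidCoordinateError(
            f"age {age_bp} yr BP outside [0, start={start_bp}]"
        )
    return int(math.floor((start_bp - age_bp) / gen_years + 0.5))


class Deme(NamedTuple):
    """A located cell: flat index, row/col and land flag."""

    index: int
    row: int
    col: int
    is_land: bool


@dataclass
class WorldGrid:
    """Lattice of square demes with Plate Carree georeferencing.

    ``origin`` is the (x, y) of the grid's lower-left (south-west) corner in
    metres; ``land_mask`` has shape (n_rows, n_cols) with row 0 the
    southernmost row.  Cells are half-open ``[edge, edge + cell_size)``
    intervals on both axes, so every in-bounds point belongs to exactly one
    cell.
    """

    n_cols: int = 75
    n_rows: int = 47
    cell_size: float = 100_000.0
    origin: tuple[float, float] = (
        -10.0 * METERS_PER_DEGREE,
        30.0 * METERS_PER_DEGREE,
    )
    land_mask: np.ndarray | None = None
    zone_boundary_latitude: float = ZONE_BOUNDARY_LATITUDE

    def __post_init__(self) -> None:
        if self.land_mask is None:
            self.land_mask = np.ones((self.n_rows, self.n_cols), dtype=bool)
        self.land_mask = np.asarray(self.land_mask, dtype=bool)
        if self.land_mask.shape != (self.n_rows, self.n_cols):
            raise ValueError(
                f"land_mask shape {self.land_mask.shape} != "
                f"({self.n_rows}, {self.n_cols})"
            )

    # -- indexing ---------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def land_flat(self) -> np.ndarray:
        """Flattened land mask indexed by deme index (row-major, row 0 south)."""
        if not hasattr(self, "_land_flat"):
            self._land_flat = self.land_mask.reshape(-1)
        return self._land_flat

    def index_of(self, row: int, col: int) -> int:
        return row * self.n_cols + col

    def rowcol_of(self, index: int) -> tuple[int, int]:
        return divmod(int(index), self.n_cols)

    def locate(self, x: float, y: float) -> Deme:
        """Cell containing (x, y); half-open cells, error if out of bounds."""
        col = math.floor((x - self.origin[0]) / self.cell_size)
        row = math.floor((y - self.origin[1]) / self.cell_size)
        if not (0 <= col < self.n_cols and 0 <= row < self.n_rows):
            raise OutOfBoundsError(f"point ({x}, {y}) outside grid")
        idx = self.index_of(row, col)
        return Deme(idx, row, col, bool(self.land_flat[idx]))

    def deme_of(self, x: float, y: float) -> int:
        return self.locate(x, y).index

    def cell_center(self, index: int) -> tuple[float, float]:
        row, col = self.rowcol_of(index)
        return (
            self.origin[0] + (col + 0.5) * self.cell_size,
            self.origin[1] + (row + 0.5) * self.cell_size,
        )

    def cell_center_latitude(self, index: int) -> float:
        return self.cell_center(index)[1] / METERS_PER_DEGREE

    def zone_of(self, index: int) -> str:
        """'north' iff the cell-center latitude is strictly above 43.2 deg."""
        lat = self.cell_center_latitude(index)
        return "north" if lat > self.zone_boundary_latitude else "south"

    def row_latitudes(self) -> np.ndarray:
        rows = np.arange(self.n_rows)
        return (self.origin[1] + (rows + 0.5) * self.cell_size) / METERS_PER_DEGREE

    def north_mask_flat(self) -> np.ndarray:
        """Boolean per-cell flag: cell center strictly north of the boundary."""
        north_rows = self.row_latitudes() > self.zone_boundary_latitude
        return np.repeat(north_rows, self.n_cols)

    def neighbors(self, index: int) -> list[int]:
        """Orthogonal in-grid neighbours (stepping-stone adjacency)."""
        row, col = self.rowcol_of(index)
        out = []
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            r, c = row + dr, col + dc
            if 0 <= r < self.n_rows and 0 <= c < self.n_cols:
                out.append(self.index_of(r, c))
        return out


def default_world() -> WorldGrid:
    """The 75 x 47 all-land default world spanning roughly 10W-57E / 30N-72N.

    The published analysis used a western-Eurasia coastline raster that is not
    redistributed; the default world keeps its grid geometry and georeference
    with an all-land mask so that every study deme maps onto a valid cell.
    """
    return WorldGrid()


# -- Esri ASCII raster I/O ------------------------------------------------

def load_world(path: str | Path, water_values: Sequence[float] = (0,)) -> WorldGrid:
    """Read an Esri ASCII grid; NODATA and ``water_values`` cells are water."""
    path = Path(path)
    header: dict[str, float] = {}
    lines = path.read_text().splitlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise SchemeError(f"malformed Esri ASCII header: missing {key}")
    nodata = header.get("nodata_value", -9999.0)
    n_cols, n_rows = int(header["ncols"]), int(header["nrows"])
    values = np.array(" ".join(lines[i:]).split(), dtype=float)
    if values.size != n_cols * n_rows:
        raise SchemeError(
            f"raster body has {values.size} values, expected {n_cols * n_rows}"
        )
    grid = values.reshape(n_rows, n_cols)[::-1]  # Esri rows run north->south
    land = (grid != nodata)
    for wv in water_values:
        land &= grid != wv
    return WorldGrid(
        n_cols=n_cols,
        n_rows=n_rows,
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        land_mask=land,
    )


def save_world(world: WorldGrid, path: str | Path) -> None:
    """Write a WorldGrid as an Esri ASCII grid (land=1, water=0)."""
    path = Path(path)
    body = world.land_mask[::-1].astype(int)
    lines = [
        f"ncols {world.n_cols}",
        f"nrows {world.n_rows}",
        f"xllcorner {world.origin[0]:.6f}",
        f"yllcorner {world.origin[1]:.6f}",
        f"cellsize {world.cell_size:.6f}",
        "NODATA_value -9999",
    ]
    lines += [" ".join(str(v) for v in row) for row in body]
    path.write_text("\n".join(lines) + "\n")


# -- sampling schemes -----------------------------------------------------

@dataclass(frozen=True)
class SampleSpec:
    """One population sample: who, where, when, how many individuals."""

    label: str
    layer: str  # 'HG' or 'FA'
    x: float
    y: float
    n_individuals: int
    mean_age: float
    generation: int

    def __post_init__(self) -> None:
        if self.layer not in ("HG", "FA"):
            raise SchemeError(f"layer must be HG or FA, got {self.layer!r}")
        if self.n_individuals < 1:
            raise SchemeError(f"sample {self.label}: n_individuals < 1")


@dataclass
class SamplingScheme:
    """An ordered collection of population samples plus the simulation clock."""

    samples: list[SampleSpec] = field(default_factory=list)
    start_bp: float = DEFAULT_START_BP
    generations_total: int = DEFAULT_GENERATIONS

    def __post_init__(self) -> None:
        labels = [s.label for s in self.samples]
        if len(set(labels)) != len(labels):
            raise SchemeError("duplicate sample labels")
        for s in self.samples:
            if not (0 <= s.generation < self.generations_total):
                raise SchemeError(
                    f"sample {s.label}: generation {s.generation} outside "
                    f"[0, {self.generations_total})"
                )

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def n_genomes(self) -> int:
        return sum(s.n_individuals for s in self.samples)

    def demes(self, world: WorldGrid) -> list[int]:
        """Deme index per sample; every sample must fall on land."""
        out = []
        for s in self.samples:
            deme = world.locate(s.x, s.y)
            if not deme.is_land:
                raise SchemeError(f"sample {s.label} falls on a water cell")
            out.append(deme.index)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [s.label for s in self.samples],
                "layer": [s.layer for s in self.samples],
                "x": [s.x for s in self.samples],
                "y": [s.y for s in self.samples],
                "n": [s.n_individuals for s in self.samples],
                "mean_age": [s.mean_age for s in self.samples],
                "generation": [s.generation for s in self.samples],
            }
        )


def load_sampling_scheme(
    path_or_frame: str | Path | pd.DataFrame,
    start_bp: float = DEFAULT_START_BP,
    generations_total: int = DEFAULT_GENERATIONS,
    gen_years: float = GENERATION_YEARS,
) -> SamplingScheme:
    """Load a sampling scheme from CSV (columns label, layer, x, y, n, mean_age)."""
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame
    else:
        df = pd.read_csv(path_or_frame)
    required = {"label", "layer", "x", "y", "n", "mean_age"}
    missing = required - set(df.columns)
    if missing:
        raise SchemeError(f"sampling scheme missing columns: {sorted(missing)}")
    samples = [
        SampleSpec(
            label=str(r.label),
            layer=str(r.layer),
            x=float(r.x),
            y=float(r.y),
            n_individuals=int(r.n),
            mean_age=float(r.mean_age),
            generation=generation_from_age(float(r.mean_age), start_bp, gen_years),
        )
        for r in df.itertuples(index=False)
    ]
    return SamplingScheme(samples, start_bp=start_bp, generations_total=generations_total)
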