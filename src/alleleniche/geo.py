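"""Raster stacks, occurrence tables, spatial thinning and value extraction.

Conventions used throughout the package (stated once, here):

* Coordinates are WGS84 decimal degrees; great-circle distances use the
  haversine formula on a sphere of radius 6371 km.
* Grids are cell-centre registered with row 0 at the north edge.
* Point-in-cell containment uses half-open intervals ``[west, east) x
  [south, north)``: a point on a cell's east or north edge belongs to the
  neighbouring cell.
* Rasters are read and written as ESRI ASCII grids (the ``ncols/nrows/
  xllcorner/yllcorner/cellsize/NODATA_value`` header followed by rows of
  values, north row first).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0
DEFAULT_NODATA = -9999.0

__all__ = [
    "ClimateStack",
    "OccurrenceSet",
    "GeometryError",
    "haversine_km",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_raster_stack",
    "read_occurrences",
    "thin_occurrences",
    "extract_values",
    "sample_background",
]


class GeometryError(ValueError):
    """Raised when raster geometries disagree or points fall off-grid/off-mask."""


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

def read_ascii_grid(path):
    """Read an ESRI ASCII grid. Returns ``(values, header)``.

    ``values`` is a float array with NoData replaced by NaN; ``header`` is a
    dict with keys ncols, nrows, xllcorner, yllcorner, cellsize, nodata_value.
    """
    path = Path(path)
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines[:6]:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            key = parts[0].lower()
            header[key] = float(parts[1])
            n_header += 1
        else:
            break
    if "ncols" not in header or "nrows" not in header:
        raise GeometryError(f"{path}: not an ESRI ASCII grid (missing ncols/nrows header)")
    header.setdefault("nodata_value", DEFAULT_NODATA)
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    values = np.loadtxt(lines[n_header:], dtype=float)
    values = values.reshape(nrows, ncols)
    nodata = header["nodata_value"]
    values = np.where(values == nodata, np.nan, values)
    header["ncols"], header["nrows"] = ncols, nrows
    return values, header


def write_ascii_grid(path, values, xllcorner, yllcorner, cellsize, nodata=DEFAULT_NODATA):
    """Write a 2-D array (row 0 = north) as an ESRI ASCII grid; NaN -> NoData."""
    values = np.asarray(values, dtype=float)
    nrows, ncols = values.shape
    out = np.where(np.isnan(values), nodata, values)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {float(xllcorner)!r}\n")
        fh.write(f"yllcorner {float(yllcorner)!r}\n")
        fh.write(f"cellsize {float(cellsize)!r}\n")
        fh.write(f"NODATA_value {float(nodata)!r}\n")
        for row in out:
            # repr of a Python float is the shortest exact round-trip form
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# ClimateStack
# ---------------------------------------------------------------------------

@dataclass
class ClimateStack:
    """Co-registered stack of named climate layers on a shared grid.

    ``data`` has shape ``(n_layers, nrows, ncols)`` with NaN at NoData cells.
    ``mask`` marks study-area cells that are NoData-free in every layer.
    """

    names: list[str]
    data: np.ndarray
    xllcorner: float
    yllcorner: float
    cellsize: float
    mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 + 1:
            raise GeometryError("data must be (n_layers, nrows, ncols)")
        if len(self.names) != self.data.shape[0]:
            raise GeometryError("one name per layer required")
        valid = ~np.any(np.isnan(self.data), axis=0)
        if self.mask is None:
            self.mask = valid
        else:
            self.mask = np.asarray(self.mask, dtype=bool) & valid
        # layers must be NoData-free on the mask by construction
        self.data[:, ~self.mask] = np.nan

    # -- geometry ----------------------------------------------------------
    @property
    def nrows(self):
        return self.data.shape[1]

    @property
    def ncols(self):
        return self.data.shape[2]

    @property
    def n_layers(self):
        return self.data.shape[0]

    @property
    def yurcorner(self):
        return self.yllcorner + self.nrows * self.cellsize

    def lon_centers(self):
        return self.xllcorner + (np.arange(self.ncols) + 0.5) * self.cellsize

    def lat_centers(self):
        """Latitudes of cell centres, row 0 (north) first."""
        return self.yurcorner - (np.arange(self.nrows) + 0.5) * self.cellsize

    def cell_of(self, lon, lat):
        """Row/col of the cell containing (lon, lat); half-open [west,east) x [south,north)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.xllcorner) / self.cellsize).astype(int)
        row_s = np.floor((lat - self.yllcorner) / self.cellsize).astype(int)
        row = self.nrows - 1 - row_s
        inside = (col >= 0) & (col < self.ncols) & (row >= 0) & (row < self.nrows)
        return row, col, inside

    def cell_center(self, row, col):
        lon = self.xllcorner + (np.asarray(col) + 0.5) * self.cellsize
        lat = self.yurcorner - (np.asarray(row) + 0.5) * self.cellsize
        return lon, lat

    def same_grid(self, other: "ClimateStack"):
        return (
            self.data.shape[1:] == other.data.shape[1:]
            and math.isclose(self.xllcorner, other.xllcorner, abs_tol=1e-9)
            and math.isclose(self.yllcorner, other.yllcorner, abs_tol=1e-9)
            and math.isclose(self.cellsize, other.cellsize, rel_tol=1e-12)
        )

    # -- values ------------------------------------------------------------
    @property
    def n_unmasked(self):
        return int(self.mask.sum())

    def mask_indices(self):
        """(row, col) arrays of unmasked cells in row-major order."""
        return np.nonzero(self.mask)

    def values_table(self):
        """DataFrame of layer values over unmasked cells (one row per cell)."""
        rows, cols = self.mask_indices()
        return pd.DataFrame(
            {name: self.data[k, rows, cols] for k, name in enumerate(self.names)}
        )

    def layer(self, name):
        try:
            k = self.names.index(name)
        except ValueError:
            raise KeyError(f"no layer named {name!r}; have {self.names}") from None
        return self.data[k]

    def subset(self, names: Sequence[str]):
        """New stack restricted to the given layers (same grid and mask)."""
        data = np.stack([self.layer(n) for n in names])
        return ClimateStack(list(names), data, self.xllcorner, self.yllcorner, self.cellsize, self.mask.copy())

    def shifted(self, shifts: dict):
        """New stack with per-variable additive shifts (a simple 'future' scenario)."""
        data = self.data.copy()
        for name, delta in shifts.items():
            data[self.names.index(name)] += delta
        return ClimateStack(list(self.names), data, self.xllcorner, self.yllcorner, self.cellsize, self.mask.copy())

    # -- I/O -----------------------------------------------------------------
    def write(self, directory):
        """Write one ASCII grid per layer, named ``<layer>.asc``. Returns paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for k, name in enumerate(self.names):
            p = directory / f"{name}.asc"
            write_ascii_grid(p, self.data[k], self.xllcorner, self.yllcorner, self.cellsize)
            paths.append(p)
        return paths


def read_raster_stack(paths: Sequence, variable_names: Sequence[str] | None = None) -> ClimateStack:
    """Read co-registered ESRI ASCII grids into a ClimateStack.

    The mask is the intersection of non-NoData cells across layers. Raises
    :class:`GeometryError` naming the offending file on any geometry mismatch.
    """
    paths = [Path(p) for p in paths]
    if variable_names is None:
        variable_names = [p.stem for p in paths]
    if len(variable_names) != len(paths):
        raise ValueError("variable_names must match paths")
    layers = []
    ref_header = None
    for p in paths:
        values, header = read_ascii_grid(p)
        if ref_header is None:
            ref_header = header
        else:
            for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
                if not math.isclose(header[key], ref_header[key], rel_tol=1e-12, abs_tol=1e-9):
                    raise GeometryError(
                        f"{p}: {key}={header[key]} does not match first layer ({ref_header[key]})"
                    )
        layers.append(values)
    data = np.stack(layers)
    return ClimateStack(
        list(variable_names), data,
        ref_header["xllcorner"], ref_header["yllcorner"], ref_header["cellsize"],
    )


# ---------------------------------------------------------------------------
# Occurrences
# ---------------------------------------------------------------------------

@dataclass
class OccurrenceSet:
    """Typed allele presence records (longitude, latitude, allele label)."""

    table: pd.DataFrame
    provenance: str = ""

    COLUMNS = ("longitude", "latitude", "allele")

    def __post_init__(self):
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"occurrence table missing columns {missing}")
        t = self.table.reset_index(drop=True)
        if (t["latitude"].abs() > 90).any() or (t["longitude"].abs() > 180).any():
            raise ValueError("coordinates out of WGS84 range")
        if t.duplicated(subset=list(self.COLUMNS)).any():
            dup = t[t.duplicated(subset=list(self.COLUMNS), keep=False)]
            raise ValueError(f"duplicate records (same coordinates and allele):\n{dup}")
        self.table = t

    def __len__(self):
        return len(self.table)

    @property
    def alleles(self):
        return sorted(self.table["allele"].unique())

    def counts(self) -> dict:
        """Records per allele label."""
        return self.table["allele"].value_counts().to_dict()

    @property
    def n_sites(self):
        """Distinct coordinates (a dual-type site counts once)."""
        return len(self.table[["longitude", "latitude"]].drop_duplicates())

    def for_allele(self, allele) -> "OccurrenceSet":
        sub = self.table[self.table["allele"] == allele]
        if sub.empty:
            raise ValueError(f"no records for allele {allele!r}")
        return OccurrenceSet(sub.copy(), provenance=f"{self.provenance}|allele={allele}")

    def coords(self):
        return self.table["longitude"].to_numpy(), self.table["latitude"].to_numpy()

    def write(self, path, sep=","):
        self.table.to_csv(path, sep=sep, index=False)

    @classmethod
    def concat(cls, sets: Iterable["OccurrenceSet"], provenance=""):
        return cls(pd.concat([s.table for s in sets], ignore_index=True), provenance=provenance)


def read_occurrences(path, sep=None, provenance=None) -> OccurrenceSet:
    """Read a headered delimited occurrence table (longitude, latitude, allele)."""
    table = pd.read_csv(path, sep=sep, engine="python")
    table.columns = [c.strip().lower() for c in table.columns]
    return OccurrenceSet(table, provenance=provenance or str(path))


def thin_occurrences(occ: OccurrenceSet, min_distance_km: float) -> OccurrenceSet:
    """Greedy spatial thinning, per allele.

    Records are processed in input order; a record is kept iff it lies at
    least ``min_distance_km`` (great-circle, inclusive) from every already
    kept record of the same allele. A site shared by two alleles is thinned
    independently for each, so dual-type sites survive.
    """
    if min_distance_km < 0:
        raise ValueError("min_distance_km must be >= 0")
    if min_distance_km == 0 or len(occ) == 0:
        return occ
    keep_rows = []
    kept_by_allele: dict = {}
    for idx, rec in occ.table.iterrows():
        kept = kept_by_allele.setdefault(rec["allele"], [])
        if kept:
            lons = np.array([r["longitude"] for r in kept])
            lats = np.array([r["latitude"] for r in kept])
            d = haversine_km(rec["longitude"], rec["latitude"], lons, lats)
            # strict '<' rejection makes the >= threshold inclusive
            if np.any(d < min_distance_km - 1e-12):
                continue
        kept.append(rec)
        keep_rows.append(idx)
    return OccurrenceSet(
        occ.table.loc[keep_rows].copy(),
        provenance=f"{occ.provenance}|thinned>={min_distance_km}km",
    )


def extract_values(stack: ClimateStack, occ: OccurrenceSet) -> pd.DataFrame:
    """Climate design matrix at occurrence points (one row per record).

    Every point must fall in an unmasked cell; offending points are listed
    in the raised :class:`GeometryError`.
    """
    lon, lat = occ.coords()
    row, col, inside = stack.cell_of(lon, lat)
    bad = []
    for i in range(len(lon)):
        if not inside[i]:
            bad.append((lon[i], lat[i], "outside grid"))
        elif not stack.mask[row[i], col[i]]:
            bad.append((lon[i], lat[i], "masked/NoData cell"))
    if bad:
        lines = ", ".join(f"({x:.5f}, {y:.5f}): {why}" for x, y, why in bad)
        raise GeometryError(f"{len(bad)} occurrence point(s) unusable: {lines}")
    out = pd.DataFrame(
        {name: stack.data[k, row, col] for k, name in enumerate(stack.names)},
        index=occ.table.index,
    )
    return out


def sample_background(stack: ClimateStack, n: int, seed, layer_names=None):
    """Uniform sample of ``n`` unmasked cells without replacement.

    Returns ``(design_matrix, cell_indices)`` where cell_indices is an array of
    ``(row, col)`` pairs. Deterministic given ``seed``.
    """
    rows, cols = stack.mask_indices()
    n_cells = len(rows)
    if n > n_cells:
        raise ValueError(f"requested {n} background cells but mask has only {n_cells}")
    rng = np.random.default_rng(seed)
    pick = rng.choice(n_cells, size=n, replace=False)
    r, c = rows[pick], cols[pick]
    mat = pd.DataFrame({name: stack.data[k, r, c] for k, name in enumerate(stack.names)})
    if layer_names is not None:
        mat = mat[list(layer_names)]
    return mat, np.column_stack([r, c])
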