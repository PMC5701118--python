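"""Raster overlay machinery for niche-model post-processing.

Continuous habitat-suitability surfaces (one per species) are binarized with
the minimum-training-presence rule, intersected into areas of potential
sympatry, and compared per pixel into a suitability-dominance map.  Occurrence
localities are deduplicated and classified against the sympatry mask and
axis-aligned contact-zone boxes.

Conventions
-----------
* Grids are stored in ESRI ASCII row order: row 0 is the northernmost row.
* Point-in-cell membership uses half-open intervals ``[edge, edge + cell_size)``
  measured from the lower-left grid origin, so a point exactly on a cell's
  lower-left corner belongs to that cell.
* The study extent is small; all geometry is planar (no great-circle terms).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd

__all__ = [
    "SuitabilityGrid",
    "BinaryMap",
    "DominanceMap",
    "ZoneBox",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_localities",
    "write_localities",
    "dedup_localities",
    "threshold_mtp",
    "potential_sympatry",
    "dominance_map",
    "classify_localities",
]

# Dominance codes
DOM_OUTSIDE = -1
DOM_TIE = 0
DOM_A_HIGHER = 1
DOM_B_HIGHER = 2


class GridAlignmentError(ValueError):
    """Raised when rasters with different georeferences are combined."""


class LocalityError(ValueError):
    """Raised for localities that violate a raster precondition."""


@dataclass
class SuitabilityGrid:
    """A georeferenced real-valued suitability lattice.

    ``values`` is an ``(n_rows, n_cols)`` float array in ESRI ASCII row order
    (top row first); nodata cells hold NaN in memory and ``nodata_value`` on
    disk.  Non-nodata values are expected in [0, 1] (logistic-style output).
    """

    values: np.ndarray
    origin_lon: float
    origin_lat: float
    cell_size: float
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("grid values must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("suitability values must lie in [0, 1]")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def georef(self) -> tuple:
        return (self.n_rows, self.n_cols, round(self.origin_lon, 12),
                round(self.origin_lat, 12), round(self.cell_size, 12))

    def same_georef(self, other: "SuitabilityGrid | BinaryMap") -> bool:
        return self.georef() == other.georef()

    def cell_index(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Array (row, col) of the cell containing the point, or None.

        Half-open convention: the cell covers ``[edge, edge + cell_size)``
        in both axes.
        """
        col = int(np.floor((lon - self.origin_lon) / self.cell_size))
        row_from_bottom = int(np.floor((lat - self.origin_lat) / self.cell_size))
        if not (0 <= col < self.n_cols and 0 <= row_from_bottom < self.n_rows):
            return None
        return self.n_rows - 1 - row_from_bottom, col

    def value_at(self, lon: float, lat: float) -> float:
        idx = self.cell_index(lon, lat)
        if idx is None:
            return np.nan
        return float(self.values[idx])

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) center coordinates as two ``(n_rows, n_cols)`` arrays."""
        cols = np.arange(self.n_cols)
        rows_from_bottom = self.n_rows - 1 - np.arange(self.n_rows)
        lon = self.origin_lon + (cols + 0.5) * self.cell_size
        lat = self.origin_lat + (rows_from_bottom + 0.5) * self.cell_size
        return np.broadcast_to(lon, self.values.shape).copy(), \
            np.broadcast_to(lat[:, None], self.values.shape).copy()


@dataclass
class BinaryMap:
    """Thresholded suitability: 1 suitable, 0 unsuitable, -1 nodata."""

    values: np.ndarray
    origin_lon: float
    origin_lat: float
    cell_size: float
    threshold: float = float("nan")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if not np.isin(self.values, (-1, 0, 1)).all():
            raise ValueError("binary map values must be in {-1, 0, 1}")

    n_rows = SuitabilityGrid.n_rows
    n_cols = SuitabilityGrid.n_cols
    georef = SuitabilityGrid.georef
    same_georef = SuitabilityGrid.same_georef
    cell_index = SuitabilityGrid.cell_index

    @property
    def suitable(self) -> np.ndarray:
        return self.values == 1

    def n_suitable(self) -> int:
        return int(self.suitable.sum())


@dataclass
class DominanceMap:
    """Per-pixel winner inside the potential-sympatry mask.

    Codes: 1 species A higher, 2 species B higher, 0 exact tie, -1 outside
    the mask (including nodata).
    """

    values: np.ndarray
    origin_lon: float
    origin_lat: float
    cell_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)

    n_rows = SuitabilityGrid.n_rows
    n_cols = SuitabilityGrid.n_cols
    georef = SuitabilityGrid.georef
    same_georef = SuitabilityGrid.same_georef
    cell_index = SuitabilityGrid.cell_index

    def counts(self) -> dict[str, int]:
        v = self.values
        return {
            "a_higher": int((v == DOM_A_HIGHER).sum()),
            "b_higher": int((v == DOM_B_HIGHER).sum()),
            "tie": int((v == DOM_TIE).sum()),
            "outside": int((v == DOM_OUTSIDE).sum()),
        }


@dataclass(frozen=True)
class ZoneBox:
    """Axis-aligned contact-zone bounding box (half-open on upper edges)."""

    label: str
    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float

    def __post_init__(self) -> None:
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise ValueError(f"zone {self.label!r}: min bounds must be < max bounds")

    def contains(self, lon, lat):
        lon = np.asarray(lon)
        lat = np.asarray(lat)
        return (
            (lon >= self.lon_min) & (lon < self.lon_max)
            & (lat >= self.lat_min) & (lat < self.lat_max)
        )


def _check_disjoint(zones: Sequence[ZoneBox]) -> None:
    for i, a in enumerate(zones):
        for b in zones[i + 1:]:
            if (a.lon_min < b.lon_max and b.lon_min < a.lon_max
                    and a.lat_min < b.lat_max and b.lat_min < a.lat_max):
                raise ValueError(f"zone boxes {a.label!r} and {b.label!r} overlap")


# ---------------------------------------------------------------------------
# ESRI ASCII raster I/O


def read_ascii_grid(source: str | Path | TextIO) -> SuitabilityGrid:
    """Read an ESRI ASCII (.asc) raster into a SuitabilityGrid.

    Header keys ncols/nrows/xllcorner/yllcorner/cellsize are required;
    NODATA_value is optional (default -9999).  Values are row-major, top
    row first; nodata cells become NaN.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    lines = text.splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value"):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"ASCII grid header missing {key!r}")
    nodata = header.get("nodata_value", -9999.0)
    data = np.loadtxt(io.StringIO("\n".join(lines[i:])), ndmin=2)
    data = data.reshape(int(header["nrows"]), int(header["ncols"]))
    values = np.where(data == nodata, np.nan, data)
    return SuitabilityGrid(
        values=values,
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"],
        cell_size=header["cellsize"],
        nodata_value=nodata,
    )


def write_ascii_grid(grid: SuitabilityGrid, sink: str | Path | TextIO) -> None:
    """Write a SuitabilityGrid as ESRI ASCII, echoing the header faithfully."""
    out = io.StringIO()
    out.write(f"ncols {grid.n_cols}\n")
    out.write(f"nrows {grid.n_rows}\n")
    out.write(f"xllcorner {grid.origin_lon!r}\n")
    out.write(f"yllcorner {grid.origin_lat!r}\n")
    out.write(f"cellsize {grid.cell_size!r}\n")
    out.write(f"NODATA_value {grid.nodata_value!r}\n")
    filled = np.where(np.isnan(grid.values), grid.nodata_value, grid.values)
    for row in filled:
        out.write(" ".join(repr(float(v)) for v in row) + "\n")
    if hasattr(sink, "write"):
        sink.write(out.getvalue())
    else:
        Path(sink).write_text(out.getvalue())


# ---------------------------------------------------------------------------
# Locality tables


REQUIRED_COLUMNS = ("species", "lon", "lat")


def read_localities(source: str | Path | TextIO) -> pd.DataFrame:
    """Read a locality CSV; the species,lon,lat header is mandatory."""
    table = pd.read_csv(source)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"locality CSV missing columns: {missing}")
    bad = ~np.isfinite(table["lon"]) | ~np.isfinite(table["lat"])
    if bad.any():
        rows = table.index[bad].tolist()
        raise LocalityError(f"non-finite coordinates at rows {rows}")
    return table


def write_localities(table: pd.DataFrame, sink: str | Path | TextIO) -> None:
    table.to_csv(sink, index=False)


def dedup_localities(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse exact duplicate (species, lon, lat) records.

    Uniqueness is species-scoped: the same point occupied by two species
    yields two records.  First occurrence wins; order is stable.
    """
    bad = ~np.isfinite(table["lon"].to_numpy(dtype=float)) | \
        ~np.isfinite(table["lat"].to_numpy(dtype=float))
    if bad.any():
        raise LocalityError(
            f"non-finite coordinates at rows {table.index[bad].tolist()}")
    return table.drop_duplicates(
        subset=["species", "lon", "lat"], keep="first").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Overlay operations


def threshold_mtp(grid: SuitabilityGrid, training_points: pd.DataFrame) -> BinaryMap:
    """Binarize by the minimum-training-presence rule.

    The threshold is the minimum suitability over cells containing training
    points; cells with value >= threshold (inclusive, so no training point is
    ever omitted from its own prediction) are suitable.  Nodata propagates.
    """
    if len(training_points) == 0:
        raise LocalityError("no training points supplied")
    offending = []
    vals = []
    for row in training_points.itertuples(index=False):
        idx = grid.cell_index(row.lon, row.lat)
        v = np.nan if idx is None else grid.values[idx]
        if not np.isfinite(v):
            offending.append((row.lon, row.lat))
        else:
            vals.append(v)
    if offending:
        raise LocalityError(
            f"training points in nodata or out-of-extent cells: {offending}")
    threshold = float(min(vals))
    out = np.where(np.isnan(grid.values), -1,
                   (grid.values >= threshold).astype(np.int8))
    return BinaryMap(out, grid.origin_lon, grid.origin_lat, grid.cell_size,
                     threshold=threshold)


def potential_sympatry(bin_a: BinaryMap, bin_b: BinaryMap) -> BinaryMap:
    """Intersect two binary maps: suitable iff suitable for both species.

    Nodata in either input is nodata in the result.  Commutative and
    idempotent.
    """
    if not bin_a.same_georef(bin_b):
        raise GridAlignmentError("binary maps have different georeferences")
    nodata = (bin_a.values == -1) | (bin_b.values == -1)
    both = (bin_a.values == 1) & (bin_b.values == 1)
    out = np.where(nodata, -1, both.astype(np.int8))
    return BinaryMap(out, bin_a.origin_lon, bin_a.origin_lat, bin_a.cell_size)


def dominance_map(grid_a: SuitabilityGrid, grid_b: SuitabilityGrid,
                  mask: BinaryMap) -> DominanceMap:
    """Per-pixel suitability winner within the mask-suitable cells.

    Exact floating-point ties get their own category instead of an arbitrary
    assignment.
    """
    if not (grid_a.same_georef(grid_b) and grid_a.same_georef(mask)):
        raise GridAlignmentError("grids and mask have different georeferences")
    out = np.full(grid_a.values.shape, DOM_OUTSIDE, dtype=np.int8)
    inside = mask.suitable
    a, b = grid_a.values, grid_b.values
    out[inside & (a > b)] = DOM_A_HIGHER
    out[inside & (b > a)] = DOM_B_HIGHER
    out[inside & (a == b)] = DOM_TIE
    return DominanceMap(out, grid_a.origin_lon, grid_a.origin_lat,
                        grid_a.cell_size)


def classify_localities(table: pd.DataFrame, mask: BinaryMap,
                        zones: Sequence[ZoneBox]) -> pd.DataFrame:
    """Flag localities by sympatry-mask membership and contact-zone box.

    Adds columns ``in_potential_sympatry`` (bool), ``zone`` (zone label or
    empty), ``in_extent`` (bool).  Out-of-extent records are flagged and a
    warning is emitted; they carry no mask or zone assignment.
    """
    _check_disjoint(list(zones))
    table = table.reset_index(drop=True).copy()
    in_symp = np.zeros(len(table), dtype=bool)
    in_extent = np.ones(len(table), dtype=bool)
    zone = np.array([""] * len(table), dtype=object)
    for i, row in enumerate(table.itertuples(index=False)):
        idx = mask.cell_index(row.lon, row.lat)
        if idx is None:
            in_extent[i] = False
            continue
        in_symp[i] = mask.values[idx] == 1
        for box in zones:
            if box.contains(row.lon, row.lat):
                zone[i] = box.label
                break
    n_out = int((~in_extent).sum())
    if n_out:
        warnings.warn(f"{n_out} localities outside grid extent were excluded "
                      "from counts", stacklevel=2)
    table["in_potential_sympatry"] = in_symp
    table["zone"] = zone
    table["in_extent"] = in_extent
    return table


def sympatry_zone_counts(table: pd.DataFrame, species_a: str, species_b: str,
                         zone_labels: Iterable[str]):
    """Tabulate unique in-sympatry localities: away vs per contact zone.

    Returns ``(a_away, b_away, {zone: (n_a, n_b)})`` computed from a
    classified, deduplicated locality table.  Input order is irrelevant.
    """
    t = dedup_localities(table)
    t = t[t["in_extent"] & t["in_potential_sympatry"]]
    is_a = t["species"] == species_a
    is_b = t["species"] == species_b
    away = t["zone"] == ""
    a_away = int((is_a & away).sum())
    b_away = int((is_b & away).sum())
    per_zone = {}
    for label in zone_labels:
        in_z = t["zone"] == label
        per_zone[label] = (int((is_a & in_z).sum()), int((is_b & in_z).sum()))
    return a_away, b_away, per_zone
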