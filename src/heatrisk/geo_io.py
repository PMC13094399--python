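"""Geospatial and tabular I/O for the heat-risk screening pipeline.

Grids are single-band rasters holding BIO5 (maximum temperature of the
warmest month, °C) and are read/written as ESRI ASCII grids (``.asc``), a
plain-text single-band raster format.  Species ranges are GeoJSON feature
collections carrying ``species_id`` and ``epoch`` attributes; translocation
sites are CSV point records.  Every downstream stage assumes the aligned
data model enforced here: one shape, one affine transform, one CRS and one
shared nodata mask across all layers of a scenario set.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "Affine",
    "ClimateGrid",
    "ScenarioSet",
    "SpeciesRange",
    "SiteRecord",
    "GridFormatError",
    "EmptyGridError",
    "AlignmentError",
    "SchemaError",
    "read_climate_grid",
    "write_climate_grid",
    "assemble_scenarios",
    "read_ranges",
    "write_ranges",
    "read_sites",
    "write_sites",
]

DEFAULT_NODATA = -9999.0
DEFAULT_CRS = "EPSG:4326"


class GridFormatError(ValueError):
    """Raised when a raster file cannot be parsed."""


class EmptyGridError(ValueError):
    """Raised when a grid contains no valid (non-nodata) cell."""


class AlignmentError(ValueError):
    """Raised when grids do not share shape/transform/CRS.

    Misaligned inputs are an error by design: silent resampling would
    change envelope extrema, so layers must be prepared on one grid.
    """


class SchemaError(ValueError):
    """Raised when a vector/tabular file lacks required attributes."""


@dataclass(frozen=True)
class Affine:
    """Affine map from (col, row) pixel space to world coordinates.

    ``x = a*col + b*row + c`` and ``y = d*col + e*row + f`` — the same
    coefficient ordering used by mainstream raster tooling.  Cell values
    are referenced at cell centers; the transform maps the upper-left
    corner of cell (0, 0).
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    @classmethod
    def from_origin(cls, west: float, north: float, xsize: float, ysize: float) -> "Affine":
        """North-up transform with upper-left corner at (west, north)."""
        return cls(xsize, 0.0, west, 0.0, -ysize, north)

    @property
    def determinant(self) -> float:
        return self.a * self.e - self.b * self.d

    def xy(self, row: float, col: float, offset: str = "center") -> tuple[float, float]:
        """World coordinates of a pixel (center by default)."""
        if offset == "center":
            row, col = row + 0.5, col + 0.5
        elif offset != "ul":
            raise ValueError(f"unknown offset {offset!r}")
        x = self.a * col + self.b * row + self.c
        y = self.d * col + self.e * row + self.f
        return x, y

    def rowcol(self, x: float, y: float) -> tuple[int, int]:
        """Integer (row, col) of the cell containing world point (x, y)."""
        det = self.determinant
        if det == 0:
            raise ValueError("transform is singular")
        dx, dy = x - self.c, y - self.f
        col = (self.e * dx - self.b * dy) / det
        row = (self.a * dy - self.d * dx) / det
        return int(math.floor(row)), int(math.floor(col))


@dataclass
class ClimateGrid:
    """One gridded BIO5 layer (°C) with coordinate metadata and nodata mask."""

    values: np.ndarray
    transform: Affine
    crs: str = DEFAULT_CRS
    nodata_mask: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise GridFormatError("grid values must be 2-D")
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise GridFormatError("nodata mask shape differs from values")
        if self.transform.determinant == 0:
            raise GridFormatError("affine transform is not invertible")
        if not np.any(~self.nodata_mask):
            raise EmptyGridError(f"grid {self.label!r} has no valid cell")
        if not np.all(np.isfinite(self.values[~self.nodata_mask])):
            raise GridFormatError("non-finite values outside the nodata mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(xs, ys) world coordinates of every cell center, as 2-D arrays."""
        nrows, ncols = self.shape
        cols, rows = np.meshgrid(np.arange(ncols) + 0.5, np.arange(nrows) + 0.5)
        t = self.transform
        xs = t.a * cols + t.b * rows + t.c
        ys = t.d * cols + t.e * rows + t.f
        return xs, ys

    def bounds(self) -> tuple[float, float, float, float]:
        """(minx, miny, maxx, maxy) of the grid extent."""
        nrows, ncols = self.shape
        corners = [self.transform.xy(r, c, offset="ul")
                   for r in (0, nrows) for c in (0, ncols)]
        xs = [p[0] for p in corners]
        ys = [p[1] for p in corners]
        return min(xs), min(ys), max(xs), max(ys)

    def aligned_with(self, other: "ClimateGrid", atol: float = 1e-9) -> bool:
        if self.shape != other.shape or self.crs != other.crs:
            return False
        t1, t2 = self.transform, other.transform
        return all(
            math.isclose(getattr(t1, k), getattr(t2, k), rel_tol=0.0, abs_tol=atol)
            for k in "abcdef"
        )


@dataclass
class ScenarioSet:
    """Aligned baseline plus labelled future grids sharing one nodata mask."""

    baseline: ClimateGrid
    futures: list[ClimateGrid]
    labels: list[tuple[str, str]] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.futures)


@dataclass
class SpeciesRange:
    """Historical and current range polygons for one species."""

    species_id: str
    historical: BaseGeometry
    current: BaseGeometry

    def __post_init__(self) -> None:
        for epoch in ("historical", "current"):
            geom = getattr(self, epoch)
            if geom.is_empty:
                raise SchemaError(f"{self.species_id}: empty {epoch} polygon")
            if not geom.is_valid:
                setattr(self, epoch, repair_geometry(geom))


@dataclass(frozen=True)
class SiteRecord:
    """A translocation release site treated as a point location."""

    species_id: str
    site_name: str
    lon: float
    lat: float


def repair_geometry(geom: BaseGeometry) -> BaseGeometry:
    """Repair invalid polygons, preserving every positive-area lobe.

    Uses constructive validity repair rather than the zero-buffer trick:
    buffer(0) silently discards odd-winding lobes of self-intersecting
    rings (a bow-tie would lose half its area), whereas the repaired
    geometry here keeps both lobes with positive area.
    """
    if geom.is_valid:
        return geom
    fixed = shapely.make_valid(geom)
    if fixed.geom_type == "GeometryCollection":
        polys = [g for g in fixed.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
        fixed = shapely.unary_union(polys) if polys else fixed
    if fixed.is_empty or not fixed.is_valid:
        raise SchemaError("geometry could not be repaired")
    return fixed


# ---------------------------------------------------------------------------
# Raster I/O — ESRI ASCII grid

def read_climate_grid(
    path: str | Path,
    label: str = "",
    scale: float = 1.0,
    offset: float = 0.0,
) -> ClimateGrid:
    """Read a single-band ESRI ASCII raster into a :class:`ClimateGrid`.

    ``scale``/``offset`` convert stored integers to °C for datasets that
    ship BIO5 as scaled values (e.g. ``scale=0.1`` for °C×10 storage).
    Nodata cells become masked; an adjacent ``.crs`` sidecar, if present,
    supplies the CRS string (default EPSG:4326).
    """
    path = Path(path)
    try:
        text = path.read_text().splitlines()
    except OSError as exc:
        raise GridFormatError(f"cannot read {path}: {exc}") from exc

    header: dict[str, float] = {}
    data_start = 0
    for i, line in enumerate(text):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            data_start = i + 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise GridFormatError(f"{path}: missing header field {key!r}")

    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    try:
        values = np.loadtxt(text[data_start:], dtype=np.float64, ndmin=2)
    except ValueError as exc:
        raise GridFormatError(f"{path}: cannot parse data block: {exc}") from exc
    if values.shape != (nrows, ncols):
        raise GridFormatError(
            f"{path}: data block is {values.shape}, header says {(nrows, ncols)}"
        )

    mask = values == nodata
    values = np.where(mask, np.nan, values * scale + offset)
    if mask.all():
        raise EmptyGridError(f"{path}: every cell is nodata")

    cellsize = header["cellsize"]
    north = header["yllcorner"] + nrows * cellsize
    transform = Affine.from_origin(header["xllcorner"], north, cellsize, cellsize)

    crs_path = path.with_suffix(".crs")
    crs = crs_path.read_text().strip() if crs_path.exists() else DEFAULT_CRS
    return ClimateGrid(values, transform, crs=crs, nodata_mask=mask,
                       label=label or path.stem)


def write_climate_grid(grid: ClimateGrid, path: str | Path,
                       nodata: float = DEFAULT_NODATA) -> Path:
    """Write a grid as an ESRI ASCII raster (lossless for float64 values)."""
    path = Path(path)
    t = grid.transform
    if t.b != 0 or t.d != 0 or t.a <= 0 or t.e >= 0 or abs(t.a) != abs(t.e):
        raise GridFormatError("ESRI ASCII requires a north-up square-cell transform")
    nrows, ncols = grid.shape
    out = np.where(grid.nodata_mask, nodata, grid.values)
    if np.any(out[~grid.nodata_mask] == nodata):
        raise GridFormatError("valid cell collides with the nodata sentinel")
    lines = [
        f"ncols {ncols}",
        f"nrows {nrows}",
        f"xllcorner {t.c!r}",
        f"yllcorner {t.f + t.e * nrows!r}",
        f"cellsize {t.a!r}",
        f"nodata_value {nodata!r}",
    ]
    body = "\n".join(" ".join(f"{v:.17g}" for v in row) for row in out)
    path.write_text("\n".join(lines) + "\n" + body + "\n")
    if grid.crs != DEFAULT_CRS:
        path.with_suffix(".crs").write_text(grid.crs + "\n")
    return path


def assemble_scenarios(
    baseline: ClimateGrid,
    futures: Sequence[ClimateGrid],
    labels: Sequence[tuple[str, str]] | None = None,
) -> ScenarioSet:
    """Verify alignment and unify nodata masks across baseline + futures.

    The combined mask is the union of all layers' masks, so a cell is
    either valid in every layer or excluded everywhere (keeps every
    per-scenario denominator identical).  Idempotent.
    """
    futures = list(futures)
    if not futures:
        raise AlignmentError("a scenario set needs at least one future grid")
    for fut in futures:
        if not baseline.aligned_with(fut):
            raise AlignmentError(
                f"future grid {fut.label!r} is not aligned with the baseline "
                f"({fut.shape} vs {baseline.shape}); resample inputs upstream"
            )
    combined = baseline.nodata_mask.copy()
    for fut in futures:
        combined |= fut.nodata_mask
    if combined.all():
        raise EmptyGridError("combined nodata mask leaves no valid cell")

    def with_mask(g: ClimateGrid) -> ClimateGrid:
        vals = np.where(combined, np.nan, g.values)
        return ClimateGrid(vals, g.transform, crs=g.crs,
                           nodata_mask=combined.copy(), label=g.label)

    if labels is None:
        labels = [_parse_label(f.label) for f in futures]
    return ScenarioSet(with_mask(baseline), [with_mask(f) for f in futures],
                       list(labels))


def _parse_label(label: str) -> tuple[str, str]:
    if ":" in label:
        gcm, ssp = label.split(":", 1)
        return gcm, ssp
    return label, ""


# ---------------------------------------------------------------------------
# Vector and tabular I/O

def read_ranges(path: str | Path) -> list[SpeciesRange]:
    """Read species range polygons from a GeoJSON feature collection.

    Features must carry ``species_id`` and ``epoch`` (historical|current)
    properties; multiple features per species/epoch are unioned.  Species
    missing either epoch are reported with a warning and dropped.
    """
    path = Path(path)
    doc = json.loads(path.read_text())
    feats = doc.get("features")
    if feats is None:
        raise SchemaError(f"{path}: not a GeoJSON FeatureCollection")

    per_species: dict[str, dict[str, list[BaseGeometry]]] = {}
    for feat in feats:
        props = feat.get("properties") or {}
        if "species_id" not in props or "epoch" not in props:
            raise SchemaError(f"{path}: feature missing species_id/epoch")
        epoch = str(props["epoch"]).lower()
        if epoch not in ("historical", "current"):
            raise SchemaError(f"{path}: unknown epoch {props['epoch']!r}")
        geom = repair_geometry(shape(feat["geometry"]))
        per_species.setdefault(str(props["species_id"]), {}).setdefault(
            epoch, []).append(geom)

    ranges: list[SpeciesRange] = []
    for sid in per_species:
        epochs = per_species[sid]
        if "historical" not in epochs or "current" not in epochs:
            missing = {"historical", "current"} - set(epochs)
            warnings.warn(
                f"species {sid!r} lacks {sorted(missing)} feature(s); dropped",
                stacklevel=2,
            )
            continue
        ranges.append(SpeciesRange(
            sid,
            shapely.unary_union(epochs["historical"]),
            shapely.unary_union(epochs["current"]),
        ))
    return ranges


def write_ranges(ranges: Iterable[SpeciesRange], path: str | Path) -> Path:
    path = Path(path)
    feats = []
    for rng in ranges:
        for epoch in ("historical", "current"):
            feats.append({
                "type": "Feature",
                "properties": {"species_id": rng.species_id, "epoch": epoch},
                "geometry": mapping(getattr(rng, epoch)),
            })
    path.write_text(json.dumps(
        {"type": "FeatureCollection", "features": feats}, sort_keys=True))
    return path


def read_sites(path: str | Path) -> list[SiteRecord]:
    """Read translocation sites from CSV (species_id,site_name,lon,lat)."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"species_id", "site_name", "lon", "lat"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise SchemaError(f"{path}: header must contain {sorted(required)}")
        return [
            SiteRecord(row["species_id"], row["site_name"],
                       float(row["lon"]), float(row["lat"]))
            for row in reader
        ]


def write_sites(sites: Iterable[SiteRecord], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["species_id", "site_name", "lon", "lat"])
        for s in sites:
            writer.writerow([s.species_id, s.site_name,
                             repr(float(s.lon)), repr(float(s.lat))])
    return path
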