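"""Scope filters and data-quality cleaning of occurrence records.

Stages run in a fixed order — taxonomic/spatial/temporal scope, record
quality, proximity to centroid/institution reference points, polygon masks,
then per-species DBSCAN outlier removal — and every stage appends a row to a
:class:`FilterReport`, so the provenance of each removed record is explicit.

Distances are great-circle on a sphere of radius 6371.0088 km (the IUGG mean
Earth radius).  Polygon tests count boundary points as inside.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from sklearn.cluster import DBSCAN

from .occurrences import OccurrenceTable

log = logging.getLogger(__name__)

#: mean Earth radius (km) for all great-circle distances in cleaning
EARTH_RADIUS_MEAN_KM = 6371.0088

#: Darwin Core basis-of-record controlled vocabulary (for spec validation)
BASIS_VOCABULARY = frozenset(
    {
        "PRESERVED_SPECIMEN",
        "FOSSIL_SPECIMEN",
        "LIVING_SPECIMEN",
        "MATERIAL_SAMPLE",
        "MATERIAL_CITATION",
        "HUMAN_OBSERVATION",
        "MACHINE_OBSERVATION",
        "OBSERVATION",
        "OCCURRENCE",
    }
)


@dataclasses.dataclass
class DbscanSpec:
    enabled: bool = False
    eps_km: float = 500.0
    min_pts: int = 20


@dataclasses.dataclass
class FilterSpec:
    """Declarative description of all scope and quality filters."""

    species_keys: set | None = None
    bbox: tuple | None = None  # (lon_min, lon_max, lat_min, lat_max), closed
    countries: set | None = None
    min_year: int | None = None
    max_year: int | None = None
    basis_include: set | None = None
    basis_exclude: set | None = None
    keep_missing_basis_on_include: bool = False
    max_coord_precision: float | None = None
    max_uncertainty_m: float | None = None
    centroid_radius_km: float = 2.0
    institution_radius_km: float = 2.0
    dbscan: DbscanSpec = dataclasses.field(default_factory=DbscanSpec)

    def validate(self) -> None:
        if self.bbox is not None:
            lon_min, lon_max, lat_min, lat_max = self.bbox
            if not (lon_min < lon_max and lat_min < lat_max):
                raise ValueError(f"degenerate bbox {self.bbox}")
        if (
            self.min_year is not None
            and self.max_year is not None
            and self.min_year > self.max_year
        ):
            raise ValueError("min_year > max_year")
        if self.basis_include and self.basis_exclude:
            overlap = set(self.basis_include) & set(self.basis_exclude)
            if overlap:
                raise ValueError(f"basis_include and basis_exclude overlap: {overlap}")
        for tokens in (self.basis_include, self.basis_exclude):
            if tokens:
                unknown = set(tokens) - BASIS_VOCABULARY
                if unknown:
                    warnings.warn(f"unknown basis-of-record token(s): {sorted(unknown)}")
        if self.dbscan.enabled:
            if self.dbscan.eps_km <= 0:
                raise ValueError("dbscan eps_km must be > 0")
            if self.dbscan.min_pts < 1:
                raise ValueError("dbscan min_pts must be >= 1")


@dataclasses.dataclass
class ReferenceGeodata:
    """User-supplied reference layers (never bundled with the package)."""

    centroid_points: pd.DataFrame | None = None  # columns latitude, longitude
    institution_points: pd.DataFrame | None = None
    land_polygons: list | None = None  # shapely geometries, WGS84
    urban_polygons: list | None = None
    region_polygons: list | None = None


@dataclasses.dataclass
class StageRecord:
    stage: str
    rows_in: int
    rows_removed: int
    parameters: dict


class FilterReport:
    """Ordered per-stage accounting; conserves row counts exactly."""

    def __init__(self):
        self.stages: list[StageRecord] = []

    def add(self, stage: str, rows_in: int, rows_removed: int, parameters: dict):
        if self.stages:
            prev = self.stages[-1]
            assert rows_in == prev.rows_in - prev.rows_removed, "report chain broken"
        self.stages.append(StageRecord(stage, rows_in, rows_removed, parameters))

    @property
    def rows_final(self) -> int:
        if not self.stages:
            return 0
        last = self.stages[-1]
        return last.rows_in - last.rows_removed

    def total_removed(self) -> int:
        return sum(s.rows_removed for s in self.stages)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.stage,
                    "rows_in": s.rows_in,
                    "rows_removed": s.rows_removed,
                    "parameters": json.dumps(s.parameters, default=str, sort_keys=True),
                }
                for s in self.stages
            ]
        )

    def write(self, path_tsv=None, path_json=None):
        if path_tsv:
            self.to_frame().to_csv(path_tsv, sep="\t", index=False)
        if path_json:
            Path(path_json).write_text(
                json.dumps(
                    [dataclasses.asdict(s) for s in self.stages],
                    indent=2,
                    default=str,
                )
            )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def haversine_km(lat1, lon1, lat2, lon2, radius_km: float = EARTH_RADIUS_MEAN_KM):
    """Great-circle distance in km; broadcasts over numpy arrays."""
    la1, lo1, la2, lo2 = map(np.deg2rad, (lat1, lon1, lat2, lon2))
    a = (
        np.sin((la2 - la1) / 2) ** 2
        + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2
    )
    return 2 * radius_km * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def apply_scope(table: OccurrenceTable, spec: FilterSpec):
    """Taxonomic, spatial and temporal scope; bounds are closed intervals.

    Rows with missing ``year`` are removed only when a year bound is active.
    """
    spec.validate()
    df = table.data
    entries = []

    def _stage(name, keep_mask, params):
        nonlocal df
        entries.append(StageRecord(name, len(df), int((~keep_mask).sum()), params))
        df = df[keep_mask]

    if spec.species_keys is not None:
        _stage(
            "scope_species",
            df["species_key"].isin(list(spec.species_keys)).to_numpy(),
            {"n_keys": len(spec.species_keys)},
        )
    if spec.countries is not None:
        _stage(
            "scope_country",
            df["country_code"].isin(list(spec.countries)).to_numpy(),
            {"countries": sorted(spec.countries)},
        )
    if spec.bbox is not None:
        lon_min, lon_max, lat_min, lat_max = spec.bbox
        keep = (
            (df["longitude"] >= lon_min)
            & (df["longitude"] <= lon_max)
            & (df["latitude"] >= lat_min)
            & (df["latitude"] <= lat_max)
        ).to_numpy()
        _stage("scope_bbox", keep, {"bbox": list(spec.bbox)})
    if spec.min_year is not None or spec.max_year is not None:
        keep = df["year"].notna()
        if spec.min_year is not None:
            keep &= df["year"] >= spec.min_year
        if spec.max_year is not None:
            keep &= df["year"] <= spec.max_year
        _stage(
            "scope_year",
            keep.fillna(False).to_numpy(),
            {"min_year": spec.min_year, "max_year": spec.max_year},
        )
    if len(df) == 0 and entries:
        warnings.warn("scope filters removed every record")
    return OccurrenceTable(df, table.report), entries


def filter_quality(table: OccurrenceTable, spec: FilterSpec):
    """Basis-of-record and coordinate precision/uncertainty filters.

    Records with *missing* precision or uncertainty survive those filters;
    records with missing basis are excluded by an include-list unless
    ``keep_missing_basis_on_include`` is set.
    """
    spec.validate()
    df = table.data
    entries = []

    def _stage(name, keep_mask, params):
        nonlocal df
        entries.append(StageRecord(name, len(df), int((~np.asarray(keep_mask)).sum()), params))
        df = df[keep_mask]

    if spec.basis_include is not None:
        keep = df["basis_of_record"].isin(list(spec.basis_include))
        if spec.keep_missing_basis_on_include:
            keep |= df["basis_of_record"].isna()
        _stage(
            "quality_basis_include",
            keep.to_numpy(),
            {
                "include": sorted(spec.basis_include),
                "keep_missing": spec.keep_missing_basis_on_include,
            },
        )
    if spec.basis_exclude is not None:
        keep = ~df["basis_of_record"].isin(list(spec.basis_exclude))
        _stage("quality_basis_exclude", keep.to_numpy(), {"exclude": sorted(spec.basis_exclude)})
    if spec.max_coord_precision is not None:
        keep = df["coord_precision"].isna() | (
            df["coord_precision"] <= spec.max_coord_precision
        )
        _stage(
            "quality_coord_precision",
            keep.to_numpy(),
            {"max_coord_precision": spec.max_coord_precision},
        )
    if spec.max_uncertainty_m is not None:
        keep = df["coord_uncertainty_m"].isna() | (
            df["coord_uncertainty_m"] <= spec.max_uncertainty_m
        )
        _stage(
            "quality_uncertainty",
            keep.to_numpy(),
            {"max_uncertainty_m": spec.max_uncertainty_m},
        )
    if len(df) == 0 and entries:
        warnings.warn("quality filters removed every record")
    return OccurrenceTable(df, table.report), entries


def remove_near_points(
    table: OccurrenceTable,
    points: pd.DataFrame | None,
    radius_km: float,
    stage: str = "near_points",
):
    """Drop records within ``radius_km`` (inclusive) of any reference point."""
    if radius_km <= 0:
        raise ValueError("radius_km must be > 0")
    df = table.data
    if points is None or len(points) == 0:
        warnings.warn(f"{stage}: empty reference point set, nothing removed")
        entry = StageRecord(stage, len(df), 0, {"radius_km": radius_km, "n_points": 0})
        return table, entry
    d = haversine_km(
        df["latitude"].to_numpy()[:, None],
        df["longitude"].to_numpy()[:, None],
        points["latitude"].to_numpy()[None, :],
        points["longitude"].to_numpy()[None, :],
    )
    near = (d <= radius_km).any(axis=1)
    entry = StageRecord(
        stage, len(df), int(near.sum()), {"radius_km": radius_km, "n_points": len(points)}
    )
    return OccurrenceTable(df[~near], table.report), entry


def polygon_mask(
    table: OccurrenceTable,
    polygons,
    mode: str = "keep_inside",
    stage: str = "polygon_mask",
):
    """Point-in-polygon filter; the boundary counts as inside.

    ``keep_inside`` retains records inside any polygon, ``drop_inside``
    removes them.
    """
    if mode not in ("keep_inside", "drop_inside"):
        raise ValueError(f"unknown mode {mode!r}")
    for i, g in enumerate(polygons):
        if g is None or not g.is_valid:
            raise ValueError(f"invalid polygon geometry at feature index {i}")
    df = table.data
    pts = shapely.points(df["longitude"].to_numpy(), df["latitude"].to_numpy())
    inside = np.zeros(len(df), dtype=bool)
    for g in polygons:
        inside |= shapely.covers(g, pts)  # covers: boundary counts as inside
    keep = inside if mode == "keep_inside" else ~inside
    entry = StageRecord(
        stage, len(df), int((~keep).sum()), {"mode": mode, "n_polygons": len(polygons)}
    )
    return OccurrenceTable(df[keep], table.report), entry


def dbscan_outliers(table: OccurrenceTable, eps_km: float, min_pts: int):
    """Remove per-species spatial outliers with great-circle DBSCAN.

    DBSCAN runs independently for each species; records labelled noise are
    removed.  Species with fewer than ``min_pts`` records cannot form a core
    point and are exempt (fully retained): a sparse range is not evidence of
    error.
    """
    if eps_km <= 0:
        raise ValueError("eps_km must be > 0")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    df = table.data
    noise = np.zeros(len(df), dtype=bool)
    flags = {}
    for key, idx in df.groupby("species_key").indices.items():
        if len(idx) < min_pts:
            flags[key] = np.zeros(len(idx), dtype=bool)
            continue
        sub = df.iloc[idx]
        coords = np.deg2rad(sub[["latitude", "longitude"]].to_numpy(dtype=float))
        labels = DBSCAN(
            eps=eps_km / EARTH_RADIUS_MEAN_KM,
            min_samples=min_pts,
            metric="haversine",
            algorithm="ball_tree",
        ).fit_predict(coords)
        sp_noise = labels == -1
        flags[key] = sp_noise
        noise[np.asarray(idx)[sp_noise]] = True
    entry = StageRecord(
        "dbscan",
        len(df),
        int(noise.sum()),
        {"eps_km": eps_km, "min_pts": min_pts},
    )
    return OccurrenceTable(df[~noise], table.report), flags, entry


def run_cleaning(
    table: OccurrenceTable,
    spec: FilterSpec,
    geodata: ReferenceGeodata | None = None,
) -> tuple[OccurrenceTable, FilterReport]:
    """Full cleaning chain: scope -> quality -> proximity -> polygons -> DBSCAN."""
    spec.validate()
    geodata = geodata or ReferenceGeodata()
    report = FilterReport()

    def _push(entries):
        for e in entries:
            report.add(e.stage, e.rows_in, e.rows_removed, e.parameters)

    def _noop(stage):
        report.add(stage, len(table.data), 0, {"active": False})

    table, entries = apply_scope(table, spec)
    _push(entries) if entries else _noop("scope")
    table, entries = filter_quality(table, spec)
    _push(entries) if entries else _noop("quality")
    if geodata.centroid_points is not None:
        table, e = remove_near_points(
            table, geodata.centroid_points, spec.centroid_radius_km, stage="centroids"
        )
        _push([e])
    else:
        _noop("centroids")
    if geodata.institution_points is not None:
        table, e = remove_near_points(
            table,
            geodata.institution_points,
            spec.institution_radius_km,
            stage="institutions",
        )
        _push([e])
    else:
        _noop("institutions")
    if geodata.land_polygons is not None:
        table, e = polygon_mask(
            table, geodata.land_polygons, mode="keep_inside", stage="land_mask"
        )
        _push([e])
    else:
        _noop("land_mask")
    if geodata.urban_polygons is not None:
        table, e = polygon_mask(
            table, geodata.urban_polygons, mode="drop_inside", stage="urban_mask"
        )
        _push([e])
    else:
        _noop("urban_mask")
    if spec.dbscan.enabled:
        table, _flags, e = dbscan_outliers(table, spec.dbscan.eps_km, spec.dbscan.min_pts)
        _push([e])
    else:
        _noop("dbscan")
    return table, report


# ---------------------------------------------------------------------------
# reference geodata I/O (GeoJSON)
# ---------------------------------------------------------------------------


def load_geojson_polygons(path) -> list:
    """Polygon/MultiPolygon geometries from a GeoJSON file (WGS84)."""
    doc = json.loads(Path(path).read_text())
    feats = doc["features"] if doc.get("type") == "FeatureCollection" else [doc]
    geoms = []
    for i, f in enumerate(feats):
        g = shapely.geometry.shape(f["geometry"] if "geometry" in f else f)
        if g.geom_type not in ("Polygon", "MultiPolygon"):
            raise ValueError(f"feature {i} is {g.geom_type}, expected polygonal")
        if not g.is_valid:
            raise ValueError(f"invalid polygon geometry at feature index {i}")
        geoms.append(g)
    return geoms


def load_points(path) -> pd.DataFrame:
    """Reference points from GeoJSON (Point features) or CSV (lat/lon columns)."""
    path = Path(path)
    if path.suffix.lower() in (".json", ".geojson"):
        doc = json.loads(path.read_text())
        feats = doc["features"] if doc.get("type") == "FeatureCollection" else [doc]
        rows = []
        for f in feats:
            g = shapely.geometry.shape(f["geometry"] if "geometry" in f else f)
            rows.append({"latitude": g.y, "longitude": g.x})
        return pd.DataFrame(rows)
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    lat = cols.get("latitude", cols.get("decimallatitude", cols.get("lat")))
    lon = cols.get("longitude", cols.get("decimallongitude", cols.get("lon")))
    if lat is None or lon is None:
        raise ValueError(f"no latitude/longitude columns in {path.name}")
    return df.rename(columns={lat: "latitude", lon: "longitude"})[["latitude", "longitude"]]
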