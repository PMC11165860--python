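"""Result export: CSV tables, GeoPackage layers, interactive maps, provenance.

Numeric CSV output uses 6 significant digits; the GeoPackage keeps full
double precision.  The GeoPackage writer emits the minimal OGC-conformant
core (spatial_ref_sys, contents, geometry_columns and one feature table
with standard GeoPackageBinary geometries) over the standard library's
sqlite3, so the file opens in QGIS and friends without further ado.
"""

from __future__ import annotations

import datetime as _dt
import json
import sqlite3
import struct
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from . import __version__
from .canape import PALETTE
from .hexgrid import PresenceMatrix, cell_polygon

_FLOAT_FORMAT = "%.6g"

_WGS84_WKT = (
    'GEOGCS["WGS 84",DATUM["WGS_1984",SPHEROID["WGS 84",6378137,298.257223563]],'
    'PRIMEM["Greenwich",0],UNIT["degree",0.0174532925199433],'
    'AUTHORITY["EPSG","4326"]]'
)


def _fmt(x) -> str:
    if isinstance(x, (float, np.floating)):
        return _FLOAT_FORMAT % x
    return str(x)


def assemble_results(
    metrics: pd.DataFrame,
    sig: pd.DataFrame | None = None,
    labels: pd.Series | None = None,
) -> pd.DataFrame:
    """Join metrics, significance and CANAPE labels into one per-cell table."""
    out = metrics.copy()
    if sig is not None:
        if not out.index.equals(sig.index):
            sig = sig.reindex(out.index)
        out = out.join(sig)
    if labels is not None:
        out["canape"] = labels.reindex(out.index).astype(str)
    return out


def export_csv(results: pd.DataFrame, path) -> Path:
    path = Path(path)
    results.to_csv(path, float_format=_FLOAT_FORMAT, index_label="cell")
    return path


# ---------------------------------------------------------------------------
# GeoPackage
# ---------------------------------------------------------------------------


def _gpkg_geometry(geom, srs_id: int = 4326) -> bytes:
    """Standard GeoPackageBinary: GP header + little-endian ISO WKB."""
    minx, miny, maxx, maxy = geom.bounds
    header = struct.pack(
        "<2sBBi4d", b"GP", 0, 0b00000011, srs_id, minx, maxx, miny, maxy
    )
    return header + shapely.to_wkb(geom, byte_order=1)


def read_gpkg_geometry(blob: bytes):
    """Parse a GeoPackageBinary blob back to a shapely geometry."""
    flags = blob[3]
    env_code = (flags >> 1) & 0x07
    env_len = {0: 0, 1: 32, 2: 48, 3: 48, 4: 64}[env_code]
    return shapely.from_wkb(bytes(blob[8 + env_len:]))


def export_geopackage(
    matrix: PresenceMatrix,
    results: pd.DataFrame,
    path,
    layer: str = "phylodiversity",
) -> Path:
    """One EPSG:4326 feature layer: a (multi)polygon per cell plus all columns.

    Cells crossing the antimeridian are exported as split multi-part
    geometries; every geometry is validated before writing.
    """
    path = Path(path)
    if path.exists():
        path.unlink()
    cells = list(results.index)

    con = sqlite3.connect(path)
    try:
        cur = con.cursor()
        cur.execute("PRAGMA application_id = 1196444487")  # 'GPKG'
        cur.execute("PRAGMA user_version = 10300")
        cur.execute(
            """CREATE TABLE gpkg_spatial_ref_sys (
                srs_name TEXT NOT NULL, srs_id INTEGER PRIMARY KEY,
                organization TEXT NOT NULL, organization_coordsys_id INTEGER NOT NULL,
                definition TEXT NOT NULL, description TEXT)"""
        )
        cur.executemany(
            "INSERT INTO gpkg_spatial_ref_sys VALUES (?,?,?,?,?,?)",
            [
                ("WGS 84", 4326, "EPSG", 4326, _WGS84_WKT, None),
                ("Undefined cartesian", -1, "NONE", -1, "undefined", None),
                ("Undefined geographic", 0, "NONE", 0, "undefined", None),
            ],
        )
        cur.execute(
            """CREATE TABLE gpkg_contents (
                table_name TEXT NOT NULL PRIMARY KEY, data_type TEXT NOT NULL,
                identifier TEXT UNIQUE, description TEXT DEFAULT '',
                last_change DATETIME NOT NULL DEFAULT (strftime('%Y-%m-%dT%H:%M:%fZ','now')),
                min_x DOUBLE, min_y DOUBLE, max_x DOUBLE, max_y DOUBLE,
                srs_id INTEGER)"""
        )
        cur.execute(
            """CREATE TABLE gpkg_geometry_columns (
                table_name TEXT NOT NULL, column_name TEXT NOT NULL,
                geometry_type_name TEXT NOT NULL, srs_id INTEGER NOT NULL,
                z TINYINT NOT NULL, m TINYINT NOT NULL,
                CONSTRAINT pk_geom_cols PRIMARY KEY (table_name, column_name))"""
        )

        attr_cols = []
        for col in results.columns:
            sql_type = "TEXT" if results[col].dtype == object else "DOUBLE"
            attr_cols.append(f'"{col}" {sql_type}')
        cur.execute(
            f'CREATE TABLE "{layer}" (fid INTEGER PRIMARY KEY AUTOINCREMENT, '
            f'geom BLOB, cell TEXT, {", ".join(attr_cols)})'
        )

        bounds = [180.0, 90.0, -180.0, -90.0]
        rows = []
        for cell in cells:
            geom = cell_polygon(cell)
            if not geom.is_valid:
                raise ValueError(f"invalid exported geometry for cell {cell}")
            b = geom.bounds
            bounds = [
                min(bounds[0], b[0]),
                min(bounds[1], b[1]),
                max(bounds[2], b[2]),
                max(bounds[3], b[3]),
            ]
            vals = []
            for v in results.loc[cell]:
                if isinstance(v, np.generic):
                    v = v.item()
                if isinstance(v, float) and np.isnan(v):
                    v = None
                vals.append(v)
            rows.append((_gpkg_geometry(geom), str(cell), *vals))
        placeholders = ",".join("?" * (len(results.columns) + 2))
        cur.executemany(
            f'INSERT INTO "{layer}" (geom, cell, '
            + ", ".join(f'"{c}"' for c in results.columns)
            + f") VALUES ({placeholders})",
            rows,
        )
        cur.execute(
            "INSERT INTO gpkg_contents (table_name, data_type, identifier, "
            "min_x, min_y, max_x, max_y, srs_id) VALUES (?,?,?,?,?,?,?,?)",
            (layer, "features", layer, bounds[0], bounds[1], bounds[2], bounds[3], 4326),
        )
        cur.execute(
            "INSERT INTO gpkg_geometry_columns VALUES (?,?,?,?,?,?)",
            (layer, "geom", "GEOMETRY", 4326, 0, 0),
        )
        con.commit()
    finally:
        con.close()
    return path


# ---------------------------------------------------------------------------
# interactive map
# ---------------------------------------------------------------------------

_MAP_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>phylohex results</title>
<link rel="stylesheet" href="https://unpkg.com/leaflet@1.9.4/dist/leaflet.css"/>
<script src="https://unpkg.com/leaflet@1.9.4/dist/leaflet.js"></script>
<style>html,body,#map{height:100%;margin:0}</style></head>
<body><div id="map"></div>
<script>
var data = __GEOJSON__;
var metrics = __METRICS__;
var palette = __PALETTE__;
var map = L.map('map');
L.tileLayer('https://tile.openstreetmap.org/{z}/{x}/{y}.png',
  {attribution: '&copy; OpenStreetMap contributors'}).addTo(map);
function ramp(t){
  var stops=[[68,1,84],[59,82,139],[33,145,140],[94,201,98],[253,231,37]];
  t=Math.max(0,Math.min(1,t)); var i=Math.min(3,Math.floor(t*4)); var f=t*4-i;
  var c=stops[i].map(function(v,k){return Math.round(v+f*(stops[i+1][k]-v));});
  return 'rgb('+c.join(',')+')';
}
var overlays = {};
metrics.forEach(function(m){
  var vals = data.features.map(function(f){return f.properties[m];})
                 .filter(function(v){return v!==null && isFinite(v);});
  var lo = Math.min.apply(null, vals), hi = Math.max.apply(null, vals);
  overlays[m] = L.geoJSON(data, {
    style: function(f){
      var v = f.properties[m];
      var t = (hi>lo)? (v-lo)/(hi-lo) : 0.5;
      return {color:'#555', weight:0.5, fillOpacity:0.75, fillColor: ramp(t)};
    },
    onEachFeature: function(f, lyr){ lyr.bindPopup(f.properties.popup); }
  });
});
if (metrics.indexOf('canape') < 0 && 'canape' in data.features[0].properties) {
  overlays['canape'] = L.geoJSON(data, {
    style: function(f){ return {color:'#555', weight:0.5, fillOpacity:0.85,
      fillColor: palette[f.properties.canape] || '#cccccc'}; },
    onEachFeature: function(f, lyr){ lyr.bindPopup(f.properties.popup); }
  });
}
var first = Object.keys(overlays)[0];
overlays[first].addTo(map);
map.fitBounds(overlays[first].getBounds());
L.control.layers({}, overlays, {collapsed:false}).addTo(map);
</script></body></html>
"""


def export_map(
    results: pd.DataFrame,
    path,
    metrics_to_show: list[str] | None = None,
) -> Path:
    """Self-contained Leaflet HTML: one toggleable layer per index.

    Hovering/clicking a cell pops up the exact exported values (formatted
    identically to the CSV).  Refuses an empty metric selection.
    """
    if len(results) == 0:
        raise ValueError("no results to map")
    if metrics_to_show is None:
        preferred = ["richness", "pd", "pd_p", "rpd", "we", "cwe", "pe", "rpe", "redundancy"]
        metrics_to_show = [m for m in preferred if m in results.columns]
    if not metrics_to_show:
        raise ValueError("empty metric selection for map export")
    for m in metrics_to_show:
        if m not in results.columns:
            raise ValueError(f"metric {m!r} not in results")

    features = []
    for cell in results.index:
        geom = cell_polygon(cell)
        row = results.loc[cell]
        popup = f"<b>cell {cell}</b><br>" + "<br>".join(
            f"{k}: {_fmt(v)}" for k, v in row.items()
        )
        props = {
            k: (None if isinstance(v, float) and np.isnan(v) else (float(v) if isinstance(v, (int, float, np.number)) else str(v)))
            for k, v in row.items()
        }
        props["cell"] = str(cell)
        props["popup"] = popup
        features.append(
            {
                "type": "Feature",
                "geometry": shapely.geometry.mapping(geom),
                "properties": props,
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    html = (
        _MAP_TEMPLATE.replace("__GEOJSON__", json.dumps(doc))
        .replace("__METRICS__", json.dumps(metrics_to_show))
        .replace("__PALETTE__", json.dumps(PALETTE))
    )
    path = Path(path)
    path.write_text(html)
    return path


# ---------------------------------------------------------------------------
# provenance and run manifest
# ---------------------------------------------------------------------------


def provenance_report(table, tree_source: str | None, path) -> Path:
    """Dataset-key record counts for crediting data providers.

    Counts reflect the retained (filtered) rows only; when the table has no
    ``dataset_key`` values a stub file notes that provenance is unavailable.
    """
    path = Path(path)
    df = table.data if hasattr(table, "data") else table
    lines = ["# phylohex provenance report"]
    if tree_source:
        lines.append(f"# tree source: {tree_source}")
    if "dataset_key" not in df.columns or df["dataset_key"].notna().sum() == 0:
        lines.append("# WARNING: no dataset_key column/values; provenance unavailable")
        path.write_text("\n".join(lines) + "\n")
        return path
    counts = (
        df.dropna(subset=["dataset_key"])
        .groupby("dataset_key")
        .size()
        .sort_values(ascending=False)
    )
    lines.append("datasetKey\tn_records")
    for k, n in counts.items():
        lines.append(f"{k}\t{n}")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_manifest(path, config: dict, filter_report=None) -> Path:
    doc = {
        "software": "phylohex",
        "version": __version__,
        "created": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "config": config,
    }
    if filter_report is not None:
        doc["filter_report"] = [
            {
                "stage": s.stage,
                "rows_in": s.rows_in,
                "rows_removed": s.rows_removed,
                "parameters": s.parameters,
            }
            for s in filter_report.stages
        ]
    path = Path(path)
    path.write_text(json.dumps(doc, indent=2, default=str))
    return path
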