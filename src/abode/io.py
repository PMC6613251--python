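"""Readers and writers for the pipeline's plain-text formats.

Geometries travel as GeoJSON (RFC 7946, WGS84 lon/lat), point tables as
delimited text with lon/lat columns, and the land-use raster as an ESRI
ASCII grid.  On input everything is projected into the local planar frame;
synthetic regions are inverse-projected on output so the generator writes
exactly the formats the pipeline reads.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Polygon, mapping

from .allocation import Well
from .census import CensusBlock
from .geometry import (
    Frame,
    GeoPoint,
    ProjectionSpec,
    polygon_from_rings,
    project_polygon,
    project_xy,
    unproject_xy,
)
from .rhu import CandidateLocation

__all__ = [
    "read_geojson_features",
    "write_geojson",
    "geojson_centroid_spec",
    "load_blocks",
    "load_candidates",
    "load_wells",
    "load_setback_rules",
    "load_removals",
    "write_region",
]

log = logging.getLogger(__name__)


def _geom_from_geojson(g: dict):
    t = g.get("type")
    if t == "Polygon":
        rings = g["coordinates"]
        return polygon_from_rings(rings[0], rings[1:])
    if t == "MultiPolygon":
        polys = [polygon_from_rings(rings[0], rings[1:]) for rings in g["coordinates"]]
        return MultiPolygon(polys)
    if t == "Point":
        lon, lat = g["coordinates"][:2]
        return GeoPoint(float(lon), float(lat), Frame.GEOGRAPHIC)
    raise ValueError(f"unsupported GeoJSON geometry type {t!r}")


def read_geojson_features(path: str | Path) -> list[tuple[object, dict]]:
    """Read a GeoJSON FeatureCollection into (geometry, properties) pairs."""
    path = Path(path)
    with path.open() as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a FeatureCollection")
    out = []
    for feat in doc.get("features", []):
        out.append((_geom_from_geojson(feat["geometry"]), feat.get("properties") or {}))
    return out


def write_geojson(path: str | Path, features: list[tuple[object, dict]]) -> None:
    """Write (geometry, properties) pairs as a GeoJSON FeatureCollection."""
    feats = []
    for geom, props in features:
        if isinstance(geom, GeoPoint):
            gj = {"type": "Point", "coordinates": [geom.x, geom.y]}
        else:
            gj = mapping(geom)
        feats.append({"type": "Feature", "geometry": gj, "properties": props})
    with Path(path).open("w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def geojson_centroid_spec(path: str | Path) -> ProjectionSpec:
    """Projection centred on the bounding-box centre of a GeoJSON file."""
    feats = read_geojson_features(path)
    xs: list[float] = []
    ys: list[float] = []
    for geom, _ in feats:
        if isinstance(geom, GeoPoint):
            xs.append(geom.x)
            ys.append(geom.y)
        else:
            minx, miny, maxx, maxy = geom.bounds
            xs += [minx, maxx]
            ys += [miny, maxy]
    if not xs:
        raise ValueError(f"{path}: no geometries")
    return ProjectionSpec((min(xs) + max(xs)) / 2.0, (min(ys) + max(ys)) / 2.0)


def load_blocks(path: str | Path, spec: ProjectionSpec) -> list[CensusBlock]:
    """Census blocks from GeoJSON, projected into the planar frame.

    Required properties: block_id, total_population, housing_units.
    group_quarters_population defaults to 0 with a warning; an optional
    ``pph`` property overrides the derived persons-per-household.
    """
    blocks = []
    warned = False
    for geom, props in read_geojson_features(path):
        if isinstance(geom, GeoPoint):
            raise ValueError(f"{path}: blocks must be polygons")
        if "group_quarters_population" not in props and not warned:
            log.warning("%s: group_quarters_population missing, defaulting to 0", path)
            warned = True
        blocks.append(
            CensusBlock(
                block_id=str(props["block_id"]),
                geometry=project_polygon(geom, spec),
                total_population=float(props["total_population"]),
                group_quarters_population=float(props.get("group_quarters_population", 0)),
                housing_units=int(props["housing_units"]),
                pph_override=(float(props["pph"]) if "pph" in props else None),
            )
        )
    return blocks


def _load_point_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".json", ".geojson"):
        rows = []
        for geom, props in read_geojson_features(path):
            if not isinstance(geom, GeoPoint):
                raise ValueError(f"{path}: expected point features")
            rows.append({**props, "lon": geom.x, "lat": geom.y})
        return pd.DataFrame(rows)
    return pd.read_csv(path)


def load_candidates(path: str | Path, spec: ProjectionSpec) -> list[CandidateLocation]:
    """Candidate dwelling points from CSV (candidate_id, lon, lat[, source])
    or GeoJSON points; projected to planar metres."""
    df = _load_point_table(path)
    x, y = project_xy(df["lon"].to_numpy(), df["lat"].to_numpy(), spec)
    sources = df["source"] if "source" in df else ["address"] * len(df)
    return [
        CandidateLocation(
            str(cid), GeoPoint(float(xi), float(yi), Frame.PLANAR), source=str(src)
        )
        for cid, xi, yi, src in zip(df["candidate_id"], x, y, sources)
    ]


def load_wells(path: str | Path, spec: ProjectionSpec) -> list[Well]:
    """Wells from CSV (well_id, facility_id, state, lon, lat) or GeoJSON."""
    df = _load_point_table(path)
    x, y = project_xy(df["lon"].to_numpy(), df["lat"].to_numpy(), spec)
    return [
        Well(
            well_id=str(row["well_id"]),
            x=float(xi),
            y=float(yi),
            state=(str(row["state"]) if "state" in row and pd.notna(row["state"]) else None),
            facility_id=(
                str(row["facility_id"])
                if "facility_id" in row and pd.notna(row["facility_id"])
                else None
            ),
        )
        for (_, row), xi, yi in zip(df.iterrows(), x, y)
    ]


def load_setback_rules(path: str | Path) -> dict[str, float]:
    """State setback distances in feet from a two-column CSV (state, setback_ft)."""
    df = pd.read_csv(path)
    return {str(r["state"]): float(r["setback_ft"]) for _, r in df.iterrows()}


def load_removals(path: str | Path) -> list[str]:
    """Verification removal ids from a one-column CSV."""
    df = pd.read_csv(path)
    return [str(v) for v in df.iloc[:, 0]]


def write_region(region, outdir: str | Path, spec: ProjectionSpec | None = None) -> dict:
    """Write a synthetic region in the formats the pipeline reads.

    Planar coordinates are inverse-projected to lon/lat under ``spec``
    (default: a projection centred at lon 0, lat 0).  Returns the mapping of
    logical names to file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = spec or ProjectionSpec(0.0, 0.0)

    def _unproject_poly(poly: Polygon) -> Polygon:
        def ring(coords):
            arr = np.asarray(coords)
            lon, lat = unproject_xy(arr[:, 0], arr[:, 1], spec)
            return list(zip(lon, lat))

        return Polygon(ring(poly.exterior.coords), [ring(r.coords) for r in poly.interiors])

    paths = {
        "blocks": outdir / "blocks.geojson",
        "candidates": outdir / "candidates.csv",
        "wells": outdir / "wells.csv",
        "land_use": outdir / "landuse.asc",
        "truth": outdir / "truth.csv",
        "setback_rules": outdir / "setback_rules.csv",
    }
    write_geojson(
        paths["blocks"],
        [
            (
                _unproject_poly(b.geometry),
                {
                    "block_id": b.block_id,
                    "total_population": b.total_population,
                    "group_quarters_population": b.group_quarters_population,
                    "housing_units": b.housing_units,
                },
            )
            for b in region.blocks
        ],
    )
    lon, lat = unproject_xy(
        np.array([c.point.x for c in region.candidates]),
        np.array([c.point.y for c in region.candidates]),
        spec,
    )
    pd.DataFrame(
        {
            "candidate_id": [c.candidate_id for c in region.candidates],
            "lon": lon,
            "lat": lat,
            "source": [c.source for c in region.candidates],
        }
    ).to_csv(paths["candidates"], index=False)
    wlon, wlat = unproject_xy(
        np.array([w.x for w in region.wells]), np.array([w.y for w in region.wells]), spec
    )
    pd.DataFrame(
        {
            "well_id": [w.well_id for w in region.wells],
            "facility_id": [w.facility_id for w in region.wells],
            "state": [w.state for w in region.wells],
            "lon": wlon,
            "lat": wlat,
        }
    ).to_csv(paths["wells"], index=False)
    region.land_use.to_ascii(paths["land_use"])
    region.truth.to_csv(paths["truth"], index=False)
    pd.DataFrame({"state": ["SYN"], "setback_ft": [200.0]}).to_csv(
        paths["setback_rules"], index=False
    )
    # Ready-made run configuration.  The ASCII land-use grid lives in planar
    # metres of the projection used here, so a pipeline run over these files
    # must use the same projection centre — the INI pins it.
    ini = outdir / "run.ini"
    with ini.open("w") as fh:
        fh.write("[run]\n")
        for key in ("blocks", "candidates", "land_use", "wells", "setback_rules"):
            fh.write(f"{key} = {paths[key].resolve()}\n")
        fh.write(f"center_lon = {spec.center_lon}\n")
        fh.write(f"center_lat = {spec.center_lat}\n")
    paths["run_ini"] = ini
    return paths
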