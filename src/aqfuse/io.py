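"""Readers and writers for the pipeline's on-disk formats.

All geometries travel as GeoJSON (RFC 7946) in projected planar meters
(the CRS is declared in the FeatureCollection metadata, not transformed);
tabular data as header-keyed CSV; concentration rasters as ESRI ASCII
grids (NODATA_value -9999). Every format round-trips: read(write(x))
reproduces x.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .dispersion import ConcentrationField, EmissionSource, ReceptorGrid
from .monitoring import Zone

__all__ = [
    "write_sources_geojson", "read_sources_geojson",
    "write_zones_geojson", "read_zones_geojson",
    "write_met_csv", "read_met_csv",
    "write_asc", "read_asc",
    "write_field", "write_observations_csv", "read_observations_csv",
    "scenario_to_json",
]

NODATA = -9999.0
CRS_NOTE = "projected planar meters (local grid)"


# --- GeoJSON ---------------------------------------------------------------


def write_sources_geojson(sources: Sequence[EmissionSource], path) -> None:
    features = []
    for s in sources:
        features.append({
            "type": "Feature",
            "geometry": mapping(s.geometry),
            "properties": {
                "id": s.id,
                "group": s.group,
                "rates_gs": dict(s.rates),
                "release_height": s.release_height,
                "sigma_y0": s.sigma_y0,
                "sigma_z0": s.sigma_z0,
            },
        })
    doc = {"type": "FeatureCollection", "crs_note": CRS_NOTE, "features": features}
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_sources_geojson(path) -> list[EmissionSource]:
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    out = []
    for i, feat in enumerate(doc["features"]):
        try:
            p = feat["properties"]
            out.append(EmissionSource(
                id=p["id"], group=p["group"], geometry=shape(feat["geometry"]),
                rates=p["rates_gs"], release_height=p["release_height"],
                sigma_y0=p.get("sigma_y0", 0.0), sigma_z0=p.get("sigma_z0", 0.0),
            ))
        except (KeyError, TypeError) as exc:
            raise ValueError(f"{path}: malformed feature {i}: {exc}") from exc
    return out


def write_zones_geojson(zones: Sequence[Zone], path) -> None:
    features = [{
        "type": "Feature",
        "geometry": mapping(z.polygon),
        "properties": {"id": z.id, "label": z.label},
    } for z in zones]
    doc = {"type": "FeatureCollection", "crs_note": CRS_NOTE, "features": features}
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_zones_geojson(path) -> list[Zone]:
    doc = json.loads(Path(path).read_text())
    out = []
    for i, feat in enumerate(doc["features"]):
        try:
            p = feat["properties"]
            out.append(Zone(id=int(p["id"]), label=str(p["label"]),
                            polygon=shape(feat["geometry"])))
        except (KeyError, TypeError) as exc:
            raise ValueError(f"{path}: malformed feature {i}: {exc}") from exc
    return out


# --- meteorology CSV -------------------------------------------------------


def write_met_csv(met_year, path) -> None:
    pd.DataFrame({
        "timestamp": [h.timestamp.isoformat() for h in met_year],
        "ws": [h.wind_speed for h in met_year],
        "wd": [h.wind_direction for h in met_year],
        "L": [h.monin_obukhov_L for h in met_year],
        "zi": [h.mixing_height for h in met_year],
        "stability": [h.stability.value for h in met_year],
        "season": [h.season for h in met_year],
    }).to_csv(path, index=False)


def read_met_csv(path):
    from .meteorology import met_year_from_frame

    return met_year_from_frame(pd.read_csv(path))


# --- ESRI ASCII grid -------------------------------------------------------


def write_asc(grid: ReceptorGrid, values: np.ndarray, path) -> None:
    """ESRI ASCII raster; rows run north to south, as the format requires."""
    v = np.asarray(values, dtype=float)
    if v.shape != grid.shape:
        raise ValueError(f"values shape {v.shape} != grid shape {grid.shape}")
    body = np.where(np.isfinite(v), v, NODATA)[::-1]  # top row = max y
    header = (
        f"ncols {grid.nx}\n"
        f"nrows {grid.ny}\n"
        f"xllcorner {grid.origin[0]:.6f}\n"
        f"yllcorner {grid.origin[1]:.6f}\n"
        f"cellsize {grid.spacing:.6f}\n"
        f"NODATA_value {NODATA:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.10g")


def read_asc(path) -> tuple[ReceptorGrid, np.ndarray]:
    lines = Path(path).read_text().splitlines()
    hdr = {}
    for i, line in enumerate(lines[:6]):
        key, val = line.split()
        hdr[key.lower()] = float(val)
    grid = ReceptorGrid(
        origin=(hdr["xllcorner"], hdr["yllcorner"]),
        nx=int(hdr["ncols"]), ny=int(hdr["nrows"]), spacing=hdr["cellsize"],
    )
    body = np.loadtxt(lines[6:])
    body = np.atleast_2d(body)[::-1]  # back to south-to-north rows
    body = np.where(body == hdr["nodata_value"], np.nan, body)
    return grid, body


def write_field(field: ConcentrationField, out_dir, stem: str) -> list[Path]:
    """One .asc per source group plus the all-sources total, and a
    long-format CSV (x, y, group, value)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    surfaces = dict(field.values)
    surfaces["all_sources"] = field.total
    xr, yr = field.grid.mesh()
    long_rows = []
    for group, surface in surfaces.items():
        p = out_dir / f"{stem}_{group}.asc"
        write_asc(field.grid, surface, p)
        written.append(p)
        long_rows.append(pd.DataFrame({
            "x": xr, "y": yr, "group": group, "value": surface.ravel(),
        }))
    csv_path = out_dir / f"{stem}_long.csv"
    pd.concat(long_rows, ignore_index=True).to_csv(csv_path, index=False)
    written.append(csv_path)
    return written


# --- observation set -------------------------------------------------------


def write_observations_csv(obs, path) -> None:
    obs.table.to_csv(path, index=False)


def read_observations_csv(path):
    from .monitoring import ObservationSet

    return ObservationSet(pd.read_csv(path))


# --- scenario serialization ------------------------------------------------


def scenario_to_json(scenario) -> str:
    """Canonical JSON of a scenario (inventories, sites, zones, met hash,
    truth hash) — byte-identical for identical seeds."""
    import hashlib

    def geom_obj(g):
        return mapping(g)

    doc = {
        "config": {
            k: (v if not hasattr(v, "__dict__") else vars(v).copy())
            for k, v in vars(scenario.config).items()
        },
        "true_sources": [
            {"id": s.id, "group": s.group, "geometry": geom_obj(s.geometry),
             "rates": dict(s.rates), "release_height": s.release_height}
            for s in scenario.true_sources
        ],
        "model_sources": [s.id for s in scenario.model_sources],
        "sites": scenario.stationary_sites.to_dict("records"),
        "zones": [
            {"id": z.id, "label": z.label, "geometry": geom_obj(z.polygon)}
            for z in scenario.zones
        ],
        "met_sha": hashlib.sha256(
            "".join(f"{h.timestamp}{h.wind_speed:.9f}{h.wind_direction:.9f}"
                    for h in scenario.met_year).encode()
        ).hexdigest(),
        "truth_sha": hashlib.sha256(
            np.ascontiguousarray(scenario.ground_truth.total).tobytes()
        ).hexdigest(),
    }
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, tuple):
            return list(o)
        return vars(o)
    return json.dumps(doc, indent=1, sort_keys=True, default=default)
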