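"""Monitoring-data reduction: stationary annual means, mobile-monitoring
"air-quality zone" aggregation, and assembly of the fused observation set.

Stationary sensors stream near-continuously for a year; mobile platforms
cover space instead of time, traversing fixed routes with many repeated
passes. Each zone — a polygon within the routes expected to be impacted
by a distinct source mix — is turned into a pseudo-stationary site: its
repeated-pass records collapse to one annual value (mean of per-pass
medians, robust to within-pass spikes). The observation vector for data
fusion is the stationary annual means plus the zone annual values, each
paired with the dispersion-model value interpolated at the site (the
study configuration is 6 stationary sites + 21 zones = 27).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .dispersion import ConcentrationField

__all__ = [
    "Zone",
    "ObservationSet",
    "annual_mean_stationary",
    "aggregate_mobile_to_zones",
    "assemble_observations",
]

#: A gap longer than this between consecutive in-zone records starts a
#: new pass (one vehicle traversal of the zone).
PASS_GAP_S = 120.0


@dataclass(frozen=True)
class Zone:
    """A mobile-monitoring air-quality zone."""

    id: int
    label: str
    polygon: Polygon

    def __post_init__(self) -> None:
        if self.polygon.is_empty or self.polygon.area <= 0:
            raise ValueError(f"zone {self.id}: empty polygon")

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.polygon.centroid
        return (c.x, c.y)


@dataclass
class ObservationSet:
    """Aligned observation/model vectors for the fusion stage.

    One row per site: ``id``, ``kind`` (stationary | zone), coordinates
    (site point, or zone centroid), the observed annual value ``z`` and
    the co-located model value ``o``.
    """

    table: pd.DataFrame  # columns: id, kind, x, y, z, o

    def __post_init__(self) -> None:
        required = {"id", "kind", "x", "y", "z", "o"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"ObservationSet missing columns {sorted(missing)}")
        if self.table["id"].duplicated().any():
            raise ValueError("duplicate site ids")
        if not np.isfinite(self.table[["x", "y", "z", "o"]].to_numpy()).all():
            raise ValueError("non-finite observation values")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def coords(self) -> np.ndarray:
        return self.table[["x", "y"]].to_numpy(dtype=float)

    @property
    def z(self) -> np.ndarray:
        return self.table["z"].to_numpy(dtype=float)

    @property
    def o(self) -> np.ndarray:
        return self.table["o"].to_numpy(dtype=float)


def annual_mean_stationary(
    series: pd.DataFrame, completeness_min: float = 0.75
) -> float:
    """Annual value of a stationary monitor: mean of daily means.

    ``series`` has columns ``timestamp`` and ``value`` for one site and
    pollutant. Completeness = fraction of calendar days in the spanned
    period with at least one record; below ``completeness_min`` the year
    is rejected rather than silently biased.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    ts = pd.to_datetime(series["timestamp"])
    days = ts.dt.floor("D")
    span_days = (days.max() - days.min()).days + 1
    n_days = days.nunique()
    completeness = n_days / span_days
    if completeness < completeness_min:
        raise ValueError(
            f"completeness {completeness:.2f} below threshold {completeness_min}"
        )
    daily = series.groupby(days.values)["value"].mean()
    return float(daily.mean())


def _assign_zone(records: pd.DataFrame, zones: Sequence[Zone]) -> np.ndarray:
    """Zone id per record (-1 = outside all zones).

    Boundary ties are deterministic: zones are scanned in ascending id and
    a record on a shared boundary goes to the lowest id (``covers`` is
    boundary-inclusive).
    """
    x = records["x"].to_numpy(dtype=float)
    y = records["y"].to_numpy(dtype=float)
    out = np.full(len(records), -1, dtype=int)
    for zone in sorted(zones, key=lambda z: z.id):
        unassigned = out == -1
        if not unassigned.any():
            break
        hit = shapely.intersects_xy(zone.polygon, x[unassigned], y[unassigned])
        idx = np.flatnonzero(unassigned)[hit]
        out[idx] = zone.id
    return out


def aggregate_mobile_to_zones(
    records: pd.DataFrame,
    zones: Sequence[Zone],
    min_passes: int = 10,
) -> pd.DataFrame:
    """Collapse mobile records into per-zone summaries.

    ``records`` columns: ``timestamp``, ``x``, ``y``, ``value``. Records
    are spatially joined to zones (point-in-polygon, boundary ties to the
    lowest zone id), segmented into passes wherever consecutive in-zone
    records are separated by more than 120 s, and summarized as the
    median of each pass then aggregated across passes.

    Returns a DataFrame indexed by zone id with columns ``label``,
    ``n_records``, ``n_passes``, ``median``, ``q25``, ``q75``, ``mean``,
    ``annual_value`` (mean of per-pass medians) and ``eligible`` (enough
    passes to enter the fusion observation set). The number of records
    outside every zone is available as ``df.attrs['n_dropped']``.
    """
    if len(records) == 0:
        raise ValueError("no mobile records")
    recs = records.sort_values("timestamp").reset_index(drop=True)
    zone_ids = _assign_zone(recs, zones)
    n_dropped = int((zone_ids == -1).sum())

    rows = []
    for zone in sorted(zones, key=lambda z: z.id):
        sub = recs[zone_ids == zone.id]
        if len(sub) == 0:
            rows.append({
                "zone_id": zone.id, "label": zone.label, "n_records": 0,
                "n_passes": 0, "median": np.nan, "q25": np.nan, "q75": np.nan,
                "mean": np.nan, "annual_value": np.nan, "eligible": False,
            })
            continue
        t = pd.to_datetime(sub["timestamp"]).astype("int64") / 1e9
        gaps = np.diff(t.to_numpy())
        pass_id = np.concatenate([[0], np.cumsum(gaps > PASS_GAP_S)])
        pass_medians = sub.groupby(pass_id)["value"].median()
        values = sub["value"].to_numpy(dtype=float)
        rows.append({
            "zone_id": zone.id,
            "label": zone.label,
            "n_records": len(sub),
            "n_passes": int(pass_medians.size),
            "median": float(np.median(values)),
            "q25": float(np.percentile(values, 25)),
            "q75": float(np.percentile(values, 75)),
            "mean": float(values.mean()),
            "annual_value": float(pass_medians.mean()),
            "eligible": bool(pass_medians.size >= min_passes),
        })
    out = pd.DataFrame(rows).set_index("zone_id")
    out.attrs["n_dropped"] = n_dropped
    return out


def assemble_observations(
    stationary: pd.DataFrame,
    zone_summary: pd.DataFrame,
    zones: Sequence[Zone],
    model_field: ConcentrationField,
) -> ObservationSet:
    """Build the fusion observation vector.

    ``stationary`` columns: ``id``, ``x``, ``y``, ``z`` (annual means at
    site points). ``zone_summary`` is the output of
    :func:`aggregate_mobile_to_zones`; only eligible zones enter, located
    at their polygon centroid. The model offset ``o`` is the annual model
    field interpolated bilinearly at each site coordinate.
    """
    zone_by_id = {z.id: z for z in zones}
    rows = []
    for _, r in stationary.iterrows():
        rows.append({
            "id": str(r["id"]), "kind": "stationary",
            "x": float(r["x"]), "y": float(r["y"]), "z": float(r["z"]),
        })
    for zone_id, r in zone_summary.iterrows():
        if not r["eligible"]:
            continue
        cx, cy = zone_by_id[int(zone_id)].centroid
        rows.append({
            "id": f"zone_{zone_id}", "kind": "zone",
            "x": cx, "y": cy, "z": float(r["annual_value"]),
        })
    table = pd.DataFrame(rows)
    table["o"] = model_field.interp(
        table["x"].to_numpy(), table["y"].to_numpy()
    )
    return ObservationSet(table=table)
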