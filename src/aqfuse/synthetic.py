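"""Seeded synthetic scenarios emulating a community-scale near-source
study design.

A scenario is a self-contained, reproducible stand-in for a field study
in a ~10 km x 10 km industrial river-valley community: rail lines and
rail yards along a valley axis (the dominant local source, with a
maintenance-facility shed embedded in the largest yard), a cluster of
warehouses/distribution centers in the northern sector, a road network,
a few industrial point stacks, a year of hourly meteorology with a
diurnal stability cycle, six stationary monitoring sites, and 21 mobile
"air-quality zone" polygons along the monitoring routes.

Two inventories are produced: the TRUE inventory that generates the
ground-truth concentration field and the monitor samples, and a MODEL
inventory — a deliberately imperfect copy (by default the warehouse
group is scaled to 20% and one area source omitted entirely) — so the
dispersion-model field underpredicts near those sources and the fusion
stage has a real deficit to recover.

Everything is generated from a single integer seed; no global random
state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon, box

from . import emissions as em
from .dispersion import (
    ConcentrationField,
    EmissionSource,
    ReceptorGrid,
    annual_field,
)
from .meteorology import (
    MetHour,
    RepresentativeSet,
    Stability,
    classify_stability,
    select_representative_hours,
    _SEASON_BY_MONTH,
)
from .monitoring import Zone

__all__ = [
    "PerturbationSpec",
    "ScenarioConfig",
    "Scenario",
    "generate_met_year",
    "generate_scenario",
    "sample_monitors",
    "SYNTHETIC_IDLING_RATES",
]

#: Placeholder hourly idling emission rates (per pollutant, at 30 F and
#: 80 F) for the warehouse estimation chain. Synthetic values of a
#: plausible magnitude — NOT from any regulatory emissions platform.
SYNTHETIC_IDLING_RATES: dict[str, tuple[float, float]] = {
    "nox": (0.12, 0.09),
    "pm25": (0.004, 0.003),
    "ec25": (0.003, 0.0022),
}


@dataclass(frozen=True)
class PerturbationSpec:
    """How the model inventory deviates from the truth.

    ``scale_by_group`` multiplies every rate of a source group;
    ``omit_ids`` removes sources entirely. ``none()`` gives a perfect
    inventory (useful as a control).
    """

    scale_by_group: dict[str, float] = field(
        default_factory=lambda: {"warehouse": 0.2}
    )
    omit_ids: tuple[str, ...] = ("warehouse_1",)

    @classmethod
    def none(cls) -> "PerturbationSpec":
        return cls(scale_by_group={}, omit_ids=())


@dataclass(frozen=True)
class ScenarioConfig:
    """Knobs of the synthetic study; defaults are the study-like design."""

    seed: int
    domain_m: float = 10_000.0
    spacing_m: float = 75.0
    n_area_sources: int = 9  # 3 rail yards + warehouses
    n_point_sources: int = 3
    n_roads: int = 4
    n_rail_lines: int = 2
    n_stationary: int = 6
    n_zones: int = 21
    met_hours: int = 8760
    n_representative: int = 100
    pollutant: str = "ec25"
    noise_sigma: float = 0.3  # multiplicative lognormal sigma
    noise_floor: float = 0.02  # additive Gaussian sd, ug/m3
    perturbation: PerturbationSpec = field(default_factory=PerturbationSpec)
    #: area-source quadrature refinement for annual runs; < 1 coarsens the
    #: sub-cell raster (sub-cell initial spread keeps the field smooth)
    area_refinement: float = 0.25
    #: max along-wind extent (m) of line-source sub-segments; larger is
    #: faster, with ~(extent/distance)^2 relative error at a receptor
    line_alongwind: float = 10.0

    def __post_init__(self) -> None:
        if self.spacing_m <= 0 or self.domain_m <= 0:
            raise ValueError("domain and spacing must be positive")
        if round(self.domain_m / self.spacing_m) * self.spacing_m != self.domain_m:
            raise ValueError("spacing must divide the domain size")
        if self.n_area_sources < 4:
            raise ValueError("need >= 4 area sources (3 yards + >=1 warehouse)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def grid(self) -> ReceptorGrid:
        n = int(round(self.domain_m / self.spacing_m))
        return ReceptorGrid(origin=(0.0, 0.0), nx=n, ny=n, spacing=self.spacing_m)


@dataclass
class Scenario:
    """A generated study: inventories, met, sites, zones, ground truth."""

    config: ScenarioConfig
    true_sources: list[EmissionSource]
    model_sources: list[EmissionSource]
    met_year: list[MetHour]
    representative: RepresentativeSet
    stationary_sites: pd.DataFrame  # id, x, y
    zones: list[Zone]
    ground_truth: ConcentrationField  # annual field from the TRUE inventory


# ---------------------------------------------------------------------------
# meteorology


def generate_met_year(
    seed: int, n_hours: int = 8760, start: str = "2020-01-01"
) -> list[MetHour]:
    """A year of hourly meteorology with diurnal and seasonal structure.

    Wind directions favor the valley axis (SSW and N modes), speeds are
    Weibull with a winter maximum, the Monin-Obukhov length follows a
    diurnal cycle (stable nights, convective afternoons, neutral
    transitions), and mixing heights are tied to stability. Calm hours
    (< 0.5 m/s) occur and are dropped downstream.
    """
    rng = np.random.default_rng(seed)
    times = pd.date_range(start, periods=n_hours, freq="h")
    hours: list[MetHour] = []
    for t in times:
        hod = t.hour
        month = t.month
        seasonal = 1.0 + 0.25 * np.cos(2 * np.pi * (month - 1) / 12.0)
        ws = float(rng.weibull(2.0) * 3.2 * seasonal)
        # bimodal direction climatology along the valley axis
        if rng.random() < 0.55:
            wd = rng.normal(200.0, 30.0)  # SSW mode
        else:
            wd = rng.normal(0.0, 35.0)  # northerly mode
        wd = float(wd % 360.0)
        # diurnal stability: stable night, convective midday
        if 10 <= hod <= 16:
            inv_l = -abs(rng.normal(0.015, 0.01))
        elif 7 <= hod <= 9 or 17 <= hod <= 19:
            inv_l = rng.normal(0.0, 0.0015)
        else:
            inv_l = abs(rng.normal(0.015, 0.01))
        if abs(inv_l) < 1e-5:
            inv_l = 1e-5 if inv_l >= 0 else -1e-5
        L = float(1.0 / inv_l)
        stab = classify_stability(L)
        if stab in (Stability.CONVECTIVE, Stability.SLIGHTLY_CONVECTIVE):
            zi = float(rng.uniform(800.0, 2000.0))
        elif stab is Stability.NEUTRAL:
            zi = float(rng.uniform(400.0, 900.0))
        else:
            zi = float(rng.uniform(100.0, 400.0))
        if ws < 0.5:
            continue  # calm hour: excluded from dispersion
        hours.append(
            MetHour(
                timestamp=t, wind_speed=ws, wind_direction=wd,
                monin_obukhov_L=L, mixing_height=zi, stability=stab,
                season=_SEASON_BY_MONTH[month],
            )
        )
    return hours


# ---------------------------------------------------------------------------
# inventory


def _gs(tons_per_year: float) -> float:
    return em.tons_per_year_to_grams_per_second(tons_per_year)


def _rates_gs(t: em.PollutantTotals) -> dict[str, float]:
    return {"nox": _gs(t.nox), "pm25": _gs(t.pm25), "ec25": _gs(t.ec25)}


def _build_true_inventory(config: ScenarioConfig, rng: np.random.Generator):
    """Source geometries and rates with the study-like structure.

    The main rail yard's national-inventory total is split between its
    maintenance-facility shed and the rest of the yard (44/49/49%
    maintenance fractions for NOx/PM2.5/EC2.5); warehouse rates come from
    the footprint-based idling chain with synthetic hourly rates.
    """
    L = config.domain_m
    sources: list[EmissionSource] = []

    # --- main rail yard with embedded maintenance facility -------------
    yard_totals = em.PollutantTotals(
        nox=158.218, pm25=3.921, ec25=em.ec_from_pm25(3.921)
    )
    alloc = em.allocate_facility(
        yard_totals, {"nox": 0.44, "pm25": 0.49, "ec25": 0.49}
    )
    yard_poly = box(0.52 * L, 0.44 * L, 0.70 * L, 0.49 * L)
    mf_poly = box(0.53 * L, 0.455 * L, 0.545 * L, 0.465 * L)
    yard_only = yard_poly.difference(mf_poly)
    sources.append(EmissionSource(
        id="rail_yard_main", group="rail_yard", geometry=yard_only,
        rates=_rates_gs(alloc.remainder_share), release_height=3.0,
    ))
    sources.append(EmissionSource(
        id="maintenance_facility", group="maintenance_facility",
        geometry=mf_poly, rates=_rates_gs(alloc.mf_share), release_height=5.0,
    ))

    # --- two secondary yards -------------------------------------------
    for name, cx, cy, w, h, nox, pm in (
        ("rail_yard_west", 0.22 * L, 0.52 * L, 0.10 * L, 0.035 * L, 39.899, 1.089),
        ("rail_yard_south", 0.40 * L, 0.42 * L, 0.07 * L, 0.03 * L, 22.277, 0.606),
    ):
        t = em.PollutantTotals(nox=nox, pm25=pm, ec25=em.ec_from_pm25(pm))
        sources.append(EmissionSource(
            id=name, group="rail_yard",
            geometry=box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2),
            rates=_rates_gs(t), release_height=3.0,
        ))

    # --- warehouses in the northern sector ------------------------------
    n_wh = config.n_area_sources - 3
    for i in range(n_wh):
        cx = rng.uniform(0.15 * L, 0.85 * L)
        cy = rng.uniform(0.68 * L, 0.88 * L)
        side = rng.uniform(150.0, 320.0)
        footprint_sqft = (side * side) * 10.7639 * 0.5  # half the lot is building
        totals = em.warehouse_idling_emissions(
            footprint_sqft, SYNTHETIC_IDLING_RATES
        )
        sources.append(EmissionSource(
            id=f"warehouse_{i+1}", group="warehouse",
            geometry=box(cx - side / 2, cy - side / 2, cx + side / 2, cy + side / 2),
            rates=_rates_gs(totals), release_height=2.0,
        ))

    # --- rail lines along the valley axis --------------------------------
    rail_totals_per = em.PollutantTotals(nox=30.0, pm25=0.8, ec25=em.ec_from_pm25(0.8))
    for i in range(config.n_rail_lines):
        y = 0.50 * L + (i - (config.n_rail_lines - 1) / 2) * 0.03 * L
        wiggle = rng.uniform(-0.01 * L, 0.01 * L, size=3)
        line = LineString([
            (0.0, y + wiggle[0]), (0.4 * L, y + wiggle[1]), (L, y + wiggle[2]),
        ])
        sources.append(EmissionSource(
            id=f"rail_line_{i+1}", group="rail_line", geometry=line,
            rates=_rates_gs(rail_totals_per), release_height=2.0,
        ))

    # --- road network -----------------------------------------------------
    road_specs = [
        LineString([(0.0, 0.30 * L), (L, 0.32 * L)]),           # E-W highway
        LineString([(0.55 * L, 0.0), (0.57 * L, L)]),           # N-S highway
        LineString([(0.0, 0.72 * L), (L, 0.60 * L)]),           # northern arterial
        LineString([(0.15 * L, 0.0), (0.80 * L, L)]),           # diagonal
    ]
    for i in range(config.n_roads):
        line = road_specs[i % len(road_specs)]
        km = line.length / 1000.0
        t = em.PollutantTotals(
            nox=12.0 * km, pm25=0.35 * km, ec25=em.ec_from_pm25(0.35 * km)
        )
        sources.append(EmissionSource(
            id=f"road_{i+1}", group="road", geometry=line,
            rates=_rates_gs(t), release_height=1.3, sigma_y0=3.0, sigma_z0=1.5,
        ))

    # --- industrial point stacks -----------------------------------------
    for i in range(config.n_point_sources):
        px = rng.uniform(0.70 * L, 0.95 * L)
        py = rng.uniform(0.15 * L, 0.45 * L)
        t = em.PollutantTotals(nox=rng.uniform(20, 80), pm25=rng.uniform(0.5, 2.0))
        t = em.PollutantTotals(t.nox, t.pm25, em.ec_from_pm25(t.pm25) * 0.3)
        sources.append(EmissionSource(
            id=f"stack_{i+1}", group="point_industrial", geometry=Point(px, py),
            rates=_rates_gs(t), release_height=float(rng.uniform(20.0, 50.0)),
            sigma_y0=2.0, sigma_z0=2.0,
        ))
    return sources


def _perturb_inventory(
    sources: Sequence[EmissionSource], spec: PerturbationSpec
) -> list[EmissionSource]:
    out = []
    for s in sources:
        if s.id in spec.omit_ids:
            continue
        k = spec.scale_by_group.get(s.group)
        if k is not None:
            out.append(replace(s, rates={p: r * k for p, r in s.rates.items()}))
        else:
            out.append(s)
    return out


# ---------------------------------------------------------------------------
# sites and zones


def _place_sites(config: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Six stationary sites around the main sources, community-sited."""
    L = config.domain_m
    anchors = [
        (0.50, 0.47), (0.545, 0.50),  # near yard / near MF
        (0.30, 0.55), (0.64, 0.52),   # neighborhoods flanking the yards
        (0.45, 0.65), (0.75, 0.35),   # north community / SE community
    ]
    rows = []
    for i in range(config.n_stationary):
        ax, ay = anchors[i % len(anchors)]
        rows.append({
            "id": f"stationary_{i+1}",
            "x": float(np.clip(ax * L + rng.normal(0, 0.01 * L), 0.02 * L, 0.98 * L)),
            "y": float(np.clip(ay * L + rng.normal(0, 0.01 * L), 0.02 * L, 0.98 * L)),
        })
    return pd.DataFrame(rows)


def _place_zones(
    config: ScenarioConfig,
    sources: Sequence[EmissionSource],
    rng: np.random.Generator,
) -> list[Zone]:
    """Air-quality zone polygons along the monitoring routes.

    Zones sample the expected impact areas: adjacent to the maintenance
    facility and yards, downwind of the warehouse cluster, along the
    highways, and in the residential blocks between.
    """
    L = config.domain_m
    by_id = {s.id: s for s in sources}
    anchors: list[tuple[float, float, str]] = []

    def near(geom, dx, dy, label):
        c = geom.centroid
        anchors.append((c.x + dx * L, c.y + dy * L, label))

    near(by_id["maintenance_facility"].geometry, 0.012, 0.015, "near-MF")
    near(by_id["rail_yard_main"].geometry, 0.0, 0.045, "yard-north")
    near(by_id["rail_yard_main"].geometry, 0.0, -0.045, "yard-south")
    near(by_id["rail_yard_west"].geometry, 0.03, 0.02, "west-yard")
    near(by_id["rail_yard_south"].geometry, 0.02, 0.025, "south-yard")
    wh = [s for s in sources if s.group == "warehouse"]
    for i, s in enumerate(wh[:4]):
        near(s.geometry, 0.0, -0.02, f"warehouse-{i+1}")
    n_more = config.n_zones - len(anchors)
    for i in range(max(0, n_more)):
        anchors.append((
            float(rng.uniform(0.08 * L, 0.92 * L)),
            float(rng.uniform(0.15 * L, 0.85 * L)),
            f"community-{i+1}",
        ))

    zones = []
    half = 0.016 * L  # ~320 m zones at the default domain
    for zid in range(1, config.n_zones + 1):
        ax, ay, label = anchors[zid - 1]
        ax = float(np.clip(ax, half + 0.01 * L, L - half - 0.01 * L))
        ay = float(np.clip(ay, half + 0.01 * L, L - half - 0.01 * L))
        zones.append(Zone(
            id=zid, label=label,
            polygon=box(ax - half, ay - half, ax + half, ay + half),
        ))
    return zones


# ---------------------------------------------------------------------------


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Build a complete scenario deterministically from ``config.seed``.

    Ground truth is the annual concentration field of the TRUE inventory,
    computed by the dispersion module over the weighted representative
    meteorological hours.
    """
    rng = np.random.default_rng(config.seed)
    true_sources = _build_true_inventory(config, rng)
    model_sources = _perturb_inventory(true_sources, config.perturbation)
    met_year = generate_met_year(
        int(rng.integers(0, 2**31 - 1)), config.met_hours
    )
    representative = select_representative_hours(met_year, config.n_representative)
    sites = _place_sites(config, rng)
    zones = _place_zones(config, true_sources, rng)
    truth = annual_field(
        true_sources, config.grid, representative, config.pollutant,
        config.area_refinement, config.line_alongwind,
    )
    return Scenario(
        config=config,
        true_sources=true_sources,
        model_sources=model_sources,
        met_year=met_year,
        representative=representative,
        stationary_sites=sites,
        zones=zones,
        ground_truth=truth,
    )


def sample_monitors(
    scenario: Scenario,
    seed: int,
    n_campaign_days: int = 40,
    passes_per_zone_per_day: int = 1,
    records_per_pass: int = 20,
    stationary_hours: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw noisy stationary and mobile records from the ground truth.

    Stationary: one value per hour at each site,
    ``truth * LogNormal(0, sigma) + floor * eps``. Mobile: for each
    campaign day and zone, ``passes_per_zone_per_day`` traversals of a
    transect across the zone at 1-s cadence, same noise model; passes are
    separated by > 120 s so downstream pass segmentation recovers them.

    Returns ``(stationary_records, mobile_records)`` with columns
    (site_id, timestamp, value) and (timestamp, x, y, value, zone_hint).
    """
    cfg = scenario.config
    if cfg.noise_sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    rng = np.random.default_rng(seed)
    truth = scenario.ground_truth
    n_hours = stationary_hours if stationary_hours is not None else cfg.met_hours
    times = pd.date_range("2020-01-01", periods=n_hours, freq="h")

    stat_rows = []
    for _, site in scenario.stationary_sites.iterrows():
        base = float(truth.interp(site["x"], site["y"])[0])
        noise = rng.lognormal(0.0, cfg.noise_sigma, size=n_hours) if cfg.noise_sigma > 0 else np.ones(n_hours)
        floor = rng.normal(0.0, cfg.noise_floor, size=n_hours) if cfg.noise_floor > 0 else np.zeros(n_hours)
        vals = np.maximum(base * noise + floor, 0.0)
        stat_rows.append(pd.DataFrame({
            "site_id": site["id"], "timestamp": times, "value": vals,
        }))
    stationary = pd.concat(stat_rows, ignore_index=True)

    mob_rows = []
    day_starts = pd.date_range("2020-03-01", periods=n_campaign_days, freq="D")
    for day in day_starts:
        t_cursor = day + pd.Timedelta(hours=9)
        for zone in scenario.zones:
            minx, miny, maxx, maxy = zone.polygon.bounds
            for _ in range(passes_per_zone_per_day):
                frac = np.linspace(0.08, 0.92, records_per_pass)
                # transect across the zone, jittered laterally
                xs = minx + frac * (maxx - minx)
                ys = miny + (maxy - miny) * np.clip(
                    0.5 + rng.normal(0, 0.12, size=records_per_pass), 0.06, 0.94
                )
                base = truth.interp(xs, ys)
                noise = rng.lognormal(0.0, cfg.noise_sigma, size=records_per_pass) if cfg.noise_sigma > 0 else np.ones(records_per_pass)
                floor = rng.normal(0.0, cfg.noise_floor, size=records_per_pass) if cfg.noise_floor > 0 else np.zeros(records_per_pass)
                vals = np.maximum(base * noise + floor, 0.0)
                ts = t_cursor + pd.to_timedelta(np.arange(records_per_pass), unit="s")
                mob_rows.append(pd.DataFrame({
                    "timestamp": ts, "x": xs, "y": ys, "value": vals,
                    "zone_hint": zone.id,
                }))
                t_cursor = ts[-1] + pd.Timedelta(seconds=300)  # > pass gap
    mobile = pd.concat(mob_rows, ignore_index=True)
    return stationary, mobile
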