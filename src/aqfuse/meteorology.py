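"""Hourly meteorology: stability classification and meteorologically
weighted averaging.

Annual dispersion averages are expensive if every hour of a year is
simulated. The weighted-averaging shortcut used here simulates a small set
of *representative* hours (default 100) and averages the resulting fields
with weights equal to how often each representative's conditions occur in
the year. Representatives are chosen by binning hours on season, stability
regime, wind-direction sector and speed class, and taking each occupied
bin's medoid.

Stability is described by five named regimes (Stable, SlightlySstable,
Neutral, SlightlyConvective, Convective) keyed to the inverse
Monin-Obukhov length 1/L with conventional surface-layer cutoffs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Stability",
    "MetHour",
    "RepresentativeSet",
    "classify_stability",
    "select_representative_hours",
    "metare_average",
    "met_year_from_frame",
]


class Stability(enum.Enum):
    """Five stability regimes, from strongly stratified to convective."""

    STABLE = "Stable"
    SLIGHTLY_STABLE = "SlightlyStable"
    NEUTRAL = "Neutral"
    SLIGHTLY_CONVECTIVE = "SlightlyConvective"
    CONVECTIVE = "Convective"


#: Cutoffs on 1/L (1/m). Golder-style surface-layer ranges; the class
#: names come from the screening model, the numeric cutoffs are this
#: package's documented convention.
INV_L_STABLE = 0.02
INV_L_NEUTRAL = 0.002


def classify_stability(L: float) -> Stability:
    """Map a signed Monin-Obukhov length L (m) to a stability regime.

    The classification is a monotone step function of 1/L: large positive
    1/L (small positive L) is Stable, |1/L| below 0.002 is Neutral, large
    negative 1/L is Convective.
    """
    if L == 0:
        raise ValueError("Monin-Obukhov length must be nonzero")
    inv = 1.0 / L
    if inv >= INV_L_STABLE:
        return Stability.STABLE
    if inv >= INV_L_NEUTRAL:
        return Stability.SLIGHTLY_STABLE
    if inv > -INV_L_NEUTRAL:
        return Stability.NEUTRAL
    if inv > -INV_L_STABLE:
        return Stability.SLIGHTLY_CONVECTIVE
    return Stability.CONVECTIVE


@dataclass(frozen=True)
class MetHour:
    """One hour of surface meteorology used by the dispersion kernels.

    wind_direction follows the meteorological convention: degrees
    clockwise from north, the direction the wind blows FROM.
    """

    timestamp: pd.Timestamp
    wind_speed: float  # m/s
    wind_direction: float  # deg from N, FROM convention
    monin_obukhov_L: float  # m, signed
    mixing_height: float  # m
    stability: Stability
    season: str  # winter | spring | summer | fall

    def __post_init__(self) -> None:
        if self.wind_speed <= 0:
            raise ValueError("wind_speed must be > 0 for dispersion use")
        if self.mixing_height <= 0:
            raise ValueError("mixing_height must be > 0")


_SEASON_BY_MONTH = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "fall", 10: "fall", 11: "fall",
}


def met_year_from_frame(frame: pd.DataFrame) -> list[MetHour]:
    """Build MetHour records from a met table.

    Expected columns: ``timestamp``, ``ws``, ``wd``, ``L``, ``zi``
    (mixing height, m). ``season`` and ``stability`` are derived when
    absent. Calm hours (ws < 0.5 m/s) are dropped — steady-state plume
    kernels are undefined in calms — and the caller re-weights.
    """
    ts = pd.to_datetime(frame["timestamp"])
    hours: list[MetHour] = []
    for i in range(len(frame)):
        row = frame.iloc[i]
        ws = float(row["ws"])
        if ws < 0.5:
            continue
        t = ts.iloc[i]
        season = row["season"] if "season" in frame.columns else _SEASON_BY_MONTH[t.month]
        if "stability" in frame.columns and isinstance(row["stability"], str):
            stab = Stability(row["stability"])
        else:
            stab = classify_stability(float(row["L"]))
        hours.append(
            MetHour(
                timestamp=t,
                wind_speed=ws,
                wind_direction=float(row["wd"]) % 360.0,
                monin_obukhov_L=float(row["L"]),
                mixing_height=float(row["zi"]),
                stability=stab,
                season=str(season),
            )
        )
    if not hours:
        raise ValueError("no usable (non-calm) hours in met input")
    return hours


@dataclass(frozen=True)
class RepresentativeSet:
    """Representative hours and their frequency weights (sum to 1)."""

    hours: tuple[MetHour, ...]
    weights: np.ndarray  # shape (n,), sums to 1
    n_source_hours: int
    n_calm_dropped: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if len(w) != len(self.hours):
            raise ValueError("weights/hours length mismatch")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be >= 0 and sum to 1")


_SPEED_EDGES = (2.0, 4.0, 6.0)  # m/s class edges: <2, 2-4, 4-6, >=6
_N_SECTORS = 16  # 22.5 deg wind-rose sectors


def _bin_key(h: MetHour) -> tuple:
    sector = int(((h.wind_direction + 11.25) % 360.0) // 22.5)
    speed_class = int(np.searchsorted(_SPEED_EDGES, h.wind_speed, side="right"))
    return (h.season, h.stability.value, sector, speed_class)


def select_representative_hours(
    met_year: Sequence[MetHour], n: int = 100
) -> RepresentativeSet:
    """Pick weighted representative hours from a year of meteorology.

    Hours are binned by (season x stability regime x 16 wind sectors x 4
    speed classes); each occupied bin contributes its medoid — the member
    hour minimizing summed normalized distance over (speed, 1/L, mixing
    height), ties broken by earliest timestamp — weighted by the bin's
    share of hours. If more than ``n`` bins are occupied, the smallest
    bins are merged into their nearest large bin (same season and regime
    preferred) until ``n`` remain, so the weights still sum to 1.
    """
    if not met_year:
        raise ValueError("met_year is empty")
    bins: dict[tuple, list[MetHour]] = {}
    for h in met_year:
        bins.setdefault(_bin_key(h), []).append(h)

    # Merge the smallest bins until at most n remain, sacrificing the
    # least concentration-relevant structure first: season (the kernels
    # never see it), then adjacent wind sectors within the same regime
    # and speed class. Speed classes are preserved as long as possible —
    # concentration scales as 1/u, so averaging across speeds biases the
    # weighted annual mean.
    def sector_dist(a: int, b: int) -> int:
        d = abs(a - b) % _N_SECTORS
        return min(d, _N_SECTORS - d)

    while len(bins) > n:
        small_key = min(bins, key=lambda k: (len(bins[k]), k))
        season, regime, sector, speed = small_key
        others = [k for k in bins if k != small_key]
        # 1. same regime/sector/speed, different season
        pool = [k for k in others
                if k[1:] == (regime, sector, speed)]
        if not pool:
            # 2. same regime and speed class, nearest sector
            cands = [k for k in others if k[1] == regime and k[3] == speed]
            if cands:
                best = min(sector_dist(k[2], sector) for k in cands)
                pool = [k for k in cands if sector_dist(k[2], sector) == best]
        if not pool:
            # 3. same speed class anywhere
            pool = [k for k in others if k[3] == speed]
        if not pool:
            pool = others
        target = max(pool, key=lambda k: (len(bins[k]), k))
        bins[target].extend(bins.pop(small_key))

    def medoid(members: list[MetHour]) -> MetHour:
        """Member closest to the bin means of (1/u, 1/L, 1/zi).

        Plume concentrations scale as 1/u (and, well-mixed, as 1/zi), so
        the member whose reciprocal speed matches the bin mean of 1/u
        represents the bin's mean concentration far better than the
        speed-central member; ties break to the earliest timestamp.
        """
        if len(members) == 1:
            return members[0]
        inv_u = np.array([1.0 / m.wind_speed for m in members])
        inv_l = np.array([1.0 / m.monin_obukhov_L for m in members])
        inv_zi = np.array([1.0 / m.mixing_height for m in members])
        feats = np.column_stack([inv_u, inv_l, inv_zi])
        scale = feats.std(axis=0)
        scale[scale == 0] = 1.0
        d = (np.abs(feats - feats.mean(axis=0)) / scale).sum(axis=1)
        order = np.lexsort((
            [m.timestamp.value for m in members],
            d,
        ))
        return members[order[0]]

    keys = sorted(bins)
    reps = tuple(medoid(bins[k]) for k in keys)
    total = sum(len(bins[k]) for k in keys)
    weights = np.array([len(bins[k]) / total for k in keys])
    return RepresentativeSet(hours=reps, weights=weights, n_source_hours=total)


def metare_average(
    fields: Sequence[np.ndarray], weights: Sequence[float]
) -> np.ndarray:
    """Receptor-wise convex combination of per-hour concentration fields.

    With every hour present at weight 1/N this is exactly the annual mean;
    with representative hours it is the frequency-weighted approximation.
    """
    w = np.asarray(weights, dtype=float)
    if len(fields) != len(w):
        raise ValueError(
            f"{len(fields)} fields but {len(w)} weights"
        )
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("weights must be nonnegative and sum to 1")
    out = np.zeros_like(np.asarray(fields[0], dtype=float))
    for f, wi in zip(fields, w):
        out += wi * np.asarray(f, dtype=float)
    return out
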