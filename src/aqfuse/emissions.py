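"""Local emissions estimation for community-scale inventories.

Three estimation procedures feed the source inventory:

* **Facility allocation** — a national-inventory total for a rail yard is
  split between a maintenance-facility (MF) shed and the remainder of the
  yard using per-pollutant maintenance fractions derived from a local
  facility inventory.
* **EC from PM2.5** — elemental carbon is taken as a fixed fraction
  (0.7712) of fine particulate mass, a ratio found consistent across the
  rail yards studied.
* **Warehouse idling** — hoteling (extended-idle) truck emissions for
  warehouses and distribution centers, from building footprint via a
  trucks-per-day factor, idling-duration bins, and temperature-dependent
  hourly emission rates averaged over a cold and a warm month.

All quantities are annual totals in US short tons/year unless noted.
Dispersion kernels consume g/s; see :func:`tons_per_year_to_grams_per_second`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "PollutantTotals",
    "FacilityAllocation",
    "IdlingBin",
    "DEFAULT_IDLING_BINS",
    "EC_TO_PM25_RATIO",
    "IDLING_TONS_PER_RATE_HOUR",
    "SHORT_TON_GRAMS",
    "METRIC_TON_GRAMS",
    "allocate_facility",
    "ec_from_pm25",
    "warehouse_idling_emissions",
    "tons_per_year_to_grams_per_second",
    "round_half_away",
]

#: Elemental-carbon fraction of PM2.5 for rail-yard sources.
EC_TO_PM25_RATIO = 0.7712

#: Conversion applied to (idling hours x hourly rate) to obtain tons/year.
#: Honored verbatim from the estimation procedure; treat as opaque.
IDLING_TONS_PER_RATE_HOUR = 0.00965625

SHORT_TON_GRAMS = 907_184.74
METRIC_TON_GRAMS = 1_000_000.0
SECONDS_PER_YEAR = 8760 * 3600.0


def round_half_away(x: float, ndigits: int = 3) -> float:
    """Round half away from zero (table-reporting convention).

    Python's built-in ``round`` is banker's rounding; emissions tables
    conventionally round 0.0005 up.
    """
    import math

    scale = 10.0 ** ndigits
    scaled = x * scale
    if scaled >= 0:
        return math.floor(scaled + 0.5) / scale
    return math.ceil(scaled - 0.5) / scale


@dataclass(frozen=True)
class PollutantTotals:
    """Annual emission totals (tons/year) for the three modeled pollutants."""

    nox: float = 0.0
    pm25: float = 0.0
    ec25: float = 0.0

    def __post_init__(self) -> None:
        for name in ("nox", "pm25", "ec25"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    def __add__(self, other: "PollutantTotals") -> "PollutantTotals":
        return PollutantTotals(
            self.nox + other.nox, self.pm25 + other.pm25, self.ec25 + other.ec25
        )

    def scaled(self, k: float) -> "PollutantTotals":
        return PollutantTotals(self.nox * k, self.pm25 * k, self.ec25 * k)

    def rounded(self, ndigits: int = 3) -> "PollutantTotals":
        return PollutantTotals(
            round_half_away(self.nox, ndigits),
            round_half_away(self.pm25, ndigits),
            round_half_away(self.ec25, ndigits),
        )

    def as_dict(self) -> dict[str, float]:
        return {"nox": self.nox, "pm25": self.pm25, "ec25": self.ec25}


@dataclass(frozen=True)
class FacilityAllocation:
    """Split of a facility total between maintenance shed and remainder.

    Shares are carried at full precision; round only for reporting.
    """

    total: PollutantTotals
    mf_fraction: Mapping[str, float]
    mf_share: PollutantTotals
    remainder_share: PollutantTotals


def allocate_facility(
    total: PollutantTotals, mf_fraction: Mapping[str, float]
) -> FacilityAllocation:
    """Distribute a facility's inventory total between its maintenance
    facility (MF) and the rest of the yard.

    Parameters
    ----------
    total
        Facility-wide annual totals (tons/year).
    mf_fraction
        Per-pollutant fraction of the total attributed to maintenance
        activity, keyed by ``nox`` / ``pm25`` / ``ec25``; each in [0, 1].
        A missing key defaults to 0 (no maintenance share).

    Returns
    -------
    FacilityAllocation
        ``mf_share = fraction * total`` and
        ``remainder_share = total - mf_share``; the two sum to the input
        exactly, per pollutant.
    """
    shares = {}
    for name in ("nox", "pm25", "ec25"):
        f = float(mf_fraction.get(name, 0.0))
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"mf_fraction[{name!r}] must be in [0, 1], got {f}")
        shares[name] = f
    def split(total_v: float, f: float) -> tuple[float, float]:
        # compensated split: recomputing mf from the rounded remainder
        # makes mf + remainder == total exact in floating point
        mf_v = total_v * f
        rest_v = total_v - mf_v
        mf_v = total_v - rest_v
        return mf_v, rest_v

    mf_nox, rest_nox = split(total.nox, shares["nox"])
    mf_pm, rest_pm = split(total.pm25, shares["pm25"])
    mf_ec, rest_ec = split(total.ec25, shares["ec25"])
    mf = PollutantTotals(mf_nox, mf_pm, mf_ec)
    rest = PollutantTotals(rest_nox, rest_pm, rest_ec)
    return FacilityAllocation(total=total, mf_fraction=dict(shares), mf_share=mf, remainder_share=rest)


def ec_from_pm25(pm25: float, ratio: float = EC_TO_PM25_RATIO) -> float:
    """Elemental carbon (tons/year) from a PM2.5 total via the fixed
    rail-yard EC/PM2.5 ratio."""
    if pm25 < 0:
        raise ValueError(f"pm25 must be >= 0, got {pm25}")
    return ratio * pm25


@dataclass(frozen=True)
class IdlingBin:
    """One truck idling-duration bin.

    ``minutes`` is the representative idling duration per truck for the
    bin (default: the bin midpoint) and ``fraction`` the share of daily
    trucks falling in it.
    """

    label: str
    minutes: float
    fraction: float


#: Six 5-minute bins covering 0-29 minutes of idling. The survey the bin
#: scheme comes from does not publish occupancy fractions, so the default
#: is uniform; pass study-specific fractions where known.
DEFAULT_IDLING_BINS: tuple[IdlingBin, ...] = tuple(
    IdlingBin(label=f"{lo}-{lo + 4}", minutes=lo + 2.0, fraction=1.0 / 6.0)
    for lo in (0, 5, 10, 15, 20, 25)
)


def warehouse_idling_emissions(
    footprint_sqft: float,
    hourly_rate_by_temp: Mapping[str, tuple[float, float]],
    bins: Sequence[IdlingBin] = DEFAULT_IDLING_BINS,
    workdays: int = 250,
    trucks_per_ksqft: float = 0.21,
) -> PollutantTotals:
    """Annual hoteling (extended-idle) emissions for a warehouse facility.

    The chain: trucks/day = ``trucks_per_ksqft`` x footprint/1000; trucks
    are allocated to idling-duration bins; annual idling minutes per bin =
    trucks-in-bin x representative minutes x workdays; total idling hours
    are multiplied by the hourly emission rate for a cold month (30 °F,
    January) and a warm month (80 °F, July), each times
    :data:`IDLING_TONS_PER_RATE_HOUR` to give tons/year; the two monthly
    estimates are averaged.

    Parameters
    ----------
    footprint_sqft
        Building footprint inside the facility polygon, square feet.
    hourly_rate_by_temp
        Per pollutant (``nox``/``pm25``/``ec25``), the pair of hourly
        emission rates ``(rate_at_30F, rate_at_80F)``.
    bins
        Idling-duration bins; fractions must sum to 1.
    """
    if footprint_sqft < 0:
        raise ValueError(f"footprint_sqft must be >= 0, got {footprint_sqft}")
    frac_sum = sum(b.fraction for b in bins)
    if abs(frac_sum - 1.0) > 1e-9:
        raise ValueError(f"idling-bin fractions must sum to 1, got {frac_sum}")

    trucks_per_day = trucks_per_ksqft * footprint_sqft / 1000.0
    annual_minutes = sum(
        trucks_per_day * b.fraction * b.minutes * workdays for b in bins
    )
    annual_hours = annual_minutes / 60.0

    out = {}
    for name in ("nox", "pm25", "ec25"):
        if name not in hourly_rate_by_temp:
            raise KeyError(
                f"hourly_rate_by_temp missing pollutant {name!r}; "
                "need (rate@30F, rate@80F) pairs"
            )
        rates = hourly_rate_by_temp[name]
        if len(rates) != 2:
            raise ValueError(f"need (rate@30F, rate@80F) for {name!r}")
        january = annual_hours * rates[0] * IDLING_TONS_PER_RATE_HOUR
        july = annual_hours * rates[1] * IDLING_TONS_PER_RATE_HOUR
        out[name] = 0.5 * (january + july)
    return PollutantTotals(**out)


def tons_per_year_to_grams_per_second(
    rate: float, ton_definition: str = "short"
) -> float:
    """Convert an annual emission total (tons/year) to a steady g/s rate
    over an 8760-hour year.

    ``ton_definition`` is ``"short"`` (US, 907184.74 g — the default, as
    national-inventory totals are short tons) or ``"metric"``.
    """
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    grams = {"short": SHORT_TON_GRAMS, "metric": METRIC_TON_GRAMS}
    if ton_definition not in grams:
        raise ValueError(f"unknown ton definition {ton_definition!r}")
    return rate * grams[ton_definition] / SECONDS_PER_YEAR
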