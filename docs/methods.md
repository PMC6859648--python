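# Methods

This note documents the models, numerical choices and limitations of
`aqfuse`, stage by stage.

## Emissions estimation

**Facility allocation.** A rail-yard inventory total is split between
the maintenance-facility (MF) shed and the remainder of the yard with
per-pollutant maintenance fractions (NOx 44%, PM₂.₅ 49%, EC₂.₅ 49% for
the main yard). The split is conservative by construction: the shares
are computed with a compensated rounding step (`remainder = total − mf`
followed by `mf = total − remainder`) so that `mf + remainder == total`
holds bit-for-bit in double precision, for any fraction. All chains
carry full precision; rounding (half away from zero, 3 decimals) is
applied only when reporting tables.

**EC from PM₂.₅.** EC₂.₅ = 0.7712 × PM₂.₅, a ratio found consistent
across the rail yards of the local facility inventory the fractions
come from. Because both this map and the allocation are linear, they
commute — EC can be derived before or after splitting with identical
results.

**Warehouse idling.** trucks/day = 0.21 × footprint(ft²)/1000; trucks
are allocated to six 5-minute idling bins (0–29 min). The survey the
binning comes from does not publish occupancy fractions, so the default
is uniform (1/6 each) with the bin midpoint (2, 7, …, 27 min) as the
representative duration; both are configurable. Annual idling hours ×
the hourly emission rate at 30 °F (January) and 80 °F (July) ×
0.00965625 give two monthly tons/year estimates that are averaged. The
0.00965625 constant is applied verbatim as the procedure states it; its
unit provenance is not re-derived. Hourly rates are a required input:
the synthetic scenarios ship plausible placeholder rates
(`SYNTHETIC_IDLING_RATES`) that are *not* from any regulatory emissions
platform.

**Units.** Inventory totals are US short tons/year (the national
inventory's convention); dispersion consumes g/s via 907 184.74 g/short
ton over an 8760-h year. A metric-ton option exists.

## Dispersion

The kernel is the classic steady-state Gaussian plume, selected as a
fully documented, oracle-verifiable formulation:

- **Spread curves:** Briggs rural σy(x), σz(x), keyed to the five
  stability regimes (Stable→F, SlightlySstable→E, Neutral→D,
  SlightlyConvective→C, Convective→B). Regimes come from cutoffs on 1/L
  (±0.002 and ±0.02 m⁻¹, a conventional surface-layer convention;
  configurable).
- **Vertical term:** ground + mixing-lid image sources. The image
  series is truncated when converged to 1e-6 relative; because entries
  beyond the well-mixed switch are replaced anyway, σz is clamped at
  1.6·zi inside the sum, which bounds the number of non-negligible
  images analytically (≈8 for ground sources). Once σz > 1.6·zi the
  vertical profile is uniform (1/zi).
- **Upwind cutoff:** receptors ≤ 1 m downwind contribute zero (steady
  plumes do not disperse upwind). Calm hours (< 0.5 m/s) are dropped at
  met ingestion and the representative weights renormalize.
- **Area sources** are rasterized into sub-cells of side
  max(5 m, diameter/50)/refinement, each a point source at its centroid
  carrying its share of area, with an initial lateral spread of half the
  sub-cell side so adjacent sub-cells blend. Refinement > 1 tightens the
  quadrature (the Monte-Carlo oracle test uses 1); annual scenario runs
  default to 0.25 (≈4× coarser), which changes receptor values at grid
  distances by well under the weighted-averaging error.
- **Line sources** use the closed-form crosswind error-function
  solution per sub-segment. Segments are split so no piece exceeds
  100 m of crosswind extent or ~10 m of *along-wind* extent (the closed
  form treats downwind distance as constant over a piece; the along-wind
  cap keeps the error ≤ ~0.2% even for receptors 100 m from an oblique
  line). Pieces nearly parallel to the wind (< 0.5 m crosswind extent)
  fall back to point sources; zero-length segments are skipped. Scenario
  runs may relax the along-wind cap to 25 m (error ~(cap/distance)²).
- **Coordinates** are projected planar meters; wind direction uses the
  meteorological FROM convention, converted internally to the plume
  bearing (TO = FROM + 180°).

Everything is linear in emission rates, so per-group fields superpose
exactly to the all-sources field; apportionment at sites is bilinear
interpolation of the group surfaces from cell centers.

Not modeled: plume rise, building downwash, deposition, chemistry,
terrain. The kernel interface is swappable if a higher-fidelity
formulation is needed.

## Weighted annual averaging

Annual means can be computed exhaustively (equal-weight mean over all
non-calm hours) or from ~100 representative hours. Hours are binned by
season × stability regime × 16 wind sectors (22.5°) × 4 speed classes
(<2, 2–4, 4–6, ≥6 m/s). Each occupied bin contributes one
representative — the member hour closest (normalized L1) to the bin
means of **1/u, 1/L and 1/zi** — weighted by the bin's share of hours.
The reciprocal-mean choice matters: plume concentrations scale exactly
as 1/u, so a speed-central representative systematically under-weights
slow hours and biases the annual mean low by 5–10%; matching mean 1/u
removes the bias (domain mass ratio ≈ 0.99 at 100 hours).

When more bins are occupied than hours requested, the smallest bins are
merged, sacrificing the least concentration-relevant structure first:
season (the kernels never see it), then nearest wind sector within the
same regime and speed class. Speed classes are preserved as long as
possible for the 1/u reason above.

Fidelity: on a full synthetic year with three broad facility-type
plumes (volume-source idealization) on a 100 × 100 grid, the 100-hour
weighted average matches the exhaustive mean's domain median within
~9%, with RMSE decreasing monotonically as the hour budget grows.
Pointwise agreement at individual receptors is weaker (median ~25% at
100 hours) because plume widths are narrower than any affordable wind
sector — and 2–3× weaker still for narrow elevated stack plumes. The
shortcut is an annual-scale screening average, not a receptor-exact
one.

## Monitoring reduction

Stationary annual value = mean of daily means, rejected below 75%
day-completeness. Mobile records are point-in-polygon joined to zones
(boundary ties deterministically to the lowest zone id), segmented into
passes at >120 s gaps, and summarized as the mean of per-pass medians —
robust to within-pass spikes; zones with fewer than 10 passes are
flagged and excluded from fusion. The zone's representative coordinate
is its polygon centroid. Model offsets o_h are bilinear interpolations
of the annual model field at the site coordinates.

## Residual-kriging fusion

Residuals x_h = z_h − o_h are a homogeneous spatial random field with
exponential covariance C(h) = sill·exp(−3h/range) (practical range: C
falls to 5% of the sill). The experimental covariance uses 10
equal-width lag bins to half the maximum pair distance, with the
zero-lag bin equal to the sample variance; bins with <5 pairs are
flagged sparse and excluded from the fit when enough bins remain. The
fit is weighted least squares (weights = pair counts), sill initialized
at the sample variance, range at half the maximum lag, both bounded
positive; a range at its upper bound (10× max lag) flags a spatially
flat structure, and with 27 sites the range estimate is genuinely noisy
(median relative error ≈ 45% in the built-in recovery study — small-n
honesty, not a defect).

Kriging is ordinary kriging with the unbiasedness constraint, a
diagonal jitter of 1e-10·sill, and an explicit duplicate-coordinate
check. The nugget defaults to 0 — observations are hard (exact) data —
so the fused surface z = o + x̂ reproduces every observation at its
site with zero variance; far from all sites it tends to
model + mean-residual. Negative fused values (kriging undershoot below
the model) are floored at zero and counted.

Scoring against observations offers two modes: in-sample (exact by
construction with zero nugget, so MB = 0 identically) and leave-one-out
(each site predicted from the other n−1), the honest mode used in the
model-vs-fusion comparison tables.

## Evaluation

MB, ME, RMSE in concentration units and NMB in percent (a −52.9-style
magnitude is only plausible as a percentage). ME ≥ |MB| and RMSE ≥ ME
hold by Jensen/Cauchy–Schwarz and are asserted over random vectors.

## Synthetic scenarios

The generator emulates the study design, not its geography: a river-
valley axis with two rail lines, three rail yards (the largest with an
embedded MF sub-polygon, carrying the facility-allocation totals), six
warehouses in a northern sector (rates from the idling chain), four
roads, three stacks, 6 stationary sites, 21 zone polygons placed near
the expected impact areas, and a met year with bimodal valley-axis
winds, Weibull speeds, a diurnal stability cycle and stability-tied
mixing heights. Ground truth is the annual field of the TRUE inventory
over the representative hours. The model inventory defaults to
warehouse rates × 0.2 with one warehouse omitted entirely, so the model
underpredicts near the warehouse district and fusion has a real deficit
to recover.

Monitor noise is multiplicative lognormal (σ = 0.3) plus a small
additive Gaussian floor (0.02 µg/m³): concentrations are positive and
right-skewed, and no instrument error model is prescribed, so this is
the package's documented default. Note the lognormal mean exp(σ²/2)
inflates stationary annual means by ~4.6% while per-pass medians are
median-unbiased — a realistic platform-dependent bias the fusion stage
simply absorbs into the residual field.

What passing tests show — and don't. The synthetic data share the real
study's *structure* (site counts, sampling cadence, source mix,
inventory deficit) but not its instrument artifacts, spatially
correlated met errors, seasonal campaign imbalance, or real terrain
effects. Pipeline results on synthetic scenarios demonstrate the
machinery is correct and that fusion improves on dispersion under a
known deficit; they do not reproduce the original study's numerical
scores, which depend on unpublished monitor data.

## Problem sizes

The test-bench and the acceptance script run scenarios at reduced size
as the package's own default for CI-scale verification: 500-m receptor
spacing (20 × 20 grid over the 10-km domain), one month of hourly met,
20 representative hours, area quadrature refinement 0.2 and a 25-m
line along-wind cap — with the sampling design itself (6 + 21 sites, 40
campaign days, default noise and perturbation) at full study scale. The
full-resolution configuration (75-m grid, 8760 h, 100 representative
hours) is the library default and runs in tens of minutes on one CPU.
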