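# Methods

This note documents the models, defaults and numerical choices behind
`peathaze`, and what the synthetic study conditions do and do not show
about real data.

## Scope and shape of the problem

The package estimates the long-term mortality burden of peat-fire smoke
on a province-scale population at village resolution. The chain is:
hotspot filtering → peat-depth classification → per-class sampling →
per-hotspot 24-h plume → class-mean plume → scale-up by hotspot counts →
station calibration → village zonal exposure → multi-year mean →
relative risk / attributable fraction / attributable mortality →
sensitivity analysis. Morbidity, cross-province smoke inflow, ambient
(non-fire) PM2.5 and sub-annual exposure metrics are out of scope.

## Smoke transport: Gaussian-puff surrogate

Operational assessments of this kind drive a Lagrangian trajectory model
with global reanalysis meteorology. Here the transport step is a
deliberately simple Gaussian-puff surrogate, because the quantity the
rest of the chain needs is a plausible, calibratable plume *shape*, not
transport physics: the station-calibration step (part of the assessed
method itself) absorbs all absolute-scale error, and the final field is
provably invariant to the emission-rate choice (tested).

Each hotspot releases `n_puffs` = 24 puffs over a 24-h release duration.
A puff of age t (s) is a 2-D Gaussian with variance σ²(t) = 2Kt + σ₀²,
advected by the day's wind, vertically well mixed over the plume layer
H = 100 m AGL, with surviving mass fraction exp[−(v_d/H + Λ)t]. The 24-h
mean field averages mid-interval snapshots every `dt_sample_h` = 1 h.

Parameters, with units and defaults:

| parameter | default | meaning |
|---|---|---|
| `release_duration_h` | 24 | pollutant release window per hotspot |
| `averaging_period_h` | 24 | output averaging window |
| `plume_layer_top_m` | 100 | vertical averaging layer (AGL) |
| `dry_deposition_velocity_ms` | 0.001 | v_d |
| `wet_scavenging_rate_s` | 8.0e-5 | Λ, first-order scavenging |
| `horizontal_diffusivity_m2s` | 3000 | K; σ ≈ 23 km after 24 h |
| `sigma0_m` | 500 | initial puff size (~1-km detection pixel) |
| `emission_rate` | 1 | arbitrary units; cancelled by calibration |

The wet rate is read as a first-order scavenging coefficient in s⁻¹ —
the only dimensionally coherent interpretation — and is applied
unconditionally (no precipitation switch), matching the single constant
rate the assessment prescribes. The first four rows and the deposition
rates follow the original transport-model configuration; K, σ₀ and the
step sizes are surrogate-specific choices (K set so a day-old plume is a
few tens of km wide, typical of haze plumes at this scale).

Numerics: puff kernels are evaluated separably (outer product of 1-D
Gaussians), without range truncation, so a brute-force per-cell summation
reproduces field values to 1e-10 relative (tested). Snapshot mass
integrals over a sufficiently large grid conserve released mass to
better than 0.5% without deposition; the decay factor matches an
independent ODE integration to 1e-6.

## Averaging, scale-up, calibration

The "average plume of one peat-fire hotspot" is computed in
source-relative coordinates: each sampled hotspot's field is computed on
a grid centred on the source (odd cell counts, so the source is a cell
centre), then averaged cell-wise per peat class. Averaging in absolute
coordinates is available behind `recenter=False`. Scale-up re-places the
class-mean plume by FFT convolution with the class's hotspot density map
(a normalised 2-D histogram of all retained hotspots of that class and
year) and multiplies by the class's hotspot count. This is one defensible
reading of re-expanding a 200-hotspot average to the full hotspot
population; FFT ringing can leave ~1e-16-scale negatives, which are
clipped to zero to preserve field non-negativity. Calibration multiplies
the whole annual field by observed/modelled at the station cell — exact
at the station by construction, one factor per year, one station.

Grid convention: 1-km square cells, cell-centre coordinates, values are
cell means, row 0 is the southern edge. Fields export as CSV
(x, y, value) with a JSON metadata sidecar.

## Village exposure

Village annual means are area-weighted polygon means using exact
polygon-cell intersection areas (vectorised shapely); for the synthetic
tile villages this reduces to plain cell means, making zonal statistics
exactly checkable, and it matches a fine-subgrid integration oracle to
1e-6 on random rectangles (tested). Area weighting (not population
weighting) within villages is the implemented choice. The period mean is
the unweighted arithmetic mean over study years. Exposure is reported
throughout as the fire-smoke *increment*: months without fire contribute
zero, and no ambient background is added.

Exceedance semantics follow the reporting conventions: strictly < 10
μg/m³ (the WHO annual guideline), ≥ 20, strictly > 80. X_o is the
minimum village period mean region-wide (a single reference), not
per-district.

## Health impact

Forms and defaults (β per μg/m³ PM2.5):

| category | form | β | share of deaths | age group (fraction) |
|---|---|---|---|---|
| all_cause | linear | 0.0008 × 48/21 ≈ 0.001829 | 100% | all (100%) |
| chronic_respiratory | linear | 0.00166 × 48/21 ≈ 0.003794 | 4% | under 5 (10%) |
| cardiovascular | log_linear | 0.15515 | 33% | 30+ (44.5%) |
| lung_cancer | log_linear | 0.23218 | 2% | 30+ (44.5%) |

PM10-based coefficients are converted with the exact rational 48/21 and
kept at full precision internally; 6-decimal rounding is display-only.
CDR = 0.0058 deaths per person-year. RR is clamped to exactly 1 below
X_o (no negative attributable burden). AF = RR(X) − 1 is uncapped;
values above 1 (possible for extreme exposures under the log-linear
form) emit a warning. Each village's AF uses its own X against the
regional X_o; regional totals are sums of unrounded village values, and
half-up rounding to integers happens only at reporting time.

Age-group accounting: the all-ages row applies AF to the full
population; the age-group row scales it by the age fraction. Both are
emitted; the headline uses the all-ages basis. Percent changes in the
sensitivity analysis are computed on unrounded totals; the −10 μg/m³
variant floors village exposure at zero, and the exposure-shift variants
keep the baseline X_o.

A caution on convexity: the exponential ("linear") form is convex in X,
so village-resolved totals are never below the homogeneous regional
estimate with the same mean — this is why a one-village computation on
the regional mean brackets the resolved headline from below. The
log-linear form with β < 1 is *concave* in X, so that argument applies
only to the exponential-form categories (both behaviours are
property-tested).

## Synthetic study conditions

The generator emulates the study's input structure on a 240 × 160 km
rectangle: a southern peat belt of four depth-code rectangles (D1–D4),
per-year hotspot totals 3155 / 3604 / 1246 / 7454 / 21408 with deep
exceeding shallow by 8% overall, uniform-integer confidences 0–100
(≈21% retained at the ≥ 80 filter), dry-season (Jul–Nov) timing at 4×
weight, 1,569 rectangle-tile villages partitioning the region exactly,
log-normal populations (σ = 1.2, heavy tail for the dominant city)
summing exactly to 2.5 million, daily winds (mean 1.5 m/s toward the
northwest, direction SD 70°), and one station with per-year observed
annual means 30 / 33 / 18 / 44 / 65 μg/m³ (five-year mean 38).

Hotspot locations mix tight clusters (an intensively used
ex-agricultural-project analogue; fraction 0.55, SD 14 km) with a
diffuse component over the class's peat polygons, by rejection sampling.
The station sits at (100, 72) km, just north of the belt — placed, like
the real station city, well inside the smoke gradient at roughly
max/2.7 of the exposure surface. With these defaults the village period
means span at least 5–100 μg/m³ (the designed dynamic-range contract,
asserted in tests) with a mean around 26–37 across seeds.

What passing tests do **not** show about real data: the synthetic
exposure surface has a broader low tail than a real province (24-h
plumes do not accumulate a regional haze floor), so X_o lands near zero
rather than ~4 μg/m³ — which inflates the log-linear categories'
attributable fractions relative to the published setting; villages are
rectangles; meteorology is a daily region constant; and detection
physics (confidence vs fire intensity) is not modelled. The health
arithmetic is insensitive to all of these by construction, which is why
its checks use printed inputs and closed-form oracles instead.

## Problem sizes and determinism

The full-size preset samples 10 hotspots per class per year (the
original design point is 100; the sampling density affects only the
class-mean plume's smoothness, not its scale) on 281 × 281-cell
recentred plume grids, and completes end-to-end in well under a minute
on one CPU. All randomness flows from one seed through
`numpy.random.SeedSequence` (per-year sampling seeds are derived, kept
below 2³¹); reruns are byte-identical, which the tests assert by
hashing output CSVs.

## Known limitations

- The puff surrogate has no chemistry, terrain, vertical wind shear or
  precipitation coupling; it is a calibratable shape model only.
- One calibration station: spatial error grows with distance from it,
  exactly as in the assessed method.
- The density-based re-expansion of the class-mean plume assumes sampled
  hotspots are representative of their class's spatial distribution.
- Exposure is an annual-mean increment; acute episode effects are not
  represented.
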