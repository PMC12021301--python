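# Methods

This note records the models, parameter choices and numerical
conventions behind `urbanfrail`, and what the synthetic study design
does and does not establish.

## Frailty phenotype

The classifier implements the operationalised Fried phenotype: five
binary components scored from clinical measurements, with the count
mapping 0 → robust, 1–2 → prefrail, ≥ 3 → frail.

Boundary conventions, fixed once and tested exhaustively:

| component | rule | boundary |
|---|---|---|
| slowness | gait speed < 0.8 m/s | strict: 0.80 does **not** flag |
| weakness | grip < 27 kg (men) / < 15 kg (women) | strict |
| weight loss | ≥ 5 kg in 6 months | inclusive |
| exhaustion | max of the two item frequencies ≥ 3 days/week | inclusive |
| low activity | either walking-difficulty item true | — |

The wording "below a cut-off" and "<" is read as strict inequality;
"at least" as inclusive. Exhaustion flags on *either* of the two
depression-scale items. Protocols that adjust the walk cut-off by sex
and height can supply a per-stratum cut-off table in
`ThresholdConfig.gait_cutoff_by_stratum`; the default is a flat
0.8 m/s because no adjustment table is universal, and the flat value is
the common operationalisation.

## Proximity scoring

All geometry is planar metres; geographic coordinates must be projected
upstream. Distances are exact Euclidean point-to-geometry distances
(zero inside polygons). The raster convention is fixed: row 0 is the
southernmost row, cell values are evaluated at cell centres, and point
sampling is a nearest-cell lookup with no interpolation — a bit-exact,
reproducible contract. The reference semantics of `distance_field` is
per-cell-centre evaluation; the implementation uses an STR-tree nearest
query, which is exact, and the test suite pins it to a brute-force
oracle on grids up to 128×128.

Band classification puts both break values in the middle band
(`d < near → 3`, `near ≤ d ≤ far → 2`, `d > far → 1`), forced by the
strict "<" and ">" bounds of the published band tables. Default breaks
per category (metres): shops 300/600, senior centres 500/1000,
pharmacies 500/1000, emergency centres 1000/2000, squares/parks
200/400, health centres 700/1400, stadiums 400/600.

Per-participant distance statistics use the vector-exact distances, not
raster samples: the raster path exists for the index and map export,
and raster sampling would add cell-size quantisation noise to point
statistics. Default grid resolution is 25 m over the 10 km extent
(400×400 cells), configurable.

## Synthetic city and cohort

The generator emulates a compact mid-sized city and a geocoded cohort
of ~251 adults aged ≥ 65 (74.5% women), with category fractions
0.36 / 0.48 / 0.16 (robust / prefrail / frail).

**Sectors.** Six Voronoi cells of well-separated seeded generator
points partition the extent; each carries one socioeconomic label
(high, low, lower-middle, historic-center, medium-high, industrial).
The historic-center generator is drawn from the central third of the
extent so commercial clustering has a meaningful anchor. Real city
districts are irregular; Voronoi cells preserve the property that
matters here — six labelled, space-filling, interior-disjoint sectors —
without any map dependency.

**Facilities.** Counts per category were set once from the Poisson
nearest-neighbour relation E[d] ≈ 0.5·(count/area)^(-1/2) so typical
nearest distances match a compact city: shops ≈ 300, senior centres
≈ 130, pharmacies ≈ 100, emergency centres ≈ 20, squares/parks ≈ 500
(small square polygons, 40–120 m sides), health centres ≈ 25, stadiums
≈ 120 — giving mean distances of a few hundred metres for everyday
amenities and 1–2 km (between-resident sd ≈ 900 m) for emergency
centres. A configurable fraction of each category is drawn from a
Gaussian around the historic centre (60% for shops and pharmacies, down
to 20% for stadiums); the rest is uniform.

**Population surface.** One Gaussian bump per sector, centred at the
sector centroid with σ equal to the sector's equivalent radius and an
amplitude per socioeconomic label (0.004–0.013 persons/m²). Default
amplitudes put sector mean densities in ≈ 0.008–0.015 persons/m²,
matching the magnitude of published urban densities when expressed in
persons/m². The surface is linear in the amplitudes and strictly
positive. How real studies obtain density at a residence (census block,
kernel estimate, …) varies and is often unstated; this surface is a
smooth stand-in, not a model of any particular source.

**Planted associations.** The cohort model is: residence uniform over
the city; frailty category drawn per sector with a per-label additive
log-odds shift on the frail category (defaults: lower-middle +1.0,
medium-high +0.3, low +0.1, historic-center 0, industrial −0.3, high
−0.6), re-centred by a global constant (solved by root-finding) so the
citywide category marginals stay at the configured fractions. On top of
this, frail residences are tilted by maximum-entropy weights
exp(λ·f(x)), where f(x) collects the nearest distances of the
categories with a requested effect plus (optionally) density. λ is
solved by convex optimisation on a 4000-point candidate pool so that
the tilted frail mean minus the nonfrail mean equals the requested
shift exactly in expectation — sector confounding included. Sampling is
batched rejection with a cap of 10 000 attempts per participant; an
unreachable target (outside the support of the candidate features, or a
diverging λ) raises a generation error instead of looping. Default
planted effects mirror the direction and order of magnitude of the
associations this kind of study reports: emergency centres −400 m,
stadiums −140 m, senior centres −68 m, squares/parks −50 m, shops
+60 m, density +0.003 persons/m².

**Measurements.** Category first, measurements second: the number of
flagged components is drawn within the category's band (robust 0,
prefrail 1–2, frail 3–5), the flagged subset uniformly, and each
measurement uniformly on the flagged or unflagged side of its cut-off
with a guard band (e.g. gait U(0.30, 0.79) flagged, U(0.81, 1.40)
otherwise), so classifier recovery of the planted category is exact by
construction. Age is truncated normal (mean 74, sd 6, support 65–95);
BMI is lognormal with median 29 (σ = 0.18), matching the high-BMI
profile typical of older Chilean cohorts. A mechanistic model (frailty
emerging from measurements) would be more realistic but untestable; the
conditional construction gives a sharp, testable recovery property.

**What passing tests show.** The synthetic study validates the
*machinery*: that the classifier, scoring engine, exposure builder and
statistics recover exactly the structure the generator planted, at the
stated sample sizes. It does not validate any claim about real cities:
real residence patterns, facility layouts and measurement noise are all
richer than this model (no geocoding error, no missing data, no
measurement-device variance, convex sectors, isotropic distances).

## Statistics

- **Wilson score intervals** (no continuity correction) for all
  proportions. The Wilson form reproduces the published cohort table's
  printed intervals exactly at one-decimal rounding for (64, 251),
  (10, 64), (16, 64) and (19, 187); one printed interval in that table
  (the women's gender row, 187/251 → printed 68.7–79.4 vs Wilson
  68.8–79.5) disagrees in the last digit and is treated as a typo in
  the source rather than evidence for a different method.
- **Yates chi-square** from the closed 2×2 form
  N(|ad−bc|−N/2)²/(r₁r₂c₁c₂), with the continuity term floored at zero;
  cross-checked against `scipy.stats.chi2_contingency(correction=True)`.
  The per-cluster comparison in the cluster-distribution table spans
  three frailty categories (a 2×3 table, df = 2), where a continuity
  correction has no standard definition; plain Pearson chi-square is
  used there, and Yates whenever the table is 2×2.
- **Test gate.** "ANOVA or Kruskal–Wallis as appropriate" is
  operationalised as: ANOVA (with Tukey HSD pairwise p-values from the
  studentized range distribution) if every group passes Shapiro–Wilk at
  α = 0.05 and has n ≥ 3, else Kruskal–Wallis (tie-corrected, with the
  convention H = 0, p = 1 when all values are identical). The gate can
  be forced either way (`policy="anova" | "kw"`). Tukey follow-up
  accompanies ANOVA only; no pairwise follow-up after Kruskal–Wallis,
  and no multiple-testing correction across the nine compared
  variables.
- Significance is two-sided α = 0.05 throughout.

## Simulation design for calibration checks

The size of the comparison driver is checked with 2000 null replicates
(all planted effects zero; city fixed, cohort redrawn per replicate):
each of the nine variables must reject at a rate inside [0.03, 0.07].
Power is probed with 100 replicates of a −400 m emergency-centre shift
at n = 251. At this effect size the three-group omnibus noncentrality
is ≈ 6.7, so attainable power is ≈ 0.63–0.70 — a useful reference point
when interpreting single-study significance patterns at these sample
sizes. Replicates keep the city fixed and redraw only the cohort, which
isolates sampling variability of residents from the (fixed) facility
layout, and keeps the full 2000-replicate run around a minute on one
CPU.

## Degenerate inputs and tie-breaks

- Sector boundary points are assigned to the lowest containing sector
  id (deterministic, order-independent).
- Residences outside every sector get a sentinel cluster id (−1), stay
  in distance/density comparisons, and are excluded from
  cluster-stratified tables, with a logged warning and no silent drops.
- A cluster×category table with a zero margin (e.g. a single-cluster
  city) reports p = NaN rather than failing.
- Raster sampling errors name the offending point positions; points
  exactly on the east/north extent edge belong to the last cell.
- ASC grids round-trip NODATA (−9999) as NaN; coordinates and cell
  values survive write/read to 1e-9.

## Known limitations

- Euclidean distances only: no road network, travel time or impedance.
- Sectors are convex Voronoi cells; real districts are not.
- The density surface is smooth and unimodal per sector.
- The exposure pipeline assumes planar, pre-projected coordinates.
- Kruskal–Wallis pairwise follow-ups are deliberately out of scope.
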