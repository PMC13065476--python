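# Methods

## Model overview and assumptions

The package implements a two-stage spatial multi-criteria evaluation
(SMCE) for *Mytilus edulis* longline aquaculture. Stage 1 answers "where
is cultivation feasible at all?" with Boolean exclusion masks; stage 2
answers "how suitable are the feasible areas?" with fuzzy (continuous)
physiological response scores combined by a weighted sum. The split
matters: the suitability index averages conditions over time, so a
lethal-but-brief event (a heat spike) would be invisible to it — hence
extreme events are handled as hard exclusions, not as score penalties.

Assumptions baked into the design:

- environmental layers are regular lat/lon grids, cell-center registered,
  latitude ascending, longitude in [−180, 180); no projection engine is
  provided and all areas are spherical (R = 6371 km,
  A = R²·Δλ·(sin φ_top − sin φ_bot) per cell). Whether an equal-area
  projection would be preferable for the km² accounting is moot at the
  accuracies involved; spherical areas are exact on the sphere and make
  the full-ring band identity testable to 1e-6.
- feasibility is evaluated on the fine grid (0.05°-like, matching the
  daily SST product it emulates); suitability on the coarse grid
  (0.25°-like). The Boolean product is carried to the coarse grid by
  strict-majority aggregation (> 50 % of valid fine cells feasible); this
  is an unbiased default and is configurable, since no single convention
  is canonical for Boolean coarsening.
- missing data (NaN) propagate: a coarse cell is missing only if all
  contributing fine cells are missing; missing days break heat-spike
  runs; cells missing in any factor have missing SI.

## Feasibility criteria

| criterion | rule | default |
|---|---|---|
| heat spike | count of maximal runs of consecutive days with SST strictly above the threshold, run length ≥ 3 d; any episode over the record excludes the cell | > 25 °C, ≥ 3 d, occurrence < 1 |
| depth | depth_min ≤ depth ≤ depth_max, both inclusive; land/missing excluded | 5–100 m |
| current | record-max rule: no daily-mean speed may reach the limit | < 1 m s⁻¹ |

Decisions taken where the rules admit readings:

- "above 25 °C" is strict (>): "above" as printed; an equality would
  shift run boundaries. Configurable.
- episodes are *maximal* runs — a 7-day exceedance is one episode, not
  five overlapping windows — because an episode denotes an event and the
  occurrence criterion counts events.
- the current criterion ("1 m s⁻¹ daily average") is read as a record-max
  rule: a single extreme day endangers longline gear, mirroring the logic
  of the heat-spike exclusion. The alternative period-mean reading is
  available as `current_rule="period_mean"`.
- depth bounds are inclusive at both ends ("5–100 m" as a closed range).

## Suitability scoring

Factor responses and their sources in the code
(`musselsite.suitability`):

- **SST** — CTMI-style curve, T_opt = 15.8 °C, T_max = 30 °C, c = 0.393.
  Its supremum is exactly 1 (at T_opt) and its infimum 0 (at T_max), so
  min–max standardization is the identity and is not applied.
- **CHL** — Michaelis–Menten, X_K = 1.06 mg m⁻³; range [0, 1).
- **SSS** — quartic fit (dry-weight/wet-weight ratio vs salinity);
  negative values are clamped to 0 (a negative response proportion is
  physiologically meaningless), then min–max standardized over the
  evaluation domain, default [0, 40]. The extrema used for
  standardization are found by a 20 001-point grid search refined with
  the exact critical points (roots of the derivative), so the scale is
  accurate to machine precision rather than grid pitch. Note the fitted
  quartic peaks near S ≈ 21 and declines toward fully marine salinities;
  the published coefficients are implemented as printed.
- **SPM** — quadratic fit (carbon absorption efficiency vs suspended
  inorganic sediment), clamped and standardized over [0, 100] g m⁻³;
  monotone non-increasing, reaching 0 at the quadratic's positive root
  (~54 g m⁻³).

The standardization domains are recorded in every run's summary; they are
a genuine free choice (the source material standardizes "from 0 to 1"
without stating the domain) and both bracket the values the respective
fits were built from.

Scores are computed per time slice at each factor's native cadence (daily
SST and CHL, monthly SSS and SPM — no temporal interpolation across
cadences) and then averaged: score-then-average, never average-then-score,
because the response curves are nonlinear. Fine-grid mean scores are then
coarsened by area-weighted block means, which conserve the area-weighted
domain mean to 1e-9.

Weights come from an AHP principal eigenvector (power iteration to 1e-12,
λ_max by Rayleigh average), CI = (λ_max − n)/(n − 1), CR = CI/RI with
Saaty's RI table (RI(4) = 0.90); CR ≥ 0.1 is flagged inconsistent. The
expert judgment matrix behind the published weights is not public, so the
default configuration ships the perfectly consistent matrix reconstructed
from the weight ratios w_i/w_j (CR = 0 by construction, weights recovered
to 1e-9); a user-supplied judgment matrix is accepted everywhere a weight
vector is.

SI classification uses five bands, left-closed right-open except the last
([0.8, 1.0] closed), so every SI in [0, 1] maps to exactly one class.

## Auxiliary layers

Accessibility is 100 × (steps with wave height strictly under 1.5 m) /
(valid steps); "under" is strict, so a tie at exactly 1.5 m counts as
inaccessible. Maximum wave uses the record maximum against a 6 m limit.
Distance to port is great-circle (haversine) to the nearest port point in
nautical miles (1 nm = 1.852 km), with no land-avoiding routing — it is a
screening layer, not a voyage planner.

## Climate delta

The SI under a climate scenario replaces only the SST factor score,
computed from a single decadal-mean SST raster (no temporal averaging);
CHL/SSS/SPM scores are held fixed. Both the reference and the projected
SI use this same decadal pathway so the percent change
100 × (Proj − Ref)/Ref compares like with like; cells with Ref = 0 are
reported missing rather than infinite. The feasibility mask is *not*
updated under projection: heat-spike detection needs daily data, which a
decadal mean cannot provide. With all cells below T_opt in both decades
and warming toward it, the delta is non-negative everywhere — the
mechanism behind the poleward "improving suitability" pattern, and a
property test.

## Co-location ranking

Farm polygons are summarized by the mean of raster cells whose centers
fall inside the polygon (cell-center rasterization; area-weighted
fractional coverage would be a refinement, not a correction, at 0.25°
with multi-cell farms). A polygon smaller than a cell falls back to the
value at the cell center nearest its centroid. Farms are ranked by
descending mean SI, ties by descending accessibility, remaining ties by
id — a deterministic total order; farms with no valid SI cells (fully
infeasible) sort last and are flagged. Polygon areas use the spherical
line-integral formula, exact for lat/lon-aligned rectangles.

## Synthetic scenario generator

The generator (`musselsite.synthetic`) emulates the *structure* of the
real forcing layers, not their physics:

- **SST**: zonal-mean field cooling poleward (default 14 °C at the
  southern edge, −0.75 °C per °lat), a sinusoidal seasonal cycle
  (±5 °C), and AR(1) day-to-day noise (sd 0.6 °C, ρ 0.7), independent
  across cells — the simplest structure that exercises run-length logic
  without spatial artifacts. Defaults keep the unforced field well below
  25 °C (≈ 6 σ margin), so heat spikes exist only where injected.
- **heat-spike injection** forces exactly N disjoint maximal runs of the
  requested duration at 26.5 °C inside a region box, each bracketed by
  two sub-threshold days; the feasibility detector recovers the injected
  count exactly, which is tested over 100 random configurations.
- **CHL / SPM**: offshore baseline plus exponential coastal enrichment
  (land is a missing-cell strip along the eastern grid edge; "distance
  from coast" is zonal distance to it), a spring-bloom modulation for
  CHL, river-outflow hotspots for SPM, lognormal noise.
- **SSS**: marine baseline 35 with a low-salinity sub-basin at salinity 3
  (a Bothnian-Bay-like brackish end-member where the clamped salinity
  response is 0) — this reproduces the expected pattern that the brackish
  basin receives lower SI than fully marine water.
- **current**: background 0.2 m s⁻¹ with a channel box peaking at
  1.3 m s⁻¹ (deliberately above the 1 m s⁻¹ limit).
- **waves**: 3-hourly by default (hourly optional) — the accessibility
  metric is a fraction of time steps and is cadence-invariant in
  expectation; mean 1 m, Poisson storms (10 yr⁻¹) with a 2-day
  grow-and-decay envelope of amplitude 2.5 m.
- **bathymetry**: a 50 m shelf ramping to a 2000 m basin offshore, land
  along the eastern edge — producing a feasible depth band and a
  deep exclusion.
- **decadal SST**: the noise-free annual-mean field, and a projection
  warmed by 0.5 °C at the south edge increasing by 0.25 °C per °lat
  poleward (stronger high-latitude warming).
- **farms/ports**: disjoint rectangular farm polygons on a jittered slot
  grid with statuses drawn from {production, accepted, planned}; ports
  just seaward of the coast.

One global seed expands into fixed per-variable child seeds
(`default_rng([seed, offset])`), so adding a variable never perturbs the
others and a fixed config + seed is byte-reproducible.

The default scenario spans 4° × 4° (80 × 80 fine cells, 16 × 16 coarse)
over 5 years — large enough that every pipeline stage has non-trivial
spatial structure, small enough that the full run takes seconds. What
passing tests on this scenario demonstrate: correct mask logic, exact
episode recovery, correct score/weight arithmetic, deterministic
orchestration. What they do not demonstrate: realism of any real sea
(no advection, no spatially correlated weather, no tides, no real
coastline), so absolute areas and SI values from synthetic runs are
illustrative only.

## Numerical choices and degenerate inputs

- Power iteration tolerance 1e-12, ≤ 10 000 iterations; CI and CR are
  floored at 0 to absorb rounding on consistent matrices.
- Regridding: bilinear/nearest via `scipy.interpolate
  .RegularGridInterpolator`; values extrapolated at the outermost
  half-cell are clipped to physical ranges by callers where relevant
  (e.g. current speed ≥ 0).
- Empty feasible set: the pipeline completes, the SI map is all-missing,
  class areas are 0, the ranking has all farms flagged unrankable.
- An all-missing cell in any stack yields a missing mean score, never 0.
- File formats: gridded data as classic NetCDF (xarray/scipy backend),
  vectors as GeoJSON, tables as UTF-8 CSV. Write-then-read round-trips
  preserve values bit-for-bit.

## Known limitations

- No socio-economic layer, carrying-capacity, or spat-supply modelling.
- Single species parameterization ships (*M. edulis*); all parameters are
  configurable but no alternative defaults (e.g. *M. galloprovincialis*)
  are provided.
- Geographic coordinates only; polygon areas assume lat/lon-aligned,
  small polygons.
- The climatological marine-heatwave definition (90th percentile of a
  30-year baseline) is deliberately not implemented; the heat-spike
  criterion is species-specific.
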