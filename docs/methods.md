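# Methods

This note documents the models, numerical choices and limitations of
`reefdrift` the way a maintainer would want them recorded: what is computed,
under which assumptions, and what the tests do and do not demonstrate.

## Kinematics and integration

Particles are passive surface tracers in a 2-D velocity field on geographic
coordinates.  Velocities in m/s convert to angular rates with the spherical
approximation (Earth radius R = 6 371 000 m):

    dλ/dt = u / (R·π/180 · cos φ),    dφ/dt = v / (R·π/180)

No projection is applied; at the study latitudes (24–29° N) the cos φ factor
is the only metric correction that matters for 21-day tracks.

The integrator is classical fixed-step RK4 with Δt = 200 s (default),
sampling the interpolated field at the usual four substeps.  The scheme
choice is a package decision — validated two ways:

* **Solid-body rotation oracle** — in an analytic rotation field (period
  2 days) the orbit closes to ~7×10⁻¹⁰ degrees after one period at
  Δt = 200 s.  The fourth-order convergence factor measured between
  Δt = 200 s and 100 s is 15.9999937; the exact value for the discrete RK4
  rotation map is 16·(1 − O((ωΔt)²)), marginally *below* the idealized 16,
  so the test brackets the factor two-sidedly (15.999–16.001), which
  excludes third-order (8×) and fifth-order (32×) behaviour by wide margins.
  The measurement runs in 80-bit extended precision against an
  arbitrary-precision analytic endpoint because at float64 the ~10⁻¹¹-degree
  truncation errors are contaminated at the 10⁻⁵ relative level by roundoff.
* **Small-step Euler cross-check** — a 21-day track in the eddy-free
  synthetic jet agrees between RK4 at 200 s and forward Euler at 1 s to
  3×10⁻⁷ degrees.

The single-particle research integrator (`integrate_path`) accumulates
positions with Kahan compensation and accepts a dtype argument
(`np.longdouble` for oracle-grade runs); the ensemble kernel uses ordinary
float64, whose roundoff is irrelevant at trajectory scale.

**Interpolation** is bilinear in lon/lat and linear in time.  Land nodes get
zero weight and the remaining bilinear weights are renormalized; a cell with
four land nodes yields zero velocity.  This prevents spurious onshore
advection near coasts at the cost of slightly damping alongshore speed in
the last half-cell.  The interpolation scheme of the original tracking
systems this emulates is generally unstated; bilinear/linear is the
conventional choice and the Euler cross-check bounds its interaction with
the integrator.

## Land, settlement and particle fate

* **Cell semantics.** A position's "cell" is its nearest grid node.  The
  water mask is rasterized from the coastline polygons with a half-cell
  erosion: a node is land only if it lies inside the coastline eroded by
  half a grid spacing.  Subgrid islets therefore do not block flow on coarse
  grids, and nodes that fall numerically on a polygon vertex count as water.
  Settlement and seeding always use the exact polygons, never the raster.
* **Beaching.** Non-destination coastline is non-absorbing.  A step whose
  endpoint lands on a land node is replaced by a coast-parallel slip: the
  zonal-only displacement component is tried, then the meridional-only one,
  else the particle holds position.  On a raster coastline this is the
  projection of the displacement onto the coast tangent.  Particles are thus
  conserved for the connectivity census (an absorbing variant would be a
  one-line change in the kernel but is not exposed; losses to open-boundary
  exit are reported separately).
* **Settlement.** Default semantics are *continuous absorption*: the first
  position inside any destination-area polygon after the competency delay
  (default 0 days) terminates the particle.  Because every area is also a
  source, self-settlement at step 0 would be universal; it is suppressed by
  requiring at least one intermediate position outside the natal polygon.
  A *snapshot* mode instead evaluates membership once, at the end of the
  pelagic larval duration — the two modes bracket the ambiguity in how
  "arrival within 21 days" can be operationalized, and both are exposed
  (`TrackingParams.settlement_mode`).
* **Exit.** Leaving the grid bounding box (including at an RK4 substep) is a
  terminal `exited` status, reported separately rather than folded into
  loss-by-drifting, since open-boundary fate is genuinely unknown.
* **Accounting.** `released = drifting + settled + exited` holds exactly for
  every run; connectivity rows satisfy `Σⱼ P[i][j] + loss[i] = 1` to
  10⁻¹² (it is exact rational arithmetic divided once).

Positions are recorded at the output sampling interval (default every 18
steps = hourly) plus at release and termination; the maximum-latitude field
used for LDP classification is the maximum over recorded samples.  The
tracking kernel is numba-compiled and per-particle; settlement tests use a
cell-candidate raster as prefilter and exact ray-casting point-in-polygon
for candidates, so polygon membership is never approximated by the raster.

## Synthetic ocean

The generator emulates the statistical setting of a reef lagoon upstream of
a poleward western boundary current, with three superposed components:

| parameter | default | unit | rationale |
|---|---|---|---|
| jet peak speed | 1.2 | m/s | boundary-current core speed |
| jet half-width | 40 (lagoon) / 60 (regional) | km | Gaussian e-folding half-width of the current |
| eddy count | 6 | – | a few mesoscale features in the domain at a time |
| eddy amplitude | 0.35 | m/s | mesoscale eddy swirl speed |
| eddy radius | 40 | km | solid-body (Rankine) core radius |
| eddy drift speed | 0.15 | m/s | slow translation along the jet axis |
| tidal amplitude | 0.25 | m/s | rotary tide, spatially uniform |
| tidal period | 12.42 | h | M2 |

The jet contributes `peak · exp(−(d/L)²)` along the local tangent of a
configurable axis polyline (d = distance to the axis).  Eddies are rigid
Rankine vortices (linear core, 1/r tail with a Gaussian envelope) whose
centres drift along the axis and re-enter at its start; placement and
polarity are drawn once from the seeded RNG, so identical config + seed
gives a bit-identical field.  The tide is a spatially uniform clockwise
rotary oscillation.  No divergence-free guarantee is claimed or needed —
the tracker never assumes one; fields are only required to be finite on
water.

Two grid presets are used: the lagoon close-up at 0.01° with hourly output,
and the regional domain (122–129° E, 23.5–29° N) at 0.05°/hourly.  Fields
are written as CF NetCDF (classic format via xarray's scipy backend).

**What the generator does not emulate**: realistic bathymetric steering,
stratification or vertical shear, wind-driven variability, coastally
trapped waves, or the observed spectra of a data-assimilative regional
model.  Green tests on synthetic fields therefore validate the *machinery*
(integration, settlement logic, censuses, conservation) and the qualitative
topology of transport (jet entrainment, channel routing), not quantitative
connectivity for the real lagoon — that requires feeding `read_field` with
real model output.

## Fixture domains

`sekisei_like` reproduces the topology of the study region with stylized
coordinates (not digitized coastlines): 145 circular coastal areas of
radius 0.006° in 18 numbered groups around four islands — a large western
island (exterior groups 1, 2, 4, 5, 11 plus lagoon-facing interior group
3), a large eastern island (exterior 7, 8, 9, 12, 13 plus interior 10), a
small central island with interior groups 16 (south coast) and 17 (north
coast) flanked by the `west_channel` and `east_channel` gates, and a small
northern islet carrying group 6.  Interior lagoon patch reefs (groups 14,
15, 18) sit on tiny synthetic islets so every area is coastal.  The interior
group set is exactly {3, 10, 14, 15, 16, 17, 18}.  Per-area-per-night
release count defaults to 25 so the full protocol (145 areas × 8 nights)
releases exactly 29,000 particles; the published total this emulates is an
order-of-magnitude statement, so the per-night count is a package choice.

`channel` (two areas joined by a strait with one gate) and `two_island`
(two areas, no gates) support deterministic flux tests.

## Release phenology

Nightly releases at 20:00 local, starting the first night after the May
full moon.  The four season start dates (2012-05-07, 2013-05-24,
2014-05-15, 2015-05-03) are shipped as configuration rather than computed
from an ephemeris — four known dates do not justify an astronomy
dependency.  The interior-lagoon experiment uses 7 nightly releases, the
downstream experiment 14; both track each particle for 21 days.

## Analysis products

* **Connectivity matrix** — area-level settlement records are summed into
  groups before normalization (group-level normalization; the area-level
  alternative is recoverable from `settlement.csv`).  Source groups with no
  released particles are excluded from rows with a warning.
* **Exterior-source ranking** — exterior groups sorted by arrival
  probability into the destination group, ties broken by ascending group
  number.  The pipeline picks the destination as the interior group with
  the largest settled inflow — computed, not hard-wired.
* **Reachability PDF** — time-integrated mode bins every recorded position
  within the larval duration; snapshot mode bins one position per particle
  (day-PLD position for drifters, terminal position otherwise).
  Normalization is per selected source filter, with the filter recorded in
  the output metadata; density units are deg⁻².  Grid default: the velocity
  grid's resolution.
* **LDP classification** — strictly greater than the 26.5° N threshold;
  a maximum of exactly 26.5° N does not qualify.  The maximum is taken over
  the tracked duration (positions are only recorded within it).
* **Route classification** — trajectory segments are walked in time order;
  the first gate segment *properly* crossed (strict two-sided orientation
  test; touches do not count) wins, and if one trajectory segment crosses
  two gates the one hit earlier along the segment wins.

## Determinism and output

Every stochastic choice (eddy placement/polarity, seeding positions) flows
from explicit integer seeds; per-year seeds are derived from the experiment
seed by a fixed affine map.  Reruns of `run_experiment` with identical
config and seed produce byte-identical CSV outputs (verified by test).
Trajectory positions are stored as float32 (~1 m quantization, far below
any physical fidelity of the model); trajectory CSVs are thinned (default
every 10th particle) to keep bundles small, while settlement records are
always complete.

## Problem sizes

The test suite runs the full protocol census — 29,000 particles for 21 days
at Δt = 200 s — in well under a minute on one CPU (numba kernel; ~10⁹
velocity evaluations).  The acceptance script uses the full 145-area domain
and protocol timing with reduced per-night counts (4 060 particles per
experiment), which keeps the whole reproduction run at a few minutes while
leaving every computation path identical to the full-scale run.

## Known limitations

* Pure advection: no sub-grid diffusion / random walk, no larval behaviour,
  buoyancy, mortality or vertical migration.  Adding a stochastic
  displacement term would be straightforward in the kernel but changes the
  determinism contract.
* 2-D surface only; no vertical structure or sigma-coordinate handling.
* The axis-decomposed slip is first-order in coastline orientation; strongly
  oblique coasts on coarse grids bias slip direction toward grid axes.
* Settlement is purely geometric (polygon entry); no habitat suitability or
  settlement competency window beyond the minimum-delay parameter.
* Synthetic fields are kinematic constructions, not dynamical solutions;
  see "What the generator does not emulate" above.
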