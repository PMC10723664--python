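# Methods

This note documents the models and numerical choices behind `turtletrack`,
what the synthetic generator does and does not emulate, and the design
decisions taken where the procedure left room.

## Scope and data model

The pipeline infers movement structure of benthic-stage green turtles from
Fastloc-GPS (snapshot GPS) fixes. The atom is a fix: tag id, UTC timestamp,
longitude/latitude (WGS84), the number of satellites in the position
solution, and the solution's residual-error score. Raw per-animal tracking
data from the Bermuda study this pipeline is modeled on were never deposited,
so the package carries two kinds of inputs: (a) synthetic tracks with known
ground truth, produced by `turtletrack.synthetic`, and (b) the per-animal
summary tables of the published study, packaged as CSV under
`turtletrack/data` and used by the reporting layer. Every aggregate the
report prints is recomputed from per-row values at run time; nothing is
cached.

All timestamps are stored UTC. Diel computations use a fixed UTC−4 offset
(Atlantic Standard Time; Bermuda observes no daylight saving in the sense
relevant here — the fixed offset matches how the tag duty cycle and the
behavioral hour bins are defined). Projected computations use a local
spherical azimuthal equidistant projection centered on the data centroid
(Earth radius 6371 km); at platform scale (~50 km) area distortion is below
0.1%, which is negligible against the 2-decimal-place area reporting.

## Quality control

A fix is discarded when it has fewer than 6 satellites **or** a residual
above 30 (boundary values retained). The two-clause rule is read
disjunctively: keeping 5-satellite fixes would defeat the <100 m accuracy
such screening targets. The conjunctive reading is available via
`QCConfig(rule="and")`.

The speed filter is an iterative great-circle rule: an interior fix whose
required inbound *and* outbound speeds both exceed `vmax` (default 10 km/h,
roughly 4× the mean migratory travel rate, generous for residency movement)
is removed, and the pass repeats until stable. Endpoints have only one
adjacent speed, so they are removed only when it exceeds `3·vmax`. A cluster
of adjacent outliers displaced in the *same* direction can survive the
interior rule; in practice the quality rule catches nearly all of these
because low-quality solutions carry high residuals. The first 24 h after
release are excluded from residence-area analyses (handling effects), and
tracks are split into bursts at transmission gaps longer than 3 days.

## Re-discretization and phase segmentation

Fixes are resampled to a regular 12-h series by linear interpolation along
the chord between bracketing fixes; epochs inside gaps longer than 3 days
are not emitted, and epochs with no observed fix within 1 h are flagged
interpolated.

Segmentation fits a piecewise-stationary Gaussian model: within a segment,
x and y are independent normals with their own mean and variance. For each
candidate segment count K the exact optimum of the contrast
`Σ_segments Σ_coords m·log σ̂²` is found by dynamic programming over the
precomputed segment-cost table (O(K·n²); exact, no heuristic search), with a
minimum segment length of 40 epochs (20 days at 12-h spacing). A variance
floor of `max(1e-12, 1e-6 × series variance)` guards the classic unbounded-
likelihood degeneracy of zero-variance segments without distorting costs at
data scale.

K is selected in two steps:

1. **Curvature rule.** The contrast curve J(1..Kmax) is trimmed to its
   strictly decreasing prefix — once the minimum-length constraint makes
   extra segments infeasible to place well, J stops improving and the tail
   would otherwise fake a curvature spike — then normalized so J̃(1)=Keff,
   J̃(Keff)=1, and the largest K whose second difference exceeds 0.75 is
   taken (1 if none).
2. **Evidence guard.** Each accepted increment K−1→K must additionally
   reduce the contrast by at least `5·log n` (an extra segment adds two
   means, two variances, and one breakpoint). The curvature rule alone is
   noisy when the 20-day minimum caps Kmax at a handful of segments; the
   guard removes its false splits on stationary series while leaving real
   shifts (whose contrast drops are orders of magnitude larger) untouched.

With these defaults, a planted 10σ mean shift in a 200-epoch series is
recovered within ±2 epochs in 20/20 seeded replicates, stationary noise
yields K=1 in 20/20, and the DP optimum matches exhaustive enumeration on
every tested short series. Segmentation is deliberately segmentation-only
(no shared recurring states): the goal is detecting shifts, not classifying
them.

Phase distinctness uses the Bhattacharyya coefficient `BC = Σ √(p_a·p_b)`
of the two phases' utilization distributions evaluated on a shared grid,
each masked to its own 95% isopleth and renormalized; phases with BC < 0.5
are distinct. Unmasked BC on Gaussian samples matches the closed form
`exp(−Δ²/(8(s²+h²)))` to within 0.03 at n=2000.

## Kernel home ranges

The utilization distribution is a bivariate Gaussian kernel density on a
50 m grid (binned counts convolved with the kernel, truncation 6σ), padded
3h beyond the data bounding box and normalized to integrate to exactly 1.
The L% isopleth is the smallest-mass cell set: cells ranked by density,
cumulative mass thresholded at L, polygonized as the union of cell squares.
Contiguity is judged by 8-connectivity of the selected cells. The 50 m cell
resolves the study's 0.003–0.2 km² use areas with tens to thousands of
cells; against the Gaussian closed forms the 50% isopleth area is within 5%
and enclosed mass within 0.02.

The smoothing parameter follows the contiguity rule: start from the
reference value `h₀ = σ·n^(−1/6)` with `σ = √((var_x+var_y)/2)`, multiply
by 0.95 per step ("gradually reduced"), and stop at the smallest h whose
95% isopleth is still a single connected region. Shrinking stops at one
grid cell, below which the contiguity test is meaningless. When even h₀
yields a fragmented 95% region (genuinely multimodal ranges — e.g. distinct
foraging and resting clusters several hundred meters apart), the rule cannot
be satisfied; h₀ is returned with a flag rather than inflating h without
bound.

The total residence area is the minimum convex polygon of all retained
fixes. The asymptote check computes cumulative MCP area by tracking day and
flags an asymptote when the final 10% of days adds less than 5% of the
final area.

## Distinct use areas

The published workflow identified discrete concentrations of fixes by
visual inspection and manual digitization; this package replaces that step
with density-connected clustering (DBSCAN, radius 100 m, 15 neighbors, in
projected meters). The 100 m radius reflects Fastloc accuracy for ≥6
satellite solutions (50% of fixes within ~18 m, 95% within ~70 m); each
cluster's polygon is its convex hull buffered by half the radius.

Classification: clusters with a seagrass majority are foraging areas
(`foraging_f`) — on-meadow foraging and on-meadow resting are not separable
from fix data, so the label covers the combined f/r use regardless of
photoperiod; off-meadow clusters split into day (`rest_day_r`) and night
(`rest_night_r`) resting by majority photoperiod (solar elevation of the
sun's center at the fix position and time, standard approximate solar
position algorithm). A cluster with ≥80% cool-season fixes whose mean depth
is at least 1.5× the animal's foraging-area depth is overridden to
`cool_refuge_c`; when no foraging cluster exists to supply the baseline the
shallowest cluster stands in. Season follows the month rule: warm May–Nov,
cool Dec–Apr, anchored to the ~20 °C threshold in the buoy record.

Occupancy histograms report, for each even local hour, the fraction of
fixes lying on seagrass, with a bimodality statistic (mean occupancy at
06/08/18/20 h over mean at 10/12/14 h) that exceeds 1 under the
morning/evening foraging schedule. Temperature correlates use the buoy
series as the temperature proxy, match each fix to the nearest record
within 24 h, aggregate to one distance/temperature pair per day, and report
Pearson r.

Binned dive summaries use the tag convention of n edges defining n+1 bins
with an open top bin. Weighted means take bin midpoints (bottom bin: half
its upper edge; open bin: lower edge plus half the preceding bin's width)
weighted by time-in-bin proportions. The published tag settings include a
bin-edge list with a repeated value; the package accepts any strictly
increasing edge list and does not attempt to resolve that ambiguity.

## Migration metrics

Departure is the first fix outside the platform boundary followed by no
return inside it (a looping excursion that comes back is a foray, not a
departure). Pre-departure forays are maximal runs of fixes outside the
residency 95% isopleth within the 30 days before departure, lasting 4–15
days, that end with a return or lead directly into departure.

Path metrics are computed on the pelagic portion (per-fix depth > 200 m
where available, else outside the platform polygon): total great-circle
path distance; path bearing as the circular mean of per-step initial
bearings with circular SD (the per-track ±SD values below 1° in the source
tables imply a per-step statistic, not an endpoint bearing); travel rate
per step, excluding steps with gaps over 12 h so transmission dropouts do
not bias rates; day/night rates by the photoperiod of the step midpoint,
compared with Welch's two-sample test; and the 3-position straightness
index — for each consecutive triple (A,B,C), `d(A,C)/(d(A,B)+d(B,C))`,
averaged along the path after dropping zero-length steps. Surface current
speed is `√(u²+v²)` of pre-extracted per-fix components; no ocean-model
retrieval is performed.

## Detectability

Per animal, detectability is `100 × captures / sets` for entrapment-net
sets made within the presumed foraging area during the residency period.
The study-level mean and sample SD (n−1) cover animals with ≥12 months of
residency at a single sampling site; rates enter the summary at full
precision and are half-up rounded only for display. When sets must be
assigned geometrically, a set counts if it falls inside the foraging-area
polygon buffered by the net enclosure radius (~100 m, configurable).

## Synthetic generator

The generator is a discrete-time biased random walk (Ornstein–Uhlenbeck-
like attraction) at 30-minute steps: each step pulls the animal toward the
active center with configurable strength plus isotropic Gaussian noise
(default 30 m/step). The active center follows a diel schedule in local
time (default: foraging 06–09 and 17–20, day rest 10–16, night rest
otherwise), overridden to a deeper refuge center while simulated water
temperature is below 20 °C, and overridden to directed migration
(von Mises step headings, concentration 10, 2.3 km/h toward 232.5°) after a
configured departure date. Water temperature is a day-of-year sinusoid with
mean 23.9 °C and amplitude 7.75 °C peaking in mid-August (the observed
seasonal envelope of the emulated system), with optional AR(1) noise.
Default geometry places resting centers ~700–800 m from the foraging meadow
and the refuge ~3 km away, matching the reported mean separations.

Observation follows the tag duty cycle: one candidate fix per even GMT
hour, retained with probability 0.85; position error is Gaussian with sd
15 m for good solutions (satellite count ≥6, probability 0.9) and 75 m for
poor ones; with probability 0.02 a fix is displaced 10 km as an outlier.
The residual model is synthetic — the source material gives no residual
distribution — and is constructed so screening has known operating
characteristics: clean fixes draw residuals in [0,15], while low-quality or
outlier fixes draw residuals above 30 with probability 0.95. Measured over
seeded replicates, the combined quality+speed screen removes ≥96% of
planted errant fixes with no false positives.

What the generator does **not** emulate: positional autocorrelation of the
error process, tide- or weather-driven behavior, current-advected drift,
3-D dive trajectories (only per-role depth histograms), gradual habitat
change, or individual behavioral variation beyond the configured schedule.
Passing recovery tests therefore demonstrates algorithmic correctness under
the stated movement model, not performance on any particular real tag
deployment.

## Problem sizes and determinism

Test and acceptance problem sizes are chosen to exercise each estimator at
the scale where its asymptotics hold while keeping runs quick: KDE oracles
use 10,000 points, BC oracles 2,000 per phase, segmentation recovery 200
epochs × 20 replicates, enumeration equivalence series of length ≤60 with a
10-epoch minimum, pipeline recovery 30–60-day tracks × 10–20 replicates.
All randomness flows through explicit integer seeds (`numpy.random.
default_rng`); the acceptance script derives per-replicate seeds from its
`--seed` argument and is deterministic given it.

## Known limitations

- The contiguity smoothing rule is undefined for genuinely multimodal
  ranges; the flagged fallback to h₀ is a convention, not an inference.
- Per-coordinate Gaussian segmentation is rotation-invariant only for
  near-isotropic within-phase scatter; strongly anisotropic residency
  clouds could make breakpoint placement axis-dependent.
- DBSCAN cluster shape depends on the 100 m radius; very elongated transit
  corridors can bridge adjacent clusters at high fix density.
- The detectability estimator assumes constant residency and constant
  catchability across the residency period, as the source procedure does.
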