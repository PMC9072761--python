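# Methods

This note documents the model's structure, the choices made where the
design was genuinely open, and what the scaled test worlds do and do not
demonstrate.

## Model overview

A run advances three coupled subsystems on a shared clock (`dt`, default
1 s), for as many ticks as a vehicle at the speed limit would need to
traverse the loop road five times — so landscapes at different speed limits
see the same number of nominal pass-bys. Per tick: traffic steps; receiver
noise exposures and detection radii refresh; searchers move and scan; trail
and station detections are booked.

## Acoustics

**Source spectra.** Vehicles radiate 1/3-octave-band levels (dB re 20 µPa,
referenced to 1 m) on the nominal band centres 50–10000 Hz. Per band, the
level follows a least-squares power law in speed, L(v) = a + b·log₁₀v,
fitted at the reference speeds 6.7, 11.2 and 24.6 m/s. Below the slowest
reference speed the law is clamped: idling and accelerating engine noise is
not modelled, so stopped or crawling vehicles radiate like a 6.7 m/s
pass-by. Above the fastest reference speed the law is likewise clamped.

**Propagation.** Received band level =
L_src − A_div − A_atm − A_gr.

* *Divergence*: because source spectra are referenced to a measurement at
  1 m, the default is plain spherical spreading, A_div = 20·log₁₀(d/1 m).
  The ISO 9613-2 free-field convention (+11 dB, for sound-power sources) is
  available via `divergence="iso"`. Distances under 1 m clamp to 1 m.
* *Atmospheric absorption* (ISO 9613-1): oxygen and nitrogen relaxation
  plus the classical term, as a function of temperature (°C), relative
  humidity (%) and pressure. Pressure is configured in bar (the model's
  parameter vocabulary) and converted to kPa internally against the
  101.325 kPa reference.
* *Ground effect* (ISO 9613-2): source/middle/receiver region
  decomposition with the standard's per-octave-band functions; each
  1/3-octave band uses its containing octave band's formula. The ground
  factor is G = 1 − hardness (the model's `ground-hardness` runs 0 =
  porous to 1 = hard; ISO's G runs the other way). A single G describes
  the whole landscape.
* Barriers, foliage and meteorological refraction are out of scope.

**A-weighting** uses the IEC 61672 closed form, normalised to exactly 0 dB
at 1 kHz. Decibel sums are energetic: 10·log₁₀Σ10^(L/10), computed with a
max-shift for numerical safety.

**Propagation tables.** Each run's per-receiver levels come from a
precomputed table of received overall A-level on a (distance × speed) grid:
50 log-spaced distance nodes per decade from 1 m to 100 km, and 1 m/s speed
steps whose endpoints coincide exactly with the power-law clamp limits (so
interpolation never mixes a clamped with an unclamped node). Lookup is
bilinear in (log₁₀ d, v) and clamps outside the grid. At this resolution
off-node queries agree with direct computation to within ~0.1 dB over the
audible range. Vehicles whose table level falls 16 dB below ambient are
skipped when summing exposure (each contributes < 0.1 dB).

## Detection radius

The model reduces masking to a single law: a stimulus detectable at radius
r₀ when the total level equals the quiet ambient L₀ is detectable at

r(L) = r₀ · 10^(−(L−L₀)/20),

capped at r₀ (sound below ambient confers no extra range). This constant
source-level assumption excludes the Lombard effect. The law reproduces the
calibration triple 50 m → 28.1 m → 15.8 m at 25/30/35 dBA and halves the
listening area πr² per +3.01 dB.

## Traffic

The loop road is the landscape's columns stacked end to end: length
nx·ny + (ny−1) metres (120,700 m for the 400 × 301 default, unwrapped
coordinate ±60,350 m), of which the central ±ny·cell/2 segment runs along
the landscape. Vehicles spawn at distinct integer-metre patches at their
maximum speed: the limit plus a centred Gamma deviate (shape 2, scale
SD/√2 — mean 0, standard deviation `speed-limit-SD`, permitting both slower
and faster vehicles; shape is configurable). Speeds are floored at 1 m/s so
every vehicle eventually clears the landscape segment.

The nominal `num-vehicles` (per hour) converts to a loop population as
count = round(VPH·L/(v_limit·3600)) — the steady-state flux of that many
vehicles at the limit equals the requested passage rate; a `count` mode
accepts the population directly. Overtaking is resolved in
ascending-position order against the leader's pre-move position: a vehicle
that would catch its leader this tick passes unchanged with probability
`vpass-probability`, otherwise it brakes to (leader speed − `excess-brake`)
and is held 1 m behind. Realized VPH is the median of hourly counts of
crossings into the landscape-adjacent segment (non-overlapping 3600 s
windows, trailing partial window dropped; shorter runs use a single
whole-run rate).

## Landscape and agents

Cells are 10 m squares; the road occupies the x = 0 edge and the trail the
central row. The resource count follows the transect-encounter relation
N = area/(2·r₀·D) where D is `meters-moved-per-resource`. Placement is
uniform without replacement, or — in noise-constrained mode — weighted by
the reciprocal of each column's expected traffic-noise excess above ambient
(steady traffic at the speed limit, floored at 0.1 dB so quiet columns get
large finite weight; a flat field reduces to uniform sampling).

Searchers are correlated random walks (Gaussian heading increments, SD
`search-turn-sd`) that scan after moving: first contacts within the
noiseless radius are booked as counterfactual detections, first contacts
within the current radius as actual detections, and an idle searcher locks
onto the nearest in-range unvisited resource and pursues it to the cell
centre. Memory is per searcher and append-only; a resource is never
revisited by the same searcher but may be visited by several. Boundaries
reflect: the heading is mirrored about the violated edge plus a Gaussian
jitter, redrawn until the step stays inside (the landscape cannot wrap —
noise is asymmetric across it).

Trail cells and stations listen with radius `human-mult` × `basePercept`,
noise-scaled per tick at their own positions; searchers, humans and
stations share one receiver height. Station tallies are episode-based: a
counterfactual episode opens when a searcher enters the noiseless radius,
and at most one actual detection is tallied per episode (the first tick
also inside the degraded radius). Tallying once per episode keeps the
noiseless count a strict upper bound even when the degraded radius
fluctuates tick to tick; re-entry after leaving counts as a new episode.
The "birdable probability" is the landscape fraction within the human
radius of the trail — computed noiselessly at initialisation and from the
final tick's noise field during a run.

## Reproducibility

The run seed spawns three independent substreams (traffic, searcher
movement, resource placement), so a run with noise bookkeeping disabled is
trajectory-identical to one with zero vehicles under the same seed, and
repeated runs are bit-identical.

## Defaults

The model's parameter vocabulary fixes names and units but not values; the
package defaults are: ambient 25 dBA; 20 °C, 60 % RH, 1.01325 bar; ground
hardness 0.5; source height 0.5 m, receiver height 1.5 m; `basePercept`
50 m; `human-mult` 2; `meters-moved-per-resource` 50 m; 10 searchers at
0.5 m/s with 30° turn SD; speed limit 60 kph (SD 10), acceleration 2 m/s²,
pass probability 0.5, excess brake 5 kph; five stations at semigeometric
trail offsets 125/250/500/1000/2000 m on the 4 km reference landscape
(scaled proportionally on smaller worlds). The demonstration grid overrides
the varied factors and slaves `basePercept` = 50·10^(−(A−25)/20) m and
`meters-moved-per-resource` = 50·10^((A−25)/20) m to ambient A, holding
resource density 1/(2rD) constant.

## Scaled test worlds

The behavioural test suites run on a 100 × 75-cell world (1 km × 750 m,
7,574 m loop; ~2,300 ticks at 60 kph) with 3–5 replicate seeds — sizes
chosen so the full suite runs in minutes while every directional effect
(masking vs traffic volume, distance-from-road recovery, emergent
congestion) is still well resolved. Two statistics need deliberate scenario
design:

* *Trail audibility* is heavy-tailed per searcher (it hinges on whether a
  path wanders along the trail), so VPH comparisons average 30 searchers ×
  5 seeds.
* The *boundary visit artifact* — edge-adjacent resources faring better
  than interior ones — requires searchers that actually reach and reflect
  off edges many times per run; the artifact scenario therefore uses faster
  (2 m/s), straighter (10° turn SD) foragers. In this implementation the
  artifact expresses itself in the detection *success fraction* (visits per
  noiseless-radius contact): reflected paths parallel the edges and re-pass
  the same resources, raising conversion under masking, while the *raw*
  visit density at edges stays depressed because an edge resource's
  detection disc is clipped in half. Several alternative reflection rules
  (incident-heading rejection, turn-in-place, wall-sliding, tangent-
  continuing release) were evaluated and none produced a raw-density excess
  at the wall; the specular-plus-jitter rule was retained.

## What the synthetic inputs do not show

The vehicle spectra are constructed (log-frequency Gaussian bumps with
25 dB/decade speed growth, motorcycle pinned 10 dBA above the sedan), not
measured: absolute exposure levels and distance decay rates are plausible
but uncalibrated, so simulation outputs support relative comparisons across
traffic scenarios, not prediction of field sound levels. Resources call
continuously — intermittent signalling, signal-specific masked audibility,
the Lombard effect, vehicle acceleration noise, and non-acoustic road
effects (mortality, avoidance) are all outside the model.
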