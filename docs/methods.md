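# Methods

This note documents the models implemented in `gdea`, the defaults and why
they were chosen, what the simulated observers do and do not emulate, and
the numerical choices a maintainer would want to know.

## 1. Genotype and genetic algorithm (`gdea.genome`)

A chromosome is (DS, ORI, BINA): DS ∈ [0, 4.25]° codes deviation from
mirror symmetry as a displacement distance, ORI ∈ [0, 90]° the axis
orientation, BINA ∈ {−1, +1} a sign such that ORI × BINA is the rendered
axis angle. The 0–90 encoding exists so that genotype distance is
perceptually meaningful (0 and 90 are vertical and horizontal, no
wrap-around aliasing); for the same reason the fitness-estimation embedding
treats ORI linearly, not circularly, and ignores BINA.

Populations hold exactly 48 members. Per generation:

- **Selection**: tournaments of size 3 drawn without replacement; the two
  fittest sampled members become parents. Fitness ties break toward the
  earlier population index so runs are exactly reproducible.
- **Crossover**: per-gene arithmetic blend `w·p1 + (1−w)·p2` with
  independent `w ~ U(0,1)` per continuous gene. Blending suits continuous
  genes and keeps offspring inside the parents' range; BINA, being binary,
  is inherited from a uniformly chosen parent.
- **Mutation**: with probability 0.1 per continuous gene, add Gaussian
  noise with σ = 5 % of the gene range (0.2125° for DS, 4.5° for ORI);
  out-of-range values are reflected back into the interval, which avoids
  the boundary pile-up that clamping would create. BINA flips with
  probability 0.05. These magnitudes are package defaults (exposed in
  `GeneticParams`): small enough to preserve continuous variation, large
  enough to keep the gene pool from collapsing.
- **Replacement**: 16 tournaments produce 32 offspring (2 per parent pair)
  that replace the 32 least-fit members; the 16 fittest survive unchanged
  (implicit elitism), so the population size is constant.

Survivors keep their fitness only as input to the replacement step; every
generation all 32 unpresented members (survivors included) receive fresh
estimates, so provenance counts are always 16 presented / 32 estimated.

## 2. Phenotype construction (`gdea.stimulus`)

Coordinates are degrees of visual angle, origin at screen centre, x
rightward, y upward; pixel conversion (1024 px / 34° ≈ 30.1 px/°) and the
y-flip happen only at rasterization. The disk diameter is 8.5° (a quarter
of the screen width); dot diameters are the six even steps 0.9, 1.02, …,
1.5° ("size" is read as diameter), one dot of each size per side.

A template places six dot centres uniformly in one half-disk — with margins
so the whole dot stays inside the disk and does not cross the midline
(centre at least one dot-radius from the axis) — and mirrors them.
`apply_ds` then displaces each of the 12 dots by exactly DS degrees in an
independent uniform direction. Directions violating a constraint are
resampled up to 100 times; if none is feasible the displacement for that
dot is shrunk to the largest feasible step along the best sampled
direction. Resampling the direction (rather than the template position)
preserves the distance semantics of the gene. Templates are re-randomized
on every realization, so identical genotypes practically never produce
identical phenotypes. Dots may overlap each other; only disk and midline
constraints apply.

`measured_asymmetry` validates the construction: reflect the dot centres
about the axis, optimally pair original and reflected dots of equal
diameter (Hungarian assignment per size class) and return half the mean
pair distance. It is zero iff the pattern is perfectly symmetric and grows
with DS through the mid-range. **Caveat**: the metric saturates and then
declines near the gene maximum (~0.78° mean at DS = 2 vs ~0.39° at DS = 4),
because the disk and midline constraints concentrate extreme displacements
near the axis-end corner regions, where the optimal matching pairs dots
cheaply. This is intrinsic to any exact-distance displacement rule under
these constraints (pure rejection sampling behaves the same), so monotone
behaviour should only be expected below saturation.

Trial layouts place the four disks at nominal quadrant centres (±8.5°,
±6.0°) — chosen so the disks fit a 4:3 screen without overlapping — with
independent per-axis jitter up to 0.33°, which prevents the four stimuli
from forming one large symmetric grouping.

## 3. Simulated observers (`gdea.observer`)

Synthetic gaze is sampled at 120 Hz for 5 s (600 samples). The 1 s
pre-trial fixation cross is modelled only as the gaze starting at screen
centre. Every planned fixation is placed at the target disk centre plus
Gaussian jitter (σ = 0.15°); samples within a fixation get a small ocular
tremor (σ = 0.02°, well inside the 0.5° dispersion radius); transitions are
30 ms linearly interpolated saccade samples, generated (not blanked) so the
fixation filter is exercised on realistic input.

All policies first scan the four disks in random order (dwell ≈ N(400 ms,
60 ms), floored at 150 ms) and form one noisy internal estimate of each
pattern's DS: `max(0, DS + N(0, σ))` with σ = 0.2°. The perceptual noise
models the limits of symmetry discrimination; a noiseless observer would
make the symmetry and zero-tolerance preference policies identical.

- **symmetry**: after the scan, fixate the minimum-estimate disk until the
  trial ends (broken into 250–500 ms fixations at re-jittered locations).
- **preference**: utility `u_i = −max(0, est_i − tolerance)` with tolerance
  0.5°; remaining dwell time is split across disks proportionally to
  `softmax(u_i / 0.25)` and executed in shuffled ~400 ms chunks, which
  produces revisits. Patterns within tolerance of perfect symmetry are
  equally liked — the minimal mechanism for convergence to *imperfect*
  symmetry. The `strict` condition is this policy with tolerance 0.
- **freeview**: dwell chunks target disks uniformly at random, independent
  of the stimuli. Real free-viewing participants are heterogeneous (some
  spontaneously prefer symmetry, some do the opposite); this single
  stand-in reproduces the group-level null, not individual differences.
- **control**: no gaze at all; the engine assigns i.i.d. U(0,1) fitness
  (`control_fitness_mode="uniform"`), so reproduction continues as pure
  genetic drift. The original control procedure is not documented beyond
  "no feedback"; uniform noise is the choice that keeps the replacement
  machinery running, and a `"zero"` mode is available for comparison.

Recorded gaze can replace simulation: `read_gaze_file` parses delimited
tables (`t_ms,x_deg,y_deg`), preserving irregular timestamps and marking
dropout rows invalid.

## 4. Oculometrics (`gdea.oculometrics`)

Fixation detection is greedy I-DT: grow a window while the dispersion span
`(max Δx + max Δy)` stays within 2 × radius (the configured 0.5° "radius"
is read as ±0.5° about the centroid), emit when the minimum duration
(100 ms) is covered, otherwise slide the start forward. Invalid samples
split windows. The implementation is verified against a brute-force
maximal-window oracle. Duration comparisons use a 1 ns tolerance because
twelve 120 Hz intervals only approximate 100 ms in floating point.

Fixations belong to the AOI whose 8.5° disk contains their centroid;
fixations outside all disks are discarded. Dwell sums fixation durations;
first-fixation ranks record the order of first entry; a revisit is a
re-entry after fixating a different AOI. Scores combine these with weights
0.6 / 0.2 / 0.2 (dwell share / linear first-fixation bonus (5−rank)/4 /
revisit share). The published predecessor of this scoring is not public;
the weights are declared package defaults, exposed in `FitnessWeights`.
Response latency is deliberately not part of the score.

Fitness estimation for unpresented genotypes uses Shepard interpolation:
inverse-squared-distance weights in (DS/4.25, ORI/90) space with a 1e-6
distance floor; coincident genotypes return the presented fitness exactly,
and estimates are clipped to the presented min/max, so the step never
extrapolates. A global linear least-squares variant
(`estimation_method="linear"`) is kept for sensitivity analysis; Shepard is
the default because a plane fit through 16 anchors in 2-D imposes a global
trend the data need not have, while inverse-distance weighting honours
local proximity and degrades gracefully.

## 5. Engine and reproducibility (`gdea.engine`)

One master seed spawns named `numpy` SeedSequence substreams per run
(population init, stimulus realization, gaze, genetics), so modules can be
driven independently in tests and results are bit-for-bit reproducible.
Interleaved and blocked run arrangements execute the same per-run
substreams in different orders and therefore yield identical per-run
results by construction — mirroring the original finding that arrangement
did not matter. The presented 16 are sampled uniformly without replacement
each generation; fitness-biased presentation was deliberately not used, to
avoid confounding the selection pressure already exerted by replacement.
Results persist as a JSON manifest plus one CSV population snapshot per
generation, with floats serialized via `repr` for exact round-tripping.

## 6. Analysis (`gdea.analysis`)

The unit of analysis is the per-generation population median (mean of the
middle pair for even counts) of DS and ORI. A participant's two runs are
averaged element-wise. DS change is the mean of the final five generations'
medians minus generation 1's. Trends are ordinary least-squares slopes over
1-based generation ranges (first half 1–10, second half 11–20); the
original mixed ANOVAs with sphericity corrections apply to human group data
and are intentionally not reproduced — on simulated data, per-participant
slopes and descriptive summaries carry the same qualitative content.
`calibrate_null_slopes` runs extra no-observer participants to quantify the
slope spread that pure drift produces, which is the package's yardstick for
"no trend".

## 7. What the simulation shows — and does not

Passing tests demonstrate that the *algorithmic* claims hold under the
stated observer models: drift-only control and freeview trajectories stay
flat on average, symmetry-seeking observers drive strong early convergence,
and looser tolerance leaves the population at higher final DS. They do not
validate the observer models against human gaze: real scanpaths, saliency
effects, fatigue, blinks and smooth pursuit are not modelled, and the
freeview policy deliberately averages away individual differences.

Two behaviours of the implemented system are worth flagging. First, the
asymmetry metric's saturation near the DS maximum (§2). Second, with soft
Gaussian perceptual noise the symmetry condition approaches its floor
asymptotically: the generations 11–20 slope is ~18× flatter than in
generations 1–10 (−0.009 vs −0.17 °/generation) but remains a small
systematic decline rather than an exact plateau; a hard discrimination
threshold would be needed to freeze the population completely.

## 8. Problem sizes

Defaults reproduce the study scale: 48 genotypes, 16 presented per
generation in four trials, 20 generations, two runs per participant, 18
participants per condition, 5 s trials at 120 Hz. A full condition
simulates ≈ 1.7 M gaze samples and runs in well under a minute on one CPU;
examples use fewer participants only to keep their runtime to seconds, and
state so inline.
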