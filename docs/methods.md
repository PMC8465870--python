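# Methods

This note records the models, parameter choices and numerical decisions
behind `swaysom`, and what the synthetic cohort does and does not show
about real recordings.

## Inverted-pendulum sway projection

Quiet stance is modelled as a pendulum pivoting at the ground: the centre
of mass (COM) stays at a fixed distance `L` from the ground, and the
measured specific-force direction gives the instantaneous inclination.
`project_sway` computes the resultant `R`, the direction cosines, and the
ground displacements `d_x = −L cos α`, `d_y = −L cos β`, `H = L cos γ` per
sample. Two conservation laws hold at every sample and are enforced by
tests: `cos²α + cos²β + cos²γ = 1` and `d_x² + d_y² + H² = L²`. Because
only the *direction* of the resultant matters, the projection is invariant
to the acceleration unit; accelerations are kept in g until displacement,
velocity (cm/s) and acceleration (cm/s²) are derived by differencing the
projected path.

`L` is not measurable from the accelerometer alone; the default is the
standard anthropometric COM fraction 0.53 × body height, overridable per
subject in the cohort manifest. The worn device's axis convention is also
a configuration (`axis_map`, default x→ML, y→AP, z→vertical).

## Filtering and kinematics

Raw counts are divided by the sensitivity scale factor (16,384 LSB/g for
±2 g) and lowpass-filtered with a single causal forward pass of a
2nd-order Butterworth at 4 Hz. The filter state is initialised to steady
state at the first sample, so a constant input is reproduced exactly and
the projection sees no startup transient; a zero-phase forward–backward
variant is available by flag but off by default because it doubles the
effective order. Velocity and acceleration use first differences with
`T = 1/fs`; the undefined leading entries are dropped (D spans 1..N, V
spans 2..N, A spans 3..N) and each RMS normalises by its own valid length,
rather than zero-padding, which would bias the RMS downward. Each 30 s
condition window is treated independently.

## Synthetic cohort

The real cohort (23 healthy adults, 4 mCTSIB conditions × 30 s at 60 Hz)
is not public. The generator emulates the statistical structure the
analysis depends on:

- **Sway path:** Gaussian white noise through a 2nd-order Butterworth
  lowpass at the condition's sway bandwidth (default 1 Hz, below the 4 Hz
  analysis cutoff), then mean-removed, re-anchored so the first sample is
  exactly zero via a slow (τ = 2 s) exponential correction, and rescaled
  so the sample RMS equals the condition target exactly. The zero anchor
  makes the downstream first-sample offset removal a no-op on clean data,
  so RMS targets are recoverable end-to-end; the price is a path mean that
  is only approximately zero.
- **Condition effect sizes (cm RMS):** AP 0.40/0.70/0.90/1.40 and
  ML 0.30/0.45/0.32/0.60 for conditions 1–4. Sway grows as sensory input
  is removed, the AP effect exceeds the ML effect, and ML barely moves
  between the eyes-open conditions (1 and 3). The magnitudes are plausible
  stand-ins for lower-back COM sway, not calibrated values.
- **Subject traits:** each subject carries a lognormal amplitude factor
  (σ = 0.40) per direction and a lognormal sway-bandwidth factor (σ = 0.7,
  capped at 2.5 Hz), both shared across conditions. The amplitude spread
  matches normative between-subject sway-RMS variability (CVs of 30–50 %)
  and creates the class overlap that keeps healthy-cohort clustering
  "poor"; the tempo spread decouples RMS position from RMS velocity while
  keeping velocity and acceleration collinear — the correlation structure
  the screening stage assumes. With tighter spreads the synthetic
  conditions become nearly perfectly separable and all three RMS features
  collapse onto one axis, neither of which resembles real cohorts.
- **Sensor model:** additive Gaussian noise (default 0.0005 g, a MEMS
  accelerometer with its onboard lowpass enabled), gain to LSB, rounding,
  clipping to [−2 g·16384, 2 g·16384 − 1]. At substantially higher noise
  the double-differenced acceleration channel is dominated by its noise
  floor, which real recordings of this design do not show.
- **Seeding:** one master seed; every stream (heights, per-subject traits,
  per-recording path and noise) is keyed by a documented
  `SeedSequence([master, counter...])` scheme, so any subject/condition
  subset regenerates identically.

Quasi-static inversion (R = 1 g) makes the generator analytically
invertible: path → acceleration → projection round-trips to machine
precision before noise and quantization. The generator does **not**
simulate forward dynamics, gyroscope channels, postural drift, or
non-stationarity within a window; passing tests therefore demonstrate the
pipeline's correctness and its qualitative behaviour under realistic
amplitude/overlap structure, not performance on any particular clinical
population.

## Feature screening

Candidate features are the RMS position, velocity and acceleration per
direction, pooled across conditions within a direction (giving one sample
per feature per direction). Each pooled sample is Shapiro–Wilk tested
(α = 0.05; a zero-variance sample is reported non-normal with a warning);
a pair uses Pearson's r only if both members pass, Kendall τ-b otherwise.
Pairs at |coef| ≥ 0.85 are resolved by dropping the later-listed member:
candidate order encodes the kinematic derivative ladder, so of a collinear
pair the lower-order, more directly measured quantity survives. The rule
is deterministic and idempotent. (A drop rule based on mean absolute
correlation to the remaining features was considered and rejected: under
the correlation pattern typical of these features — velocity slightly more
correlated with position than acceleration is — it discards velocity,
which is the wrong member to lose.) With cohort defaults the velocity–
acceleration correlation sits around the threshold, so occasional draws
retain all three features; the pipeline handles either width.

## Kohonen map

- **Grid:** 10×10 hexagonal by default, unit spacing, link (hop-count)
  neighbourhood distance; rectangular topology available for tests.
- **Competition:** best-matching unit by Euclidean distance, ties to the
  lowest neuron index.
- **Batch training** (the pipeline mode): per epoch every neuron's weight
  becomes the mean of all samples whose BMU lies within the current radius
  (step-function kernel); neurons with empty neighbourhoods keep their
  weights. The radius shrinks linearly from 3 to 1 over the first half of
  the 1000 iterations (the ordering phase) and then stays at 1. Updates
  are order-independent by construction and the seed only drives
  initialisation.
- **Sequential training** is provided for completeness with the classic
  per-sample rule `W ← W + μ·h·(X − W)`, Gaussian neighbourhood `h`, and
  linear decay of μ and σ to their floors.
- **Initialisation:** small uniform random weights in [0, 0.01] (seeded);
  a principal-axes linear span is available by flag.
- **Feature scaling:** features are z-scored over the 46-row pair matrix
  before training (flag to disable); position (cm) and velocity (cm/s)
  otherwise contribute unequally to the Euclidean metric.
- Quantization error is provably non-increasing per epoch only at radius
  0, where each epoch is exactly a Lloyd step; at the pipeline's floor
  radius of 1 the neighbourhood smoothing can raise it transiently (a few
  percent on fixed fixtures). Tests assert monotonicity at radius 0.

## Two-level clustering

Prototypes are the active neurons (≥ 1 hit); each prototype vector is the
centroid of its member data points (the raw neuron weight is available by
flag). K-means is Lloyd's algorithm from k-means++ seeding, Euclidean
metric, empty clusters re-seeded at the farthest point, 10 restarts keeping
the lowest within-cluster sum of squares. The Davies–Bouldin index uses
σ = RMS member-to-centroid distance (the natural scalar "standard
deviation" of a vector-valued cluster) and the standard maximum over all
j ≠ i. The K-scan covers 2..30 (clipped with a warning when fewer
prototypes exist, since all-singleton clusterings degenerate the DB ratio);
candidate K are the local minima of the mean DB curve (endpoints one-sided,
global minimum always included) and the candidate with the highest mean
F-measure on the reference pair wins, ties to the smaller K. The K chosen
on the reference pair (1 vs 4), in the AP direction when present, is shared
by all pairs and directions — the protocol's cluster-count decision is made
once.

## External evaluation

Clusters are labelled by their majority condition (ties to the lower
condition index). Purity is the cluster-size-weighted majority fraction;
precision, recall and F are unweighted cluster averages (their defining
sums carry no size weights), with per-cluster recall = majority count /
that class's dataset total. For the balanced 23 + 23 design the collapse
of everything into one cluster floors purity and average precision at 0.5,
and the minimum cluster-averaged recall over assignments into exactly K
non-empty clusters equals 1/K — computed exactly by a dynamic program over
integer cluster compositions (number of members of each class per cluster),
verified against explicit enumeration at small sizes. All four measures
cap at 1, attained by a pure and complete clustering. The repetition
protocol reruns shuffle → SOM → K-means → propagate → measure with
counter-derived seeds (default 30 repetitions) and reports medians and
interquartile ranges; ML vs AP distributions are compared per measure,
pooled over the three condition pairs, with an independent-samples t-test
when both samples pass Shapiro–Wilk and a two-sided Mann–Whitney U
otherwise.

## Problem sizes and determinism

The default protocol (23 subjects, 3 pairs × 2 directions × 30
repetitions, 10×10 map at 1000 iterations, K-scan 2..30 with 10 restarts
and 10 scan repetitions) completes in well under a minute on one CPU core;
the test suite runs the full protocol at these defaults. Every run is
reproducible from (config, master seed): summary CSVs are byte-identical
across reruns.

## Known limitations

- The pendulum projection assumes a fixed `L` and quasi-static resultant;
  fast transients violate both.
- The generator's band-limited-noise sway has no physiological feedback
  dynamics; only RMS amplitude/tempo structure is emulated.
- The minimum-recall bound machinery supports two classes (the pairwise
  protocol's case), not general multi-class designs.
- No multiple-testing correction is applied across the three condition
  pairs or four measures, matching the protocol it implements.
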