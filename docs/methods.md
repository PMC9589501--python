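# Methods

`stressfeat` post-processes finite-element (FE) analyses of a cat forepaw
landing on a force platform.  Instead of comparing stress heatmaps or maximum
stress values between landing conditions, it treats every bone's full
node-stress distribution as a candidate *feature* and asks which bones'
stress distributions carry enough information to recognise the landing
condition.  The package implements the complete post-processing chain —
ground-reaction-force (GRF) waveform conditioning and principal-component
reconstruction, node-stress structuring, binary particle-swarm (BPSO)
wrapper feature selection, and multi-classifier pattern recognition — plus a
seeded synthetic generator that stands in for the CT-derived FE model and
the live recordings, so the whole chain runs and is testable at desk scale.

## GRF conditioning and principal waveforms

Force-platform trials (three axes, 1 kHz by default) are conditioned the
standard way for gait data:

* **Contact detection** — first sample whose vertical force strictly exceeds
  10 N (strict inequality, no debounce).
* **Low-pass filtering** — fourth-order Butterworth, 50 Hz cut-off, applied
  forward and backward (zero phase lag) with reflective padding of
  `3 * order` samples.  The forward-backward pass squares the magnitude
  response; tests check a 200 Hz tone against the closed-form magnitude with
  the bilinear-transform frequency warping of the digital design.
* **Phase normalisation** — the landing-phase segment (contact to the end of
  the configured phase window) is linearly interpolated onto 101 points
  representing 0–100 % of the landing phase.  The landing phase properly
  ends at maximum elbow flexion; deriving that event from motion capture is
  out of scope, so the event phase is an *input* (config or a companion
  angle series), not something the package estimates.

The trial-by-phase matrix of each axis is decomposed by mean-centred PCA
(no variance scaling — all phase points share units of newtons; each
component's largest-magnitude entry is made positive).  The first component
dominates the variance of these bell-shaped pulses, so every trial is
reconstructed as `mean + score_1 * component_1` and the unweighted mean of
the reconstructions is reported as the principal GRF.  By Eckart–Young this
rank-1 reconstruction is optimal in the Frobenius sense, which the tests
verify against an SVD-truncation oracle.  Whether the per-trial average
should be weighted is not documented for the original procedure; the
unweighted mean is used and stated here.  Axis names are treated as opaque
strings throughout because source descriptions of the horizontal axes
conflict.

## Node-stress structuring

An FE export assigns one scalar stress (assumed von Mises equivalent
stress, MPa — the stress measure is not standardised, so files label the
column generically as `stress_mpa`) to each mesh node of each bone; 12 bones
around the paw pad (MP1–MP5, PP2–PP5, DP2/DP3/DP5) with ~3,300 nodes each
are the default universe.  Structuring operations:

* **Ranking** — stresses descending, ties broken by node id ascending, so
  every derived object is a deterministic function of the field.
* **Pareto distribution** — 30 equal-width bins spanning [min, max],
  enumerated from the highest range downward; a constant bone collapses to
  one bin.
* **Percentile bands** — stress ranges of the last 50/80/90/95 % of nodes
  (the low end of the descending ranking, with the band's high end at
  descending rank `ceil((1-f)·n)+1`) and of the first 5 % (top
  `ceil(0.05·n)` nodes).  A small epsilon guards the ceilings against
  floating-point error.
* **Top-k subsets** — the k highest-stress nodes *per bone* (cases
  all/2000/1000/500/200).  Per-bone rather than pooled selection keeps every
  bone represented in every case, which per-bone recognition requires.

## Feature matrices

The original study's per-dataset instance construction is not publicly
documented, so the package reconstructs it from the node-stress fields.
Three constructions are provided:

* **`sampled`** (default for analysis): for each condition, each bone's
  subset stresses enter the instance rows in an independent seeded random
  order — equivalently, every instance draws one node stress per bone
  without replacement.  Per-bone marginals are exactly the subset values;
  columns are independent within a condition.
* **`rank_aligned`**: instance r holds every bone's rank-r stress.  This is
  the natural "no extra FE runs" construction, and it is retained for rank
  profile inspection — but it is *degenerate for multi-feature
  classification*: sorted columns are comonotone, so each condition's
  instances lie on a smooth one-dimensional order-statistic curve, and any
  two columns separate two independent curves almost perfectly regardless of
  planted effects.  During development this showed up as ~zero hold-out
  error for arbitrary bone pairs, which makes a wrapper objective unable to
  prefer genuinely informative bones.  The `sampled` construction keeps the
  same values while restoring the between-column independence that wrapper
  selection and multi-feature classification assume.
* **`mean` / `max`**: one instance per replicate sample with a per-bone
  scalar summary, for conventional summary-level comparisons.

Matrices built from dense node sets are thinned deterministically (evenly
spaced rows, at most 200 instances per condition by default) before
selection and cross-validation; 200 per condition is the scale at which the
package's calibration properties are defined, and it keeps the full
12 × 3,300-node demonstration within desk-scale runtimes.  The caps are
ordinary config fields (`select_max_instances`, `recognition_max_instances`).

## BPSO wrapper feature selection

Particles move in [0, 1]^d (d = 12 bone features) under the global-best PSO
update `V <- wV + c1 r1 (Pbest - X) + c2 r2 (Gbest - X)`, `X <- clip(X + V)`,
with w = 0.9, c1 = c2 = 2, 100 iterations, and positions decoded to masks by
thresholding at 0.5 (a coordinate >= 0.5 selects the feature).  Because this
parameterisation is divergent without bounds, velocities are clamped
(default 0.6) and positions clipped to the unit cube.  The swarm size is not
part of the canonical parameterisation; 20 particles is common practice.

Mask fitness is `alpha * E_R + (1 - alpha) * |R|/|S|` with alpha = 0.9,
where `E_R` is the hold-out error of a KNN learner (k = 5, Euclidean
distance, per-column standardisation fitted on the training portion,
majority vote with a distance-weighted tie-break) trained on the masked
columns, `|R|` the selected count and `|S|` the total.  The empty mask
scores the worst value 1.0 by convention.  One stratified hold-out split
(fraction 0.2) is drawn per run seed and reused for every evaluation in
that run — a per-evaluation split would make the objective stochastic and
non-comparable across particles.  Fitness is memoised per mask (the
objective is deterministic within a run), which is what keeps 20 seeds x
100 iterations x 20 particles cheap.  Personal and global bests update only
on strict improvement, so the global-best trace is nonincreasing — asserted
on every pipeline run.

Single runs are split-dependent, so the final selection is a consensus: the
three features selected most often across 20 independent seeded runs, with
count ties broken by mean stress magnitude (descending) and then label
order.  A documented curiosity of the canonical 0.5-threshold decoding
example is that its index list contains five entries while its prose counts
six; the index list is what the rule produces and is treated as
authoritative.

`BpsoFeatureSelector` wraps the multi-seed procedure as a scikit-learn
selector (`fit`, `get_support`, `transform`), so it composes with sklearn
pipelines; `run_bpso`/`consensus_features` expose the same functionality
functionally.

## Pattern recognition

Each bone is classified *on its own feature column* by three families under
seeded, stratified 10-fold cross-validation (per-fold standardisation fitted
on the training fold): KNN (k = 5), an RBF SVM (C = 1, inverse-dimension
kernel width), and a single-hidden-layer neural network (10 logistic units,
at most 500 epochs, seeded initialisation) — canonical small-data settings,
all exposed in config.  Accuracies are aggregated by arithmetic mean per
(comparison, case) and per comparison; how the original aggregation combined
its three models is undocumented, so the mean is used and labelled as such.
"Stand-out" features are operationalised as accuracy at least 0.10 above the
within-(comparison, case, family) median (configurable).

## Synthetic data: what it emulates and what it does not

Node stresses are log-normal per bone: median `base_scale` (0.1 MPa) and
log-sd `tail_shape` (1.4).  The log-normal reproduces the Pareto-style
descending stress profiles of FE exports — a light bulk and a heavy tail —
and `tail_shape = 1.4` puts >= 50 % of the summed stress in the top decile
of nodes, matching the observation that only 5–10 % of nodes carry large
stresses.  This heavy tail implies a wider min–max range than a real bone's
printed range (the calibration targets the order of magnitude, roughly
0.001–20 MPa around a 0.1 MPa median, not exact endpoints).

**Each condition draws an independent latent field per bone** (each landing
height is its own FE solve).  This is a deliberate structural choice: with
*any* strongly correlated latent fields, the two conditions' empirical
quantile profiles are smooth displacements of each other; nearest
neighbours of every instance then alternate between classes and null
classification is biased systematically *below* chance (measured down to
~0.23 during development).  Independent fields make the null exchangeable
and chance-centred, which the calibration tests require.  Planted effects
multiply designated bones by a shift under condition B — either globally or
only on the top decile of B's own ranking (`tail` locus), reflecting that
condition information concentrates in high-stress nodes.  Replicate samples
within a condition share that condition's latent field and apply unit-mean
multiplicative log-normal noise per node (CV 0.1 by default).  Because
replicates share the solve, they are not independent draws: rank-aligned or
sampled matrices should be built from one replicate per condition (the
default), and location tests of the null operate on node values, not on
replicate means.

GRF trials are a quiet baseline followed by a beta-shaped pulse per axis
(`t^p (1-t)^q`, p = 2, q = 3, normalised to unit peak — rising faster than
decaying), with default peaks (15, 25, 120) N for (x, y, z): a ~4.3 kg cat
landing at two to three body weights of vertical force.  `height_factor`
scales amplitudes as `sqrt(h / 1 m)` (impact velocity scaling); per-trial
log-normal amplitude factors with CV `trial_noise_cv` (default 0.05) plus
mild shape jitter provide trial-to-trial variation, so the sample CV of
vertical peaks equals the configured CV.  The generator does not emulate
force oscillations, sensor noise floors, double peaks, or kinematics.

Passing tests on these synthetics show that the *pipeline machinery* is
correct and well-calibrated (null at chance, planted effects recovered,
accuracy gradient across node subsets); they do not show that real paw
stress fields are log-normal or that real effect sizes match the planted
ones.

## Demonstration configuration

Two landing-height comparisons, five node-subset cases.  Planted tail-locus
effects: 0.8 m vs 1.0 m shifts MP4/PP2 by 1.5 and MP3/PP3 by 1.3; 1.0 m vs
1.2 m shifts the same bones by 1.25/1.15.  The weaker second comparison
mirrors the finding that the lower pair of heights is the more recognisable
one.  Per-stage seeds derive from the master seed by a counter scheme over
`numpy.random.SeedSequence` and are recorded in the run manifest, so any
stage can be replayed in isolation; a rerun with the same configuration is
byte-identical apart from wall-clock timings in the manifest.

## Numerical choices and degenerate inputs

* Ranking ties: node id ascending; consensus count ties: magnitude then
  label order; Pbest/Gbest: strict improvement, first-found among equals.
* Constant stress vectors: one degenerate Pareto bin; all percentile bands
  collapse to (c, c).
* Standardisation of a zero-variance column uses unit scale.
* Contact threshold is a strict inequality; a series never crossing it is a
  detectable no-contact condition.
* Interpolation endpoints are preserved exactly; monotone inputs stay
  monotone.
* All validation failures raise `ValidationError` with the offending row,
  trial or parameter named.

## Known limitations

* With all ~3,300 nodes per bone as input, per-bone accuracy sits at chance
  — most nodes are uninformative, so the gradient toward the top-k cases is
  the meaningful signal, and recognisability at top-200 (~0.6–0.75 per
  planted bone at a 1.5 tail shift) is well short of perfect separation.
* The wrapper objective is evaluated on a single hold-out split per run;
  individual runs overfit that split, which is why the multi-seed consensus,
  not any single mask, is the reported selection.
* The synthetic generator models marginal stress distributions only — no
  spatial correlation on the mesh, no biomechanical coupling between bones,
  no load-dependent tail shape.
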