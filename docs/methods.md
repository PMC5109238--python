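# Methods

This note documents the models, estimators and numerical choices behind
`mitoscreen`, and what the synthetic-data generators do and do not emulate.

## Synthetic movies

The movie generator scripts each cell's mitotic phase sequence explicitly
(contiguous half-open `(phase, start, end)` segments) and renders two
channels at a fixed 2D position per cell:

* **Chromatin channel** — an anisotropic Gaussian blob per cell whose size,
  amplitude and eccentricity depend on phase: large/dim in interphase
  (σ = 5 px, amplitude 90 over a background of 10), condensing through
  prophase (3.8 px, 130) to a small bright prometaphase mass (2.6 px, 180),
  an elongated metaphase plate (4.4 × 1.6 px, oriented perpendicular to the
  division axis), and two separated daughter blobs from anaphase onset.
* **Reporter channel** — a flat cytoplasmic disk (radius 15 px, intensity
  60) with a nuclear compartment rendered at `60 × ratio(phase)`. The
  nuclear compartment is the chromatin blob's 1.25 σ ellipse, so it always
  sits strictly inside the segmented chromatin mask: the cytoplasmic ring
  then samples pure cytoplasm and the measured nuclear/cytoplasmic ratio
  tracks the scripted profile monotonically (compressed toward 1 by the
  mask/compartment area ratio, which changes no ordering and no threshold
  crossing).

The default ratio profile is interphase 3.0, prophase 2.6, prometaphase and
metaphase 0.8 (the reporter disperses at nuclear envelope breakdown),
anaphase 0.9 and telophase 2.2. With the segregation-frame ratio at 0.9 the
1.5× reassembly threshold is 1.35, crossed at the first telophase frame —
the scripted reassembly truth is computed from the same profile, so exact
recovery is well defined.

Divisions replace the mother with two daughters offset ±9 px along a
per-cell random axis at the first anaphase frame. Cells are placed by
rejection sampling with a 34 px minimum separation and a 20 px border
margin; an image too small for the requested cell count raises a generation
error. Pixel noise is i.i.d. Gaussian; "10% intensity noise" in the tests
means σ = 16 against a nuclear signal amplitude of ≈160.

*Not emulated:* optics (PSF, photobleaching), cell migration, z-sectioning,
intensity heterogeneity between cells, or tissue-scale morphology. Passing
tests therefore demonstrate the correctness of the measurement logic —
thresholding, ratio rules, transition detection, assignment — not robustness
to microscope-specific artifacts.

## Segmentation and the cytoplasmic ring

The threshold statistic is the local mean over an odd window (default
33 px) minus an offset; the default offset of −20 places the threshold 20
intensity units *above* the local mean, which returns nothing on flat
background and is robust at the default noise levels after a σ = 1 px
Gaussian pre-smooth (intensity summaries always use raw pixels). Components
below 20 px are discarded. Centroids are intensity-weighted, which is
unbiased for symmetric blobs.

Each object's cytoplasmic ring is its mask dilated by a disk of the ring
width (default 3 px) minus *all* nuclear pixels; pixels claimed by several
objects go to the nearest object centroid, ties to the lowest label. Rings
clipped by the image border are flagged rather than silently truncated.

## Phase classification

Ten features per object — area, eccentricity, solidity, perimeter²/area,
chromatin mean/sd/max, gradient mean/sd, and the reporter ratio — feed a
standardised radial-kernel SVM (C = 10, γ = "scale") with probability
estimates. The feature list is a documented design choice: the approach
(texture + shape + reporter partition) matters, not the exact descriptors.
Training requires ≥ 5 examples per class and is deterministic given a seed;
the serialized model carries its feature ordering so a stored classifier can
never be applied to permuted columns. On generated movies the training
labels come from the generator's truth via nearest-centroid matching
(≤ 6 px), standing in for manual annotation.

## Tracking

Consecutive frames are linked by the assignment minimising total centroid
distance among maximum-cardinality matchings whose links stay within the
gating radius (default 15 px). This is solved with the Hungarian algorithm
on a padded matrix in which leaving an object unlinked costs one gating
radius: any feasible link (cost ≤ radius) then always beats two unlinked
ends (cost 2 × radius), so cardinality is maximised first and total distance
second — exactly the brute-force enumeration oracle used in the tests. An
unmatched new object adjacent to a linked predecessor becomes a split (the
mitosis signature; optionally restricted to parents labelled
metaphase/anaphase within their last 3 frames); an unmatched old object
adjacent to a linked successor is recorded as a merge, and merged tracks are
excluded from event statistics. All tie-breaks favour the lowest label, so
results are deterministic given input ordering.

## Event detection

NEBD is the first frame of the first prophase→prometaphase transition;
anaphase onset is the first anaphase-labelled frame after NEBD or the
track's split frame, whichever comes first; the measured interval is their
difference times the frame interval (a required configuration value, never
inferred). Labels are smoothed by a 3-frame majority vote before detection
(ties keep the centre label; disable with `smooth=False`) because a
per-frame classifier can flicker at boundaries. A track whose anaphase
precedes any prometaphase is reported as inconsistent and skipped.
Reassembly is the first post-segregation frame with ratio > 1.5× the
segregation-frame ratio, evaluated on the daughter track when the cell
split; the rule is invariant to common positive rescaling of both channels
because only ratios enter.

## Spindle geometry

The ODR plane is computed in closed form: normal = smallest right singular
vector of the centred points; residual RMS = smallest singular value /√n.
Degeneracy (second singular value ≤ 1e−12 × scale) raises an error. The
normal's sign is canonicalised (largest-magnitude component positive).
α is reported relative to the *plane* (arcsin of |axis·normal|), because
that is the geometrically meaningful quantity for planar vs vertical
divisions; the normal-relative angle is kept as a secondary field. All
axis angles are folded to [0°, 90°] since pole labelling is arbitrary.
Coordinates are micrometres in a right-handed frame; anisotropic z spacing
must be pre-scaled by the reader.

The annotation generator samples true angles from a normal distribution
truncated to [0°, 90°], places five (configurable ≥ 3) surface points in a
5 µm-radius patch around each cell — the scale of an anaphase progenitor's
cell body — with optional bowl curvature (`amplitude × (d/10 µm)²`) and
Gaussian point noise along the normal. With 0.2 µm point noise the median
recovery error over 200 cells is ≈1.9°, essentially all of it from the
plane fit (five points, finite patch); this is the information limit of the
annotation geometry, not estimator slack, and it fluctuates by a few tenths
of a degree between seeds.

Rotation statistics operate on per-interval angles between successive
undirected spindle axes; the default summary is mean velocity (°/min), with
cumulative and max-interval variants also emitted because the field does
not standardise this metric.

## Kinetics

The leaving-fraction estimators assume a steady-state asynchronous
population (uniform cycle positions), a single S-phase window, and an
inter-pulse interval shorter than S (so no cell can enter *and* leave S
between pulses). The inter-pulse interval Ti is caller-supplied, including
any convention about the short interval between the second pulse and
fixation. The Tc denominator is the caller's marker-defined cycling
population; the package does not decide marker gating. Proportions get
Wilson intervals; (Ts, Tc) get seeded multinomial-bootstrap percentile
intervals (default 1000 resamples) over the four label classes.

## Screen statistics

The plate location statistic is the median (robust to the right-skewed
duration distribution; mean by flag). Mimic scores are computed per
replicate on per-well mean durations and standardised with the population
(ddof = 0) mean and sd of all data points of that replicate — so per-
replicate z-scores have mean 0 and sd 1 identically — then averaged across
replicates and ranked descending; a per-cell scoring variant is available
by flag. Synthetic screens draw per-cell durations from a log-normal
(median 22 min, σ_log = 0.25), matching the right skew of empirical mitotic
duration histograms; hits multiply the median, plate factors emulate
temporal-sampling differences. The screen's temporal sampling interval has
no canonical value and is therefore only a configuration parameter.

The test-selection rule runs KS normality per sample (against a normal with
estimated parameters — conservative, and documented as such) and a
two-sided F variance test at the same α; Student's t-test is used when both
samples pass normality with equal variances, Welch's otherwise (including
non-normal samples, as the more conservative option). Every intermediate
decision is recorded in the comparison report. Bonferroni correction
(`p_adj = min(1, m·p)`) applies across pairs in multi-group designs.

## Problem sizes and runtimes

The test suite and acceptance script use 160×160 px, 30-frame movies with 3
dividing cells (20 movies per noise condition), 200 annotated cells for
angle recovery, 131 vs 107 cells per group for the power analysis (200
replicates; 1000 for null calibration), 135 mimics × 2 replicates × 80
cells/well × 100 simulations for hit recovery, and 1000-cell specimens ×
200 simulations for the kinetics estimators — sizes chosen to match the
study designs being mirrored while keeping a full run in the order of a
minute on one CPU.

## Known limitations

* The imaging stages are 2D; 3D tissue segmentation is out of scope.
* Exact timing recovery on synthetic movies reflects the generator's clean
  phase-dependent rendering; on real data, classifier confusion at phase
  boundaries would add frame-level jitter that only the smoothing vote
  mitigates.
* The curved-surface generator bends the *sampled points*; the fit is
  always a plane, so curvature enters as structured residual, matching the
  planar-reference convention of the measurement.
* Merged tracks are excluded from event statistics rather than resolved.
* KS normality with estimated parameters is anticonservative as a formal
  test; it is used here as a recorded screening decision, not an inference.
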