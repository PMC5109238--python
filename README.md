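# mitoscreen

Quantitative machinery for live-cell mitotic screening and spindle-orientation
analysis, built as a reusable, fully testable pipeline. It targets the kind of
study in which a chromatin marker (e.g. H2B–mCherry) and a nuclear-import
reporter (an importin-β-binding-domain fusion, "IBB" reporter) are imaged by
automated time-lapse microscopy across a perturbation library, mitotic timing
is scored per cell, and spindle orientation of dividing progenitors is
measured in 3D against the ventricular surface of the embryonic cortex.

No imaging data ships with the package. Every stage is driven and verified by
a first-class synthetic-data module with known ground truth, so the whole
pipeline — segmentation to screen ranking — is checkable to the frame, degree
and z-score.

## What it computes

**Mitotic timing from two-channel movies** (`segmentation`, `classify`,
`tracking`, `events`). Nuclei are segmented by local adaptive thresholding of
the chromatin channel; a fixed-width cytoplasmic ring around each nucleus
yields the nuclear/cytoplasmic reporter ratio. Shape, texture and ratio
features feed a radial-kernel SVM that labels each object with one of six
mitotic phases. Cells are tracked by a constrained nearest-neighbour
assignment (Hungarian, with trajectory splitting and merging); a mitotic
event runs from nuclear envelope breakdown (NEBD, the prophase→prometaphase
transition) to anaphase onset, and nuclear envelope reassembly is the first
post-segregation frame whose ratio exceeds 1.5× the ratio at chromosome
segregation.

**Spindle geometry** (`geometry`). The ventricular surface around a dividing
cell is summarised by the plane minimising summed squared orthogonal
distances to sampled surface points (orthogonal distance regression; the
normal is the least-variance direction of the centred points). The spindle
angle α ∈ [0°, 90°] is the angle between the centrosome–centrosome axis and
that plane. Metaphase spindle rotation is quantified from per-interval angles
between successive pole–pole axes (cumulative, mean-velocity or max-interval
statistic).

**Cell-cycle kinetics from dual-pulse labeling** (`kinetics`). With an
EdU pulse followed Ti hours later by BrdU, uniform cycle positions give the
leaving-fraction estimators

    Ts = Ti · n(BrdU+) / n(EdU+ BrdU−)        (S-phase duration)
    Tc = Ti · n(proliferating) / n(EdU+ BrdU−)  (total cycle duration)

with seeded-bootstrap CIs, plus cycle-exit fractions (label+/Ki67− with
Wilson intervals), cells-per-100-µm surface densities and reference-stain
intensity ratios.

**Screen statistics** (`screen`). Per-plate median rescaling removes
plate-wide temporal-sampling factors; each mimic's mean duration is
standardised per replicate (z-score against all mimics), averaged across
replicates and ranked. Group comparisons run Kolmogorov–Smirnov normality
and F variance checks, select Student's or Welch's two-tailed t-test
accordingly, and apply Bonferroni correction across pairs.

## Worked example

```python
from mitoscreen.synthetic import (MovieSpec, CellScript, division_schedule,
                                  gen_timelapse_movie)
from mitoscreen.classify import training_set_from_movie, train_phase_classifier
from mitoscreen.events import extract_mitotic_events

# train the phase classifier on one annotated (here: generated) movie
sched = division_schedule(nebd_frame=8, anaphase_frame=16, frame_count=30)
spec = MovieSpec(frame_count=30, frame_interval_min=3.0,
                 cells=[CellScript(phase_schedule=list(sched))] * 3,
                 image_size=(160, 160), seed=1)
clf = train_phase_classifier(*training_set_from_movie(*gen_timelapse_movie(spec)), seed=0)

# score an unseen movie
spec.seed = 42
stack, truth = gen_timelapse_movie(spec)
tracks, events = extract_mitotic_events(stack, clf, frame_interval_min=3.0)
for e in events:
    print(f"track {e.track_id}: NEBD frame {e.nebd_frame}, anaphase onset frame "
          f"{e.anaphase_onset_frame}, duration {e.duration_pm_ana_min:.0f} min, "
          f"reassembly frame {e.reassembly_frame}")
```

prints

```
track 1: NEBD frame 8, anaphase onset frame 16, duration 24 min, reassembly frame 18
track 2: NEBD frame 8, anaphase onset frame 16, duration 24 min, reassembly frame 18
track 3: NEBD frame 8, anaphase onset frame 16, duration 24 min, reassembly frame 18
```

— each cell entered prometaphase at frame 8 and segregated at frame 16, so at
3 min/frame the prometaphase→anaphase duration is 24 min, matching the
movie's scripted truth exactly; reassembly lands on the first telophase frame
(18), where the reporter ratio recrosses 1.5× its segregation value.

Dual-pulse kinetics at the in-vivo design (Tc = 24 h, Ts = 6 h, Ti = 2.5 h,
1000 cells):

```python
from mitoscreen.synthetic import gen_dual_pulse_counts
from mitoscreen.kinetics import bootstrap_dual_pulse

c = gen_dual_pulse_counts(tc_hours=24.0, ts_hours=6.0, ti_hours=2.5,
                          n_cells=1000, seed=1)
res = bootstrap_dual_pulse(c, seed=0)
# Ts = 6.09 h  95% CI [4.85, 7.71]
# Tc = 24.75 h  95% CI [20.83, 29.76]
```

A 135-mimic screen with one planted hit (1.3× mitotic delay) and a 1.2×
plate sampling factor:

```python
from mitoscreen.synthetic import gen_screen_plates
from mitoscreen.screen import normalize_plate, zscore_mimics

ds = gen_screen_plates(hits={"mimic_042": 1.3},
                       plate_sampling_factors={"r1p1": 1.2}, seed=7)
print(zscore_mimics(normalize_plate(ds)).head(3).round(2))
#            z_rep1  z_rep2  mean_z  rank
# mimic_042    7.87    8.19    8.03     1
# mimic_024    1.69    1.02    1.35     2
# mimic_070    0.48    1.55    1.02     3
```

The planted hit ranks first with a mean z-score of 8; all other mimics sit
within the null band.

## Command line

`mitoscreen simulate|segment-track|timing|angles|rotation|kinetics|screen|run`
wrap the library stages; `mitoscreen run --config run.yaml` executes a
configured multi-stage pipeline, echoing the resolved configuration and a
SHA-256 manifest of every artifact so runs are reproducible bit for bit from
the emitted config and seed.

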