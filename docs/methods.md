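# Methods

This note records the models, conventions and design choices behind
`cmiwarp`, in the order the data flows through the package.

## Coordinates and units

Every coordinate inside the package is a physical position in µm. Skeleton
files store voxel indices plus a per-dataset voxel scale; voxel index *i*
maps to physical position *i* × scale (0-based, origin at the voxel corner).
This is applied at ingest and inverted at write, so file round trips are the
identity to below 1e-6 µm. Landmark CSVs are taken to be physical µm
already. Exported tracings whose units are unknown can be forced with a
voxel-scale override (including a unit scale for already-physical files)
rather than guessed.

## Warp model

A warp between two modality spaces is the 3D polyharmonic radial basis
interpolant φ(r) = r with an affine + constant polynomial tail and zero
smoothing (pure interpolation). Rationale:

* the accuracy procedure treats landmarks as ground-truth correspondences,
  so they must be reproduced exactly, not approximated;
* the affine tail guarantees that any exactly-affine landmark relation
  (translation, rotation, uniform or anisotropic scaling, shear) is
  reproduced over the whole domain, which makes the affine-recovery
  experiments exact up to discretization;
* this matches the thin-plate-spline-like behaviour of the interactive
  landmark tools whose exports the package ingests. The interpolant family
  used by those tools is not documented precisely, so the basis kind is an
  explicit, serialized field of the warp format and alternatives can be
  added without a format change.

The augmented symmetric system is assembled and solved by
`scipy.interpolate.RBFInterpolator` (kernel `"linear"`, degree-1 polynomial,
`smoothing=0`), which internally shifts and scales the data for
conditioning. Our layer contributes the validity checks with meaningful
errors: ≥ 4 active pairs, non-coplanar moving points (smallest principal
extent > 1e-9 of the largest; a coplanar set leaves the out-of-plane affine
response undetermined), and no duplicate moving points (within 1e-9 µm).
Fitted residuals at the landmarks are recorded on the warp object; on
well-conditioned sets they sit at ~1e-13 µm, and the package treats ≤ 1e-6
µm as the exactness contract.

Warps are always fitted per direction. Evaluating > 10 % of the landmark
bounding-box extent outside that box logs an extrapolation warning — RBF
extrapolation degrades gracefully but is uncontrolled. Serialized warps
(JSON) store the basis kind and the landmark pairs, not the coefficients:
with zero smoothing the fit is a deterministic function of the landmarks, so
loading refits and reproduces the identical mapping while keeping the file
auditable.

Leave-one-out error (refit on n−1, evaluate at the held-out moving point) is
provided as landmark quality control; an injected gross outlier shows up as
the arg-max of the LOO profile at roughly its own magnitude.

## Accuracy procedure

Junction matching is *input* (a label ↔ node-id table per modality),
mirroring the manual matching of branch points by vessel shape; the package
deliberately contains no automatic matcher.

* **Trimming**: leaves that are not matched junctions are deleted
  iteratively; every surviving leaf is a matched junction, so all modalities
  cover the same vessels to the same extent. A matched junction of degree
  < 3 is kept with a warning (it usually signals a table mistake).
* **Splitting**: segments are maximal paths between matched junctions with
  only pass-through (degree-2) interior nodes. An *unmatched* interior
  branching node is an error — on an acyclic skeleton the alternative
  (treating paths through it as segments) would multiply-cover edges.
  Segments found in only a subset of modalities are excluded with a warning.
  Segment endpoints are canonicalized by sorting the two junction labels,
  applied identically in every modality, so pairing can never be silently
  reversed. Note that on an acyclic skeleton a forest with *j* matched
  junction nodes in *c* components yields exactly *j − c* segments.
* **Step count**: the segment's arc lengths over all modalities are
  averaged and divided by the interpolation step (default 0.5 µm); the
  result is rounded half away from zero and clamped to ≥ 2 so every segment
  contributes at least its endpoints.
* **Resampling**: *n* points at arc-length fractions i/(n−1), linear
  interpolation along the polyline, endpoints exact (junctions are the most
  reliably matched locations, so the inclusive-endpoint convention was
  chosen; spacing is mean-length/(n−1) ≈ the nominal step). Duplicate
  consecutive nodes are collapsed with a warning before resampling.
* **Distances**: all modalities are warped into one user-chosen reference
  space (the convention in a 2P/SXRT/SBEM experiment is SBEM space, with
  the reference tracing itself unwarped); for every segment, step and
  modality pair the Euclidean distance between the paired points is
  recorded, tagged with the midpoint of the pair in reference space for
  spatial accuracy maps.
* **Summary**: the overall accuracy of a pair is the mean over all its
  matched points. The mean is point-wise, so longer segments contribute
  more points — the natural weighting when the quantity of interest is "the
  accuracy at a random location on the vasculature". Min/max, percentiles
  and a histogram accompany it.

## Volume-change estimation

From *k* = 20 randomly selected landmarks (seeded RNG), distances to every
other landmark are computed; unordered pairs are deduplicated (counting a
pair twice when both endpoints are seeds would double-weight it); pairs are
ranked by *fresh-space* distance, descending, and the top 400 kept. The
volume factor is r = (mean of structural/fresh distance ratios)³. The
operator-precedence ambiguity of "averaged ratio … cubed" is real; the
mean-then-cube reading is the default and cube-then-mean is exposed as an
option flag — the two agree exactly whenever the deformation is a
similarity transform. Long baselines dominate the top-400 set, which
suppresses the effect of per-landmark jitter (1 µm jitter on a 160 µm-scale
set moves r by well under 10 %). Anisotropic deformation is *not*
corrected: r is then a single summary lying between min(s)³ and max(s)³ of
the per-axis scales.

Embedded volume is measured from a thresholded TIFF stack as
(count of voxels ≥ threshold, minus an optional exclusion mask for cracks)
× voxel volume; fresh volume = embedded / r. Per-step volume trajectories
report means and consecutive mean ratios.

## Artefact statistics

Flags are strictly {0, 1}; blanks are an error unless explicitly declared
absent (`blanks_as_absent`), because silent imputation hides scoring
problems. Occurrence, prevalence, penetrance, perfect rate, co-occurrence
and grouped rates are straightforward ratios; identities that hold by
construction (histogram mass = sample count; perfect rate + any-artefact
rate = 1; prevalence ≥ occurrence) are exercised in the tests. "undefined"
is one of the 12 flag columns and is conventionally exclusive with the
named types; this is not enforced as an error because scoring conventions
vary between tables. The two-tailed paired t-test is provided only as a
thin convenience wrapper for CLI reports, outside the validated core. The
diffusion helper returns depth-ratio² (quadratic passive-diffusion
kinetics).

## Synthetic data: what it emulates, and what it does not

The generator produces inputs with the statistical structure the analysis
assumes, at the scale of a real correlative experiment:

* **Vessel trees**: persistent random walks (step 2 µm, direction
  persistence 0.62, branch lengths 18–45 µm) grown breadth-first in a
  (160 µm)³ box — the bounding-box scale of a traced vasculature volume —
  with a configurable number of degree-3 junctions and branch radii
  shrinking monotonically from trunk (4 µm) to tips (≥ 0.5 µm). The
  persistence value was chosen so inter-junction tortuosity (arc/chord)
  averages comfortably above 1.2, visually matching cortical
  microvasculature. No quantitative tortuosity/density measurements of the
  real tissue informed these defaults; they are configuration.
* **Deformations**: per-modality maps built as affine (scales a few percent
  from unity, small shear and offset) plus Gaussian displacement bumps with
  amplitude ≤ 10 % of the box and width ≥ 40 µm — large enough to be
  genuinely nonrigid, smooth enough to stay diffeomorphic (checked by
  finite-difference Jacobian determinant on a probe grid) and within what a
  50–170-landmark warp can capture.
* **Modality rendering**: the base tree is pruned of branches below the
  radius-resolution threshold of the *least* resolving modality (thin
  vessels invisible to one modality are deleted from all, keeping the
  matched sets identical), deformed, and jittered per node (tracing error).
  Landmarks are sampled preferentially at junctions (70 % by default,
  mirroring how branch points serve as landmark sources), paired across
  spaces, and jittered per axis at each modality's σ. Unit noise is drawn
  unconditionally and scaled by σ, so noise sweeps at a fixed seed reuse
  the same realization — the cleanest way to expose the monotone effect of
  landmark noise on accuracy. Default landmark counts (60) and σ (2 µm for
  2P, sub-µm for structural modalities) sit inside the ranges a real
  experiment uses (51–171 landmarks).
* **Scoring tables**: independent Bernoulli flags per sample with defaults
  calibrated so the two dominant artefacts jointly affect ~60 % of samples,
  ~15 % are uncategorisable and ~20 % are perfect — the yield regime of a
  thick-slice staining pipeline — with an optional per-experiment
  logit-normal random effect for batch structure, and per-experiment
  metadata. Only 9 of the 12 category names are meaningful; three are
  placeholders, and names are configuration throughout.

What passing tests on these data do **not** show: real tracings contain
human errors (missed branches, wrong junction matches) that are not modelled;
real deformations include discontinuities (cracks) that violate
smoothness; real artefact flags are correlated within samples beyond the
experiment random effect; and synthetic trees have no anatomy (no layers,
no flow hierarchy). The pipeline's accuracy numbers on synthetic scenes
characterise the *method* under controlled noise, not any particular
tissue.

## Problem sizes and numerical conventions

The test suite and the acceptance script run desk-scale problems: trees of
8–12 junctions (~300–500 nodes), 15–80 landmarks, 10 000-row scoring tables
for statistical calibration and 427-row tables for the yield regime; the
whole suite completes in seconds. Tolerances: 1e-6 µm for warp exactness
and affine reproduction; 1e-9 µm for the identical-input zero property;
0.5 µm (the resampling step) as the bound for affine-recovery error; three
binomial standard errors for all rate calibrations. Rounding: step counts
round half away from zero; ties in the volume top-400 ranking are broken by
stable sort order. Degenerate inputs (coplanar landmarks, duplicate points,
zero-length polylines, empty tables, non-positive volumes) raise typed
errors naming the offence rather than producing numbers.

## Known limitations

* No smoothing/regularized warps: noisy landmarks are interpolated exactly,
  so landmark error propagates directly into the warp (quantified by the
  LOO diagnostic and the noise-sweep experiments).
* No automatic junction matching or vessel tracing; both are inputs.
* Anisotropic volume change is summarised, not modelled.
* Skeletons must be forests; vascular loops (anastomoses) are rejected by
  validation rather than handled.
* Warp accuracy far outside the landmark hull is uncontrolled
  (warned, not prevented).
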