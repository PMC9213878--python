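# cmiwarp

Landmark-based warping and quality statistics for **correlative multimodal
imaging (CMI)** of brain tissue.

Correlative experiments image the *same* piece of tissue with several
modalities — in vivo two-photon microscopy (2P) for function, synchrotron
X-ray tomography (SXRT) and serial block-face electron microscopy (SBEM) for
structure. Relating those datasets requires (i) a spatial mapping between
their coordinate spaces, (ii) an honest estimate of how accurate that mapping
is, (iii) a correction for the tissue volume change caused by fixation,
heavy-metal staining and resin embedding, and (iv) yield statistics for the
staining artefacts that decide whether a sample is usable at all. `cmiwarp`
implements all four as a tested Python library with a thin CLI, plus a
synthetic-data generator so every stage can be exercised without any imaging
data.

## What it computes

**Warp fields.** Corresponding point pairs ("warping landmarks", mostly
vessel branch points) seeded in a moving and a fixed modality space define a
smooth nonrigid map *W*. `cmiwarp` fits the 3D polyharmonic radial basis
interpolant φ(r) = r with an affine tail,

  W(x) = A·x + b + Σᵢ cᵢ ‖x − pᵢ‖,

with zero smoothing, so every landmark pair is reproduced exactly and any
exactly-affine relation is reproduced by the affine part over the whole
domain. Warps are direction-specific; the reverse map is fitted from swapped
pairs, never inverted numerically.

**Warping accuracy.** Blood vessels traced in each modality are compared
after warping into a common reference space: junctions (branch points,
degree ≥ 3) matched across modalities anchor the comparison; free-ending
tracings are trimmed back to a junction; tracings are split into
inter-junction segments; each segment's mean arc length over the modalities,
divided by a 0.5 µm step, fixes a shared number *n* of equally spaced points
per modality; and the accuracy at each of the *n* matched nodes is the
Euclidean distance between the paired points. The overall accuracy of a
modality pair is the mean of all its matched-node distances.

**Volume change.** From *k* = 20 randomly chosen landmarks, all distances to
every other landmark are ranked in the fresh (2P) space; for the top 400
pairs the ratio of structural to fresh distance is averaged and cubed, giving
the volume-change factor *r*. The fresh tissue volume is the embedded
(CT-measured) volume divided by *r*.

**Artefact statistics.** Scoring tables (one row per sample, 12 binary
artefact flags, experiment metadata) yield occurrence (fraction of samples
affected), prevalence (fraction of experiments affected), penetrance
(within-experiment affected fraction), perfect rate (no artefact at all),
co-occurrence histograms and grouped rates — plus the quadratic
diffusion-kinetics helper (staining 3× the depth takes 9× the time).

## Worked example

Simulate a three-modality scene (a tortuous vascular tree in a (160 µm)³
box, one smooth diffeomorphic deformation per modality, landmark jitter,
thin vessels unresolvable by SXRT pruned from all modalities) and run the
full accuracy pipeline in SBEM space:

```python
from cmiwarp import synthetic as syn
from cmiwarp.accuracy import warping_accuracy

scene = syn.default_scene(seed=7)
skeletons, landmarks = syn.simulate_scene(scene)
landmarks["sbem"] = None        # SBEM is the reference space
records, summary = warping_accuracy(
    skeletons, syn.scene_junction_table(scene), landmarks, reference="sbem")
for pair, s in summary.items():
    print(f"{pair}: mean {s['mean_um']:.2f} um "
          f"(range {s['min_um']:.2f}-{s['max_um']:.2f} um, n={s['n_points']})")
```

prints

```
2p->sbem: mean 3.57 um  (range 0.63-8.55 um, n=688)
2p->sxrt: mean 3.52 um  (range 0.02-7.54 um, n=688)
sbem->sxrt: mean 1.14 um  (range 0.19-2.84 um, n=688)
```

i.e. with 2 µm landmark jitter in the 2P channel and sub-micron jitter in
the structural channels, any vessel location maps between 2P and a
structural dataset to a few µm — single-cell precision — and between the two
structural datasets to about one µm. The same workflow is available from the
shell (`cmiwarp simulate`, `cmiwarp fit`, `cmiwarp apply`,
`cmiwarp accuracy`, `cmiwarp volume-ratio`, `cmiwarp artefacts`).

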