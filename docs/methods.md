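# Methods

## Problem

Intra-operative cone-beam CT (CBCT) volumes from mobile C-arms are not
aligned with the patient's anatomy, so each vertebra's anatomical
standard planes (axial, coronal, sagittal) must be found before the
volume can be displayed in a standardized multiplanar view.  A CBCT
volume contains an unknown number of vertebrae (1–10), so the task
couples object detection with per-object plane regression.  `spineplane`
implements two pipelines for this task plus the infrastructure — a
synthetic spine-phantom generator, an augmentation suite, and the study
metrics — needed to train and evaluate them end to end.

## Geometry conventions

Volumes are indexed `(x, y, z)` with `world = index * spacing + origin`
(mm).  Boxes are axis aligned and tagged with their frame (`world` mm or
patch-`normalized` `[0, 1]`).  A plane triplet is stored as a rotation
matrix whose columns are the sagittal, coronal and axial plane normals;
each plane is spanned by the other two planes' normals, ordered so
`u x v = n`.  Planes are unoriented: all angle errors use
`arccos |n̂₁·n̂₂|`, because neither annotation conventions nor PCA fix a
normal sign.  Regressed spanning vectors are projected to the nearest
valid triplet by SVD of the stacked normal matrix (the orthogonal
Procrustes solution), which is idempotent and fails loudly on degenerate
input.

## Detection pipeline (3D YOLO)

A volumetric YOLOv3 variant consumes a 160³-voxel resampled volume and
predicts one candidate per cell at three grid scales (input/32, /16, /8
cells per axis → 5³+10³+20³ = 9125 candidates at 160³).  Each candidate
has 28 channels: 3 sigmoid center offsets, 3 log extent ratios against
the scale's cubic anchor, 1 objectness logit, 3 class logits (cervical,
thoracic, lumbar), and 18 linear spanning-vector components.  The
printed architecture lists 29 head channels, which no decomposition of
the stated parameter set reproduces; 28 is implemented.  Anchors are
0.15 / 0.11 / 0.07 of the patch, the normalized sizes of typical lumbar,
thoracic and cervical vertebrae in a 160 mm field of view.

The detection blocks are implemented as `1×1 (squeeze) → 3×3 (expand) →
1×1 (28-channel head)`; the route convolutions toward the finer scales
read from the preceding feature stack (512 channels at both points),
matching the printed per-block channel counts.

Target encoding gives each vertebra the cell containing its center at
every scale (at most one responsible cell per vertebra per scale), with
box extents stored as log ratios against that scale's anchor.  This
keeps the supervision a deterministic, local function of the vertebra:
coarse grids (cells of 0.25–0.5 of the patch at reduced input sizes)
cannot separate adjacent vertebrae, and an exclusive best-scale
assignment would make the responsible scale depend on the neighbors,
blurring objectness and box targets across scales.  When two vertebrae
share a cell at some scale the larger keeps it (both remain represented
on the finer grids); duplicate per-scale predictions of one vertebra are
merged by NMS at inference.  The per-scale anchors still express the
size prior: a vertebra decodes most naturally at the scale whose anchor
matches its extent, and `assign_scale` exposes that size-IoU rule.

The loss is a weighted sum of objectness BCE at object cells (OL) and
background cells (NOL), box MSE (BL, sigmoid offsets + log ratios),
softmax class cross-entropy (CL), and per-plane spanning-vector MSE
(APL/CPL/SPL).  Weights default to 1 except NOL and BL at 10.  MSE terms
are averaged over components and object cells so the magnitudes are
resolution independent; the plane terms share the 18-component
denominator so APL+CPL+SPL equals the overall plane MSE.  Inference
keeps candidates with objectness ≥ 0.10, applies greedy per-class NMS at
IoU 0.15 (ties broken by score then lexicographic center, for
determinism), then drops survivors whose maximum class probability is
below 0.25 — the threshold combination found by the original
hyperparameter search.

## Segmentation pipeline (3D U-Net + clustering)

Each vertebra's planes are represented as flat cylinders (diameter
d = 4·h) centered on the vertebra with base normal equal to the plane
normal, one label channel per plane, class encoded as the label value.
The cylinder size is constant per volume and chosen as
`d = min(0.9 · min pairwise center distance, 1.5 · median extent)` so
cylinders of distinct vertebrae never touch (a single vertebra uses
1.5 × its extent).  A 3D U-Net (configurable depth/width,
nearest-upsample + convolution decoder, 3 channels × 4 class logits out)
is trained with the sum over channels of cross-entropy + Dice loss
(weights 1/1), using SGD with momentum 0.99.

Plane parameters are recovered without the network being trusted for
geometry: foreground voxels per channel are clustered by DBSCAN
(defaults eps = 2 voxels, min_samples = 10, exposed in config), noise
voxels are discarded, clusters below half the largest cluster's voxel
count (per channel) are dropped, and intersecting axial/coronal/sagittal
clusters (bounding-box test, nearest-centroid tie-break) form one
vertebra.  The center is the mean of the three cluster centroids; each
plane normal is the smallest principal component of its cluster's voxel
coordinates — for a flat cylinder with d = 4h the axial variance h²/12
is far below the radial variance d²/16, so the smallest eigenvector is
the base normal.  PCA signs are canonicalized against the most-aligned
volume axis.

The clustering radius interacts with resolution: at the native
512³/0.313 mm resolution the worst-case gap between cylinders of
adjacent vertebrae (≈ 7% of the minimum center distance, ≥ ~0.9 mm) is
comfortably above eps = 2 voxels, and the recovery chain is exact up to
discretization.  At strongly reduced grids (e.g. 64³, 2.5 mm voxels)
neighboring cylinders can fall within the clustering radius and merge;
the deterministic-recovery guarantee is therefore stated, and tested, at
native resolution.

## Augmentation

Seven transforms fire independently per sample, in a fixed order
(rotation/scaling together, then noise, blur, brightness, contrast,
low-resolution, gamma) with the stated probabilities and parameter
distributions (rotation-only 0.16, scaling-only 0.16, both 0.08, angles
U(−30°, 30°), scale U(0.7, 1.4); noise 0.15 with variance U(0, 0.1);
blur 0.2 with σ U(0.5, 1.5); brightness 0.15 × U(0.7, 1.3); contrast
0.15 × U(0.65, 1.5) clipped to the original range; low-res 0.25 with
factor U(1, 2), nearest down / cubic up; gamma 0.15 with γ U(0.7, 1.5)
after rescaling to [0, 1]).  Rotation and scaling are composed into one
resampling about the patch center (linear for the volume, nearest for
masks, volume minimum as fill); annotations are transformed in closed
form (centers rotated/scaled, extents replaced by the axis-aligned
bounds of the transformed box, spanning vectors rotated).  Intensity
transforms assume intensities normalized to [0, 1] and never touch
labels.

## Phantom generator

The generator emulates the study data statistics, not anatomy: 1–10
vertebrae per volume, class-dependent extents (cervical 8–13 mm,
thoracic 17–24 mm, lumbar 21–24 mm), a fixed 160.256 mm field of view
(512 voxels at 0.313 mm; the voxel spacing follows from the grid size),
roughly collinear stacking along a smoothly curved axis with
intervertebral gaps of 4–8 mm (typical disc heights), per-vertebra plane
triplets tilted up to 15° off the stacking direction, Gaussian noise
(default σ 0.02 on [0, 1] intensities), and optional bright streaks
standing in for metal-implant artifacts.  Region classes advance
cervical → thoracic → lumbar along the spine; the requested count is
truncated to the prefix that fits the field of view (truncation, not
rejection, keeps the class mix unbiased — the realized mix is roughly
23/36/40% over many mixed volumes).  Each vertebra is rendered as a
bright flattened superellipsoid body (height ≈ 0.78 × width, near-flat
endplates rendered as brighter cortical caps) plus a posterior ring,
over a smoothly varying soft-tissue background, so noise-free phantoms
are separable by a single threshold and carry a visible orientation
signal.  Everything is driven by one integer-seeded generator;
samples are bit-reproducible.

What passing phantom-based tests does **not** show: robustness to real
CBCT reconstruction artifacts, anatomical shape variability, fractures
or implants.  The phantoms establish algorithmic correctness of the
pipelines, not clinical performance.

## Evaluation

A prediction matches a ground-truth vertebra when its center lies inside
the ground-truth box (parameter free and pipeline agnostic); matching is
greedy one-to-one by ascending center distance.  Detection reports
accuracy TP/(TP+FP+FN) (no true negatives exist), error rate, recall and
precision; classification a 3×3 confusion over matched pairs.
Localization reports the center-to-center distance and the distances
from the predicted center to each ground-truth plane (d_asp, d_csp,
d_ssp, with the coronal/sagittal pair averaged per match); orientation
reports unoriented normal angle errors per plane and their mean.

## Scaled-down study sizes

The full-scale study (440 training / 218 test clinical volumes at 512³)
is replaced by phantom suites: the end-to-end detector study trains on
200 phantoms and evaluates on 50 held-out phantoms at 64³ input with
width multiplier 0.25; the deterministic recovery suite uses 50 phantoms
at the native 512³ grid.  The scaled-down detector trains with Adam
at 2e-3 (decayed to 6e-4 after epoch 5) for 6 epochs plus a 2-epoch
fine-tuning restart at 2e-4 — a schedule sized to the reduced problem
and chosen on a separate validation suite — with spanning-vector loss
weights of 3 (translating the published weight ratio into this
package's mean-normalized loss convention) and plane-supervision
dilation (the finest-scale cell neighborhood also receives
spanning-vector targets, multiplying the orientation signal per
volume).  The configuration defaults remain the original settings
(Adam, lr 1e-5, weight decay 1e-4, 1000 epochs, unit plane weights),
and the single-volume overfit check runs under those defaults.
Kaiming-normal initialization; detection-head biases start at a
background objectness prior (-2) and the canonical plane triplet.

Under these conditions the detector reaches held-out recall of about
0.90-0.95 (draw dependent).  The plane-normal regression converges more
slowly: its mean angle error is still ~12-13° when the compute budget
of the bundled study is exhausted (the loss is still falling at
cutoff), although a second-moment analysis of the same rendered
volumes recovers the axial normal to ~5°, i.e. the signal is present
and the limitation is optimization budget, not information.

## Numerical choices and edge cases

* Convolutions run in float32 as im2col + BLAS matmul.  Normalization
  layers use current-batch statistics at train and test time (with
  one-volume batches this is instance normalization, avoiding the
  train/eval statistics mismatch of running averages at batch size 1);
  eps 1e-5.
* Decoding clips centers to [0, 1] and extents to (0, 1]; degenerate
  regressed spanning vectors (possible for untrained networks) fall
  back to the identity triplet rather than failing inference.
* Empty supports define empty means as zero: a volume with no objects
  contributes only the background objectness term; an empty mask channel
  yields no clusters; empty detection sets evaluate to the documented
  conventions (detection metrics 1 on fully empty input, classification
  metrics 0 without matches).
* DBSCAN runs over voxel coordinates in row-major order with a ball-tree
  backend, making the clustering deterministic for a fixed mask.
* Cylinders crossing the volume boundary are clipped with a warning.

## Known limitations

* The hand-rolled compute backend is CPU-only and single threaded;
  training beyond the scaled-down study sizes is impractical with it.
* One candidate per cell per scale: two vertebrae whose centers share a
  cell at every scale cannot both be represented (logged when it
  happens).
* The segmentation pipeline's cluster radius must be chosen against the
  voxel spacing; strongly downsampled masks can merge neighboring
  vertebrae (see above).
* Box extents recovered by the segmentation pipeline are nominal
  (cylinder footprint), since the cylinders do not encode vertebra size.
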