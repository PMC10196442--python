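# spineplane

Vertebral body localization and anatomical standard-plane regression in
intra-operative 3D CBCT volumes.

Mobile C-arm systems produce 3D cone-beam CT scans whose orientation is
unrelated to the patient's anatomy.  Before a surgeon can read such a
scan, each vertebra's **standard planes** — the mutually orthogonal
axial, coronal and sagittal viewing planes — must be found and the
volume re-sliced along them, a manual step that takes minutes per
vertebra.  A volume may hold 1–10 vertebrae, so this is joint object
detection and per-object plane regression.

`spineplane` implements two automatic pipelines:

* **Detection-based** — a volumetric YOLOv3.  A 160³ input produces
  candidates at three grid scales (5³ + 10³ + 20³ = 9125 candidates),
  each with a box (anchors 0.15/0.11/0.07 of the patch), an objectness
  score, region-class probabilities (cervical/thoracic/lumbar) and the
  six spanning vectors of the three planes.  The loss is

  `L = w_OL·OL + w_NOL·NOL + w_BL·BL + w_CL·CL + w_APL·APL + w_CPL·CPL + w_SPL·SPL`

  with `w_NOL = w_BL = 10` and the rest 1.  Inference filters by
  objectness ≥ 0.10, greedy per-class 3D NMS at IoU 0.15, and class
  probability ≥ 0.25.

* **Segmentation-based** — a 3D U-Net segments, per plane channel, flat
  cylinders (diameter = 4 × height) centered on each vertebra, trained
  with `L = w_CE·CE + w_DC·DC` summed over the three channels.  DBSCAN
  clusters the predicted voxels, clusters below half the largest
  cluster's size are dropped, intersecting clusters are grouped per
  vertebra, the center is the mean cluster centroid, and each plane
  normal is the smallest principal component of its flat cluster.

Both emit the same per-volume annotation JSON (class, center, extents,
plane triplet per vertebra).  A seeded phantom generator supplies
CBCT-like spines with complete ground truth, and the evaluation module
implements the study metrics (detection/classification rates,
center-to-center and center-to-plane distances, plane-normal angle
errors).  All networks run on a small built-in numpy compute backend —
no GPU or deep-learning framework required.

## Worked example

Generate phantoms, train the scaled-down detector (64³ input, width
multiplier 0.25), and run inference:

```bash
spineplane simulate --config cfg.yaml --n 10 --out data/ --seed 0
spineplane train-yolo --config cfg.yaml --data data/ --out model/ --epochs 8
spineplane infer-yolo --config cfg.yaml --model model/yolo_model.npz \
    --volume data/vol_0000.nii.gz --out pred.json
spineplane evaluate --pred preds/ --gt data/ --out report.json
```

with `cfg.yaml`:

```yaml
phantom: {grid_size: 64}
yolo: {input_size: 64, width_multiplier: 0.25}
```

The same study from Python (this is what the acceptance script runs):

```python
import numpy as np
from spineplane.phantom import PhantomSpec, generate
from spineplane.training import train_yolo, infer_yolo
from spineplane.yolo3d import YoloConfig
from spineplane.evaluate import evaluate_pairs
from spineplane.yolo3d import LossWeights

cfg = YoloConfig(input_size=64, width_multiplier=0.25)
train = [generate(PhantomSpec(grid_size=64, seed=s)) for s in range(200)]
test = [generate(PhantomSpec(grid_size=64, seed=s)) for s in range(200, 250)]
samples = [(s.volume, s.annotations, s.spec.spacing) for s in train]
w = LossWeights(w_APL=3.0, w_CPL=3.0, w_SPL=3.0)
net, _ = train_yolo(samples, cfg, epochs=6, lr=2e-3, seed=7,
                    lr_milestones={5: 6e-4}, weights=w, plane_dilation=1)
net, _ = train_yolo(samples, cfg, epochs=2, lr=2e-4, seed=11, net=net,
                    weights=w, plane_dilation=1)
rep = evaluate_pairs([(infer_yolo(net, s.volume, s.spec.spacing), s.annotations)
                      for s in test])
print(f"recall    {rep.detection['recall']:.3f}")
print(f"angle err {np.mean(rep.orientation['ang_sp_bar']):.2f} deg")
print(f"d_cc      {np.mean(rep.localization['d_cc']):.2f} mm")
```

```
recall    0.901
angle err 12.48 deg
d_cc      3.23 mm
```

Recall is the fraction of ground-truth vertebrae whose matched
prediction center falls inside their box; the angle error is the mean
unoriented angle between predicted and true plane normals over the three
planes; `d_cc` is the mean center-to-center distance in millimetres.

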