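# posekin

**posekin** is a toolkit for the *non-neural* half of a 2D human-pose pipeline
aimed at physiotherapy and tele-rehabilitation: everything around the trained
keypoint detector. It defines a 25-keypoint skeleton with extra hand, foot,
neck and spine landmarks, reads and writes the plain-text annotation format
such detectors emit, computes clinical joint angles from keypoints, evaluates
detections with IoU/OKS/mAP and a keypoint-level confusion matrix, probes
detector robustness with occlusion-ablation masks and MRE reports, and applies
annotation-consistent image augmentation. A forward-kinematics stick-figure
generator produces images and annotations with exactly known joint angles, so
every stage is testable without a trained model or a real dataset.

Intended users: researchers and engineers building or validating pose-based
movement-analysis tools, who need trustworthy metric and kinematics code
around whatever detector they train.

## The skeleton

25 keypoints, indices 0–24: eyes/nose, neck, per-side
shoulder/elbow/wrist/thumb/pinky, spine, per-side
hip/knee/ankle/toe/heel. Compared with the common 17-keypoint layout this adds
a mid-torso axis (neck + spine) for trunk flexion, two hand landmarks per
wrist, and heel/toe pairs for foot orientation.

## The core quantities

Joint angle at vertex **p₂** between segments to **p₁** and **p₃**:

θ = arccos( (**ba**·**bc**) / (‖**ba**‖‖**bc**‖) ) · 180/π, with
**ba** = p₁ − p₂, **bc** = p₃ − p₂ and the cosine clamped to [−1, 1].
Angles are computed in pixel coordinates (normalized space shears angles on
non-square images).

Object keypoint similarity between a predicted and a ground-truth pose:

OKS = Σᵢ exp(−dᵢ² / (2 s² kᵢ²)) δ(vᵢ>0) / Σᵢ δ(vᵢ>0)

with dᵢ the pixel distance for keypoint *i*, s² the ground-truth box area,
kᵢ the per-keypoint falloff constant, and vᵢ the visibility flag. Boxes are
compared with IoU = |B∩B′|/|B∪B′|. Either similarity feeds greedy one-to-one
matching, precision/recall/F1, AP per threshold (101-point interpolation) and
mAP@[0.5:0.95] = (1/10) Σₜ APₜ over t = 0.50, 0.55, …, 0.95.

## Worked example

Generate 8 synthetic figures with 2 px jittered surrogate predictions, then
evaluate the predictions and read the joint angles off one annotation:

```
$ posekin synth --n 8 --out demo --seed 42 --jitter 2.0
{"n": 8, "splits": {"test": 1, "train": 6, "valid": 1}, "truth": "demo/truth.csv"}

$ posekin evaluate --gt demo/train/labels --pred demo/train/predictions
{
  "precision": 1.0,
  "recall": 1.0,
  "f1": 1.0,
  "tp": 6, "fp": 0, "fn": 0,
  "map50": 1.0,
  "map5095": 0.9721122112211221,
  ...
}

$ posekin angles --label demo/train/labels/pose_00000.txt --width 256 --height 256
person 0  neck angle                161.17°
person 0  right elbow flexion       149.79°
person 0  left elbow flexion         75.99°
person 0  right knee flexion        150.71°
person 0  left knee flexion          81.73°
person 0  right hip flexion         160.90°
person 0  left hip flexion          110.48°
person 0  trunk inclination         180.00°
person 0  pelvic tilt               148.56°
```

The 2 px jitter is small relative to the figures, so every prediction still
matches its ground truth at OKS 0.5 (precision = recall = 1.0) and only the
strictest threshold (0.95) loses average precision, pulling mAP@[0.5:0.95]
slightly below 1. The angle table is the clinical catalog measured on the
stored keypoints: this figure stands upright (trunk inclination 180°) with
the left arm and leg strongly flexed.

Other subcommands: `posekin schema` (inspect/export the skeleton),
`posekin augment` (annotation-consistent augmentation with a provenance
sidecar), `posekin mask` / `posekin ablate` (occlusion robustness),
`posekin convert` (normalized ↔ pixel annotations). Every command takes
`--seed` and the library mirrors each one as plain functions.

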