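# motionfuse

Multi-cue, keypoint-based action recognition for behavioural assessment
of children with ADHD during a continuous-performance attention test.

During such a test a child sits in front of a screen for ~20 minutes
while a camera records them; a pose estimator (e.g. AlphaPose) turns
each 2-second clip into body-keypoint and facial-landmark sequences.
`motionfuse` classifies those sequences into six behaviour states —
head turning, body shaking, resting head on hand, inattentive facial
expression, lying on the desk, no significant symptoms — giving
clinicians an objective, per-interval behaviour log to read alongside
the test's attention scores.

## The model

Three cue branches are fused at the softmax level:

* **Joints** and **bones** streams run through an adaptive graph
  convolutional network over the 17-joint upper-body skeleton.  Each
  block computes `f_out = Σ_k W_k f_in (A_k + B_k + C_k)` over the three
  partitioned adjacency subsets (`A_k` fixed, `B_k` learned, `C_k`
  data-dependent attention).  Two additions target the sudden, irregular
  movements characteristic of the population: multi-scale
  spatial-temporal taps after blocks 4 and 7 (temporal conv → channel +
  temporal attention → max-pool, summed with the final backbone feature)
  and a per-frame motion-attribute attention after block 4.
* **Face**: the 68-landmark sequence is encoded as a 68×60 pseudo-color
  image — rows are landmarks, columns frames, channels
  `(255·X/X_max, 255·Y/Y_max, 255·S)` — and classified by a
  MobileViTv2-style backbone (separable self-attention, width 1.5,
  ≈10.6 M parameters at the canonical head).
* **Fusion**: `F = W_j·ψ(F_joints) + W_b·ψ(F_bones) + W_f·ψ(F_face)`
  with ψ the softmax; prediction is the argmax.

The plain 10-block skeleton backbone counts 3.44 M trainable parameters;
with both modules, 3.91 M.  Everything (including the networks' autodiff)
runs on NumPy; see `docs/methods.md` for the full model account.

## Worked example

Train the joints branch on a generated six-class dataset and evaluate it
(about two minutes on a laptop CPU at this desk scale):

```bash
motionfuse synth --out-dir data --n-per-class 10 --seed 3
motionfuse train --data data/manifest.csv --out runs/joints \
    --branch joints --base-channels 8 --epochs 10 \
    --learning-rate 0.001 --optimizer adam --seed 1
motionfuse eval --checkpoint joints runs/joints/checkpoint.npz \
    --data data/manifest.csv --weights 1,0,0
```

The `synth` step reports `wrote 60 samples to data (42 train / 18 val)`;
training prints the final metrics:

```json
{
  "final_train_loss": 0.7376944720745087,
  "val_top1": 83.33333333333334
}
```

and `eval` emits a JSON report whose `fused` section contains the top-1
and top-2 accuracy (here 83.3% and 100.0% on the 18-sample validation
split), per-class top-k counts and the 6×6 confusion matrix.  At this
tiny size the branch resolves five of the six classes — the remaining
confusion is the subtle facial-expression state against the quiet state
— while the end-to-end test suite runs a larger configuration (100
samples per class, 40 epochs) that reaches ≥95%.  The same workflow in
Python:

```python
import numpy as np
from motionfuse import SkeletonActionClassifier
from motionfuse.synthetic import generate_arrays

bodies, faces, labels = generate_arrays(n_per_class=10, seed=3)
train = np.concatenate([np.flatnonzero(labels == c)[:7] for c in range(6)])
val = np.concatenate([np.flatnonzero(labels == c)[7:] for c in range(6)])
clf = SkeletonActionClassifier(base_channels=8, epochs=10,
                               learning_rate=1e-3, optimizer="adam", seed=1)
clf.fit(bodies[train], labels[train])
accuracy = (clf.predict(bodies[val]) == labels[val]).mean()
```

Real AlphaPose output is ingested with `motionfuse ingest poses.json
--out-dir data/` (COCO-results dialect: flat `(x, y, s)` triplets per
frame, optional `face_keypoints`), which assembles 60-frame sequences,
repairs low-confidence keypoints by temporal interpolation, and writes
the same archive + manifest format the trainer reads.

`motionfuse complexity --model agcn-multiscale` prints the parameter and FLOP
accounting per layer.

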