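# tracheidnet

Predicting the mechanical grade of conifer wood from micrographs of its
tracheids.

In softwoods such as larch, nearly all load-bearing tissue consists of
tracheids: elongated cells whose open cavity (lumen) and wall thickness
set the density, and with it the compressive strength, of the wood.
`tracheidnet` implements a complete desk-scale pipeline linking tracheid
micro-structure to the five-level strength grade used for larch:

1. **Mechanics & grading** — compressive strength parallel to grain,
   `sigma_w = P_max / (b * t)` (MPa, rounded to 0.1), graded by strict
   thresholds `Ic > 22.5 > IIc > 18.9 > IIIc > 16.9 > IVc > 14.0 > Vc`.
2. **Texture** — nine gray-level co-occurrence (GLCM) features (ASM, CON,
   CORR, ENT, VAR, SA, SV, IDM, SE) over 8x8 sliding windows, 16 gray
   levels, stride 4, 0-degree pair relation.
3. **Morphology** — mean lumen AREA (um^2) and PERIMETER (um) from labeled
   segmentation masks, with magnification-dependent calibration.
4. **Feature optimization** — Pearson redundancy pruning (threshold 0.9),
   per-feature 3-sigma outlier removal, and random-forest importance
   ranking (900 trees, depth 35) selecting the top-5 features.
5. **D-SA-FCN** — a dual-branch fully-convolutional classifier: a
   perceptron branch for the feature vector, a convolution branch for the
   image with one factorized **sparse-attention** block
   (`S_i = {j : |i-j| <= k} ∪ {j : |i-j| ∈ {2k, 3k, ...}}`), fixed random
   fusion shuffling, and a 1x1-convolution head ending in a 5-way softmax.
6. **Synthetic campaigns** — because destructive test data with paired
   electron micrographs are not publicly deposited, a generator renders
   honeycomb-like tracheid lattices with grade-dependent lumen radius and
   wall thickness, ground-truth masks, and failure loads linked linearly
   to the wall/lumen area ratio.

The neural network is implemented in pure NumPy with hand-written backward
passes (verified against finite differences in the test suite), so the
package runs anywhere the scientific Python stack is installed.

## Worked example

```python
from tracheidnet.network import DualFCN
from tracheidnet.training import (TrainConfig, evaluate, make_desk_dataset,
                                  split_dataset, train, _model_config)

ds = make_desk_dataset(n_images=500, seed=1)       # 125 specimens x 4 positions
train_idx, test_idx = split_dataset(ds.labels, 0.8, seed=1)
model = DualFCN(_model_config(ds), init_seed=1)
history = train(model, ds, TrainConfig.desk(seed=1), train_idx)
report = evaluate(model, ds, test_idx)
print(f"train acc {history['accuracy'][-1]:.2f}, test acc {report.accuracy:.2f}")
print(report.confusion)
```

prints

```
train acc 0.89, test acc 0.75
[[21  1  0  0  0]
 [ 1 15  6  1  0]
 [ 0  1  7  6  0]
 [ 0  1  6 11  1]
 [ 0  0  0  1 21]]
```

The confusion matrix rows are the true grades Ic..Vc; errors concentrate
on adjacent grades, as expected when strength noise straddles a band
boundary.  Chance level for five balanced grades is 0.20.  The
feature-only random-forest baseline on the same split reaches 0.80 —
texture and morphology features carry most of the grade signal, and the
image branch contributes the rest of the dual model's margin over the
image-only ablation.

A command-line interface mirrors the library
(`tracheidnet synth | grade | glcm | morph | select | train | eval | ablate`);
see `tracheidnet --help`.

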