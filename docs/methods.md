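# Methods

## Problem and model

Tracheids — the water-conducting cells that make up most conifer wood —
determine the macroscopic mechanics of the material: thicker cell walls
and smaller lumens mean denser tissue and higher compressive strength
parallel to the grain.  The package grades specimens into the five larch
strength classes (Ic..Vc) from two modalities extracted from micrographs:
window-averaged co-occurrence texture statistics, and lumen morphometry
from segmentation masks.  Grading itself is deterministic: the strength
`sigma_w = P_max/(b*t)` is rounded half-away-from-zero to 0.1 MPa and
compared against strict thresholds (22.5 / 18.9 / 16.9 / 14.0 MPa); a tie
falls to the weaker class, and the rounded value is what gets graded.
Inputs are assumed already conditioned to 12 % moisture content; no
moisture correction is applied.

## Texture features

The gray-level co-occurrence matrix `m(i,j)` is the normalized histogram
of ordered gray-level pairs at offset (0, 1) — the 0-degree relation at
distance 1 px, counted asymmetrically.  Images are quantized into 16
equal-width bins of [0, 255]; windows are 8x8, tiled at stride 4 from the
origin, partial windows discarded; per-image features are the unweighted
window mean.  The nine statistics are the standard Haralick forms with
1-based level indices and natural logarithms; the sum-distribution
features use `p_{x+y}(k) = sum_{i+j=k} m(i,j)` with squared deviation in
the sum variance.  Variance is computed about the GLCM row-marginal mean
and is non-negative by construction.  A constant window has undefined
correlation; it is reported as 0 with a warning rather than an error,
since constant windows legitimately occur in blank image regions.  No
per-dataset min-max rescaling is applied by default.

## Morphometry

Region area is the pixel count of a label; perimeter is the exposed-edge
count (4-neighbour faces against anything that is not the region,
including the image border).  The exposed-edge convention is an integer
and exactly reproducible, which we prefer over contour-length estimators;
note it overestimates smooth-boundary length (a digital disk has exposed
perimeter ≈ 8r versus 2*pi*r), so absolute perimeters are convention-bound
while comparisons across images remain meaningful.  Border-touching
regions are partial tracheids and are excluded from the image mean by
default.  Pixel pitch defaults to 0.5 um/px at x200 and 0.2 um/px at
x500; these are free instrument calibration constants, always
configurable, not universal values.

## Feature optimization

Pipeline order: correlation pruning, then outlier removal, then forest
ranking.  Pruning is greedy on the largest off-diagonal |r| above the
0.9 threshold; from the offending pair it drops the member with the
larger mean |r| to the retained features that are themselves free of any
above-threshold entanglement.  Measuring independence against this
"clean" baseline (rather than against all retained features) matters
inside a redundant group: a group member's correlations to its own
near-copies would otherwise dominate the mean and invert the decision.
Ties fall to the later name in canonical column order.  The 3-sigma
filter computes column means and sample SDs once on the full table and
removes any row deviating more than three SDs on any retained feature;
zero-variance columns flag nothing.  The forest is a regressor of
strength on the features (900 trees, depth 35, fixed seed, rows sorted
canonically before fitting so importances are order-stable); it reports
impurity importances normalized to sum 1, the held-out mean absolute
error, and the grade accuracy of its thresholded predictions.  The top-5
features by importance feed the network; on campaigns generated at the
defaults these are CON, CORR, AREA, PERIMETER and ASM.

## Sparse attention

Connectivity is expressed as per-position index sets, 1-based at the
interface: local (`|i-j| <= k`), atrous (`|i-j| mod k = 0`, requiring
k > 1), and sparse (the local window plus strided links at distances
2k, 3k, ...; distance k itself enters via the window).  The self index is
always a member of its own set.  Scores are scaled dot products divided
by sqrt(d).  Optional top-k truncation of the scores (ties toward the
smaller index) is off by default — the mask family is the primary
sparsification.  Interleaved combination selects pattern `r mod p` per
residual block; multi-head combination concatenates per-head products
before the post-attention matrix.

## The dual-branch network

The feature branch is a perceptron with a sigmoid input layer and ELU
(alpha = 1) hidden layers.  The image branch is a stack of 3x3 stride-2
convolutions with ELU; its final feature map is flattened row-major into
spatial tokens and passed through one masked self-attention block placed
after the last convolution.  The block adds its output residually
(`x + Wp * attend(x)`), a choice made so that a zero-weight block is an
identity — convenient for ablation probes — and training is stabler; the
mask only changes connectivity, so the parameter count is identical
across attention families.  Fusion concatenates the flattened branch
outputs and applies a permutation drawn once from `fusion_seed` and
stored with the checkpoint; re-sampling per batch would make inference
nondeterministic.  The head is a 1x1-convolution stack (no dense layer)
ending in five channels and a shift-invariant softmax.  The loss is
cross-entropy with the conventional minus sign, predictions clamped at
1e-12.  An optional parallel 1x1-conv regression head predicts the
strength directly (trained with added MSE), whose output can be graded by
thresholding; classification is the default because neither mode is
unambiguously "the" reference architecture.

Everything is NumPy with hand-written backward passes; the test suite
checks them against central finite differences at 1e-6 relative error.

## Synthetic campaigns

The generator emulates the acquisition protocol: n specimens, a number of
positions each, one image per position and magnification, one failure
load per specimen.  Tissue is a jittered hexagonal packing of elliptical
lumens (site jitter 6 % of pitch, per-lumen radius jitter 8 %, random
orientation), dark lumens (gray 70) on bright walls (gray 190), Gaussian
blur proportional to wall thickness, additive speckle (SD 8 gray levels).
Grades cycle round-robin; per-specimen lumen radius and wall thickness
are drawn at 5 % relative SD around grade means (radius 9/11/13/15/18 um,
wall 6.5/6.1/5.5/4.5/2.1 um for Ic..Vc).  The strength link is linear,

    sigma_target = 8.0 + 15.0 * (cell_area - lumen_area)/lumen_area
                 + 20.0 / pitch + N(0, 1.0)  [MPa],

with positive coefficients so strength increases monotonically with wall
thickness; the wall-thickness means were solved so each grade's expected
strength sits at its band centre.  A linear link was chosen deliberately
so that downstream feature-importance recovery has a known ground truth.
The failure load is `P_max = sigma_target * b * t` (b = t = 20 mm), and
the recorded grade is derived from the realized strength, so labels are
always consistent with the grading rule even when noise crosses a band
boundary.  Each specimen owns an RNG stream spawned from the master seed,
making regeneration stable under reordering.

What the generator does **not** emulate: earlywood/latewood ring
structure, SEM noise physics, shared tissue between the two
magnifications of one position, and any real wood mechanics beyond the
monotone wall-thickness/strength link.  Passing tests therefore
demonstrate that the pipeline recovers structure it is designed to
recover from honeycomb-like tissue — not field performance on real larch.

The bounded feature table used for filter calibration
(`random_feature_table`) draws each feature from a Beta(2, 2) rescaled to
a plausible range.  Bounded draws keep every clean row within ~2.3 column
SDs, so a 3-sigma rule flags planted gross outliers and nothing else;
with Gaussian columns a 1600-row table would flag a handful of honest
rows by chance and the planted/removed correspondence would be lost.
Planted perturbations alternate sign so column means stay put, and
magnitudes at or below 3 SDs are rejected as not guaranteed detectable.

## Problem sizes (desk profile)

The default benchmark is 500 images: 125 specimens, 4 positions, x200
only, rendered at 256x256 px (0.5 um/px — large enough that even the
weakest grade keeps interior, border-free lumens for morphometry).  The
network input is 32 px by block-mean downsampling; training uses SGD at
learning rate 0.01 for 30 epochs with batch size 32, features
standardized on the training split and images centred.  Protocol-count
emulation (1600 images) renders 128 px frames at a quarter-resolution
pixel pitch (1.0 / 0.4 um/px) that preserves the 2.5x density ratio
between magnifications while keeping whole lumens inside the reduced
frame.  The full-scale profile (500 epochs, batch 128) is exposed through
`TrainConfig` but is not exercised by the test suite.

## Known limitations

* Texture features are computed for the 0-degree relation only; the
  other Haralick directions and distances are out of scope.
* The exposed-edge perimeter convention is resolution- and
  convention-dependent (see above).
* The random-forest grade accuracy and the network's test accuracy are
  properties of the synthetic benchmark, not estimates of performance on
  real micrographs.
* The deep segmentation of real micrographs is out of scope: masks are
  inputs here, ground-truth ones when synthetic.
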