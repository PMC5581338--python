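# Methods

## Scope and model

`nodulecad` grades the internal attenuation of pulmonary nodules from CT.
Two outputs are produced per nodule: a three-way class (non-solid /
part-solid / solid) and a continuous 1–5 score. Both are computed from 2D
regions of interest only — the method deliberately avoids nodule
segmentation at prediction time, because ground-glass lesions are the ones
segmentation algorithms fail on, and avoids 3D features because clinical
slice thickness (1–3 mm) is large and variable relative to in-plane
resolution.

## Synthetic phantoms

The pipeline is developed and tested against synthetic volumes, not
clinical data. The generator emulates the *structure* of a multi-reader
thoracic-CT annotation set: HU-valued volumes with anisotropic spacing,
per-slice nodule contours, and 1–4 integer scores per nodule from
simulated raters.

* Background parenchyma: N(−870, 30²) HU. Nodules are ellipsoids with
  semi-axes jittered ±20% around half the sampled diameter.
* Class interiors: non-solid N(−650, 50²); solid N(−50, 30²); part-solid
  is a ground-glass interior containing a solid core with radius 50% of
  the nodule's, its centre offset by up to 50% of the semi-axes in a
  random direction. The eccentric core is essential: it is what makes the
  single-median-slice strategy lossy and the ALL strategy informative.
* Nodules are placed by rejection sampling with a clearance of the
  nodule's own extent plus 12 voxels from every volume face, so the 10-px
  ROI context margin is never clipped: clipped margins shift the nodule
  far off-centre in its patch, which measurably degrades patch
  classification for lesions near the volume boundary.
* Defaults: volume 64×160×160 voxels at (1.25, 1.0, 1.0) mm — a
  thin-slice acquisition at the low end of the clinical 1.25–3 mm range.
  Slice thickness matters a great deal here: at 2.5 mm the solid core of
  a part-solid nodule spans only one or two z-voxels, is invisible in the
  coronal/sagittal views, and three-class accuracy collapses toward
  chance on the part-solid class; at 1.25 mm the core is resolved in all
  three views.  30 nodules per class; diameters 8–14 mm, so a part-solid
  core is at least ~2 mm;
  4 annotators per nodule (the annotation depth of multi-reader studies;
  `"random"` draws 1–4 to exercise the annotation-count grouping); rater
  noise SD 0.4 score units, which reproduces adjacent-category
  disagreement at roughly the rate seen between human readers.
* Raters: `round(true_score + N(0, sd²))` clipped to [1, 5], with true
  scores 1 / 3 / 5 for the three classes.

What the phantoms do **not** model: reconstruction physics and noise
texture, vessels and chest-wall attachment, irregular margins, partial
volume averaging, and any within-class density variation beyond the two
fixed HU distributions. Passing the end-to-end tests therefore
demonstrates that the pipeline's machinery (masking, slicing,
augmentation, training, consensus, statistics) is correct and that the
method recovers a known ordinal attenuation structure — not that the
reported numbers transfer to clinical data.

HU class values are design choices from standard lung-CT ranges; they are
not fitted to any dataset.

## ROI extraction

Contours are filled per axial slice (even-odd rule, pixel centres) into a
single 3D mask; coronal and sagittal masks are re-slicings of that array,
so the three views are always mutually consistent. Per view, `ALL` takes
every slice with in-view mask, `SINGLE` the lower median of that list
(deterministic, unbiased toward either end; relevant only for even slice
counts). The patch is the per-slice tight bounding box expanded by 10
pixels of context, clipped at image borders. No isotropic resampling is
performed before slicing. Normalisation windows HU to [−1000, 400] —
wide enough to keep ground-glass contrast against both air and soft
tissue — maps linearly to [0, 1] and resizes bilinearly to 64×64. Window
and input size are conventions (config-exposed), not tuned values.

## Contourlet augmentation

Each pyramid level stores the exact residual `x − up(down(x))` with a
5-tap binomial kernel (DC gain 1), so reconstruction is lossless by
construction. Upsampling uses normalized interpolation (the convolution is
divided by the convolved sampling mask), which keeps unit DC gain at the
borders too — a constant image yields exactly zero detail. The
directional filter bank partitions the DFT plane into angular wedge pairs
(each wedge united with its point reflection, with Nyquist bins
symmetrized), giving real components that sum to the band exactly and are
Parseval-additive. This spectral-partition design is not critically
sampled; the augmentation role needs directional components and perfect
reconstruction, not minimal sampling.

Augmentation (training only; default 2 levels × 4 directions) adds per
patch: the lowpass-only image and one directional-sum image per level.
The cross-validation driver leaves it disabled by default: the phantoms'
class signal is almost entirely the absolute attenuation level, the
directional residuals of homogeneous-texture lesions are essentially
noise, and training on them measurably dilutes the classifier; the bands
are designed to add cues on data with real texture diversity. The
augmentation path stays first-class and switchable.
The lowpass image is clipped to [0, 1] rather than min–max stretched —
stretching would normalise away the absolute attenuation level, which is
the defining difference between ground-glass and solid tissue, and
measurably degrades the classifier. Zero-mean directional images carry no
absolute level, so they are min–max rescaled (flat bands remain zero).

## CNN

Architecture (fixed): conv 5×5/stride 2, 6 maps → maxpool 2×2/stride 2 →
conv 5×5/stride 2, 16 maps → maxpool 2×2/stride 2 → FC 84 → FC 3 →
softmax, ReLU activations; 64×64 input gives sides 30/15/6/3 and a
144-wide flatten. Training is plain SGD (no momentum) on softmax
cross-entropy, batch 32, learning rate 0.05 held constant. Weights are
Gaussian with He fan-in scaling (std √(2/fan-in)); zero biases. At a fixed
non-decaying learning rate, the init scale is the only knob controlling
early optimisation speed, and He scaling is the conventional choice for
ReLU stacks. Defaults: up to 100 epochs with patience-10 early stopping
and best-checkpoint restore on a validation set (the protocol driver
passes each fold's nodule-disjoint validation split). When the validation
patches carry nodule grouping, the checkpoint criterion is the
*nodule-level consensus accuracy* on the validation fold (ties broken by
lower validation loss) rather than the patch-level loss: many peripheral
slices are intrinsically ambiguous, so patch loss is minimised by
maximally uncertain outputs and selects under-trained checkpoints, while
the consensus metric is exactly what the deployed classifier is judged
on. The
implementation is plain numpy (im2col convolutions; gradient scatter via
`bincount`), deterministic under its seed, float32 internally.

The protocol driver instead trains each fold for a fixed 60 epochs and
restores the best-consensus checkpoint. An optional global-norm gradient
clip (default 5) guards against the occasional mini-batch gradient that
would eject the weights from a good basin at the fixed step size, and a
label-smoothing knob exists but defaults to off.

The 84-dimensional post-ReLU hidden activations feed a standard CART
random forest (100 trees, bootstrap, √d split features, unlimited depth)
whose target is the mean annotator score; forest predictions are means of
training leaf values and hence stay inside [1, 5]. The forest is trained
on original patches only, not on augmented bands.

## HIST baseline

Seven statistics of the HU histogram (48 bins over −1000…200 HU, 25 HU
width) of all 3D voxels inside the ground-truth mask: entropy (bits), the
population SD of raw voxel values, mean and maximum normalized bin
height, and the 5/25/75% quantiles (linear interpolation); out-of-range
voxels are clipped into the end bins. Classification and regression use
k-nearest neighbours, k = 12, Euclidean distance on features z-scored
with training-fold statistics; vote ties break to the class with the
smaller mean neighbour distance, then the lower class index. Because the
features are per-nodule 3D summaries, slice strategies and consensus
modes are no-ops for HIST. The "mean normalized bin height" feature is
constant (1/48) by definition; it is kept for fidelity to the published
feature list and is neutralized by z-scoring.

## Consensus and mapping

Averaged annotator scores map to classes with thresholds 2.5 and 3.5,
boundaries going to the upper class — the deterministic extension of the
integer rule (1–2 non-solid, 3 part-solid, 4–5 solid). Classification
consensus averages softmax vectors (ties to the lower class index);
score consensus is the mean of the three median-slice scores (SINGLE),
the mean over all patches (ALL-Mean), or the mean of per-view medians
with even-count medians averaging the middle two (ALL-Median).

## Protocol and statistics

Each round draws, per class, a CV pool and held-out test set in 170:20
proportion (at the package's default scale of 30 nodules per class: 27
pool / 3 test per class); folds partition the pool per class; each fold's
model is evaluated on the round's test set. All splitting is at nodule
level and the driver raises if any nodule id appears in both a training
and test set of a repetition. Cohen's κ uses the standard marginal
chance correction, returning 1.0 in the degenerate all-agree case; the
t-test is the pooled-variance Student test (Welch available in scipy if
ever needed); signed differences are CAD minus radiologist, so negative
medians mean the CAD under-scores. κ and RMSE are additionally grouped
by each nodule's annotation count (1–4).

Default problem sizes — 30 nodules/class, 2 rounds × 3 folds, ≤100
training epochs — were chosen once as the scale at which the synthetic
study is informative while a full run stays in the minutes range on one
CPU; the full-scale 190/class, 10×10 bookkeeping is exercised separately
on the split plan, which is cheap.

## Known limitations

* Phantom realism as above; HIST reaches near-ceiling performance on
  phantoms because the class HU distributions are cleanly separated given
  a perfect mask — the CNN's advantage over HIST on real data
  (segmentation-free operation) cannot be demonstrated on phantoms where
  the mask is free.
* Patch-level labels inherit the nodule label, so peripheral slices of a
  part-solid nodule are intrinsically ambiguous training examples; the
  consensus over all slices is what resolves them.
* The CNN input size, activations, optimizer details and stopping rule
  are conventions (config-exposed); the published architecture fixes only
  kernels, strides, map counts and the learning rate.
* Contourlet bands are fed as extra samples, not extra channels; a
  channel mode would be a straightforward extension.
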