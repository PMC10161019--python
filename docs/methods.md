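# Methods

`hepavess` implements a two-stage pipeline for segmenting contrast-enhanced
hepatic vessels in CT volumes: a vessel-appearance enhancement stage (Frangi
vesselness followed by coherence-enhancing diffusion, both confined to the
liver region of interest) and a learning stage (a ResDense-block U-net
trained on vessel-biased 2-D patches with soft Dice loss). This note records
the model assumptions, the parameters that matter, the numerical choices,
and what the bundled phantom studies do and do not establish.

## Input model and preprocessing

Volumes are assumed to be portal-venous-phase CTs resampled to an isotropic
1 mm grid (`resample_isotropic`, linear for intensities, nearest for masks;
output shape `round(shape * spacing / target)` per axis so world extent is
preserved). A binary liver mask is a required input — liver segmentation is
out of scope — and everything downstream operates on the liver ROI bounding
box dilated by `margin_vox` (default 8 voxels, so vessels near the liver
surface survive filter edge effects). Crop boxes are half-open `[lo, hi)`
with 0-based indices; intensity volumes are float32, eigen-decompositions
run in float64.

## Vesselness (Frangi) stage

At each analysis scale the Hessian of the Gaussian-smoothed volume is
gamma-normalized (second derivatives multiplied by sigma^2, i.e. gamma = 2)
and its eigenvalues `|l1| <= |l2| <= |l3|` feed the response

    V = (1 - exp(-Ra^2/2a^2)) * exp(-Rb^2/2b^2) * (1 - exp(-S^2/2c^2)),

nonzero only where `l2 < 0` and `l3 < 0` (bright structures), with
`Ra = |l2|/|l3|` (plate vs line), `Rb = |l1|/sqrt(|l2 l3|)` (blob penalty)
and `S` the Frobenius norm of the Hessian (structureness). The per-voxel
maximum over scales is the vesselness map, which *replaces* the CT
intensities for all later stages.

Parameter choices:

* **Scales are target vessel radii** (voxels = mm on the 1 mm grid),
  default `4..8`: large radii only, so thin, nearly-touching vessel ends are
  not fused together by the enhancement. Internally the Gaussian width is
  `sigma = scale / sqrt(2)`, because a solid cylinder of radius r maximizes
  its gamma-normalized response at `sigma = r/sqrt(2)`; with this convention
  a radius-r tube peaks at the scale nearest r (verified numerically for
  r in {4, 6, 8}), which is what makes the scale parameter meaningful.
* **alpha = beta = 0.5**, the customary defaults.
* **c** defaults to half the maximum Hessian Frobenius norm over the masked
  ROI across *all* requested scales — one shared constant. A per-scale c
  would cancel the scale dependence at the strongest voxel and destroy
  scale selectivity. Near-zero structureness (a numerically constant
  volume) short-circuits to a zero map instead of normalizing roundoff into
  responses.
* Derivative kernels are separable, reflected at boundaries, truncated at
  4 sigma. The sampled second-derivative kernel does not sum exactly to
  zero; its measured sum times the smoothed volume is subtracted from the
  diagonal Hessian entries so constant regions map to exactly zero.

Known limitation: the blob penalty `Rb` suppresses solid spheres only near
their centers. The shell just inside a solid sphere's edge is locally
ridge-like (one small and two large negative eigenvalues) and passes the
filter at roughly tube strength; plate rims behave similarly. This is a
property of the response function itself (the reference implementation in
scikit-image behaves the same or worse on identical probes), and it is the
dominant source of false positives in the phantom studies below.

## Coherence-enhancing diffusion (CED) stage

The structure tensor `J = G_rho * (grad u_sigma grad u_sigma^T)` (noise
scale sigma = 1 voxel, integration scale rho = 2 voxels) is eigen-decomposed
per voxel with `mu1 >= mu2 >= mu3 >= 0`; V3, the direction of least
intensity variation, is the local vessel axis. The coherence ratio
`k = mu2 / (mu3 + eps)` is large on tubes, ~1 on blobs, small on plates.
The diffusion tensor shares J's eigenvectors with diffusivities

    lam1 = lam2 = alpha_reg            (0.001)
    lam3 = alpha_reg + (1 - alpha_reg) * exp(-C / k^2)     (C = 1)

so diffusion acts essentially only along the vessel axis: gaps close and
intensities homogenize inside vessels while edges stay put. The update
`u <- u + tau * div(D grad u)` is an explicit Euler scheme in conservation
(face-flux) form: fluxes are evaluated on cell faces and differenced, so
with zero-flux boundaries the volume mean is conserved to machine precision.
`tau = 0.1` respects the stability bound `tau <= 1/6` for diffusivities
<= 1 on a unit grid; tensors are recomputed before each of the `n_iter = 10`
steps (lagged nonlinear diffusion). `eps = 1e-10` guards `mu3 = 0` in flat
regions. None of these values is prescribed by the underlying formulation;
all are exposed in the configuration.

## Patch sampling

Whole slices are overwhelmingly background, so training patches are drawn
only from axial slices that contain vessels, only inside the slice's liver
bounding box, as square crops of uniformly random side (default 32-80 voxels
at phantom scale; 96-384 would be the proportional choice for 512^2
clinical slices), rejected unless they contain at least one annotated
vessel voxel, resized to the network input (linear for images, nearest for
masks) and z-scored per patch (constant patches map to zeros). Sampling is
driven by an explicit seed and is bit-reproducible. Train/validation/test
splits are by volume, never by patch, to avoid leakage.

## Network

A U-net with `levels` resolution levels (2x max-pool down, nearest 2x
upsample + 3x3 conv up, encoder feature concatenated at each decoder
level). Each level holds a **ResDense block**: two conv units
(3x3 conv -> batch norm -> ReLU) whose output is *concatenated* with the
block input along channels, so the identity path carries features and
gradients through unchanged — unlike a summation residual, which mixes
them. A 1x1 convolution after each concatenation compresses channels back
to the level width (widths double per level from `base_channels`). The head
is a 1x1 convolution with a sigmoid, yielding per-pixel vessel
probabilities. Summation-residual, dense and plain blocks are available
behind the `block` switch for comparison; `blocks_per_level` stacks blocks.
The conv -> batch-norm -> ReLU order inside a unit is the standard one.

The layers are implemented directly in NumPy (channels-last feature maps;
convolutions evaluated as a sum of k^2 shifted channel matmuls, which keeps
every copy and scatter-add on large contiguous blocks; reverse-mode
gradients written per layer and verified against finite differences). Adam
uses betas (0.9, 0.999) and no weight decay.

## Training schedule

Soft Dice loss on raw probabilities, `1 - (2*sum(pt) + s)/(sum p + sum t + s)`
with smoothing s = 1, averaged over the batch; batch size 32; Adam with
initial learning rate 1e-4; LR multiplied by 0.2 after two consecutive
epochs without validation improvement (counter resets after a reduction);
early stop after four successive non-improving epochs; "improvement" means
strictly below the best seen minus 1e-5; the best-validation parameters are
restored. `max_epochs` caps at 100 since early stopping is the intended
terminator.

**Desk-scale learning rate.** The 1e-4 default is appropriate for training
runs of thousands of Adam steps over hundreds of volumes. The bundled
phantom studies train for a few hundred steps, where 1e-4 moves the weights
so little that the network stays near initialization and predicts a single
class. The phantom experiments therefore pass a larger desk-scale rate
(1e-3, 2e-3 in the CLI defaults) explicitly; the schedule semantics are
unchanged.

## Inference and evaluation

Inference mirrors the sampler: each axial slice's liver bounding box is
resized to the network input, z-scored, segmented, and the probabilities are
resized back; thresholding at 0.5 (the sigmoid midpoint) and masking to the
liver gives the volume prediction. Metrics are DSC = 2tp/(2tp+fp+fn),
sensitivity tp/(tp+fn) and specificity tn/(tn+fp), with confusion counts
restricted to an explicit evaluation region — by default the liver ROI
bounding box, because whole-volume specificity saturates near 1 and carries
no information; the region used is recorded in every report. Both-empty
DSC is defined as 1; empty denominators yield 1 with a warning flag.

## Synthetic phantoms

`make_phantom` builds a deterministic portal-venous-like scene: an
ellipsoidal "liver" (parenchyma 100 HU) in a darker surround (40 HU), a
recursive binary-branching tree of bright capsules (+60 HU, root radius 5
voxels, radius decay 0.75 per generation, three generations, branch angles
~35 deg with jitter) rasterized by exact point-to-segment distance, solid
sphere and thin-slab distractors at the same +60 HU contrast, and additive
Gaussian noise (sigma 10 HU). Defaults give a vessel fraction of ~1.5% of
the liver — the class imbalance that motivates the biased sampler. 96^3
default size keeps full-pipeline runs at minutes on one CPU.

What the phantoms emulate: tubular bright structures across radii ~2-5
voxels, matched-contrast non-tubular confounders, scanner-like white noise,
and heavy class imbalance. What they do not: textured parenchyma, lesions,
contrast inhomogeneity along vessels, partial-volume blur, anisotropic
acquisition, or anatomy-shaped organs. Passing phantom studies therefore
demonstrates that the pipeline's machinery works and that enhancement helps
under these statistics; it does not certify clinical-grade accuracy.

## Phantom study design and observed behavior

Two canned studies (`hepavess.experiments`):

* **Enhancement ablation** — one small network per replicate trained on
  enhanced input, and an identically initialized and scheduled one on raw
  cropped input, each replicate on its own phantom, with one shared
  validation phantom and one shared held-out test phantom (all
  volume-disjoint). The comparison is directional: enhanced input should
  beat raw input on held-out DSC, mirroring the with/without-enhancement
  ordering of the evaluation the pipeline was designed around. Caveat: at
  the phantom's default noise level the raw vessels already have a
  contrast-to-noise ratio around six, so the enhanced arm's margin is small
  and can invert on some phantom draws; the ordering the method targets is
  characteristic of low-CNR clinical data, which the phantom emulates only
  mildly.
* **End-to-end segmentation** — phantoms -> enhancement -> patches ->
  training -> slice-wise inference -> metrics, split by volume.

At desk scale the absolute DSC is limited by three effects: thin terminal
branches (radius ~2) fall below the enhancement's scale range, costing
sensitivity; solid-distractor rims pass the vesselness filter (see above),
costing precision — a 2-D slice of a plate rim is locally indistinguishable
from a vessel, so only learned context can reject it; and with epochs of
only a few dozen optimizer steps, the plateau/early-stop rules select
weights on validation-loss differences that sit inside the noise, so the
restored model varies from draw to draw. A threshold sweep of the enhanced
input itself bounds what intensity alone can achieve, and the trained
network beats that bound — the remaining gap to a perfect mask is carried
by the input representation and the 2-D context limit, not by the
optimizer. These are honest properties of the method at this problem size,
not implementation artifacts; held-out DSC across phantom draws spans
roughly 0.55-0.8.

## Numerical conventions and degenerate inputs

* Eigenvalues of symmetric 3x3 fields use the closed-form trigonometric
  solver (vectorized; acos argument clamped); eigenvectors, where needed,
  use the batched LAPACK path.
* Masks remain uint8 {0,1} through every resampling (nearest only).
* Constant patches z-score to zeros; empty masks are rejected where a
  nonempty mask is a precondition (ROI box, sampler).
* All randomness flows from explicit integer seeds (phantom geometry and
  noise, patch sampling, weight init, batch shuffling); identical seeds
  give bit-identical phantoms, patch sets and training histories.
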