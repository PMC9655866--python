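# Methods

This note records the model, the numerical conventions, and the design
choices that were genuinely open, in enough detail to re-derive every
default in the code.

## Data model and preprocessing

Volumes are `(transverse slice, row, column)` arrays with mm spacing;
+row is posterior, +column is patient-left. All slice-wise operations
(adjacent-voxel-difference loss, transverse-plane augmentation) refer to
this axis order.

* CT is truncated to [−600, 1000] HU: below −600 HU is air, and the window
  keeps bone; the pelvis needs nothing outside it.
* Structure masks are painted as label images on the same HU scale —
  background −600, body −400, femur-R −200, femur-L 200, rectum 600,
  bladder 800, PTV 1000 — so every channel shares one intensity scale and
  one affine normalisation.
* All channels are mapped affinely onto [−1, 1] to match the generator's
  tanh output. CT and label channels use the [−600, 1000] range. Dose uses
  [0, 1.2 × prescription]: clinical maxima run a few percent above the
  prescription, and a 20% headroom keeps the tanh unsaturated at every
  dose the model must represent while wasting little of its range.
* Resampling to isotropic 3.5 mm voxels uses index-space scaling
  (`scipy.ndimage.map_coordinates`), linear for CT/dose and nearest for
  masks (masks stay binary). The interpolation order of the original
  clinical pipeline is not recoverable from its description; linear is the
  standard choice for intensity volumes.
* Cropping to a fixed cube (128³ at clinical scale) centres on the body
  centroid — the only centring rule that needs no manual input — with the
  PTV centroid as fallback; out-of-window voxels pad with −600 (CT/labels)
  or 0 (dose).
* DICOM RTDOSE ingestion multiplies the stored integer grid by
  `DoseGridScaling` and converts GY → cGy. NIfTI is the interchange format
  everywhere else; dose NIfTIs are taken to be in cGy already.

## Networks

**Generator** — five-scale encoder–decoder with full-scale skip fusion.
Stem: three 3³ stride-1 convolutions to 32 maps. Encoder: a strided 3³
convolution (no pooling) opens each level, widths 64/128/256/512, with two
further 3³ convolutions at the 64/128/256 levels and none after the last
downsampling. Decoder steps 4→1 each fuse five 32-channel branches — the
same-scale encoder map plus all shallower encoder maps (average-pooled
down) and all deeper maps (projected, then trilinearly upsampled) — so the
fusion convolution input is 160 channels; it reduces to an 80-wide decoder
state. An 80-wide head convolution and a 3³ output convolution with tanh
close the network. Every convolution except the output carries batch norm
and ReLU; convolutions followed by batch norm have no bias.

**Discriminator** — 3D patch classifier: kernel-4 convolutions with
channel ladder 108/216/416/814 and strides (2, 2, 2, 1, 1), LeakyReLU(0.2)
throughout, batch norm on all but the first and last layers, final
1-channel logit map. The analytic receptive field
`RF = 1 + Σ (k−1)·Π s` of this plan is 70 voxels per axis.

Exact block multiplicities, the 1³ skip projections, the 80-wide decoder,
and the discriminator ladder were fixed by calibrating against the
recorded trainable-parameter totals of **11.077 M** (generator, 7-channel
input) and **29.026 M** (discriminator, 8-channel input); the resolved
plans are the dataclass defaults in `networks.py` and are reproduced
exactly (11,077,233 and 29,026,105 scalars) by `count_parameters`. Width
multipliers scale every channel count for desk-scale runs without touching
the topology.

Initialisation is Kaiming-normal with the activation's gain
(`std² = 2/((1+a²)·fan_in)`, a = 0 for ReLU, 0.2 for LeakyReLU, 1 for the
linear/tanh output); biases and batch-norm offsets start at zero.

Skip branches reduce channels *before* upsampling when coming from deeper
scales and *after* pooling when coming from shallower ones. Both orders
have identical parameter counts; projecting first makes the interpolation
operate on 32 channels instead of up to 512, which matters on CPU.

## Losses

BCE-with-logits terms are evaluated through the softplus identity
(−log σ(x) = softplus(−x)), which is exact and stable for |x| large. The
adjacent-voxel-difference (AVD) loss accumulates, over the three axes, the
squared difference between consecutive-slice differences of ground truth
and prediction. AVD and L1 default to *mean* reduction — their written
forms are sums, but mean reduction keeps the loss weights meaningful when
the crop size changes between training (96³ clinical / 32³ desk) and
inference; `reduction="sum"` restores the literal forms. The weights
λ_cGAN/λ_AVD/λ_L1 are nowhere pinned by the protocol; the defaults
(1, 10, 100) follow the established L1-dominated conditional-GAN recipe
and are config-exposed.

## Training protocol

Adam (β₁ = 0.5, β₂ = 0.999), learning rate 0.002 for epochs ≤ 200 then
linearly attenuated to 0 at epoch 500; batch size 4; 500 epochs; every
epoch checkpointed. Augmentation randomly crops a 96³ window (32³ at desk
scale — the same 2:3 crop-to-volume ratio) and rotates it by 90°, 180° or
270° in the transverse plane only, identically across channels. Per batch,
one discriminator update (real stack vs. stack with the generator output
substituted, detached) precedes one generator update; the alternation
granularity — per batch rather than per epoch — is a choice the protocol
description leaves open. A master seed is split into independent streams
for initialisation, augmentation and batch ordering, making runs
bit-reproducible on a fixed machine.

Splitting mirrors the cohort design: a seeded shuffle holds out a test
set, and the remainder rotates through 7 folds at a 6:1 train:validation
ratio (118 cases → 20 test + 98, folds of 84/14). Checkpoint selection for
testing, when needed, uses the lowest validation body-MAE; the protocol
records all epochs but states no selection rule.

The engine underneath is a minimal NumPy reverse-mode autodiff
(`dosegan.nn`): 3D convolution as per-depth-slab im2col GEMMs (slabs keep
the column matrix under ~256 MB), batch norm, factor-2 average pooling and
separable half-pixel trilinear upsampling, and the pointwise/reduction ops
the losses need. Every operator's gradient is checked against central
differences in the test suite.

## Phantoms

`phantom.py` generates the study anatomy: a soft-tissue body ellipsoid
(30 HU + 20 HU Gaussian noise) in air, bone femoral heads (700 HU,
lateral), a central PTV, bladder anterior and rectum posterior, geometry
specified in mm and scaled to the grid extent; per-case jitter (default
8%) varies sizes and positions across a cohort. The reference dose is
prescription × exp(−d/falloff) with d the Euclidean distance to the PTV
surface, falloff 25 mm, plus 0.5%-of-Rx Gaussian noise, clipped at zero.
The 25 mm scale gives DVH shoulders, OAR dose ordering
(bladder/rectum > femoral heads) and isodose surfaces in the ranges
clinical pelvic plans occupy.

What the phantoms do *not* emulate: beam/arc geometry, heterogeneity
corrections, inter-patient anatomical diversity beyond ellipsoid jitter,
and delineation noise. Passing tests therefore demonstrate that the
pipeline learns and that the metrics are computed correctly — not that
clinical-cohort accuracy figures transfer.

## Evaluation conventions

* MAE is reported relative to the prescription (×100): its plain summed
  form carries no units a percentage could come from, and the
  prescription-relative reading matches how such errors are quoted.
* D_p uses the descending-sort rank ⌈p·m/100⌉ (1-based); ties resolve by
  the sorted value. V_d is the percentage of voxels at or above d. DVH
  bins default to 10 cGy.
* HI = (D2 − D98)/D50; CI = V_TP²/(V_T·V_P) with V_P the prescription
  isodose volume (CI = 0 when V_P is empty). V40 is reported for bladder
  and rectum.
* Isodose DSC at both-empty volumes is defined as 1 (with a warning): the
  0/0 case means the two plans agree that the level is absent.
* Gamma analysis (3%/3 mm, 10% threshold, global normalisation to the
  prescription): for each above-threshold reference voxel the evaluated
  dose is sampled by trilinear interpolation on a DTA/10 lattice within a
  3×DTA sphere, offsets visited in order of increasing distance with
  per-voxel pruning. Two exact accelerations: a whole-voxel pre-pass
  tightens each voxel's bound, and a local min/max envelope of the
  evaluated grid (interpolated values cannot leave it) finalises voxels
  that provably cannot improve. Voxels whose lower bound already exceeds
  `max_gamma` (default 2) keep their whole-voxel estimate — gamma values
  above 2 are upper estimates; pass/fail at γ ≤ 1 is exact.
* The paired t-test is two-sided; zero difference variance raises instead
  of emitting an undefined p.

## Desk-scale defaults and problem sizes

The package's own test and demonstration scale is 8 phantoms at 48³
(3.5 mm), scheme B, width multiplier 0.125, 32³ crops, 30 epochs — a
configuration chosen so a full adversarial run with evaluation completes
in a few minutes on one CPU while still exercising augmentation, the
alternating updates, checkpointing and the full metric panel. The full
128³/500-epoch/width-1.0 protocol is expressible with the same config
object but is accelerator-scale.

## Known limitations

* Batch norm statistics are per-batch; with batch size 4 and width-reduced
  nets, eval-mode outputs depend on the training-batch history (as in any
  batch-norm GAN).
* The gamma search samples a finite offset lattice; γ is an upper bound on
  the continuum value (tightened by the DTA/10 step the criteria
  prescribe).
* The RTDOSE reader handles the dose-grid scale factor and GY/CGY units
  only; structure rasterisation from RTSTRUCT, registration and
  multi-modality inputs are out of scope.
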