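# Methods

## Problem and model

`longimpute` predicts a subject's brain MR image at a missing timepoint
from the image(s) at another timepoint — the practical use case being
longitudinal infant studies, where tissue contrast changes dramatically
between 6 and 12 months (myelination partially inverts the gray/white
relationship in T1w and T2w) and missing visits are common.  Completing
the cohort with predicted scans lets downstream models train on more
subjects; imputed scans are flagged and never admitted to evaluation
splits.

The translator is an adversarially trained 3D U-Net.  In the
single-contrast setting a generator G maps the input-age image x to the
target-age image ŷ and a patch discriminator D scores realism over
spatial patches (a small sigmoid score map, not a single scalar).  The
generator objective is

    L(G) = L_adv(G) + α·L_vr(G) + β·L_p(G)

with

* `L_adv(G) = E[(1 − D(G(x)))²]` — the least-squares adversarial term.
  The discriminator descends `E[(1 − D(y))²] + E[D(G(x))²]`, whose optima
  (D(real)→1, D(fake)→0) coincide with the printed minmax objective for a
  sigmoid-bounded D; a `literal_ascent` flag restores the ascent form.
* `L_vr(G) = E‖y − G(x)‖₁` — voxel-wise mean absolute error, preserving
  global structure.
* `L_p(G) = E‖φ_m(y) − φ_m(G(x))‖₁` — perceptual loss in the feature
  space of a *frozen* encoder φ, promoting sharpness that plain L1
  suppresses.

In the dual-contrast setting (the multi-contrast model) one encoder
consumes the channel-wise concatenation of the T1w and T2w input-age
images and two independent decoders emit the predicted T1w and T2w
target-age images, each with its own discriminator; every loss term is
the sum of its two per-contrast terms.  The shared encoder is literally
one parameter set — the two per-contrast generator views alias the same
objects — which is what lets complementary contrast information flow to
both decoders through per-decoder skip connections.

### Expectation and norm conventions

Batch size is 1, so every expectation is a mean over the current example;
L1 norms and discriminator score maps are likewise averaged over
voxels/positions rather than summed.  This makes α and β
resolution-independent; the defaults α = β = 25 and feature layer m = 1
are tied to this convention.

## Architectures

All convolutions are 3³ (generator, feature extractor) or 4³
(discriminator), shape-preserving via padding; input axes must be
divisible by 8 because the U-Net downsamples three times by 2× max
pooling.

* **Generator** — encoder channel stack 20-40 / 40-80 / 80-160 / 160-320
  (two convs per stage, instance norm + ReLU, pooling between stages),
  decoder 160-160 / 80-80 / 40-40 with 2× nearest-neighbour upsampling
  followed by a 3³ convolution (avoids the checkerboard artifacts of
  transposed convolution; transposed form would be a drop-in change),
  skip concatenation after each upsampling, and a 1×1×1 conv + tanh head.
* **Discriminator** — 4³ stride-2 convs with 64/128/256/512 channels,
  LeakyReLU slope 0.2, instance norm on layers 2–4 (not the first), and a
  stride-1 single-channel sigmoid head.  A 32³ input yields a 2³ score
  map; inputs under 16 per axis are rejected.
* **Feature extractor** — encoder blocks 32-64 / 64-128 / 128-256 /
  256-512 with pooling after the first three; φ_m is the m-th block
  output taken after its pooling (configurable to pre-pool).  Weights are
  a fixed-seed random initialisation by default — random frozen encoders
  are an accepted perceptual-loss practice and keep the package free of
  downloads — and an external checkpoint with a matching architecture
  fingerprint can be loaded instead.

Weight initialisation is zero-mean Gaussian, sd 0.02, fully seeded.
Instance normalisation carries no learned affine parameters (batch size 1;
keeps the layer a pure normaliser).

The layer stack itself (3D convolution, instance norm, pooling,
upsampling, Adam) is implemented in numpy with analytic backward passes;
convolution is a sum of shifted tensordot contractions.  Every backward
pass is validated against central finite differences in the test suite,
and the networks are small enough at desk scale that CPU matmuls carry
the whole training loop.  A `circular` padding mode exists so that
shift-equivariance of the conv/pool/upsample pipeline can be tested
exactly (with zero padding, boundary effects reach every voxel through
the U-Net's receptive field and the property is only approximate).

## Optimisation

Adam (β₁ = 0.5, β₂ = 0.999 — the usual convention for this family; the
momentum constants are not pinned by the published recipe), batch size 1,
one discriminator update then one generator update per iteration (both
discriminators jointly in the dual-contrast setting).  The full schedule
is lr = 2e-4 for 44 epochs, then halved every 22 epochs for a further 176
(220 epochs, 8 halvings, final lr 2e-4·0.5⁸).  Model selection keeps the
epoch with minimum validation L1, falling back to the final epoch when no
validation split exists.  Ablation variants (`unet_lvr`, `unet_lvr_lp`,
`gan`, `gan_lvr`, `pgan`, `mpgan`) are pure configuration: they switch
loss terms on and off around the same backbone.

### Desk-scale settings

The full-width networks and 220-epoch schedule target GPU-scale cohorts.
The package's tests, examples and acceptance script run a *desk-scale*
configuration chosen once: 32³ phantoms (16³ for the fastest workflow
tests), channel widths divided by 4 (`width_scale=4`; 8 for the fastest
tests), ≤ 25 epochs, and lr₀ = 1e-2.  The learning-rate rescaling is a
consequence of shrinking the schedule: 25 epochs × 3 subjects is 75 Adam
steps, and Adam's per-step displacement is bounded by the learning rate,
so at 2e-4 the parameters can move at most ~0.015 in total — far short of
the tanh saturation needed to reproduce a normalised image.  At lr 1e-2
the same 75 steps reach a held-out L1 well below the copy-input baseline.
The full-schedule defaults (`TrainConfig()`) are untouched and are what
the schedule tests assert against.

## Synthetic cohort

The phantom simulator provides the longitudinal structure the method
needs without any real data: per subject, nested ellipsoids (CSF shell ⊃
cortical GM ⊃ WM core ⊃ central deep GM) plus six mirrored pairs of small
subcortical blobs (caudate, putamen, pallidum, thalamus, amygdala,
hippocampus), rendered at two ages in two contrasts.

* **Growth** — the 12m geometry is the 6m geometry scaled by
  `growth_factor` (default 1.08 linear, ≈ +26 % volume, matching the
  rough 25 % brain-volume increase over the second half of the first
  year) about the volume centre.
* **Myelination-like contrast change** — tissue mean intensities are
  age- and contrast-specific: the T1 WM/GM gap is small at 6m and large
  at 12m, inverted in T2; at 6m at least one tissue pair is better
  separated in T2 than T1, so dual-contrast input genuinely carries
  complementary information.
* **Partial volume / noise** — per-tissue Gaussian intensity noise
  (sd 2 on a 0–100 intensity scale) and a 1 mm FWHM Gaussian blur.
* **Missingness** — a configurable fraction of subjects loses one
  timepoint, alternating 6m/12m so both prediction directions stay
  exercised; incomplete subjects are always assigned to the training
  split.

Everything is a pure function of (spec, seed); identical inputs give
bit-identical cohorts.  What the phantoms do *not* emulate: cortical
folding, anatomical shape variability beyond ellipsoid jitter, bias
fields, scanner artifacts, registration error.  Passing tests therefore
demonstrate that the machinery (losses, optimisation, imputation
protocol, metrics) behaves as specified — not that the model reaches any
particular quality on real infant MRI.

## Intensity normalisation

Each volume is affinely mapped into [−1, 1] per volume.  Exact-zero
voxels are treated as stripped-skull background: excluded from the
min/max fit and pinned to −1, so a large empty background cannot compress
the brain's usable contrast range.  If a volume contains negative
intensities the background rule disables itself (zero is then an interior
value) and the fit uses all finite voxels, preserving monotonicity.
Constant volumes normalise to all zeros; the operation is idempotent via
the `normalized` flag.  Whether normalisation should be per-volume or
cohort-wide is genuinely open; per-volume is the package's documented
choice (and `exclude_background=False` restores the uniform min–max map).

## Evaluation metrics

Between a reference segmentation S1 and a comparison S2:
AVD = |V1 − V2|/V1·100 (asymmetric), ASD = symmetric mean nearest-border
distance in mm, Dice = 2|∩|/(|S1|+|S2|), TanimotoError =
(|∪| − |∩|)/|∪|·100, and FusedScore = mean of AVD/5.6, ASD/0.27 and
TE/15.8 — the reference constants being human inter-expert variability,
so 1.0 reads "as different as experts are from each other" and lower is
better (the orientation consistent with ranking better methods lower).

Numerical choices: a border voxel is a foreground voxel with a
6-connected (face) background neighbour, out-of-grid counting as
background; distances are between voxel centres using the stored spacing;
ASD is computed with Euclidean distance transforms of the border sets and
is validated against an O(n²) all-pairs oracle to 1e-9 mm.  Structures
empty in either map produce explicit `defined=False` rows, never silent
drops or NaN propagation.

The consistency protocol — segment the predicted and the ground-truth
image with the *same* algorithm and compare the two segmentations — is
realised on phantoms with a deliberately simple nearest-tissue-mean
intensity classifier (`segment_by_intensity`).  Its known limitation: the
darkest tissue of a contrast normalises to exactly −1 and merges with
background (CSF, for T1-like phantoms); both sides of a comparison are
affected identically and the structure surfaces as an undefined row.

## Degenerate inputs and error policy

All-NaN volumes, empty reference masks, mismatched shapes/vocabularies,
non-normalised network inputs, axes not divisible by 8, checkpoints with
foreign architecture fingerprints, and attempts to impute subjects
outside the training split are rejected with typed exceptions
(`ConfigError` exits the CLI with code 1, runtime errors with 2).
Non-finite loss values raise a divergence error naming the offending
term.

## Known limitations

* Desk-scale training demonstrates optimisation behaviour, not image
  quality; no claim about real MRI transfers from phantom results.
* The feature extractor's default weights are random (frozen); loading a
  pretrained 3D medical encoder is supported but not bundled.
* The discriminator is unconditional (it scores y or G(x) alone), per the
  objective's printed form.
* One discriminator step per generator step; joint D_T1/D_T2 updates.
* No bias-field, registration or skull-stripping functionality — inputs
  are assumed preprocessed.
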