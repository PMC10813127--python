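# Methods

## The model

`dspkd` trains a small convolutional classifier (the *student*) for
multi-class skin-lesion images by progressive distillation from a larger
frozen classifier (the *teacher*) over two stages that transfer different
representations.

**Stage 1: attention-guided masked feature reconstruction.**  Both networks
expose a four-level feature pyramid (spatial resolution halves per level).
For each training image the teacher's four tap maps are converted to
per-level saliency maps — the channel mean of absolute activations, min–max
rescaled to [0, 1]; a constant map rescales to all zeros (no preferred
position) — and fused top-down: starting from the deepest map, each map is
upsampled (nearest-neighbor) to the next-shallower resolution, combined by
weighted summation (default weight 0.5 per input at every merge) and
re-normalized by its maximum.  Normalizing each input level on entry makes
the fusion exactly invariant to a common positive rescaling of the inputs.
The fused map is binarized into an occlusion mask, either by a threshold φ
(mask where attention ≥ φ) or by masking the top-*ratio* fraction of
positions (default mode, ratio 0.5; ties broken in row-major order so runs
are reproducible).  The mask is spatial only and broadcasts across channels.

The student's deepest feature map, passed through a learnable 1×1
channel-alignment convolution, is multiplied by the mask and must regenerate
the teacher's complete deepest map through a generation block of two 3×3
convolutions with one GELU between them (the random-mask baseline uses ReLU,
its conventional form).  The stage-1 objective is

    α · Σ (g − F^T)²  +  Σ (f_adapt(F^S) − F^T)²  +  CE(logits, y)

with α ≥ 0 balancing reconstruction against plain feature mimicry
(default 1.0, optionally a learnable scalar).  The task cross-entropy is
included because without it the student's classification head would receive
no gradient during stage 1; users who want the pure feature phase can weigh
it out.  Reconstruction defaults to the deepest level only — the deepest map
is what the classifier head consumes, and masking shallower levels mostly
relays texture the student can already see — but any subset of levels can be
distilled, each with its own adapter and generation block.

**Stage 2: per-sample normalized logit distillation.**  The stage-1 student
continues training against the same teacher with

    CE(logits, y) + λ · (1/N) Σ_i (T_norm σ_i^t)² · KL(p̃_i^t ‖ p̃_i^s),

where each model's logit row is softened at its own temperature
`σ_i · T_norm` (σ_i = population standard deviation over the K logits of row
i, floored at 1e−6 to guard constant rows) and the row weight uses the
*teacher's* σ.  When every row of both models shares the same σ = s, this
reduces exactly to vanilla soft-label distillation at temperature
`s · T_norm` with its usual T² compensation — a property the test suite
asserts to 1e−6.  The KL direction is teacher‖student (the conventional
distillation direction) with a configuration switch for the reverse.
λ defaults to 1.0 and T_norm to 2.0.

**Ablation lattice.**  `mode` selects what each stage optimizes: `none`
(task only), `mgd` (random-mask reconstruction, ReLU block), `mgd_hf`
(attention-guided reconstruction), `vkd`/`nkd` (logit-stage only),
`mgd_hf_vkd`, and `dsp` (attention-guided stage 1 + normalized stage 2).
Degenerate settings reduce identically: α = 0 collapses stage 1 to plain
mimicry; `stage1_epochs = 0` makes `dsp` bit-identical to `nkd`; mask
probability 0/1 gives all-ones/all-zeros masks.

## Training machinery

Because no deep-learning framework is assumed, the package carries a small
NumPy engine: im2col convolution, batch normalization, ReLU/GELU, linear
layers and global average pooling, each with a hand-written backward pass
(verified against central finite differences in the tests), and SGD with
classical momentum and weight decay.  Two four-stage reference backbones are
bundled — `tiny-teacher` (16/32/64/96 channels, 79,974 parameters at 6
classes) and `tiny-student` (8/16/24/48 channels, 15,774 parameters) — each
stage a stride-2 Conv–BN–ReLU whose output is a pyramid tap.  Standard
lightweight architectures are not re-implemented; their learnable parameter
counts (e.g., ShuffleNetV2 1.0×: 2,278,604 at 1000 classes, 1,261,804 ≈
1.262 M with an 8-class head) are computed from an analytic layer table for
model-size comparisons.

The learning-rate schedule is a linear warm-up from `lr_min` to `lr_init`
followed by half-cosine annealing back to `lr_min` at the last epoch.
Full-scale defaults are 120 distillation epochs (100 single-model), 20
warm-up epochs, lr 0.001 → 1e−5, momentum 0.9, weight decay 5e−4; batch size
defaults to 32.  A linear-decay warm-up reading is available by flag.  The
default stage split is half the total epochs per stage.

Numerical choices: the teacher is strictly frozen — its features, fused
attention masks and logits over the (fixed) training set are computed once
per run, and its serialized state is asserted unchanged after every stage.
Inside the trainer the feature losses are scaled by `1/(C·H·W·N)` so their
gradient magnitude is commensurate with cross-entropy regardless of feature
size; the op-level loss functions keep the raw summed form.  In the
normalized-logit gradient the student's own σ is treated as a constant
within each update (stop-gradient), a standard stabilization; loss values
are exact.  All randomness (init, shuffling, masks, data) flows from
explicit integer seeds through `numpy.random.default_rng`, making runs
bit-reproducible on one machine.

## Preprocessing

Images are resized bilinearly.  Hair artifacts are removed by the classical
morphological scheme: Gaussian denoising (σ = 0.8) of the grayscale image,
black-hat transform with a disk structuring element (diameter 9), a response
threshold (default 50 grey levels) forming the artifact mask, slight
dilation, and biharmonic inpainting of the masked pixels only — a hair-free
image passes through bit-identical.  The threshold sits above the strongest
black-hat response that lesion boundaries and pixel noise produce in the
synthetic imagery while thin dark strands respond several times stronger;
on noiseless imagery a much lower threshold (~10) would be appropriate.
Class imbalance is addressed by oversampling: every class below
`target_fraction` (default 0.5) of the largest class gains augmented copies
made from 1–3 operations drawn without replacement from the 14 RandAugment
operations (identity, autoContrast, equalize, rotate, solarize, color,
posterize, contrast, brightness, sharpness, shear-x/y, translate-x/y) at
magnitude 9 of 10.  The train/test split is stratified 8:2 over *source*
records; augmented copies always inherit their source's side, so no
augmented view of a test image can reach the training set.  Whether a given
image receives hair removal is decided per image (always/never) or by an
automatic rule (black-hat energy above twice the dataset median).

## The synthetic benchmark

The generator emulates labeled dermatoscopy at desk scale: each image is a
randomly toned skin background with a mild gradient, one elliptical lesion
whose hue, size, eccentricity and sinusoidal texture follow a class
signature, Gaussian pixel noise, and optional dark quadratic-Bézier hair
strands with exact ground-truth masks.  Default class signatures spread
hues over half the hue wheel with per-image jitter ±0.05 and pixel noise
sd 0.10, so neighboring classes genuinely overlap — chosen so that models
land in the 75–90 % accuracy regime typical of real dermoscopy baselines
rather than saturating.  Texture amplitude is 0.05 (low-contrast, as in
real lesions; it also keeps texture from mimicking hair in the black-hat
detector).  Labels are correct by construction and one integer seed
determines every pixel.

The packaged benchmark is six classes × 200 images at 64×64 with an 8:2
stratified split; the teacher trains 20 epochs and students get a 20 + 20
epoch dual-stage budget (the no-distillation baseline receives the same 40
epochs), averaged over three student seeds, with SGD lr 0.05, 2 warm-up
epochs, cosine floor 1e−4, batch 32.  These problem sizes let the whole
benchmark finish in a few minutes on one CPU while leaving a measurable
teacher–student gap.  Representative result (data seed 0, student seeds
1–3): teacher training accuracy 1.00, undistilled student 77.6 % mean test
accuracy, distilled student 84.4 % — a gain of ~7 points, recomputable via
`scripts/acceptance.py`.

**What the synthetic data does not show.**  The generator has a single
lesion per image, no vignetting, rulers, gel bubbles or color-calibration
patches, class differences that are low-dimensional (color/shape/texture),
and i.i.d. Gaussian noise.  Passing results demonstrate that the
distillation machinery transfers usable teacher structure and that every
pipeline contract holds; they do not certify accuracy levels on real
dermatoscopy collections, which require full-scale backbones and data.

## Known limitations

* The NumPy engine is single-threaded-friendly but far slower than a GPU
  framework; it exists to make the method runnable and testable anywhere,
  not to train at dataset scale.
* Stage-1 attention uses channel-mean absolute saliency; richer
  channel-attention weightings are exposed only as a configuration hook.
* The learnable-α option updates a single scalar by gradient descent without
  reparameterization, so very large learning rates can drive it negative;
  the fixed-α default avoids this.
* Determinism is guaranteed per machine/BLAS build, not across platforms.
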