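# Methods

This note records the model, the data-preparation conventions, the
synthetic study design, and the numerical and design choices the
implementation makes where more than one reasonable option existed.

## Reconstruction model

Three networks interact during training. The **generator** maps a
voxel vector through fully connected layers to a small spatial seed
(channels × 4 × 4) and through a stack of strided up-convolutions to an
RGB image; hidden activations are ReLU (fully connected part) and leaky
ReLU (slope 0.2, up-convolutional part); the output layer is linear and
reconstructions are clipped to [0, 1] only at evaluation time. The
**discriminator** is a strided convolutional stack with leaky-ReLU
activations, global average pooling, and a fully connected head ending
in a two-way softmax; D(x) denotes the "real" probability. The
**comparator** is a frozen convolutional feature extractor; the feature
loss compares activations at a configurable tap layer
(post-nonlinearity by default; a flag selects pre-nonlinearity).

Weights use He ("MSRA") initialization, N(0, √(2/fan-in)). All losses
are *sums* over the batch, and the default weights λ_img = 2×10⁶,
λ_feat = 0.01, λ_adv = 100 assume that reduction. Discriminator
probabilities are clamped to [ε, 1−ε], ε = 10⁻⁷, before logarithms;
this bounds the loss without materially moving its optima.

Per iteration the trainer draws a seeded batch, computes all loss terms
on the current parameters, then applies the discriminator Adam step
(if the gate allows) followed by the generator Adam step. Nothing in
the objective dictates the update order; discriminator-first matches
common adversarial practice and lets the gate act on the freshest
losses. The gate pauses discriminator updates whenever
L_discr/L_adv < 0.1 *strictly*, re-evaluated every iteration, so
updates resume as soon as the ratio recovers; L_adv = 0 is treated as a
degenerate case in which the discriminator stays active. When the
adversarial weight is ablated to zero the discriminator is never
updated at all.

Jitter-crop augmentation resizes each training image to `resize_to`²
and crops a `crop_to`² window at offsets drawn uniformly from
{0, …, resize_to − crop_to}²; the cropped window is the regression
target of that iteration (both the pixel and the feature loss compare
against the crop). At study scale this is 248 → 227, approximately one
degree of a 12-degree display. The learning rate is constant by
default; a linear-decay option exists but is off.

### No deep-learning framework

The layers, backward passes, Adam and initialization live in
`fmri2img.nn` (~300 lines of numpy). Convolution and up-convolution are
expressed through three linear primitives built on
`sliding_window_view` plus BLAS matmuls; the up-convolution's forward
pass *is* the convolution's input-gradient operator, so the two layer
types are exact adjoints by construction (tested via
⟨conv(x), y⟩ = ⟨x, convᵀ(y)⟩ and finite differences). Default parameter
dtype is float32; gradient-check tests build float64 networks.
Finite-difference checks avoid placing activations exactly on the
ReLU/leaky-ReLU kink (biases are randomized in test fixtures), since at
a kink the two-sided difference legitimately disagrees with any chosen
subgradient.

## Sample preparation

The chain, in the order applied: (1) **nuisance regression** — per
voxel, OLS on an intercept, a linear trend and six motion regressors;
the fitted trend/motion contributions are subtracted while the fitted
intercept is retained. Retaining the baseline is deliberate: the next
stage normalizes to the rest-period mean, which is only meaningful with
the baseline in place (pure OLS residuals are zero-mean per voxel and
would make the rest mean vanish). Zero-variance motion columns (e.g. a
motionless phantom) are dropped rather than treated as a rank defect;
genuinely collinear designs raise. (2) **Rest normalization** — percent
signal change relative to the mean of the initial rest window
(100·(a/ā_rest − 1)); "normalization relative to a rest baseline"
admits several formulas, and percent signal change is the standard fMRI
convention. (3) **Despiking** — clipping beyond
mean ± 3 SD per voxel, statistics computed once on the stage input
(single pass, idempotent for fixed bounds). (4) **Block averaging** —
mean over the volumes in [onset + shift, onset + shift + block), with a
4 s hemodynamic shift and 8 s (training) or 12 s (test) blocks; at
TR = 2 s that is 2 volumes shift and 4 or 6 volumes averaged.
(5) **Per-voxel z-scoring** with mean/SD estimated on training samples
only and reused verbatim for test samples. (6) **Trial averaging** of
repeated test presentations, rescaled by √n (default) or n. The √n
default compensates the √n noise-SD reduction of an n-trial average so
test inputs match the single-trial amplitude scale the z-scoring
established; a plain factor-of-n convention also appears in practice,
so mode `n` ships as a config flag wherever reconstruction is invoked,
and the choice is recorded in every saved config.

Despiking order: the chain applies nuisance regression first, then
rest normalization, then despiking, then block averaging.

## Synthetic study

The simulator emulates the structure of a block-design visual-perception
dataset: 1,200 training images × 5 presentations (6,000 samples,
each presentation a separate training sample), and test sets of 50
natural images × 24 trials, 40 artificial shapes (8 colors × 5 shapes)
× 20 trials, and 10 letters × 12 trials, with train/test category
labels disjoint by construction. Voxel dimension D is configurable
(visual-cortex voxel counts vary by subject and region selection; toy
presets use D between 64 and 1,024).

The ground-truth encoding model is linear: v = W f(x) + ε, W a fixed
seeded Gaussian matrix, ε iid Gaussian per trial and voxel. The default
feature map f is the 16×16 block-averaged grayscale image with
intensities centered at 0.5 (F = 256) — the simplest map that keeps
toy-scale reconstruction identifiable; centering makes responses
percent-signal *deviations* rather than brightness offsets, which keeps
per-voxel time-series statistics (and hence the ±3 SD despike bound)
physiological. A fixed-random rectified-convolution feature map is
available for harder, nonlinear tests. Natural-like stimuli are sums of
coarse and fine Gaussian random fields with a weaker chromatic field —
the fast-decaying spatial spectrum of natural scenes, without
photorealism. Letters render from a packaged 5×7 bitmap font (no
system-font dependency, bit-reproducible); shapes are coordinate-mask
glyphs on a mid-gray ground.

Run-level series compose additively: baseline (default 100) + block
responses delayed by the hemodynamic delay (amplitude-level boxcars; no
HRF convolution, matching the block-averaged use of the data) + linear
drift + components proportional to six smoothed-random-walk motion
regressors + sparse large spikes + iid Gaussian noise. All ground-truth
components are retained in the returned object for tests.

### What the simulator does not capture

Spatial voxel correlations, hemodynamic dynamics within blocks,
heavier-tailed noise, scanner drift nonlinearity, and the semantic
structure of natural images. Passing tests therefore demonstrate that
the pipeline's *mechanics* (preprocessing recovery, optimization,
evaluation protocols) are correct and that the end-to-end mapping is
learnable when the encoding is known and low-noise — not that the
model attains any particular accuracy on real recordings.

## Desk-scale experiment sizes

All study-scale constants (500,000 iterations, batch 64, 227² output,
1,000-epoch/batch-60 size sweep) remain the configuration defaults; the
executable experiments use a deliberately small toy preset chosen once:
noiseless encoding, 64 training images × 5 presentations at 32×32,
D = 256, 20 held-out test images, a 2-FC + 3-upconv generator, 3-conv
discriminator, 2-conv fixed-random comparator, identity crop, Adam
lr 2×10⁻³ (the toy networks are orders of magnitude smaller than the
study-scale ones, and the budget is ~10³ rather than 5×10⁵ iterations),
1,200 iterations at batch 32. The size sweep trains 100/200/400-sample
nested subsets for 60 epochs at batch 32 and scores all conditions on
one fixed seeded subsample of 10 lures per test image. The
preprocessing-recovery run presents 20 stimuli 12 times each in one
long run (≈1,460 volumes), mirroring the repeated-presentation design:
with only ~20 blocks, the seven nuisance regressors absorb a visible
share of the block signal, whereas averaging 12 presentations leaves
pattern correlations ≈ 0.999.

## Evaluation conventions

SSIM uses the standard Gaussian-weighted 11×11 window (σ = 1.5),
constants (0.01·L)² and (0.03·L)², computed per RGB channel in 2-D and
averaged across channels; the map border affected by filter padding is
cropped before averaging. Pairwise comparisons run at the generator's
output resolution; no resizing is applied before comparison. Ties in a pairwise trial earn 0.5 credit —
deterministic and unbiased. Accuracy reports carry a
normal-approximation 95% CI across per-reconstruction accuracies. The
modified RV coefficient mean-centers columns, zeroes the diagonals of
both n×n cross-product matrices, and takes their matrix correlation;
the permutation baseline shuffles reconstruction rows against fixed
stimulus rows, with p = (1 + #{null ≥ observed})/(1 + n_perm).
Winning percentages for loss ablations split ties 50/50 and cover all
six pairs of the four conditions; human-judgment trials are supported
only as externally supplied records.

## Known limitations

The gating rule's pause duration (one iteration vs a longer hold) is
re-evaluated per iteration; a different reading would change
discriminator dynamics. Checkpoint/resume reproduces loss logs exactly
only under a fixed BLAS thread configuration. The study-scale 227²
configuration is validated for geometry and forward/backward
correctness but is not trained in any test.
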