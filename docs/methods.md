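# Methods

## Problem setting

Two image collections share the same binary label semantics but differ in
global appearance — in the motivating clinical setting, plain versus
contrast-enhanced CT slices of lymph nodes, where only one scan type has
labels. The goal is a classifier that works on the unlabeled (target) domain
using labels only from the source domain: unsupervised domain adaptation.

## Model

Six parameterized functions are trained against each other:

| module | role | architecture |
| --- | --- | --- |
| `F` | shared encoder | 6 conv layers, BN before ReLU, stride 2 while spatial > 4 |
| `G_S`, `G_T` | per-domain decoders | 6 transposed convs mirroring `F`, tanh output |
| `D_S`, `D_T` | per-domain discriminators | DC-GAN-style strided convs, sigmoid scalar |
| `C` | classifier | 2 fully connected layers over the flattened latent |

`F` is fully weight-shared across domains; its output (the *cross-domain
confounding representation*) is a spatial latent map `latent_channels x 4 x 4`.
Domain invariance is enforced implicitly: latents of either domain, decoded
into a given domain, must fool that domain's discriminator. There is no
pixel-reconstruction loss and no explicit feature-distance (MMD/CORAL) term.

*Classification cycle consistency*: same-domain reconstructions
`x_{S->S'} = G_S(F(x_S))` and cross-domain translations
`x_{S->T} = G_T(F(x_S))` of labeled source images are re-encoded and
re-classified, and `-log C(F(.))_y` with the source label `y` is added to
the decoder and encoder losses (and the cross-domain term to the classifier
loss). This keeps class-conditioning information intact through the
translation cycle; ablating it is a supported experiment.

### Losses (batch means, probabilities clamped to `[eps, 1-eps]`)

For domain d with real images `x_d`, same-domain reconstruction `x_same'`
and cross-domain translation `x_cross'` into d:

- `L_D(d) = -E[log D_d(x_d) + log(1-D_d(x_same')) + log(1-D_d(x_cross'))]`,
  summed over the two domains.
- `L_G(d) = -E[log C(F(x_gen))_y] + adv(D_d(x_same'))` where the cycle term
  uses `x_{S->S'}` for `G_S` and `x_{S->T}` for `G_T` (target images carry no
  labels, so both cycle terms ride on source labels).
- `L_C = -E[log C(F(x_S))_y + log C(F(x_{S->T}))_y]`, the translations
  treated as constants (no gradient into `F` or `G`).
- `L_F = -E[log C(F(x_S))_y + log C(F(x_{S->S'}))_y + log C(F(x_{S->T}))_y]
  + adv(D_T(x_{S->T})) + adv(D_S(x_{T->S}))
  + alpha*adv(D_S(x_{S->S'})) + beta*adv(D_T(x_{T->T'}))
  + lambda_l2 * (||z_S||^2 + ||z_T||^2) / batch`.

`adv(d)` is the generator-side confusion term: the literal saturating form
`E[log(1-d)]` is selectable, but the shipped default is the non-saturating
`-E[log d]`, whose gradients do not vanish when the discriminator wins —
the standard practical choice for DC-GAN-family training. `alpha = beta =
0.1` down-weight the same-domain reconstruction terms. The L2 term is read
as squared-norm regularization of the latent codes (weight `lambda_l2 =
1e-4`); an alternative reading — penalizing the generated images — exists as
the `l2_on_images` switch, off by default, because the role of the term
(keeping the confounding representation bounded) is served by the latent
reading.

### Alternating updates with parameter isolation

One training step performs four sub-updates in order `D -> G -> C -> F`
(configurable). Each phase recomputes its forward passes with the current
parameters, owns exactly one parameter collection pair, and steps only that
collection's Adam optimizer, so no parameter leaks across phases. The test
suite asserts the full isolation matrix bitwise.

Batch-norm handling deserves care in alternating training. Every phase
normalizes with the statistics of the current batch (inference-mode
normalization through early, uncalibrated running averages produces badly
scaled gradients along the adversarial and cycle paths), but only the phase
that owns a module updates its stored running statistics — state isolation
is preserved. The encoder's running statistics are additionally estimated
from real source and target batches only, never from generated images, and
a final deterministic calibration pass (a running average of batch
statistics over a fixed interleaved source/target sample; source-only for
the baseline) replaces the exponential moving average, whose end-of-training
value otherwise reflects just the last few batches seen. Without these three
choices, end-of-training evaluation is a normalization lottery: fold-level
target accuracies swing by tens of points depending on which domain's
batches happened to come last.

Adam uses `beta1 = 0.5`, `beta2 = 0.99`: the heavy 0.99 momentum sits on
the second moment, where it is stable, while the first moment follows GAN
practice — a first-moment decay that high destabilizes adversarial
training. Learning rates default to 2e-4 for all four phases (DC-GAN
convention), each overridable.

### Verification

Only the frozen encoder and classifier are kept: `argmax C(F(x))` in
inference mode. Verification is pure — checkpoints hash identically before
and after — and the end-of-training model is the one evaluated (no early
stopping on target labels, which would violate the unsupervised premise).

## Synthetic benchmark

The CT dataset that motivated the method is private, so the package ships a
generator that reproduces the *structure* of the problem at desk scale:
class signal is geometric, domain signal is a global label-free appearance
transform.

- Classes: filled disc vs annulus (same outer radius, so size alone is not
  the cue), 25% jitter in size/position; also available: low vs high blob
  counts.
- Source domain: gamma 2.2 plus mild noise (sd 0.02) — a crisp,
  high-contrast regime, the analogue of a contrast-enhanced acquisition.
- Target domain: gamma 0.6 (contrast lift), Gaussian blur sigma 1.0, a
  correlated background texture (amplitude 0.5, correlation length 4 px)
  blended into dark regions, plus the same noise — a flat, cluttered
  regime. The texture deliberately fills the annulus hole, so intensity
  cues learned on the source mislead on the target.
- Default size: 32 x 32 px, 2000 images per domain, balanced classes.

Shift strength was calibrated with source-only baseline runs and then
frozen: a linear probe on global pixel statistics separates the domains
essentially perfectly, a source-only classifier loses a substantial,
reproducible amount of target accuracy, and within each domain the classes
stay linearly separable. These fixture properties are themselves asserted
by tests. Transforms whose severity broke the translation task itself
(heavy blur), destabilized training (strong range compression), or
confounded domain with class (intensity inversion visually swaps disc and
annulus) were evaluated and rejected; the shift must stay label-free and
GAN-translatable for the benchmark to measure adaptation rather than
generation capacity.

The generator does *not* emulate CT physics (Hounsfield calibration,
reconstruction kernels, 3D context, patient-level correlation). Passing
tests therefore demonstrate that the training machinery performs
unsupervised adaptation under a global appearance shift with intact class
geometry — not that it reaches any particular accuracy on clinical data.

Randomness uses one root seed split into independent streams (source/target
geometry, appearance noise, label shuffling, batch shuffling), so the whole
pipeline is a pure function of its configs and bit-reproducible.

## Evaluation protocol

k-fold evaluation re-trains per fold: class-stratified folds are defined on
the labeled source set and on the eval-labeled target set (at the image
level); the held-out source and target folds are scored, with the full
unlabeled target set always available to training. Accuracies are reported
as mean ± sample std (ddof = 1) in percent. Comparison (source-only vs
adapted) and ablation (with vs without cycle consistency) arms run on
identical folds and seeds.

Desk-scale defaults: k = 3 folds and 3 seeds. The full-protocol k = 10 is
supported but reserved for longer runs.

## Numerical backend and problem sizes

No GPU framework is used: the networks run on a compact numpy tensor
autodiff shipped in `cycleda.nn` (im2col/col2im convolutions over BLAS
matmuls, batch norm, Adam). Every layer's gradients are verified against
central finite differences in the test suite. Training is deterministic on
a fixed seed because all randomness flows through seeded numpy generators.

Default training schedule: two epochs over the larger domain at batch size
24 (168 steps on the default benchmark). The batch size trades batch-level
gradient averaging for optimizer steps at equal wall time; the full model,
which optimizes realism and class retention jointly, converges more slowly
per step than the ablated pure-adversarial variant and benefits from the
extra updates. The schedule keeps the whole 3-seed x 3-fold comparison and
ablation study around ten minutes on one CPU core.

Numerical choices: probability clamp `eps = 1e-7` before logs; Adam
`eps = 1e-8`; batch-norm `eps = 1e-5`, momentum 0.1; weight init N(0, 0.02)
for convs (DC-GAN convention) and N(0, 1/sqrt(fan_in)) for linear layers.
Degenerate inputs (empty batches, unequal batch sizes, non-finite losses)
raise immediately with the per-term loss breakdown in the message.

## What the ablation can and cannot show here

The cycle-consistency ablation replicates only weakly on this fixture: the
with-cycle and no-cycle arms typically land within a point of each other on
target accuracy. The reason is structural. The encoder loss retains its
source classification term either way, which already anchors class
information in the latent space, and on domains that are global transforms
of the same renders, adversarial alignment alone is nearly unambiguous. The
mechanism the generated-image class terms protect against — translations
and encodings that drift away from the class-conditional structure of a
complex image population — has little room to act. On data where the
class-conditional distributions differ in ways a global transform cannot
express (the clinical motivation), the cycle terms are the only pressure
keeping translations class-faithful; a synthetic benchmark of this kind
cannot demonstrate that effect, only the direction of the comparison.

## Known limitations

- The latent L2 reading of the regularizer is one of two defensible
  interpretations (see the config switch above).
- Image-level (not patient-level) fold splits; a clinical deployment would
  need grouped splits.
- Binary classification and exactly two domains only.
- The numpy backend is single-core; 256 px training works but is slow, and
  the defaults are sized for 32 px.
- End-of-training snapshots of adversarial models retain some run-to-run
  variance; the reported protocol averages over seeds and folds rather than
  cherry-picking checkpoints.
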