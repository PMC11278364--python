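# Methods

## Problem setting

Dense, repeated plant structures (here: wheat heads) can be segmented by a
supervised model only if per-pixel annotation exists. The pipeline in this
package manufactures that annotation: composite exactly-annotated synthetic
images from one annotated frame, translate them into the appearance of the
unannotated target domain while *provably carrying the annotation along*,
train a segmenter on the translated data, and close the remaining gap with
self-training on confident pseudo-labels.

## Cut-and-paste synthesis

Foreground components are the 8-connected components of the source mask
(diagonally touching blobs belong together; wheat heads are blobby and
diagonal joins are real). Each paste draws a cutout index, a center uniform
over the frame, a scale, a rotation and two flip bits. RGB is resampled
bilinearly; the binary alpha is resampled bilinearly and re-binarized at
0.5 (ties to foreground), so the emitted mask is exactly the union of the
pasted footprints — an invariant the tests check against a per-pixel
brute-force coverage oracle. There is no edge feathering: soft blending
would decouple the mask from the visible pixels, and making seams look
natural is the translation model's job, not the compositor's. Later pastes
occlude earlier ones in RGB; the mask is unaffected because pasted pixels
are foreground either way.

The source study sizes this dataset at 11,000 composites (10,000 train /
1,000 validation); those are the config defaults. Heads-per-image, scale
and rotation ranges are not specified there; the defaults (10–30 heads,
scale 0.7–1.3, rotation ±180°, flip probability 0.5) are one-time choices
exposed in `SynthesisConfig` and asserted nowhere.

## Mask-preserving translation

The translation model is a two-generator, two-discriminator CycleGAN in
which the annotated domain S is 4-channel (RGB in [−1,1] ⊕ mask mapped
{0,1}→{−1,+1}) and the realistic domain R is 3-channel. G_S→R: 4→3
channels; G_R→S: 3→4. D_S judges 4-channel image⊕mask samples (the
concatenation, not the image alone — the discriminator can therefore
reject samples whose mask disagrees with their content); D_R judges
3-channel images.

Losses: least-squares adversarial terms; L1 cycle losses in both
directions. The S-side cycle loss averages |original − reconstruction|
over **all four channels**, weighting the mask like an image channel —
this is the mechanism that forces annotation preservation. No
identity-mapping loss is used. Generator objective:
`adv(D_R(G_S→R(x))) + adv(D_S(G_R→S(y))) + λ·(cyc_S + cyc_R)` with λ = 10.
Discriminators train on a replay buffer (size 50; each incoming generated
sample is stored until the pool fills, then swapped out with probability
1/2) to stabilize updates.

Architectures follow the canonical unpaired-translation recipe: residual
encoder–decoder generators (7×7 stem with reflection padding, two stride-2
downsamplings, residual blocks at the bottleneck — 9 at 256 px, 6 below —
nearest-upsample+conv decoding, tanh output) with instance normalization,
and 70×70-receptive-field patch discriminators. Optimization: Adam,
lr 2·10⁻⁴, betas (0.5, 0.999), 60 epochs at full scale. Training pairs
random draws from the two manifests; one epoch is max(|S|,|R|) steps.

When translating a dataset the mask is never regenerated: the output
manifest points at a byte-for-byte copy of each source mask file. The
reverse generator's mask channel, when a discrete mask is requested, is
thresholded at 0 (the midpoint of [−1,1]) with ties to foreground.

## Segmentation

A standard configurable U-Net stands in for the study's customized
variant, whose internals are published elsewhere: double-conv encoder
blocks with instance norm, stride-2 convolution downsampling,
nearest-upsample+conv decoding with skip concatenation, sigmoid head.
Default depth 4 / base width 64; input dims must be divisible by 2^depth
(an explicit error — padding is documented as the alternative but not
silently applied). Loss is mean binary cross-entropy with probabilities
clipped at 1e-7 for stability. Optimization: SGD, lr 0.01, weight decay
0.001, momentum 0.95, ×0.1 LR step every 5 epochs, 45 epochs per phase at
full scale; the returned parameters are those of the epoch with the best
validation Dice. Prediction thresholds the probability map at 0.5 with
ties to foreground (raising the threshold can only remove pixels — tested
as a monotonicity sweep). Augmentation is random horizontal flip only; the
training recipe is otherwise deliberately plain.

## Pseudo-labeling

The source study selected 99 of 360 predictions *manually*, keeping masks
that cover the wheat heads and nothing else. The automated stand-in scores
a prediction as ½·(mean probability over predicted foreground + mean
complement over predicted background); a prediction with an empty region
gets 0 for that term and so cannot exceed 0.5. Selection is top-k or
score-threshold with lexicographic tie-breaks (so a 99-of-360-style
selection is reproducible), and an HTML contact sheet of all candidates
preserves the human-review path. The proxy is *not* claimed to reproduce
the human choice; it is the simple confidence hook that uncertainty-based
curation would replace.

## Metrics and reporting

Dice = 2|A∩B|/(|A|+|B|), IoU = |A∩B|/|A∪B| over foreground pixel sets;
two empty masks score 1.0 under both (the prediction is vacuously
correct; the identity dice = 2·iou/(1+iou) then still holds). Dataset
scores are unweighted per-image (macro) means — the common reading of
per-dataset tables; pixel-pooled averaging would weight large-foreground
images more. Comparison tables compute percentage-point deltas and IoU
ratios on stored (unrounded) precision and round only for display (3
decimals for metrics/ratios, 1 for deltas). Re-deriving the source
study's comparison figures from its printed per-model means reproduces
four deltas exactly (+10.2, +12.0, +21.0, +23.6) and all three IoU ratios
(1.272, 2.507, 2.742); its two remaining printed deltas (16.5, 23.4)
disagree with its own table arithmetic (16.6, 23.7) — presumably computed
before rounding — and this package does not force agreement with them.

## The fixture generator

Real inputs (a wheat-field video with one annotated frame, background
videos, unannotated field frames) are emulated procedurally so the whole
pipeline runs with no data: value-noise textures in a soil/canopy palette
for backgrounds; textured, shaded elliptical blobs for wheat heads, with
the mask defined as the exact union of ellipse footprints (checked against
per-pixel point-in-ellipse evaluation); and a global appearance shift —
hue rotation 50°, Gaussian blur σ 1.5 px, additive Gaussian noise
σ 0.05 — standing in for the synthetic-to-real domain gap. Test frames
are shifted frames with retained masks, emulating the study's 100
hand-annotated video frames without annotation tooling. Every fixture is a
pure function of (config, seed); reruns are byte-identical.

What the fixtures do **not** emulate: real canopy geometry (rows,
occlusion by leaves, depth-of-field), within-domain appearance diversity,
or annotation noise. Passing tests therefore demonstrate that the
machinery is correct and that translation closes an appearance gap of this
global kind — not that the pipeline reaches any particular accuracy on
real field imagery.

## Desk-scale study sizes

The acceptance runs use 64×64 frames, 120 composites (85% train), 24
unlabeled real frames, 8 test frames, a GAN with base width 12 and 2
residual blocks trained 6 epochs (~600 steps), U-Nets of depth 2 / base 8
trained 10 epochs, and 8 pseudo-labels with 4 fine-tuning epochs. These
sizes make the full study a minutes-scale, single-core computation while
preserving the study design (the stage ordering, losses, optimizers and
selection rules are identical to the full-scale configuration defaults).
At this scale the B-over-A ordering is robust; the C-over-B increment is
small and can be within noise, as expected with only 8 pseudo-labels.

## Numerical choices

The `maskcycle.nn` stack is float32 throughout; convolution is im2col +
GEMM with an explicit col2im backward; instance normalization has no
learned affine (following the translation literature's default) and
eps 1e-5. Weight init is N(0, 0.02) for GAN networks and N(0, 0.05) for
the U-Net. Bit-exact reruns are promised only for single-threaded,
fixed-seed execution; across BLAS thread counts losses reproduce to
tolerance, not bitwise. Binarization tie rules are uniform everywhere:
ties go to foreground (alpha ≥ 0.5, probability ≥ threshold, mask channel
≥ 0).

## Known limitations

- The NumPy stack is single-core and desk-scale; the full-scale defaults
  (256 px, 11,000 composites, 60+45+45 epochs) are expressible but not
  practical without a GPU framework behind the same interfaces.
- The pseudo-label confidence proxy rewards *confident* predictions, not
  *correct* ones; a systematically overconfident model defeats it. The
  review gallery exists precisely because of this.
- Separate generators for image and mask, density-map-guided paste
  layouts, and test-time augmentation are out of scope.
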