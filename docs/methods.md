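# Methods

## Problem setting

Semantic segmentation models for crop/weed discrimination are typically
trained on imagery acquired under controlled conditions (potted plants on a
uniform tray, flat illumination) and then deployed in paddy fields, where
background reflectance, illumination, water glare and clutter differ
systematically. Performance collapses under this domain shift even when the
plants themselves look similar. `swisseg` implements a domain-generalization
framework that attacks the problem in *feature space*: the appearance
("style") of an activation map is summarized by its per-channel moments, and
two complementary mechanisms randomize those moments during training so the
downstream network learns moment-invariant (style-invariant) representations.

## Style as channel moments

For a feature map x of shape (B, C, H, W), instance statistics are

    mu[b,c]    = (1/HW) sum_i x[b,c,i]
    sigma[b,c] = sqrt( (1/HW) sum_i (x[b,c,i] - mu[b,c])^2 + eps^2 )

per sample and channel, over spatial positions only (population variance;
eps = 1e-5 inside the square root so constant channels get sigma = eps). The
style vector is s = [mu ; sigma] in R^{2C}. The AdaIN-form moment injection

    out = sigma_t * (x - mu(x)) / sigma(x) + mu_t

replaces a map's moments with targets (mu_t, sigma_t) while preserving its
spatial layout. Both style mechanisms below are instances of this transform.

## Stochastic style transfer (RAIN)

A small fully connected VAE is trained over style vectors: the encoder maps
s to a latent Gaussian posterior N(xi, psi^2) (log-variance parameterization,
smoothly bounded to [-10, 10] so psi never overflows), a latent code is drawn
with the reparameterization trick z = xi + psi * noise, and the decoder
reconstructs a style vector whose sigma block passes through a softplus.
Sampling around encoded *field* styles yields novel, plausible styles that
are injected into *laboratory* content features (a config switch reverses
the direction). The training objective is

    L = lambda_content * L_content + lambda_s * L_style
        + lambda_KL * L_KL + lambda_rec * L_rec

with defaults lambda_content = 2e-4, lambda_s = 1.0, lambda_KL = 1.0,
lambda_rec = 5.0. L_content is the MSE between instance-normalized stylized
and content maps (zero under any moment injection, by construction);
L_style is the MSE between the stylized map's moments and the style source's
moments; L_KL is the closed-form KL to N(0, I); L_rec the squared distance
between original and reconstructed style vectors. Content and style losses
are defined directly in backbone feature space — no external pretrained
perceptual network is involved, keeping the package self-contained.

## Adversarial feature normalization (DGB)

A learnable per-channel pair (mu_adv, log sigma_adv) defines an adversarial
style that is injected by the same AdaIN-form transform. A gradient reversal
layer (identity forward, gradient scaled by -lambda_GRL backward) sits
between these parameters and the task loss, so one ordinary SGD step
descends the segmentation loss for the model while *ascending* it for the
adversarial statistics — the injected style chases feature distributions the
current model finds hard. The update step size is the style perturbation
rate beta = 0.01; lambda_GRL defaults to 1.0. The adversarial distribution
is initialized at the source features' own mean statistics, so early
perturbations start on the data manifold and drift outward adversarially.
Two stabilizers matter when the backbone is trained from scratch: the
CPU-scale profile ramps lambda_GRL linearly from 0 to 1 over the first 10%
of iterations (unrestrained ascent against a still-weak model otherwise
derails training), and DGB perturbs backbone stage 2 by default while RAIN
styles stage 1 — both transforms replace channel moments outright, so
applying them at the same stage would erase one another rather than
compose.

## Training protocol

When the backbone is trained from scratch (the default tiny backbone), a
brief supervised warmup (300 iterations in the CPU-scale profile) precedes
everything and is shared by every ablation variant; it stands in for the
externally pretrained backbone the full-scale protocol assumes, so that the
style statistics the VAE learns in phase 1 remain representative while the
backbone fine-tunes in phase 2.

Phase 1 pre-trains the Style VAE with Adam (lr 1e-3) on features from both
domains, with the backbone held fixed. Phase 2 freezes the VAE (its
parameters are verified bit-identical afterwards) and trains the
segmentation model with SGD at alpha = 0.03: each iteration draws a
class-presence-stratified laboratory batch, perturbs backbone features, and
minimizes pixel cross-entropy (ignore label 255) plus lambda_consist = 0.8
times the consistency penalty.

Three integration details matter and were deliberate design choices:

- **Stochastic application.** Each sample is perturbed with probability 0.5;
  unperturbed samples flow through untouched. Training every sample on
  injected statistics would starve the network of natural statistics and
  break plain-network inference (RAIN and DGB are training-time
  regularizers; inference uses the unmodified network).
- **Paired consistency.** The batch-mean consistency formula
  (1/N) sum_i ||z_i - z_bar||^2 is applied to each (clean view, stylized
  view) pair of the same image — for a pair it reduces to
  1/4 ||z_styl - z_clean||^2 — with the clean pooled-bottleneck reference
  detached. Applying it across *different* images instead provably collapses
  the pooled representation (all images pulled onto the batch mean), which
  we observed as dead channels and degraded segmentation. The standalone
  `consistency_loss` function implements the batch-mean form exactly and is
  what the pair application evaluates.
- **Separated stages.** RAIN styles stage-1 features, DGB re-normalizes
  stage-2 features (see above), so in the combined framework the two
  mechanisms perturb different statistics and compose.

## Backbone

The default backbone is deliberately small so the full benchmark runs on one
CPU core in minutes: three 3x3 conv stages (widths 8/16/16, stride 2/2/1)
with leaky-ReLU activations (slope 0.1 — plain ReLU at lr 0.03 kills
channels outright, and a dead channel has no meaningful style statistics), a
1x1 scoring head at 1/4 resolution, nearest upsampling, and a full-resolution
3x3 refinement convolution in class-score space (without it, boundary pixels
floor the achievable loss). Output score maps match the input size; H and W
must be multiples of 4. RAIN inserts after stage 1 and DGB after stage 2 by
default (both configurable). Any module exposing the same stage interface — e.g. a
DeepLabv3+/ResNet-50 adapter — can replace it; no test requires one.

All differentiable components run on the package's own reverse-mode autodiff
engine over numpy (`swisseg.autodiff`), whose primitives are verified
against central finite differences in the test suite.

## Synthetic two-domain benchmark

No public dataset accompanies the task, so the package ships a seeded scene
simulator that emulates the *structure* of a two-domain crop/weed dataset.
Laboratory scenes: uniform soil-colored background with mild smooth noise
and near-flat illumination. Field scenes at shift magnitude delta: background
reflectance moves toward wet paddy soil (per unit delta: -0.08/+0.04/+0.12
RGB), background noise +0.03, a directional illumination gradient (+0.30
amplitude), global brightness jitter (±0.25), Poisson-scattered specular
near-white glare blobs (rate 3) and background clutter ellipses (rate 4).
delta = 0 reproduces the laboratory distribution exactly. Plants are rotated
superellipse blobs with class-specific color, elongation, boundary exponent
and band-pass noise texture (one crop class, configurable weed classes);
scenes are composited back-to-front, the mask recording the top-most class
per pixel and the instance map the top-most instance.

The default benchmark is 64x64 images, 4 classes (background, crop, two
weeds), 200 laboratory training images, 100 field images (10% style/
validation, 90% held-out test), delta = 1 — sizes chosen once for single-CPU
runtimes. What the simulator does *not* model: photorealistic plant
morphology, 3-D geometry, growth stages, soil texture realism, or the
polarization physics of water glare. Passing the benchmark therefore shows
that the mechanisms bridge a controlled moment-level domain shift with
object-level confounders, not that they reach any particular accuracy on
real paddy imagery.

## Metrics

All metrics derive from a full K x K pixel confusion matrix over non-ignored
pixels. mIoU averages per-class IoU over classes present in ground truth or
prediction (absent classes are excluded; reported with and without
background). Precision, recall and F1 are micro-averaged over foreground
classes. Weed IoU merges all weed classes *at pixel level* before the IoU —
cross-species confusions inside the weed group count as true positives,
reflecting weeding-operation relevance. Values are percentages; zero
denominators yield 0 with a warning.

## Numerical choices and degenerate inputs

- float32 throughout; population variance with eps^2 = 1e-10 inside the
  square root; 1x1 spatial maps are legal (sigma = eps).
- Nearest-neighbour mask resizing uses exact index mapping, so no label id
  can be invented; rotation fills masks with the ignore label (255), images
  with black.
- Cross-entropy rejects batches in which every pixel is ignored; metrics
  reject inputs with no evaluable class.
- Stratified sampling weights each image by the mean inverse frequency of
  the foreground classes it contains; each epoch appends any images the
  weighted draw missed, so coverage is guaranteed.
- Every stochastic component takes an explicit numpy Generator; the full
  pipeline is bit-reproducible on CPU for a fixed seed.

## Known limitations

- The tiny backbone saturates well below the accuracy a modern pretrained
  segmentation network would reach; the benchmark measures *relative*
  cross-domain behavior of the style mechanisms, not absolute capability.
- The simulator's domain gap is dominated by global photometric shifts plus
  clutter/glare confounders; real paddy scenes add occlusion, species
  imbalance and optical effects the package does not model.
- Cross-domain scores on the benchmark retain seed-to-seed spread of a few
  mIoU points; conclusions should always be drawn from multi-seed means
  (the ablation harness reports mean ± sd over seeds).
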