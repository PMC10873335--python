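# Methods

`sparsect` studies how well learned image-to-image models remove the streak
artifacts that sparse-view CT acquisition produces, using a fully synthetic,
fully seeded pipeline: phantom cohort → fan-beam projection → filtered
backprojection → restoration model → ROI/whole-image metrics.  This note
records the models, the parameters that matter, the numerical choices, and
what the synthetic setting can and cannot show.

## Synthetic chest phantoms

Phantoms are additive ellipse compositions in Hounsfield units on a
−1000 HU air background: a soft-tissue body ellipse (≈ 40 HU), two lung
ellipses (≈ −800 HU) containing 5–10 vessel-like inclusions each
(≈ −250 HU, semi-axes 1–4 px at the 512-px reference grid, scaled down
proportionally on smaller grids), a circular bony spine (≈ 700 HU) and,
with probability 0.5, a soft-tissue-density tumor nodule in one lung.
Parameter ranges are fixed package defaults chosen to give HU-correct
tissue classes and plausible chest proportions; they are not fitted to any
patient population.

All anatomy is confined to the inscribed circle of the square grid.  This
is a geometric requirement, not a cosmetic one: a fan beam with a finite
detector arc covers exactly that circle, so line integrals of anything
outside it would be inconsistent between views.

A *cohort* groups slices under synthetic patients.  Slices of one patient
are the patient's base anatomy under small jitter (≤ 3 % on semi-axes,
≤ 2 px on centers), emulating the high correlation of adjacent 3 mm CT
slices.  That correlation is the reason data splitting must be
patient-level — a slice-level split would place near-duplicates of
training images in the evaluation set — and the cohort structure makes
that failure mode testable.

Measurement ROIs (lung 40×40, soft tissue 40×40, bone 15×15, air 50×50
pixels at 512 px, proportionally scaled below that with a 3-px floor) are
placed algorithmically: the rectangle must lie entirely inside a
homogeneous region of its tissue class, and among valid positions the one
whose center lies deepest inside the region is chosen.  Placement is
deterministic given the phantom; the air ROI is restricted to the
inscribed circle so that it sees reconstruction streaks rather than the
constant −1000 HU mask.  Generated phantoms have exactly piecewise-constant
tissue, so the per-ROI standard deviation is 0 HU, well under the 30 HU
homogeneity bound asserted by the tests.

The standard 10-ellipse Shepp–Logan head phantom is included as a
reconstruction-chain validation object, with its published intensities
mapped affinely to HU (summed intensity 0 → −1000 HU, peak 2 → +1000 HU).

## Fan-beam acquisition

Equiangular geometry: the source rotates on a circle of radius 400 px
around the image center (one full 360° rotation); detectors sit on an arc
at 0.25° spacing, with an odd detector count so the central ray passes
through the rotation center.  The detector count is the smallest that
covers the inscribed circle, `2*ceil(asin((size/2)/D)/Δγ) + 1`
(151 channels at 256 px).  Sparse scans acquire views every 1°, 2°, 5° or
10°.

Projection integrates HU values directly — no conversion to attenuation
coefficients.  Because projection and FBP are both linear, HU in gives HU
out, which is what lets reconstruction error be read directly on the HU
scale.  Each ray is integrated by the midpoint rule along its chord
through the inscribed circle, sampling the image by bilinear
interpolation at a default step of 0.5 px (halving the step changes
integrals by < 0.1 %; out-of-grid reads return −1000 HU but cannot occur
for chord-restricted midpoint samples).  Each view depends only on its own
source angle, so the rows of a dense scan at angles shared with a sparse
scan are bit-identical to the sparse scan — sparse acquisition and view
decimation are provably the same operation here.

## Filtered backprojection

Direct equiangular fan-beam FBP in the textbook form: samples are
pre-weighted by `D·cos γ`, each view is convolved (zero-padded, full
support: kernel half-width = detector count) with the discrete Shepp–Logan
kernel

    h[n] = −2 / (π² Δγ² (4n² − 1)),

carrying the equiangular correction `½ (γ / sin γ)²` (≤ 2 % at these fan
angles), and backprojected with inverse-square source-to-pixel distance
weighting and the angular view step as the integration measure.  Pixels
outside the inscribed circle are set to −1000 HU so that air ROIs remain
meaningful.

Numerical fidelity, measured once against a fine-sampling reference
(projection step 0.125 px) and then frozen into the tests: a 256-px
uniform disc of 0 HU in air reconstructs with interior mean error < 1 HU
and MAE ≈ 2.6 HU; a 256-px chest phantom at the 1° interval reconstructs
with interior MAE ≈ 33 HU (dominated by Gibbs ringing at the ±840–1700 HU
tissue edges) and global SSIM ≈ 0.99.  The default and fine-sampling
reconstructions agree to 0.23 HU interior MAE, so the frozen acceptance
bound is 40 HU.  Artifact severity grows monotonically with the view
interval; at desk scale the 1°-vs-2° gap is small (both are near the
angular Nyquist rate at 128 px) but consistently ordered because the
comparison is paired on the same phantoms.

## Restoration models

All three models map a unit-range artifact image to a unit-range restored
image and are exposed as sklearn-style estimators
(`fit(X, y)` / `predict(X)`, parameters via `get_params`/`set_params`):

* **AERestorer** — four encoder layers of 3×3 convolution → ReLU → 2×2
  max-pool starting at 8 filters (doubling per level), mirrored
  transposed-convolution decoder, sigmoid output; MSE loss, Adam
  (lr 0.001), batch size 4.
* **UNetRestorer** — same encoder shape with 64 initial filters at full
  scale and skip connections concatenating each encoder stage into the
  decoder (a depth-1 decoder stage therefore consumes 64 upsampled + 64
  skip channels); MSE loss, Adam (lr 0.001), batch size 4.
* **CGANRestorer** — pix2pix-style conditional GAN.  The generator is a
  U-Net-shaped encoder-decoder of convolution → batch-norm → ReLU modules
  with stride-2 downsampling; dropout (p = 0.5) on the deepest decoder
  stages is the noise source, the pix2pix convention, rather than an
  explicit noise channel.  The discriminator is a PatchGAN: four stride-2
  convolutions (LeakyReLU 0.2, batch-norm except the first) over the
  channel-concatenated (condition, candidate) pair, then a 1-channel
  sigmoid head — a 64×64 input yields a 4×4 patch-score map.  Objective:
  the discriminator ascends `E[log D(x,y)] + E[log(1 − D(x,G(x,z)))]`
  (patch-map means realize the expectations), with the usual ½ factor on
  its update slowing it relative to the generator; the generator descends
  the non-saturating form `−E[log D(x,G(x,z))] + λ·L1(G(x,z), y)` with
  λ = 100.  Adam (lr 0.0002, β₁ = 0.5) for both, batch size 1.

  The discriminator's filter count defaults to a quarter of the
  generator's (minimum 2).  This balance matters: controlled comparisons
  at desk scale (held-out SSIM under identical data and seeds) showed a
  symmetric discriminator wins the game early — its gradient noise stalls
  the generator's L1 convergence below the identity mapping — while an
  L1-only ablation converges cleanly; shrinking the discriminator restores
  stable joint training.  The symmetric pix2pix sizing remains available
  via ``disc_filters``.

  For the same reason the training schedule warms up: the first third of
  the epochs trains the generator on the weighted L1 term alone, and the
  adversarial game starts only once the generator is already competent.
  Without the warm-up, joint training from scratch converged or stalled
  depending on the run; with it, the adversarial phase consistently starts
  from (and stays near) the L1 optimum.  ``warmup_epochs`` overrides the
  default.

The networks are implemented on a small NumPy layer stack
(`sparsect.nn`: conv, transposed conv, max-pool, batch-norm, dropout,
Adam) with hand-written backpropagation, verified against central finite
differences in the tests.  Training is single-threaded and bit-reproducible
given a seed.  Where layer details were open, transposed convolution was
chosen for upsampling/"reconstruction" stages, and the discriminator's
"four convolutional layers" reading is a four-layer stride-2 stack.

### Normalization

Each training pair is scaled to (0, 1) with the *artifact* image's
(min, max); the original is scaled with the same record (and clipped, the
streak over/undershoots make the artifact range a superset of the truth
range in practice).  At inference the model output is mapped back to HU
with the input image's own record — the only record available when no
ground truth exists.  Using one record per pair keeps that inverse exact
for a perfect model; normalizing each image by its own range would make
the fixed inverse mapping systematically biased.  A consequence worth
knowing: predicted HU values always lie inside the input image's range.

## Evaluation

* **ME / MAE** — signed and absolute mean HU difference inside each tissue
  ROI.
* **SSIM** — computed *globally*: one window covering the whole image,
  with C₁ = (0.01·2000)² = 400 and C₂ = (0.03·2000)² = 3600 from a
  2000 HU dynamic range.  A sliding-window variant (`ssim_windowed`) is
  provided but not used in the headline numbers.  Global SSIM is dominated
  by mean/variance/covariance agreement, so its absolute values run much
  higher than windowed SSIM on the same images; orderings between
  conditions are the meaningful comparison.
* **PSNR** — `10·log10(max(X)²/MSE)` with the peak taken over the
  evaluated image X (literal reading; a fixed-range option exists).
* Reports aggregate per-image metrics to mean ± sample (n−1) standard
  deviation per (model, view interval, region, metric) cell, with
  two-tailed Welch t-tests against the with-artifacts condition
  (Student's pooled variant available) flagged at p < 0.005.

Metrics are computed in HU after denormalization.

## Desk-scale protocol and determinism

The package defaults target a single CPU: 64-px phantoms, 8 base filters,
cohorts of ~24 patients × 10 slices (≈ 200 training pairs after the 90/10
patient split), 30 epochs.  The full-scale setting (512 px, 64 initial
filters, 200 epochs, 40 patients × ~106 slices) is expressible through the
same configuration objects.  Every stage — cohort, split, initialization,
data order, dropout — derives from explicit seeds, and two runs of the
pipeline with one seed produce identical report tables.

At desk scale the trained CGAN improves held-out global SSIM and MAE over
the uncorrected artifact images at the sparsest (10°) interval.  The MSE
baselines also train stably here; with tiny images, piecewise-constant
anatomy and few training slices, the supervised U-Net can outperform the
CGAN — the blur-driven failure of MSE models is a fine-texture phenomenon
that 64-px ellipse phantoms only weakly exercise.

## Limitations

The generator emulates HU-correct tissue geometry, not radiography: no
photon noise, detector blur, beam hardening, scatter, or texture inside
tissues; no 3D/helical geometry.  Passing tests therefore demonstrate
that the simulation chain is numerically faithful and that the training
machinery learns to invert it at desk scale — they do not demonstrate
clinical performance, and they cannot reproduce patient-data magnitudes.
Generative restoration can hallucinate plausible structure; nothing in
this package detects or flags that.
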