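# Methods

`spectden` re-creates, end to end and at desk scale, a projection-domain
deep-learning denoising study for fast (reduced acquisition time) myocardial
perfusion SPECT: a synthetic patient cohort, the acquisition and
time-reduction model, OS-EM reconstruction, an attention-guided conditional
GAN with U-Net and cGAN baselines, and the quantitative evaluation protocol.
This note records the models, the conventions chosen where the design was
genuinely open, and what the synthetic experiments do and do not demonstrate.

## Synthetic cohort (`spectden.phantom`)

Each subject is a pair of 3D maps on a configurable grid (64 x 64 x 24 at
0.6096 cm voxels by default, matching the clinical reconstruction matrix the
package emulates):

* **Activity**: a truncated ellipsoidal left-ventricular shell (outer
  short-axis radius 2.8-3.4 cm, wall 0.9-1.3 cm, long-axis factor 1.3-1.5,
  basal opening at 0.55 of the long semi-axis) with uniform uptake 1.0,
  embedded in a soft-tissue body ellipse at a background:myocardium ratio of
  0.15. With probability `defect_fraction` (default 0.36, the prevalence of
  the emulated cohort) an azimuthal sector of the wall has its uptake reduced
  by a severity drawn from 0.3-0.8; the sector width is drawn so defects span
  roughly 5-30% of the wall.
* **Attenuation**: soft tissue at 0.15 cm^-1 (140 keV), two lung inserts at
  0.04 cm^-1, air outside the body.

Geometry jitter (center, radii, wall thickness, defect azimuth) is sampled
per subject from a counter-based RNG keyed by `(cohort seed, subject index)`,
so any subject is bitwise reproducible in isolation. The ground-truth defect
extent (% of wall voxels) and the binary defect label are carried as
metadata.

The phantom is deliberately minimal: no respiratory or cardiac motion, no
papillary muscles, no liver by default (a flag adds one), axis-aligned LV
long axis. It produces the features the pipeline needs — a bright wall whose
regional uptake can be degraded and recovered — and nothing more. Results on
it show that the pipeline works as specified, not that the network would
reach clinical performance on patients.

## Acquisition model (`spectden.projector`)

An ideal parallel-beam geometry over 180 degrees (60 views by default)
replaces the scanner's CZT fan geometry. Each view rotates the volume in the
transaxial plane and sums along an axis; the rotation is an explicit sparse
bilinear-interpolation matrix, so the backprojector is the exact transpose
and the operator pair passes an adjointness test at machine precision —
this matters because OS-EM's fixed points depend on forward/backprojector
consistency. Attenuation enters as per-voxel weights
exp(-integral of mu to the detector) computed once per view from the mu map
(with a half-voxel self-contribution), keeping the operator linear in the
activity. No collimator-detector response, scatter, or randoms are
simulated; the dual-energy-window scatter correction of the emulated
protocol therefore reduces to the identity.

Counts are calibrated so the noiseless full-time stack has a configurable
mean of 2e4 counts per view (chosen so 1 s/view stacks are visibly
noise-dominated), then Poisson noise is drawn per bin. Fast acquisitions at
t < T seconds per view are **binomial thinnings** with p = t/T of the noisy
full-time counts: thinning a Poisson process yields a Poisson process with
the scaled mean, which is statistically identical to truncating a list-mode
stream at the corresponding fraction of events. Thinnings compose
(10 s -> 5 s -> 1 s matches 10 s -> 1 s in distribution), which the tests
verify by simulation.

## Reconstruction (`spectden.osem`)

Standard OS-EM with the emulated clinical settings: 5 iterations, 4 subsets
(view i in subset i mod 4, processed in order), strictly positive uniform
start, epsilon = 1e-12 guarding empty-bin denominators (frequent at
1 s/view). Multiplicative updates keep the image non-negative at every
sub-iteration; with one subset the algorithm is MLEM, asserted against an
independently coded loop. The full-time reference image is post-filtered
with an isotropic 3D Gaussian of 0.6 voxel (reflect boundaries, count
preserving); fast and denoised reconstructions are never post-filtered.

## Preprocessing (`spectden.preprocess`)

Projection stacks are normalized to [0, 1] by division by a maximum. The
fast and full-time stacks of a subject share the **full-time** maximum by
default, so the count-level contrast (a p = 0.1 stack peaks near 0.1)
survives normalization; per-stack self-normalization is available behind the
`mode` switch since the emulated protocol does not state which was used.

The binary patient defect flag is embedded by appending four constant
64 x 64 slices at the tail of the view axis. The choice "tail" is a package
constant (the position is not stated in the emulated protocol); embedding
and stripping are exact inverses, and the four extra generator-output slices
are stripped before any loss is computed, so the flag conditions the network
without entering the regression target.

## Networks (`spectden.attgan`, `spectden.nn`)

The generator is a 3D U-Net: per resolution level one block of
[conv 3x3x3 - batch norm - ReLU - dropout 0.5], max-pooling between encoder
levels, nearest-neighbour upsampling in the mirrored decoder, one skip
connection per level, and a pointwise head with ReLU output (projection
counts are non-negative). The filter count is constant across layers; the
searched grid of the emulated protocol is {8, 16, 24, 32, 40} filters and
2-5 levels, with 3 levels / 32 filters as the package default and 3 levels /
16 filters in the desk-scale experiments.

**Attention gates.** The gate computes, from encoder features x and the
mirrored decoder features d, two pointwise projections g = W_g x and
f = W_f d, channel-resolved products u_i = ReLU(f_i * g_i) (whose channel
sum is the position-matched diagonal of the dense pairwise dependency map
f_i . g_j), a pointwise score map e = psi(u), and channel-axis softmax
weights r.  The gated skip is Att = C * r * x, a bounded per-channel
reweighting: r sums to one along its normalization axis (channels), uniform
r reduces exactly to the plain skip, and the gain is bounded by the channel
count. Two spatial-axis softmax variants were evaluated and rejected: an
elementwise form whose N-fold rescaling let single voxels dominate and
destabilized training, and a pooled form (the weighted spatial average
broadcast over positions) that is stable but reduces every skip to a global
context vector, discarding the spatial detail a U-Net needs. A brute-force
dense pairwise map is kept as an oracle for small feature maps; the tests
verify the diagonal identity and the degenerate case W_f = 0 (uniform r,
Att = x).

**Discriminator.** A conditional patch discriminator on the channel-
concatenated (fast, candidate) pair: four stride-2 3x3x3 conv levels with
filters 32/64/128/256, LeakyReLU(0.2), batch norm from the second level,
and a pointwise head whose patch logits are averaged.

**Losses and training.** Non-saturating cross-entropy adversarial loss plus
lambda = 100 times the L1 error to the normalized full-time stack;
discriminator trained with cross-entropy on (fast, FT) = real,
(fast, G(fast)) = fake, the real and fake halves processed in one batched
pass. Adam, batch size 1 (the pix2pix convention, which also maximizes
update count at a fixed epoch budget). Batch normalization uses
current-batch statistics in evaluation as well — at batch size 1 this is
instance normalization, again the image-to-image translation convention;
population running statistics at batch size 1 create a train/eval
distribution gap that collapsed evaluation outputs in early versions.
The learning rate default is 1e-4, the emulated protocol's initial rate for
its 400-epoch schedule. The desk-scale configuration compresses the
schedule to 50 epochs and rescales the rate linearly to 8e-4 so that
(rate x steps) is preserved; this was settled with a single-pair overfit
diagnostic of the optimizer mechanics, not by tuning against the evaluation
metrics. Baselines nest structurally: gates off gives the cGAN generator;
adversarial term off gives L1-only U-Net training; the defect-conditioned
variant (AttGAN-def) only adds the four-slice input block.

All networks run on the package's own numpy compute engine: a small
reverse-mode autodiff graph whose 3D convolutions gather the 27 kernel-offset
slabs into a column buffer once and run forward, weight-gradient and
input-gradient passes as single BLAS gemms (hot gather/scatter loops are
numba-jitted with a numpy fallback). Every operation's gradient is checked
against central finite differences in the test suite.

## Evaluation (`spectden.metrics`)

Voxel indices are computed in a cubic VOI (18^3, N = 5832 by default)
centered on the known LV centroid, against the filtered full-time
reconstruction:

* NMSE = sum (I_D - I_FT)^2 / sum I_FT^2;
* SSIM as a single global index over the VOI with C1 = 0.01, C2 = 0.02
  taken at face value (not the (K L)^2 derivation, and not sliding-window);
* PSNR = 10 log10(MAX_FT / MSE) — the numerator is the maximum itself, as
  printed in the emulated protocol; `convention="standard"` provides the
  squared-maximum form.

The polar map is a circumferential profile: maximum interpolated counts
along radial rays from the LV long axis, per short-axis slice and azimuth.
The intensity ratio is mean(defect ROI) / mean(normal ROI) with ROIs placed
from the synthetic ground truth (defect azimuth and extent; a fixed sector
for defect-free subjects). The **defect-extent surrogate** is the percent of
polar-map pixels below 0.6 of the normal-region mean — a documented
threshold rule standing in for proprietary clinical perfusion-defect-size
software, not a re-implementation of it. Bland-Altman limits are the mean
difference +/- 1.96 SD; joint regression is OLS of method voxels on
reference voxels with R^2 the squared Pearson correlation; paired
comparisons use the two-tailed paired t-test with Bonferroni correction
(degenerate zero-variance differences report p = 1 for identical series).
Every index is checked against an independently coded brute-force
implementation.

When raw fast stacks are evaluated as a baseline, the reconstruction is
multiplied by T/t (count-rate normalization): a thinned acquisition carries
about p times the counts, and without rescaling the comparison to the
full-time reference is dominated by the trivial scale factor rather than by
noise. OS-EM is scale-equivariant, so image- and projection-domain
rescaling are interchangeable.

## Cross-validation harness (`spectden.cv_harness`)

Fold plans shuffle the cohort once (seeded) and take contiguous blocks:
test = n/5 subjects, validation = the next n/10 cyclically, training = the
rest (35/5/10 at n = 50); the five test sets partition the cohort exactly
once and no subject enters validation twice. Training is dose-specific (one
model per acquisition-time level). Model manifests record the training
subjects and evaluation refuses to score a subject the model saw. An
identity (no-op) denoiser runs the entire pipeline unchanged as a wiring
check.

## Desk-scale study conditions

The packaged experiments (`toy_config`) use: 50 subjects on 32^3 grids at
0.6096 cm; 16 views over 180 degrees on a detector rebinned 2 x 2 to
16 x 16 (coarser bins, counts preserved); full time 10 s/view at 2e4 mean
counts per view, thinned to 1 s/view (p = 0.1); reconstruction on a 16^3
grid with the clinical 5 iterations / 4 subsets; a 3-level, 16-filter
generator trained 50 epochs at 8e-4; a 12^3 VOI (the 16^3 reconstruction
cannot hold the default 18^3). One fold (35 train / 5 validation / 10 test)
per seed; the seed controls acquisition noise, thinning and training, while
the cohort geometry is a fixed study condition. At these sizes one full
experiment (simulation, training, reconstruction, evaluation) takes about
two minutes on one CPU core.

Across ten seeds the attention-GAN consistently lowers the NMSE of
1 s/view fast SPECT against the filtered full-time reference (typically
0.05-0.10 versus about 0.33 for the count-rate-scaled raw fast images) and
improves SSIM, PSNR, the intensity-ratio error and the defect-extent
surrogate error on average; `scripts/acceptance.py` recomputes these
quantities from scratch. These synthetic results demonstrate the claimed
qualitative effect — projection-domain adversarial denoising recovers
fast-SPECT image quality toward the full-time reference — under ideal
conditions (known LV axis, no scatter, no motion, a simple phantom). They
do not reproduce the clinical cohort's absolute numbers, which depend on a
private dataset, real count levels and proprietary defect-size software.

## Numerical choices and limitations

* Projector rotations use inverse-mapping bilinear interpolation; mass is
  conserved only to a few percent at oblique angles (quasi-interpolation),
  which is irrelevant for reconstruction (the same operator pair is used
  forward and backward) but visible in single-voxel projection tests.
* OS-EM epsilon 1e-12; subset order fixed 0..3 unless overridden; a subset
  permutation changes the 5-iteration result by well under 2% NMSE.
* Gaussian post-filter boundary mode "reflect" (count preservation).
* The polar map assumes the LV long axis along z (true for the phantom);
  clinical reorientation is out of scope.
* PSNR on identical images returns +inf as a sentinel.
* Networks compute in float32; reconstruction and metrics in float64.
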