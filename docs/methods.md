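# Methods

`mrxform` studies probabilistic MR contrast translation: given an axial
brain slice of one contrast (e.g. T1-like), produce not a single
transformed slice of another contrast (T2-like) but an ensemble of
plausible transformed slices, and use the ensemble's pixel-wise spread for
uncertainty maps and out-of-distribution (OOD) detection. Everything runs
on synthetic paired-contrast phantoms so the full pipeline — data, four
trained models, metrics, OOD analysis — executes on one CPU in minutes.

## Problem formulation

A paired dataset S = {(x_i, y_i)} holds co-registered 2D axial slices of
an input contrast x and a target contrast y of the same anatomy, min-max
normalized to [0, 1]. The deterministic view fits one map f(x) ≈ y by
least squares. The probabilistic view treats (X, Y) as random and samples
from the conditional p(y | x): for a single input there is an ensemble of
valid outputs, whose pixel-wise mean is the point prediction and whose
pixel-wise standard deviation is an uncertainty map.

## Models

All four models share one encoder–decoder ("U-Net") backbone — paired
comparisons are then about the objective, not the architecture. The
backbone has `depth` resolution levels (default 2 at 32×32), channel
widths doubling per level, GroupNorm + SiLU blocks, skip connections, an
optional sinusoidal time embedding injected additively at every level, and
an optional latent vector injected through conditional instance
normalization (CIN: instance-normalize features, then scale/shift them
with a learned linear map of the latent).

- **Direct**: minimizes (1/2N) Σ ‖y_i − f(x_i)‖²; one output per input.
- **cGAN** (Wasserstein, gradient penalty): generator g(x, z) with
  z ~ N(0, I_128) injected via CIN; critic d(x, y) trained to maximize
  E[d(x,y)] − E[d(x,g(x,z))] − λ E[(‖∂_ŷ d(x, ŷ)‖−1)²] with
  ŷ = εy + (1−ε)g(x,z), ε ~ U(0,1) per sample and λ = 10; the generator
  minimizes −E[d(x, g(x,z))] with no pixel reconstruction term. Five
  critic steps per generator step, Adam(β₁=0, β₂=0.9).
- **NCSN** (variance-exploding diffusion): forward y_t = y₀ + √β_t ε with
  a geometric β schedule (1e-4 … 1.0); a time-conditioned network s̃ learns
  the score by denoising score matching,
  L = (1/2T) Σ_t β_t E‖s̃(y_t, x, t) + (y_t−y₀)/β_t‖² (one uniformly
  sampled t per example — the standard unbiased estimator). The network
  predicts a unit-scale residual and the score is net/√β_t, so every level
  contributes at the same scale. Sampling runs annealed Langevin dynamics
  y_{t−1} = y_t + γ_t s̃ + √(2γ_t) ε from y_T ~ N(0, β_T I), with step
  size γ_t = λ_γ β_t / β₁.
- **DDPM** (variance-preserving diffusion): forward
  y_t = √ᾱ_t y₀ + √(1−ᾱ_t) ε with a linear β schedule; the network
  predicts ε (loss ‖η̃ − ε‖²) plus a small variational term (weight 1e-3)
  that trains the reverse noise scales β̃(t), parameterized per step as a
  log-space interpolation between β_t and the forward-posterior variance
  (sigmoid-mapped scalar per t, mean path stop-gradiented). Ancestral
  sampling starts at N(0, I), injects √β̃(t) noise except at the final
  step.

### Numerical choices that mattered

- **Langevin step scale.** With γ_t = λ_γ β_t/β₁ and a score of magnitude
  1/β_t, the per-step contraction is λ_γ/β₁ — stable only for
  λ_γ < 2β₁. The default is λ_γ = 0.3 β₁ (contraction 0.3 per level),
  which converges for both analytic and learned scores; a fixed constant
  such as 0.05 would exceed the bound by orders of magnitude whenever
  β₁ ≈ 1e-4.
- **DDPM schedule compression.** The reference linear schedule
  (1e-4…0.02) is tied to T = 1000; at desk scale T = 100 it leaves
  ᾱ_T ≈ 0.37, so the N(0, I) sampling start does not match the forward
  terminal distribution. Defaults therefore rescale β by 1000/T
  (1e-3…0.2 at T = 100) so ᾱ_T ≈ 4e-5.
- **Reverse-chain guard.** Each DDPM reverse step clips the implied clean
  image x̂₀ = (y_t − √(1−ᾱ_t) ε̂)/√ᾱ_t to [0, 1] before forming the
  posterior mean — algebraically identical when x̂₀ is in range, and the
  standard guard against the reverse chain amplifying denoiser error by
  1/√ᾱ_T. Without it the desk-scale chain diverges; with it, isolated
  outlier pixels remain the model's characteristic failure mode, handled
  by the ensemble repair step below.
- **Outlier repair.** The DDPM mean image occasionally carries isolated
  hyper/hypo-intense pixels. Pixels whose ensemble std exceeds
  median + 5·MAD (computed within the brain mask) have their mean value
  replaced by the pixel-wise median. The rule is idempotent and local.

## Networks without a deep-learning framework

The models are trained with a compact reverse-mode autodiff engine over
numpy (`mrxform.nn.autodiff`): a primitive set (arithmetic, reductions,
reshape/concat/slice, matmul, convolution) whose vector-Jacobian products
are themselves built from the same primitives, so gradients of gradients
are available — required by the WGAN gradient-penalty term, whose critic
update differentiates the critic's own input-gradient norm. Convolution
runs as one full-plane GEMM per layer followed by contiguous shifted
accumulation. Gradient correctness, including the double-backprop path, is
verified against central finite differences in the test suite.

## Synthetic phantoms: what they emulate and what they do not

Each subject is a stack of axial slices built from nested ellipses: a
gray-matter shell, white-matter interior, two CSF "ventricles", and 2–4
deep-gray blobs, with per-subject geometric jitter and smooth radius
modulation along the slice axis. One tissue label map is rendered under
per-contrast intensity profiles (T1-like: CSF dark, white matter bright;
T2-like: CSF bright, white matter dark), so the cross-contrast map is an
exact per-class function of shared anatomy — by construction a consistent
conditional-mean estimator can reach SSIM → 100, which is what makes the
end-to-end recovery tests meaningful. Realism knobs: per-subject per-class
intensity jitter (shared across contrasts, keeping the map learnable), a
multiplicative bias field (exponential of a low-order 2D polynomial),
additive Gaussian noise, and min-max normalization after clipping to
[0, 1].

OOD corruptions: periodic bright dashed stripes (RF zipper), an attenuated
shifted copy (ghosting), amplified noise (low SNR), one smooth hyperintense
blob visible only in the target contrast (tumor — reproducing the failure
mode where models cannot reconstruct pathology absent from the input), and
small white-matter foci strongly visible in the target and faintly in the
input (lesions). Severities are free parameters of the generator, fixed
once (zipper amplitude 0.6, ghost weight 0.35, noise ×4, tumor radius
~9 % of the image side).

Deliberate simplifications: Gaussian rather than Rician noise (keeps the
within-class variance checks analytic), 2D elliptical geometry rather than
anatomy, no k-space simulation or partial-volume effects. Passing tests
therefore demonstrate correctness of the machinery and recoverability of a
separable contrast mapping — not performance on real MR data.

## Evaluation layer

- **SSIM** is computed on full normalized 3D volumes (uniform 7³ window,
  K1 = 0.01, K2 = 0.03, data range 1, sample-covariance normalization),
  reported as a percentage; the implementation is independent and is
  cross-checked against scikit-image to 1e-6 in the tests. A
  mask-restricted variant zeroes both volumes outside the brain first.
- **BSSIM**: SSIM between slice-wise Sobel gradient-magnitude maps, the
  two edge volumes jointly min-max renormalized.
- **SCSSIM**: 100·(1 − mean |ΔSSIM profile|) where a volume's profile is
  the sequence of 2D SSIMs between consecutive axial slices.
- **PSNR**: 10 log₁₀(1/MSE) dB; identical volumes yield an inf sentinel.
- **Perceptual distance** follows the LPIPS layer-sum form
  Σ_l (1/H_l W_l) Σ_{h,w} ‖w_l ⊙ (φ_l(y¹) − φ_l(y²))‖² with a pluggable
  extractor; the default is a fixed-seed random convolutional pyramid with
  channel-unit-normalized features (three layers, widths 8/16/16), so no
  pretrained weights are needed; per-slice values are averaged over the
  volume.
- **Model comparison**: pairwise one-sided Wilcoxon signed-rank tests on
  per-subject values (zero differences dropped; all-zero ⇒ p = 1); the
  best set contains every model no other model significantly beats at
  α = 0.05.

## Uncertainty and OOD analysis

Ensembles use the population (1/n) standard deviation, matching the
printed mean/std formulas. σ̂ (sigma_hat) is the std image averaged over
brain-mask voxels — one scalar per subject. Coverage curves build central
per-pixel intervals from empirical sample quantiles (linear interpolation,
symmetric tails; central rather than highest-density intervals — an
interpretation choice, flagged here) and report the fraction of masked
target pixels inside, per nominal level. Per-pixel normality uses
Shapiro–Wilk on a random subsample of masked pixels (default 2000) with
cumulants κ₁–κ₄ alongside.

For OOD detection, σ̂ is the classifier score (ID = 0, OOD = 1): ROC/AUC
(trapezoidal, tie-midpoint convention via scikit-learn), F1 swept over all
midpoint thresholds, then isotonic calibration: five folds over the ID
validation subjects, each fold joined with a randomly selected OOD subset
of matching size, per-fold isotonic fits averaged on a fixed score grid
into one monotone map, applied only to held-out test scores. "Normalized"
σ̂ means min-max scaling by the pooled validation range. Reliability:
ECE with 10 equal-width bins, Brier score, and NLL with probabilities
clipped at 1e-6.

## Study design and problem sizes

The default study trains on phantoms rendered under the generator's
realistic conditions — per-subject intensity jitter, bias field, additive
noise (14 subjects, 32×32 slices, 8 slices each, subject-level
70/15/15 split). Training on the degenerate noiseless task would collapse
every generative model's conditional spread to a point mass, making the
ensemble std — and hence σ̂ — structurally uninformative; with realistic
variability the ensembles carry genuine spread, as in the study design
this package emulates. Similarity metrics are then evaluated on two held-out
*noiseless twins* (same geometry seeds, perturbations off): on that
separable task the exact per-class contrast map exists, so SSIM → 100 is
the designed ceiling for a consistent estimator. Coverage and per-pixel
distribution checks use realistic held-out subjects, whose targets carry
the variability the ensembles are supposed to capture.

All models share the width-16, depth-2 backbone; 300 optimization steps
for the diffusion models, 300 generator steps (×5 critic steps) for the
cGAN, 150 for the baseline; T = 100 diffusion steps; n = 10 samples per
ensemble. The σ̂ sweep uses a separate labelled cohort (8–10 ID subjects,
3 per artifact kind, 1–2 per pathology kind, 3–4 slices per subject) and
reports AUC both against artifact corruptions (zipper/low-SNR) and
against all OOD kinds pooled; calibration uses two further disjoint
cohorts (8 ID + 1 per OOD kind each) scored with the cGAN, whose
sampling is single-pass and cheap. The σ̂ ROC estimates at these cohort
sizes are granular (8 ID × 6 artifact subjects gives AUC steps of 1/48),
so detection AUCs carry a run-to-run spread of roughly ±0.05–0.1 around
the underlying separability; the tests treat the detection thresholds as
stochastic at fixed seeds.
These sizes were chosen so the complete study — all four models trained
and analyzed — runs in roughly a quarter hour on one CPU.

## Known limitations

- The phantom's contrast map is nearly pixel-wise separable; models are
  not tested on long-range context, and the cGAN's known boundary
  distortions on real data only appear here in attenuated form.
- n = 10 ensembles make σ̂ itself noisy (relative SE ≈ 1/√(2n) ≈ 22 % per
  pixel before mask averaging); subject-level σ̂ is stable because it
  averages hundreds of voxels.
- The learned DDPM reverse variance is a per-step scalar, not the
  per-pixel prediction used by larger implementations.
- Isotonic calibration on small score cohorts is step-like; ECE
  improvements are demonstrated on simulated large score sets in the tests
  and on the cGAN cohort in the study.
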