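# mrxform

Probabilistic MR contrast translation on synthetic brain phantoms:
conditional generative models that map an axial brain slice of one MR
contrast (T1-like) to an *ensemble* of plausible slices of another
contrast (T2-like), with ensemble-based uncertainty maps and
out-of-distribution (OOD) input detection.

Brain MR image translation is usually treated deterministically — one
input, one output, no confidence attached. Because the same anatomy can
yield many valid images of a given contrast (scanner, protocol, noise),
the translation is better viewed as sampling from a conditional
distribution p(y | x). This package implements and compares, end to end
on synthetic paired-contrast phantoms:

- **Direct** — a deterministic U-Net baseline trained with the
  mean-squared loss L = (1/2N) Σᵢ ‖yᵢ − f(xᵢ)‖².
- **cGAN** — a conditional Wasserstein GAN with gradient penalty:
  generator g(x, z), latent z ~ N(0, I₁₂₈) injected through conditional
  instance normalization; critic d(x, y) maximizing
  E[d(x,y)] − E[d(x,g(x,z))] − λ E[(‖∂_ŷ d(x,ŷ)‖ − 1)²], ŷ = εy + (1−ε)g(x,z).
- **NCSN** — a conditional noise-conditional score network:
  variance-exploding noising y_t = y₀ + √β_t ε, denoising-score-matching
  loss (1/2T) Σ_t β_t E‖s̃(y_t,x,t) + (y_t−y₀)/β_t‖², and annealed
  Langevin sampling y_{t−1} = y_t + γ_t s̃ + √(2γ_t) ε.
- **DDPM** — a conditional denoising diffusion model:
  y_t = √ᾱ_t y₀ + √(1−ᾱ_t) ε, ε-prediction loss with a hybrid term
  learning the reverse noise scales β̃(t), ancestral sampling, and a
  robust repair of the isolated outlier pixels this model produces.

For each input, n samples give a pixel-wise mean (the prediction), a
pixel-wise std (the uncertainty map), and a scalar score σ̂ — the std
averaged over brain voxels — used to classify inputs as normal or OOD
(RF-zipper stripes, ghosting, low SNR, tumor, white-matter lesions) via
ROC/AUC and F1, with isotonic-regression calibration and ECE/Brier/NLL
reliability metrics. The similarity layer computes SSIM/PSNR/BSSIM/SCSSIM
and an LPIPS-form perceptual distance on 3D volumes, plus one-sided
Wilcoxon signed-rank model comparisons.

All networks run on a compact numpy autodiff engine included in the
package (`mrxform.nn`), with double-backpropagation support for the
gradient-penalty term — no GPU or deep-learning framework needed.

## Worked example

Train all four models on a phantom cohort and run the complete analysis
(about 15 minutes on one CPU):

```bash
python analysis/02_run_study.py
```

which prints (seed 1):

```
--- similarity of ensemble means to the target contrast (test subjects) ---
 direct: masked SSIM 98.8%, BSSIM 98.4%, SCSSIM 99.0%
   cgan: masked SSIM 83.7%, BSSIM 72.3%, SCSSIM 96.0%
   ncsn: masked SSIM 99.1%, BSSIM 98.5%, SCSSIM 98.9%
   ddpm: masked SSIM 93.0%, BSSIM 90.5%, SCSSIM 89.9%

--- sigma_hat OOD detection ---
   cgan: AUC (artifacts) 0.771, max F1 0.778
   ncsn: AUC (artifacts) 0.792, max F1 0.842

--- calibration of cGAN sigma_hat scores ---
ECE 0.459 -> 0.363 after isotonic calibration
```

Reading these numbers: the deterministic baseline and the score network
solve the separable phantom task almost exactly (the per-class contrast
map is learnable, so SSIM near 100 is the designed ceiling); the cGAN and
DDPM recover it with larger stochastic losses — the cGAN with its
characteristic boundary softening (lowest BSSIM), the DDPM with residual
sampling noise. The scalar uncertainty σ̂ of the adversarial and
score-network models ranks corrupted inputs (zipper stripes, low SNR)
above clean ones well above chance (AUC ≈ 0.8; at these small cohort
sizes the estimate moves in steps of ~0.02), and isotonic calibration
lowers the expected calibration error of the raw scores. The ensemble
coverage and per-pixel normality summaries in the written
`study_results.json` show the same ordering the models are known for:
the score network is best calibrated, the cGAN overconfident.

Other entry points:

```bash
mrxform phantom --out results/phantoms --n-id 10 --n-ood-per-kind 2
mrxform study --seed 1 --out results/study
mrxform ood --scores results/study/sigma_hat_ncsn.csv --calibrate
python analysis/03_model_comparison.py      # Wilcoxon best-set per metric
python analysis/04_ood_swarm_and_roc.py     # ROC + score swarm figure
```

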