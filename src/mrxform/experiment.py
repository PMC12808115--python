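"""End-to-end study orchestration.

Ties the pieces together the way the study is designed: generate a paired
phantom cohort, train the deterministic baseline and the three generative
models on one contrast transformation, sample ensembles on held-out test
subjects, compute the similarity-metric report, sweep sigma_hat scores
over an ID/OOD cohort for ROC/F1 analysis, calibrate scores with isotonic
regression on a separate validation cohort, and compute regression-
calibration coverage. Every stage is driven by a single integer seed.

Problem sizes default to desk scale (32x32 slices, T=100 diffusion steps,
n=10 samples per ensemble) so a full study runs on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cgan import CganConfig, sample_cgan, train_cgan
from .data_io import make_paired_dataset
from .ddpm import DdpmConfig, ddpm_sample, train_ddpm
from .direct import TrainConfig, infer_direct, train_direct
from .ensemble_uq import coverage_curve, pixel_distribution_report, sigma_hat, summarize
from .metrics import (
    RandomConvExtractor,
    bssim,
    lpips_distance,
    masked_ssim3d,
    psnr,
    scssim,
    ssim3d,
)
from .ncsn import NcsnConfig, ncsn_sample, train_ncsn
from .ood_detect import OODScoreSet, calibrate_isotonic, f1_sweep, reliability_metrics, roc_auc
from .phantom import (
    CORRUPTION_KINDS,
    CorruptionSpec,
    DEFAULT_SEVERITY,
    PhantomSpec,
    corrupt,
    generate_cohort,
    generate_subject,
)

ALL_MODELS = ("direct", "cgan", "ncsn", "ddpm")


@dataclass
class StudyConfig:
    """Desk-scale study design; seeds are derived from one master seed."""

    image_size: int = 32
    n_train_subjects: int = 14
    n_slices: int = 8
    ood_n_slices: int = 3
    input_contrast: str = "t1"
    target_contrast: str = "t2"
    models: tuple = ALL_MODELS
    n_samples: int = 10
    T: int = 100
    cgan_width: int = 16  # one backbone family across all models
    diffusion_width: int = 16
    depth: int = 2
    direct_steps: int = 150
    cgan_gen_steps: int = 300
    diffusion_steps: int = 300
    n_id_auc: int = 8
    n_ood_artifact: int = 3  # per artifact kind (zipper, low_snr)
    n_ood_other: int = 1  # per remaining kind
    n_id_calib: int = 8
    n_ood_calib: int = 1  # per kind, calibration cohorts (cGAN scores)
    n_eval_subjects: int = 1
    n_coverage_subjects: int = 1
    calibrate: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.input_contrast == self.target_contrast:
            raise ValueError("transformation contrasts must be distinct")

    def phantom_spec(self, n_slices=None, seed_offset=0, noiseless=False):
        """Phantom rendering conditions for the study.

        The realistic defaults (intensity jitter, bias field, noise) are the
        training and OOD-sweep conditions — with them the conditional
        distribution has genuine spread, so ensemble std is a meaningful
        uncertainty. ``noiseless=True`` renders the same geometry without
        perturbations: the separable evaluation task whose exact per-class
        map puts an SSIM ceiling of 100 on a consistent estimator.
        """
        return PhantomSpec(
            image_size=self.image_size,
            n_slices=n_slices or self.n_slices,
            intensity_jitter_sd=0.0 if noiseless else 0.02,
            bias_field_amplitude=0.0 if noiseless else 0.1,
            noise_sd=0.0 if noiseless else 0.015,
            geometry_jitter=0.05,
            seed=self.seed + seed_offset,
        )


def _train_models(cfg: StudyConfig, train_split, log=print):
    states = {}
    if "direct" in cfg.models:
        log("training direct (MSE baseline)...")
        states["direct"] = train_direct(
            train_split,
            TrainConfig(steps=cfg.direct_steps, lr=2e-3, batch_size=16, seed=cfg.seed),
        )
    if "cgan" in cfg.models:
        log("training cGAN (WGAN-GP)...")
        states["cgan"] = train_cgan(
            train_split,
            CganConfig(
                gen_steps=cfg.cgan_gen_steps, lr=1e-3, batch_size=16,
                base_width=cfg.cgan_width, depth=cfg.depth, critic_width=12,
                seed=cfg.seed + 1,
            ),
        )
    if "ncsn" in cfg.models:
        log("training NCSN (denoising score matching)...")
        states["ncsn"] = train_ncsn(
            train_split,
            NcsnConfig(
                T=cfg.T, steps=cfg.diffusion_steps, lr=2e-3, batch_size=16,
                base_width=cfg.diffusion_width, depth=cfg.depth, seed=cfg.seed + 2,
            ),
        )
    if "ddpm" in cfg.models:
        log("training DDPM (epsilon prediction, hybrid loss)...")
        states["ddpm"] = train_ddpm(
            train_split,
            DdpmConfig(
                T=cfg.T, steps=cfg.diffusion_steps, lr=2e-3, batch_size=16,
                base_width=cfg.diffusion_width, depth=cfg.depth, seed=cfg.seed + 3,
            ),
        )
    return states


def predict_ensemble(model, state, subject, cfg: StudyConfig, seed):
    """Ensemble (or single-sample pseudo-ensemble for the direct model)."""
    x = subject.volumes[cfg.input_contrast]
    if model == "direct":
        pred = infer_direct(state, x)
        return summarize(pred.data[None], model_tag="direct", input_ref=subject.subject_id)
    if model == "cgan":
        return sample_cgan(state, x, n=cfg.n_samples, seed=seed)
    if model == "ncsn":
        return ncsn_sample(state, x, n=cfg.n_samples, seed=seed)
    if model == "ddpm":
        return ddpm_sample(state, x, n=cfg.n_samples, seed=seed, repair=True)
    raise ValueError(f"unknown model '{model}'")


def metric_rows(model, ens, subject, cfg: StudyConfig, fx):
    target = subject.volumes[cfg.target_contrast].data
    pred = np.clip(ens.mean, 0.0, 1.0)
    return {
        "subject_id": subject.subject_id,
        "model": model,
        "transformation": f"{cfg.input_contrast}->{cfg.target_contrast}",
        "ssim": ssim3d(pred, target),
        "masked_ssim": masked_ssim3d(pred, target, subject.mask),
        "psnr": psnr(pred, target),
        "lpips": lpips_distance(pred, target, fx),
        "bssim": bssim(pred, target),
        "scssim": scssim(pred, target),
    }


def _sigma_sweep(model, state, cohort, cfg: StudyConfig, seed):
    """sigma_hat scores over a labelled cohort for one generative model."""
    scores = []
    for j, sub in enumerate(cohort):
        ens = predict_ensemble(model, state, sub, cfg, seed + j)
        scores.append(sigma_hat(ens, sub.mask, label="ID" if sub.corruption.kind == "none" else sub.corruption.kind))
    return scores


def _auc_cohort(cfg: StudyConfig):
    """ID subjects plus artifact-style corrupted subjects for the ROC sweep."""
    spec = cfg.phantom_spec(n_slices=cfg.ood_n_slices, seed_offset=100)
    cohort = [generate_subject(spec, i) for i in range(cfg.n_id_auc)]
    seed = cfg.n_id_auc
    for kind in CORRUPTION_KINDS:
        n_k = cfg.n_ood_artifact if kind in ("zipper", "low_snr") else cfg.n_ood_other
        for _ in range(n_k):
            base = generate_subject(spec, seed)
            cohort.append(corrupt(base, CorruptionSpec(kind=kind, severity=DEFAULT_SEVERITY[kind], seed=seed)))
            seed += 1
    return cohort


def _scoreset(uscores, model, kinds=None) -> OODScoreSet:
    if kinds is not None:
        uscores = [u for u in uscores if u.label == "ID" or u.label in kinds]
    return OODScoreSet.from_uncertainty_scores(uscores, model_tag=model)


def run_study(cfg: StudyConfig | None = None, out_dir=None, log=print) -> dict:
    """Execute the full desk-scale study; returns a flat results dict."""
    cfg = cfg or StudyConfig()
    rng = np.random.default_rng(cfg.seed)
    fx = RandomConvExtractor(seed=13)

    log("generating training cohort...")
    spec = cfg.phantom_spec()
    subjects = [generate_subject(spec, i) for i in range(cfg.n_train_subjects)]
    splits = make_paired_dataset(
        subjects, cfg.input_contrast, cfg.target_contrast, (0.7, 0.15, 0.15), seed=cfg.seed
    )

    states = _train_models(cfg, splits["train"], log=log)

    # held-out evaluation subjects: noiseless twins for the separable-task
    # similarity metrics, realistic renders for coverage/distribution checks
    spec_eval = cfg.phantom_spec(noiseless=True)
    eval_seeds = [5000 + k for k in range(cfg.n_eval_subjects)]
    eval_noiseless = [generate_subject(spec_eval, s) for s in eval_seeds]
    spec_cov = cfg.phantom_spec(n_slices=cfg.ood_n_slices)
    eval_realistic = [generate_subject(spec_cov, s) for s in eval_seeds[: cfg.n_coverage_subjects]]

    log("sampling ensembles on evaluation subjects and computing metrics...")
    rows, ensembles = [], {}
    for model in cfg.models:
        for k, sub in enumerate(eval_noiseless):
            ens = predict_ensemble(model, states[model], sub, cfg, seed=cfg.seed + 10 + k)
            ensembles[(model, sub.subject_id)] = (ens, sub)
            rows.append(metric_rows(model, ens, sub, cfg, fx))
    report = pd.DataFrame(rows)

    results = {}
    agg = report.groupby("model").mean(numeric_only=True)
    for model in cfg.models:
        for m in ("ssim", "masked_ssim", "psnr", "lpips", "bssim", "scssim"):
            results[f"{m}_{model}"] = float(agg.loc[model, m])

    # coverage + per-pixel distribution on realistic subjects (targets carry
    # the generative variability the ensembles are supposed to capture)
    for model in cfg.models:
        if model == "direct":
            continue
        pairs, masks = [], []
        for k, sub in enumerate(eval_realistic):
            ens = predict_ensemble(model, states[model], sub, cfg, seed=cfg.seed + 40 + k)
            pairs.append((ens, sub.volumes[cfg.target_contrast].data))
            masks.append(sub.mask)
        cc = coverage_curve(pairs, masks=masks)
        results[f"coverage_maxdev_{model}"] = float(
            np.abs(cc.empirical_coverage - cc.confidence_levels).max()
        )
        ens0 = pairs[0][0]
        if ens0.n >= 8:
            rep = pixel_distribution_report(ens0, mask=masks[0], max_pixels=500, seed=cfg.seed)
            results[f"normal_fraction_{model}"] = rep["normal_fraction"]

    # sigma_hat OOD analysis for cGAN and NCSN
    auc_cohort = _auc_cohort(cfg)
    artifact_kinds = ("zipper", "low_snr")
    sweeps = {}
    for model in ("cgan", "ncsn"):
        if model not in cfg.models:
            continue
        log(f"sigma_hat sweep over ID/OOD cohort for {model}...")
        sweeps[model] = _sigma_sweep(model, states[model], auc_cohort, cfg, seed=cfg.seed + 500)
        ss_art = _scoreset(sweeps[model], model, kinds=artifact_kinds)
        _, auc_art = roc_auc(ss_art)
        results[f"auc_artifacts_{model}"] = auc_art
        ss_all = _scoreset(sweeps[model], model)
        _, auc_all = roc_auc(ss_all)
        results[f"auc_all_ood_{model}"] = auc_all
        _, f1max, _ = f1_sweep(ss_all)
        results[f"f1_max_{model}"] = f1max

    # isotonic calibration on cGAN scores (validation vs test cohorts)
    if "cgan" in cfg.models and cfg.calibrate:
        log("isotonic calibration of cGAN sigma_hat scores...")
        spec_cal = cfg.phantom_spec(n_slices=cfg.ood_n_slices, seed_offset=200)
        val_cohort = _calib_cohort(spec_cal, cfg, start=0)
        test_cohort = _calib_cohort(spec_cal, cfg, start=1000)
        sv = _scoreset(_sigma_sweep("cgan", states["cgan"], val_cohort, cfg, cfg.seed + 700), "cgan")
        stt = _scoreset(_sigma_sweep("cgan", states["cgan"], test_cohort, cfg, cfg.seed + 800), "cgan")
        lo, hi = sv.scores.min(), sv.scores.max()
        sv.normalize(lo, hi)
        stt.normalize(lo, hi)
        raw = reliability_metrics(stt.normalized, stt.labels)
        cmap, stt = calibrate_isotonic(sv, stt, n_folds=5, ood_subset_seed=cfg.seed)
        cal = reliability_metrics(stt.calibrated, stt.labels)
        results["ece_raw_cgan"] = raw["ece"]
        results["ece_calibrated_cgan"] = cal["ece"]
        results["brier_raw_cgan"] = raw["brier"]
        results["brier_calibrated_cgan"] = cal["brier"]
        results["nll_raw_cgan"] = raw["nll"]
        results["nll_calibrated_cgan"] = cal["nll"]

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "metric_report.csv", index=False)
        with open(out / "study_results.json", "w") as f:
            json.dump({"config": asdict(cfg), "results": results}, f, indent=2, default=float)
        for model, sw in sweeps.items():
            _scoreset(sw, model).to_frame().to_csv(out / f"sigma_hat_{model}.csv", index=False)
    return {"results": results, "report": report, "states": states, "ensembles": ensembles}


@dataclass
class ExperimentConfig:
    """Config-driven wrapper around the study: one output directory, one seed."""

    study: StudyConfig = field(default_factory=StudyConfig)
    out_dir: str = "results/experiment"
    resume: bool = False

    def config_hash(self) -> str:
        import hashlib

        blob = json.dumps(asdict(self.study), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_experiment(cfg: ExperimentConfig, log=print) -> dict:
    """Fully seeded end-to-end run emitting metric report, sigma_hat tables,
    calibration outputs and a manifest keyed by the config hash."""
    out = Path(cfg.out_dir)
    manifest_path = out / "manifest.json"
    if out.exists() and any(out.iterdir()) and not cfg.resume:
        if not manifest_path.exists():
            raise FileExistsError(
                f"{out} contains partial state without a manifest; pass resume=True to overwrite"
            )
    out.mkdir(parents=True, exist_ok=True)
    bundle = run_study(cfg.study, out_dir=out, log=log)
    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.study.seed,
        "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    with open(manifest_path, "w") as f:
        json.dump(manifest, f, indent=2)
    return bundle


def n_sweep(state, model, subject, cfg: StudyConfig, n_values=(2, 5, 10, 20), seed=0):
    """Effect of the ensemble size n on the point-prediction similarity."""
    target = subject.volumes[cfg.target_contrast].data
    rows = []
    base = predict_ensemble(model, state, subject, replace_n(cfg, max(n_values)), seed)
    for n in sorted(n_values):
        sub_ens = summarize(base.samples[:n], model_tag=model, input_ref=subject.subject_id)
        rows.append(
            {
                "model": model,
                "n": n,
                "masked_ssim": masked_ssim3d(np.clip(sub_ens.mean, 0, 1), target, subject.mask),
                "mean_std": float(sub_ens.std[subject.mask].mean()),
            }
        )
    return pd.DataFrame(rows)


def replace_n(cfg: StudyConfig, n):
    from dataclasses import replace as _r

    return _r(cfg, n_samples=n)


def _calib_cohort(spec, cfg: StudyConfig, start=0):
    cohort = [generate_subject(spec, start + i) for i in range(cfg.n_id_calib)]
    seed = start + cfg.n_id_calib
    for kind in CORRUPTION_KINDS:
        for _ in range(cfg.n_ood_calib):
            base = generate_subject(spec, seed)
            cohort.append(corrupt(base, CorruptionSpec(kind=kind, severity=DEFAULT_SEVERITY[kind], seed=seed)))
            seed += 1
    return cohort
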