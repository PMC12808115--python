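"""Swarm-style plot of sigma_hat by label plus ROC curves for the models'
OOD scores, from the tables written by 02_run_study.py."""

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from mrxform.ood_detect import OODScoreSet, roc_auc

fig, axes = plt.subplots(1, 2, figsize=(9, 4))
for model in ("cgan", "ncsn"):
    df = pd.read_csv(f"results/study/sigma_hat_{model}.csv")
    ss = OODScoreSet(df["subject_id"].tolist(), df["score"].to_numpy(), df["label"].to_numpy())
    (fpr, tpr, _), auc = roc_auc(ss)
    axes[0].plot(fpr, tpr, label=f"{model} (AUC {auc:.3f})")
    jitter = 0.06 * np.random.default_rng(0).standard_normal(len(df))
    x = df["label"].to_numpy() + jitter + (0.0 if model == "cgan" else 2.0)
    axes[1].scatter(x, df["score"], s=12, label=model if model == "cgan" else None)
axes[0].plot([0, 1], [0, 1], "k--", lw=0.8)
axes[0].set(xlabel="false positive rate", ylabel="true positive rate", title="sigma_hat ROC")
axes[0].legend()
axes[1].set(xticks=[0, 1, 2, 3], xticklabels=["ID", "OOD", "ID", "OOD"],
            ylabel="sigma_hat", title="cGAN (left) / NCSN (right)")
fig.tight_layout()
fig.savefig("results/study/ood_scores.png", dpi=120)
print("wrote results/study/ood_scores.png")
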