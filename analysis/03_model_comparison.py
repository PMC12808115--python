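"""Pairwise one-sided Wilcoxon signed-rank comparison of the models on the
per-subject metric report written by 02_run_study.py; reports the best set
per metric (a model is best when no other model is significantly better)."""

import pandas as pd

from mrxform.metrics import compare_models

report = pd.read_csv("results/study/metric_report.csv")
rows = []
for metric in ("ssim", "psnr", "lpips", "bssim", "scssim"):
    pvals, best = compare_models(report, metric)
    print(f"{metric:>7}: best set = {sorted(best)}")
    for (a, b), p in sorted(pvals.items()):
        rows.append({"metric": metric, "model_a": a, "model_b": b, "p_one_sided": p})
pd.DataFrame(rows).to_csv("results/study/model_comparison.csv", index=False)
print("wrote results/study/model_comparison.csv")
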