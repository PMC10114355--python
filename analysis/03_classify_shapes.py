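"""Classify aggregate shapes: PCA on the standardized features, k-means
with k = 4, and resolution of the four clusters into the three named
morphologies (linear fractal, branched fractal, fibril).

Reads results/features.csv, writes results/scores.csv (PC1/PC2,
cluster, class) and results/class_summary.csv (proportions, medians
with quartiles), plus an optional PCA scatter under scratch/.
"""

from pathlib import Path

import pandas as pd

from aggremorph import classify

features = pd.read_csv("results/features.csv")
scores, model, summary = classify.classify_features(features, seed=20260928 % 2**31)

scores.to_csv("results/scores.csv", index=False)
summary.to_csv("results/class_summary.csv", index=False)

print(f"PC1/PC2 explained variance: "
      f"{model.explained_variance_ratio[0]:.2f} / {model.explained_variance_ratio[1]:.2f}")
print(summary.to_string(index=False))
if "true_class" in features.columns:
    acc = (scores["morph_class"].to_numpy() == features["true_class"].to_numpy()).mean()
    print(f"agreement with simulation ground truth: {100 * acc:.1f} %")

try:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    Path("scratch").mkdir(exist_ok=True)
    colors = {"linear_fractal": "tab:blue", "branched_fractal": "tab:green",
              "fibril": "tab:orange"}
    fig, ax = plt.subplots(figsize=(5, 4))
    for cls, grp in scores.groupby("morph_class"):
        ax.scatter(grp["PC1"], grp["PC2"], s=12, label=cls, color=colors.get(cls))
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig("scratch/pca_scatter.png", dpi=150)
    print("scatter written to scratch/pca_scatter.png")
except Exception as exc:  # plotting is a convenience, not a result
    print(f"scatter skipped: {exc}")
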