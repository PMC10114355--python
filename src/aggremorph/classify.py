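"""PCA + k-means shape classification of aggregate feature vectors.

Aggregates are classified into three morphologies — linear fractal,
branched fractal and fibril — by standardising the shape features,
projecting onto the first two principal components, k-means clustering
with k = 4, and then resolving the four clusters to the three named
classes: a singleton cluster whose member is a PC-space outlier (or a
ring-closed skeleton) is merged into the fibril class, the remaining
cluster with the greatest median longest-chain length is named fibril,
the one with the greatest median branch count branched-fractal, and the
rest linear-fractal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from aggremorph.morphology import FeatureVector

CLASS_LABELS = ("linear_fractal", "branched_fractal", "fibril")
DEFAULT_K = 4
DEFAULT_RESTARTS = 50
OUTLIER_SD = 3.0
# fractal aggregates are chains of resolvable ~0.5-µm puncta, so their
# LoG peak density is about 1–2 per µm of chain; a cluster whose median
# density falls below this is a smooth elongated aggregate, i.e. fibril
FIBRIL_PEAK_DENSITY = 0.5  # peaks / µm

# scale-type features spanning orders of magnitude (lengths, widths,
# intensities) are log10-transformed before z-scoring so a handful of
# very long fibrils does not dominate the decomposition
LOG_FEATURES = ("longest_chain_um", "mean_width_um", "width_per_chain",
                "total_intensity_au")


@dataclass
class PcaModel:
    feature_names: list[str]
    means: np.ndarray
    scales: np.ndarray
    components: np.ndarray  # (2, n_features), rows orthonormal
    explained_variance_ratio: np.ndarray  # (2,)
    log_features: tuple[str, ...] = LOG_FEATURES

    def transform(self, features: pd.DataFrame) -> np.ndarray:
        x = features[self.feature_names].to_numpy(dtype=float).copy()
        for j, col in enumerate(self.feature_names):
            if col in self.log_features:
                x[:, j] = np.log10(x[:, j])
        return ((x - self.means) / self.scales) @ self.components.T


def fit_pca(features: pd.DataFrame,
            feature_cols: list[str] | None = None,
            include_total_length: bool = False,
            log_features: tuple[str, ...] = LOG_FEATURES,
            ) -> tuple[PcaModel, pd.DataFrame]:
    """Standardise the features and fit a 2-component PCA.

    Scale-type features (``log_features``) are log10-transformed, then
    all features are z-scored column-wise (they carry incompatible
    units), so the decomposition is of the correlation structure. The
    sign of each component is fixed so its largest-magnitude loading is
    positive. Returns the model and a scores frame with PC1/PC2.
    """
    if feature_cols is None:
        feature_cols = list(FeatureVector.FEATURE_COLUMNS)
        if include_total_length:
            feature_cols.append(FeatureVector.OPTIONAL_COLUMN)
    if len(features) < 3:
        raise ValueError("PCA needs at least 3 aggregates")
    x = features[feature_cols].to_numpy(dtype=float).copy()
    for j, col in enumerate(feature_cols):
        if col in log_features:
            if np.any(x[:, j] <= 0):
                raise ValueError(f"feature {col} must be positive for the log transform")
            x[:, j] = np.log10(x[:, j])
    if not np.all(np.isfinite(x)):
        raise ValueError("features contain missing or non-finite values")
    means = x.mean(axis=0)
    scales = x.std(axis=0, ddof=0)
    zero_var = [c for c, s in zip(feature_cols, scales) if s == 0]
    if zero_var:
        raise ValueError(f"zero-variance feature column(s): {zero_var}")
    z = (x - means) / scales
    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(z)
    components = pca.components_.copy()
    for i in range(2):
        j = np.argmax(np.abs(components[i]))
        if components[i, j] < 0:
            components[i] = -components[i]
            scores[:, i] = -scores[:, i]
    model = PcaModel(
        feature_names=list(feature_cols),
        means=means,
        scales=scales,
        components=components,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        log_features=tuple(log_features),
    )
    out = pd.DataFrame({"PC1": scores[:, 0], "PC2": scores[:, 1]},
                       index=features.index)
    return model, out


def cluster_kmeans(scores: pd.DataFrame, k: int = DEFAULT_K, seed: int = 0,
                   n_init: int = DEFAULT_RESTARTS) -> np.ndarray:
    """k-means on the (PC1, PC2) scores; deterministic for a fixed seed."""
    x = scores[["PC1", "PC2"]].to_numpy(dtype=float)
    if len(x) < k:
        raise ValueError(f"need at least k={k} samples, got {len(x)}")
    if len(np.unique(x, axis=0)) < k:
        raise ValueError("degenerate input: fewer distinct points than clusters")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(x)


def resolve_classes(cluster_ids: np.ndarray, features: pd.DataFrame,
                    scores: pd.DataFrame) -> pd.Series:
    """Map k-means clusters to the three named morphology classes.

    (i) Singleton clusters whose member is an outlier in both PCs
    (|PC| > 3 sd) or whose skeleton closed into a ring are assigned to
    the fibril class directly. (ii) Of the remaining clusters, the one
    with the greatest median longest-chain length is fibril; each of
    the rest is branched-fractal when its median branch count is at
    least 1 (branching is what defines the class), fibril when its
    median punctum-peak density is below FIBRIL_PEAK_DENSITY (a smooth
    elongated body rather than a chain of puncta — catches k-means
    splitting a broad fibril length distribution), and linear-fractal
    otherwise.
    """
    cluster_ids = np.asarray(cluster_ids)
    labels = pd.Series(index=features.index, dtype=object)
    sd1, sd2 = scores["PC1"].std(ddof=0), scores["PC2"].std(ddof=0)
    remaining: list[int] = []
    for cid in np.unique(cluster_ids):
        members = features.index[cluster_ids == cid]
        if len(members) == 1:
            m = members[0]
            outlier = (abs(scores.loc[m, "PC1"]) > OUTLIER_SD * sd1
                       and abs(scores.loc[m, "PC2"]) > OUTLIER_SD * sd2)
            ringed = bool(features.loc[m].get("ring_flag", False))
            if outlier or ringed:
                labels.loc[m] = "fibril"
                continue
        remaining.append(int(cid))

    if remaining:
        med_chain = {cid: features.loc[cluster_ids == cid, "longest_chain_um"].median()
                     for cid in remaining}
        fibril_cid = max(remaining, key=lambda c: med_chain[c])
        mapping = {fibril_cid: "fibril"}
        for cid in remaining:
            if cid == fibril_cid:
                continue
            members = features.loc[cluster_ids == cid]
            if members["n_branch_points"].median() >= 1:
                mapping[cid] = "branched_fractal"
            elif members["intensity_peaks_per_um"].median() < FIBRIL_PEAK_DENSITY:
                mapping[cid] = "fibril"
            else:
                mapping[cid] = "linear_fractal"
        for cid in remaining:
            labels.loc[features.index[cluster_ids == cid]] = mapping[cid]

    if len(np.unique(cluster_ids)) >= 3:
        empty = [c for c in CLASS_LABELS if (labels == c).sum() == 0]
        if empty:
            raise ValueError(f"class resolution produced empty class(es): {empty}")
    return labels


def class_summary(labels: pd.Series, features: pd.DataFrame,
                  summary_cols: tuple[str, ...] = ("longest_chain_um",
                                                   "n_branch_points"),
                  ) -> pd.DataFrame:
    """Per-class proportions (%) and median [q1–q3] summaries.

    Quartiles use linear interpolation. Classes absent from the data
    are reported with n = 0.
    """
    rows = []
    n_total = len(labels)
    for cls in CLASS_LABELS:
        members = features.loc[labels == cls]
        row: dict = {"class": cls, "n": len(members),
                     "percent": 100.0 * len(members) / n_total if n_total else 0.0}
        for col in summary_cols:
            if len(members):
                vals = members[col].to_numpy(dtype=float)
                row[f"{col}_median"] = float(np.median(vals))
                row[f"{col}_q1"] = float(np.percentile(vals, 25))
                row[f"{col}_q3"] = float(np.percentile(vals, 75))
            else:
                row[f"{col}_median"] = np.nan
                row[f"{col}_q1"] = np.nan
                row[f"{col}_q3"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def classify_features(features: pd.DataFrame, seed: int = 0,
                      k: int = DEFAULT_K,
                      include_total_length: bool = False,
                      ) -> tuple[pd.DataFrame, PcaModel, pd.DataFrame]:
    """Full classification: PCA → k-means → class resolution → summary.

    Returns (scores frame with cluster and class columns, the PCA
    model, the class summary table).
    """
    model, scores = fit_pca(features, include_total_length=include_total_length)
    clusters = cluster_kmeans(scores, k=k, seed=seed)
    labels = resolve_classes(clusters, features, scores)
    scores = scores.assign(cluster=clusters, morph_class=labels)
    summary = class_summary(labels, features)
    return scores, model, summary
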