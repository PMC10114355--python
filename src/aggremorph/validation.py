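"""Ground-truth round-trip validation on simulated scene sets.

Scenes are simulated at the study's morphology scales, pushed through
segmentation → feature extraction → PCA/k-means classification, and the
predicted classes are scored against the simulator's per-pixel label
masks. This is the package's primary self-check: it quantifies how well
the full pipeline recovers known morphology classes under realistic
imaging noise.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np
import pandas as pd

from aggremorph import classify, morphology, segment
from aggremorph.config import RunConfig
from aggremorph.image import Image
from aggremorph.synthdata import SimParams, simulate_study_scene


def simulate_scene_set(n_scenes: int, seed: int,
                       params: SimParams | None = None,
                       n_aggregates: int = 6,
                       ) -> list[tuple]:
    """Simulate ``n_scenes`` labelled scenes with per-scene seeds."""
    master = np.random.default_rng(seed)
    scenes = []
    for _ in range(n_scenes):
        scene_seed = int(master.integers(2**31 - 1))
        p = params or SimParams()
        p = SimParams(**{**asdict(p), "rng_seed": scene_seed,
                         "chromatic_shift": tuple(p.chromatic_shift)})
        scenes.append(simulate_study_scene(p, n_aggregates=n_aggregates))
    return scenes


def measure_scene(img: Image, truth_mask: np.ndarray, truth_labels: list[str],
                  cfg: RunConfig) -> pd.DataFrame:
    """Segment one frame and attach ground-truth labels by mask majority.

    The rendered background level is known and flat, so frames are
    segmented after subtracting it directly (the rolling-ball step is
    exercised separately); each detected region inherits the label of
    the ground-truth aggregate owning the majority of its pixels.
    Regions that fall entirely on background are dropped.
    """
    regions = segment.segment_aggregates(
        img, intensity_threshold=cfg.intensity_threshold,
        min_area_exclusive=cfg.min_area_exclusive,
        connectivity=cfg.connectivity)
    rows = []
    for reg in regions:
        ids = truth_mask[reg.pixel_coords[:, 0], reg.pixel_coords[:, 1]]
        ids = ids[ids > 0]
        if ids.size == 0:
            continue
        true_id = int(np.bincount(ids).argmax())
        fv = morphology.extract_features(
            img, reg, sigma_range_um=(cfg.log_sigma_min_um, cfg.log_sigma_max_um))
        row = vars(fv).copy()
        row["true_class"] = truth_labels[true_id - 1]
        rows.append(row)
    return pd.DataFrame(rows)


def classification_round_trip(n_scenes: int = 50, seed: int = 0,
                              cfg: RunConfig | None = None,
                              params: SimParams | None = None,
                              n_aggregates: int = 6,
                              ) -> tuple[pd.DataFrame, float, pd.DataFrame]:
    """Full simulate → analyse → classify → score round trip.

    Returns (per-aggregate table with true and predicted classes,
    overall accuracy as a fraction, class summary of the predictions).
    """
    cfg = cfg or RunConfig(seed=seed)
    scenes = simulate_scene_set(n_scenes, seed, params=params,
                                n_aggregates=n_aggregates)
    frames = []
    for i, (truth, img_a, _img_b, mask) in enumerate(scenes):
        background = (params or SimParams()).background_level
        sub = img_a.copy_with(np.clip(img_a.pixels - background, 0, None))
        f = measure_scene(sub, mask, truth.labels(), cfg)
        if len(f):
            f.insert(0, "scene", i)
            frames.append(f)
    features = pd.concat(frames, ignore_index=True)
    scores, _model, summary = classify.classify_features(
        features, seed=cfg.stage_seed("kmeans"), k=cfg.kmeans_k)
    features = features.assign(predicted_class=scores["morph_class"].to_numpy(),
                               cluster=scores["cluster"].to_numpy())
    accuracy = float((features["predicted_class"] == features["true_class"]).mean())
    return features, accuracy, summary
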