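"""End-to-end morphometry pipeline over a two-channel scene.

preprocess (background subtraction) → segment → skeleton features →
PCA/k-means classification, with every output table carrying the
resolved configuration and seed. Rerunning with the same config
reproduces identical tables.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from aggremorph import io as amio
from aggremorph import classify, morphology, preprocess, segment
from aggremorph.config import RunConfig
from aggremorph.image import Image

log = logging.getLogger("aggremorph")


def analyze_image(img: Image, cfg: RunConfig,
                  background_subtracted: bool = False) -> pd.DataFrame:
    """Segment one frame and extract per-aggregate features."""
    if not background_subtracted:
        img = preprocess.subtract_background(img, radius=cfg.rolling_ball_radius)
    regions = segment.segment_aggregates(
        img, intensity_threshold=cfg.intensity_threshold,
        min_area_exclusive=cfg.min_area_exclusive,
        connectivity=cfg.connectivity)
    feats = [morphology.extract_features(
        img, r, sigma_range_um=(cfg.log_sigma_min_um, cfg.log_sigma_max_um))
        for r in regions]
    return morphology.features_to_frame(feats)


def analyze_scene_set(images: list[Image], cfg: RunConfig,
                      background_subtracted: bool = False,
                      ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Feature extraction + classification over a set of frames.

    Returns (features with scene/aggregate ids and class labels,
    PC scores/cluster table, class summary).
    """
    frames = []
    for scene_idx, img in enumerate(images):
        f = analyze_image(img, cfg, background_subtracted=background_subtracted)
        f.insert(0, "scene", scene_idx)
        frames.append(f)
    features = pd.concat(frames, ignore_index=True)
    if len(features) < 3:
        raise ValueError("too few aggregates across the scene set to classify")
    scores, model, summary = classify.classify_features(
        features, seed=cfg.stage_seed("kmeans"), k=cfg.kmeans_k,
        include_total_length=cfg.include_total_length)
    features = features.assign(cluster=scores["cluster"].to_numpy(),
                               morph_class=scores["morph_class"].to_numpy())
    return features, scores, summary


def run_pipeline(cfg: RunConfig, images: list[Image] | None = None) -> Path:
    """Execute the morphometry pipeline and write a run directory.

    ``images`` may be supplied directly (e.g. from the simulator);
    otherwise ``cfg.input_paths`` are read as single-page TIFFs at the
    configured calibration. The run directory holds the feature table,
    scores, class summary, resolved config and a log.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    try:
        log.info("run config: %s", asdict(cfg))
        if images is None:
            if not cfg.input_paths:
                raise ValueError("no input images: set input_paths or pass images")
            for p in cfg.input_paths:
                if not Path(p).exists():
                    raise FileNotFoundError(f"input image not found: {p}")
            images = [amio.read_image(p, pixel_size=cfg.pixel_size_um)
                      for p in cfg.input_paths]
        features, scores, summary = analyze_scene_set(images, cfg)
        amio.write_table(out / "features.csv", features.drop(columns=[], errors="ignore"))
        amio.write_table(out / "scores.csv", scores)
        amio.write_table(out / "class_summary.csv", summary)
        cfg.to_yaml(out / "config.yaml")
        log.info("wrote %d aggregates, summary:\n%s", len(features), summary)
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
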