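"""TIFF / CSV / JSON readers and writers for the pipeline."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from aggremorph.image import Image

log = logging.getLogger("aggremorph")


def read_image(path: str | Path, pixel_size: float, channel: str = "mCherry") -> Image:
    """Read a single-page TIFF as a calibrated Image.

    16-bit data are preserved exactly; 8-bit input is accepted with a
    logged note — intensity thresholds stated on the 16-bit scale must
    be rescaled by the caller (a factor of 257 maps 255 to 65535).
    """
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single 2-D page, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        log.info("%s: 8-bit input up-converted to the 16-bit scale (x257)", path)
        arr = arr.astype(np.uint16) * 257
    return Image(pixels=arr.astype(np.float64), pixel_size=pixel_size, channel=channel)


def read_stack(path: str | Path, pixel_size: float, channel: str = "ThT") -> list[Image]:
    """Read a multi-page TIFF as a list of frames."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected pages of 2-D frames, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        log.info("%s: 8-bit input up-converted to the 16-bit scale (x257)", path)
        arr = arr.astype(np.uint16) * 257
    return [Image(pixels=frame.astype(np.float64), pixel_size=pixel_size,
                  channel=channel) for frame in arr]


def write_image(path: str | Path, img: Image | np.ndarray) -> None:
    """Write an image or label mask as 16-bit TIFF (values rounded)."""
    arr = img.pixels if isinstance(img, Image) else np.asarray(img)
    out = np.clip(np.round(arr), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), out, photometric="minisblack")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def write_metadata(path: str | Path, meta: dict) -> None:
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))


def read_metadata(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
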