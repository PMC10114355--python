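"""Calibrated 2-D intensity raster shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CHANNELS = ("mCherry", "ThT", "TEM")


@dataclass
class Image:
    """A single calibrated fluorescence or TEM frame.

    Parameters
    ----------
    pixels
        2-D array of intensities in arbitrary units on the camera's
        16-bit scale (0–65535). Stored as float64 internally so that
        background subtraction and interpolation do not truncate.
    pixel_size
        Physical size of one pixel. Micrometres per pixel for
        fluorescence channels, may be nm/px for TEM as long as the
        caller is consistent.
    channel
        One of ``mCherry``, ``ThT`` or ``TEM``.
    valid_mask
        Optional boolean mask marking pixels whose values are genuine
        data (False where resampling after registration left the
        frame). ``None`` means all pixels are valid.
    """

    pixels: np.ndarray
    pixel_size: float
    channel: str = "mCherry"
    valid_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D raster, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("image intensities must be non-negative")
        if not (self.pixel_size > 0 and np.isfinite(self.pixel_size)):
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if self.valid_mask is not None:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.pixels.shape:
                raise ValueError("valid_mask shape must match pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def copy_with(self, pixels: np.ndarray, valid_mask: np.ndarray | None = None) -> "Image":
        """New Image with the same calibration/channel but new pixels."""
        return Image(
            pixels=pixels,
            pixel_size=self.pixel_size,
            channel=self.channel,
            valid_mask=self.valid_mask if valid_mask is None else valid_mask,
        )
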