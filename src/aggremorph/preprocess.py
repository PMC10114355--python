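"""Channel registration and rolling-ball background subtraction.

Chromatic aberration between the mCherry and ThT channels is modelled
as a pure translation, estimated from averaged calibration frames by
subpixel phase cross-correlation in four small regions of interest and
combined by the component-wise median (robust to one bad ROI).
Background is removed with the classic rolling-ball estimate
(grayscale opening by a ball), computed on a downsampled grid for the
large default radius of 200 px.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import transform
from skimage.restoration import rolling_ball

from aggremorph.image import Image

DEFAULT_ROLLING_BALL_RADIUS = 200
MAX_SHIFT_RADIUS = 20.0  # px, search bound for |dx|, |dy|


@dataclass
class ShiftParams:
    """Translation (rows, cols) that maps the moving channel onto the
    reference channel."""

    dy: float
    dx: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.dy) and np.isfinite(self.dx)):
            raise ValueError("shift must be finite")
        if abs(self.dy) > MAX_SHIFT_RADIUS or abs(self.dx) > MAX_SHIFT_RADIUS:
            raise ValueError(
                f"shift ({self.dy}, {self.dx}) exceeds search radius {MAX_SHIFT_RADIUS}")


def _average_stack(stack: list[Image]) -> np.ndarray:
    if not stack:
        raise ValueError("stack must be non-empty")
    shapes = {im.shape for im in stack}
    if len(shapes) != 1:
        raise ValueError("all frames must share one shape")
    return np.mean([im.pixels for im in stack], axis=0)


def _quadratic_peak(cc: np.ndarray, iy: int, ix: int) -> tuple[float, float]:
    """Subpixel peak location by separable parabolic interpolation."""

    def refine(vm, v0, vp):
        denom = vm - 2 * v0 + vp
        if denom >= 0:  # not a proper maximum; keep the integer peak
            return 0.0
        return float(np.clip(0.5 * (vm - vp) / denom, -0.5, 0.5))

    dy = dx = 0.0
    if 0 < iy < cc.shape[0] - 1:
        dy = refine(cc[iy - 1, ix], cc[iy, ix], cc[iy + 1, ix])
    if 0 < ix < cc.shape[1] - 1:
        dx = refine(cc[iy, ix - 1], cc[iy, ix], cc[iy, ix + 1])
    return iy + dy, ix + dx


def estimate_translation(ref_stack: list[Image], mov_stack: list[Image],
                         rois: list[tuple[int, int]], window: int = 16,
                         max_shift: int = 10, refine: int = 1) -> ShiftParams:
    """Estimate the displacement of the moving channel from calibration stacks.

    Each stack is averaged over frames. For each ROI centre (row, col),
    a ``window``-px patch of the averaged moving image is correlated
    (normalised cross-correlation) against a ``±max_shift`` search
    region of the averaged reference image; the correlation peak is
    refined to subpixel precision with a local quadratic fit. The four
    per-ROI estimates are combined by component-wise median, and the
    parabolic-peak bias is reduced by ``refine`` warp-and-re-estimate
    passes. The result is the (dy, dx) by which the moving channel's
    content is displaced relative to the reference.
    """
    ref = _average_stack(ref_stack)
    mov = _average_stack(mov_stack)
    if ref.shape != mov.shape:
        raise ValueError("reference and moving stacks must share dimensions")
    if not rois:
        raise ValueError("at least one ROI is required")
    total = _estimate_once(ref, mov, rois, window, max_shift)
    for _ in range(refine):
        if total == (0.0, 0.0):
            break
        warped = ndimage.shift(mov, (-total[0], -total[1]), order=1,
                               mode="nearest")
        extra = _estimate_once(ref, warped, rois, window, max_shift)
        if extra == (0.0, 0.0):
            break
        total = (total[0] + extra[0], total[1] + extra[1])
    return ShiftParams(dy=total[0], dx=total[1])


def _estimate_once(ref: np.ndarray, mov: np.ndarray,
                   rois: list[tuple[int, int]], window: int,
                   max_shift: int) -> tuple[float, float]:
    from skimage.feature import match_template

    half = window // 2
    estimates = []
    for (r, c) in rois:
        r0, r1 = r - half, r + half
        c0, c1 = c - half, c + half
        s0r, s1r = r0 - max_shift, r1 + max_shift
        s0c, s1c = c0 - max_shift, c1 + max_shift
        if s0r < 0 or s0c < 0 or s1r > ref.shape[0] or s1c > ref.shape[1]:
            raise ValueError(f"ROI search window at ({r}, {c}) leaves the frame")
        template = mov[r0:r1, c0:c1]
        search = ref[s0r:s1r, s0c:s1c]
        if np.ptp(template) == 0 or np.ptp(search) == 0:
            raise ValueError(f"ROI at ({r}, {c}) has zero variance; nothing to register")
        cc = match_template(search, template)
        iy, ix = np.unravel_index(np.argmax(cc), cc.shape)
        if cc[iy, ix] >= 1.0 - 1e-9:
            # perfect match: the shift is an exact integer, no refinement
            py, px = float(iy), float(ix)
        else:
            py, px = _quadratic_peak(cc, int(iy), int(ix))
        # template found at offset (py - max_shift) means the moving
        # content is displaced by the opposite amount
        estimates.append((max_shift - py, max_shift - px))
    med = np.median(np.asarray(estimates), axis=0)
    return (float(med[0]), float(med[1]))


def apply_translation(img: Image, shift: ShiftParams) -> Image:
    """Undo the estimated displacement by bilinear resampling.

    ``shift`` is the displacement of the image's content (as returned
    by :func:`estimate_translation`); the image is resampled by the
    inverse translation so it aligns with the reference channel. Border
    pixels invented by the resampling are marked invalid in the
    returned image's ``valid_mask`` and should be excluded from
    downstream statistics.
    """
    vec = (-shift.dy, -shift.dx)
    if vec == (0.0, 0.0):
        return img.copy_with(img.pixels.copy(),
                             valid_mask=np.ones(img.shape, dtype=bool))
    shifted = ndimage.shift(img.pixels, vec, order=1, mode="constant", cval=0.0)
    support = ndimage.shift(np.ones(img.shape), vec, order=1,
                            mode="constant", cval=0.0)
    valid = support > 0.999
    return img.copy_with(np.clip(shifted, 0, None), valid_mask=valid)


def subtract_background(img: Image, radius: int = DEFAULT_ROLLING_BALL_RADIUS) -> Image:
    """Rolling-ball background subtraction, clipped at zero.

    For radii above 40 px the background is estimated on a grid
    downsampled by ``ceil(radius / 40)`` and linearly upsampled back —
    the accepted approximation of the classic algorithm for large
    balls. A constant image maps to (approximately) zero everywhere.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if radius >= min(img.shape):
        raise ValueError(f"radius {radius} must be smaller than the image "
                         f"(min dimension {min(img.shape)})")
    pixels = img.pixels
    factor = int(np.ceil(radius / 40))
    if factor > 1:
        small = transform.rescale(pixels, 1.0 / factor, order=1,
                                  anti_aliasing=True, preserve_range=True)
        bg_small = rolling_ball(small, radius=radius / factor)
        background = transform.resize(bg_small, pixels.shape, order=1,
                                      preserve_range=True)
    else:
        background = rolling_ball(pixels, radius=radius)
    out = np.clip(pixels - background, 0, None)
    return img.copy_with(out)
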