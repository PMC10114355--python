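import numpy as np
import pytest

from aggremorph.image import Image
from aggremorph.synthdata import GroundTruth, SimParams, render_scene, _shifted, _all_points


@pytest.fixture
def sim_params():
    return SimParams(rng_seed=0)


def render_single(truth, params, noise=False, rng=None):
    """Render one aggregate in its own scene and return (image, mask)."""
    shift = -_all_points(truth).min(axis=0) + 1.5
    scene = GroundTruth([_shifted(truth, shift)])
    img_a, _img_b, mask = render_scene(scene, params, noise=noise,
                                       rng=rng or params.rng())
    return img_a, mask


def background_subtracted(img: Image, params: SimParams) -> Image:
    """Remove the known flat simulated background (not the rolling ball)."""
    return img.copy_with(np.clip(img.pixels - params.background_level, 0, None))


def mask_to_region(mask: np.ndarray, intensity: np.ndarray | None = None):
    """Build an AggregateRegion directly from a boolean mask (test helper)."""
    from aggremorph.segment import AggregateRegion

    coords = np.argwhere(mask)
    vals = intensity[mask] if intensity is not None else np.ones(len(coords))
    r0, c0 = coords.min(axis=0)
    r1, c1 = coords.max(axis=0) + 1
    return AggregateRegion(
        id=1, pixel_coords=coords, area=len(coords),
        total_intensity=float(vals.sum()),
        bbox=(int(r0), int(c0), int(r1), int(c1)),
        centroid=tuple(coords.mean(axis=0)),
    )
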