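import numpy as np
import pytest

from whealmeter import synthetic as syn
from whealmeter.palette import CLASS_WHEAL


@pytest.fixture(scope="session")
def small_scene():
    """One rendered 200x160 scene with two wheals (session-cached)."""
    spec = syn.SceneSpec(
        pixels_per_cm=20.0,
        wheal_specs=(
            syn.ShapeSpec("circle", (6.0, 2.0), 0.8, 0.8),
            syn.ShapeSpec("ellipse", (6.5, 5.5), 1.0, 0.6, 30.0),
        ),
        canvas_px=(200, 160),
        seed=7,
    )
    return syn.render_scene(spec)


@pytest.fixture(scope="session")
def training_scenes():
    """Eight small labeled scenes used by the overfit smoke tests."""
    scenes = []
    for i in range(8):
        spec = syn.random_scene_spec(
            seed=100 + i,
            canvas_px=(96, 96),
            pixels_per_cm=12.0,
            n_wheals=(1, 2),
            axis_range_cm=(0.8, 1.2),
            noise_sigma=4.0,
        )
        img, mask, _ = syn.render_scene(spec)
        scenes.append((img, mask))
    return scenes


def random_label_mask(rng: np.random.Generator, shape=(50, 50), p_wheal=0.3) -> np.ndarray:
    """Random speckle mask for clustering/metric property tests."""
    return np.where(rng.random(shape) < p_wheal, CLASS_WHEAL, 0).astype(np.uint8)
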