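import warnings

import numpy as np
import pytest

import splatphen as sp

warnings.filterwarnings("ignore", message=".*Number of distinct clusters.*")

SUITE_SEEDS = (0, 1, 2, 3, 4)


@pytest.fixture(scope="session")
def suite():
    """Default synthetic suite: (bundle, cues, lift result) per seed.

    Shared across end-to-end tests; lift scores are threshold-independent
    so every sweep reuses them.
    """
    out = []
    for seed in SUITE_SEEDS:
        bundle, cues = sp.default_suite_scene(seed)
        lift = sp.support_scores(bundle.scene, bundle.cameras, cues)
        out.append((bundle, cues, lift))
    return out


@pytest.fixture(scope="session")
def small_scene():
    """A cheap scene for unit-level checks (one plant, fewer cameras)."""
    recipe = sp.SceneRecipe(n_neighbors=0, cameras_per_pass=5)
    return sp.make_scene(recipe, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_splats(rng, n=50, spread=1.0):
    """Random well-conditioned splat set for projection/geometry tests."""
    return sp.SplatSet(
        positions=rng.normal(0, spread, (n, 3)),
        log_scales=rng.uniform(-4.5, -2.5, (n, 3)),
        rotations=rng.normal(0, 1, (n, 4)),
        opacity_logits=rng.normal(1.0, 1.0, n),
        dc_color=rng.normal(0, 0.5, (n, 3)),
    )


def random_camera(rng, image_size=(64, 48), fx=60.0):
    center = rng.normal(0, 1, 3) + np.array([0, 0, -6.0])
    return sp.look_at_camera(center, np.zeros(3), fx=fx, image_size=image_size,
                             sharpness=float(rng.uniform(1, 100)))
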