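"""Shared fixtures: one synthetic turntable scene rendered once per session."""

from __future__ import annotations

import numpy as np
import pytest

from leaf3d import lifting, synthetic

SCENE_SEED = 42
N_LEAVES = 8
POINTS_PER_LEAF = 600
N_VIEWS = 32
CORRUPTION = synthetic.CorruptionSpec(merge_prob=0.1, split_prob=0.1, dropout_prob=0.1, seed=7)


@pytest.fixture(scope="session")
def scene() -> synthetic.SyntheticScene:
    return synthetic.generate_scene(N_LEAVES, POINTS_PER_LEAF, seed=SCENE_SEED)


@pytest.fixture(scope="session")
def clean_views(scene):
    return synthetic.render_ring(scene, n_views=N_VIEWS)


@pytest.fixture(scope="session")
def clean_lifted(scene, clean_views):
    cfg = lifting.FusionConfig()
    vls = [lifting.lift_view(scene.cloud, v, cfg) for v in clean_views]
    visible = np.any([vl.labels >= 0 for vl in vls], axis=0)
    return vls, visible


@pytest.fixture(scope="session")
def corrupted_views(clean_views):
    return [synthetic.corrupt_masks(v, CORRUPTION) for v in clean_views]


@pytest.fixture(scope="session")
def corrupted_lifted(scene, corrupted_views):
    cfg = lifting.FusionConfig()
    vls = [lifting.lift_view(scene.cloud, v, cfg) for v in corrupted_views]
    visible = np.any([vl.labels >= 0 for vl in vls], axis=0)
    return vls, visible
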