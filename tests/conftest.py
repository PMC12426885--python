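"""Shared expensive fixtures: the dynamic-slice study scene."""

import pytest

from dtvtomo.scenes import dynamic_slice_scene, filling_timeline_scene

SCENE_SEED = 1


@pytest.fixture(scope="session")
def slice_scene():
    """Full single-slice study: reference scan, dynamic scan, 3 recon chains."""
    return dynamic_slice_scene(SCENE_SEED)


@pytest.fixture(scope="session")
def timeline_scene():
    """Capillary-filling timeline for waterfront tracking."""
    return filling_timeline_scene(seed=SCENE_SEED, grid=(96, 48, 48),
                                  n_vessels=6, t_max=144.0, dt=9.0)
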