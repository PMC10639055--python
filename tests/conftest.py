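import numpy as np
import pytest

from rloopkit.simulate import SceneConfig, simulate_nucleus_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_noisefree_scene():
    """Five noise-free foci on a flat field, plus ground truth."""
    cfg = SceneConfig(
        n_foci=5,
        poisson_noise=False,
        read_noise_sd=0.0,
        background_level=100.0,
        diffuse_level=100.0,
        seed=3,
    )
    stack, truth = simulate_nucleus_scene(cfg)
    return cfg, stack, truth


def greedy_match(true_xyz, det_xyz, tol=3.0):
    """Number of ground-truth foci matched to a distinct detection
    within *tol* voxels (nearest-centroid greedy matching)."""
    from scipy.spatial import cKDTree

    if len(det_xyz) == 0 or len(true_xyz) == 0:
        return 0
    d, idx = cKDTree(np.asarray(det_xyz)).query(np.asarray(true_xyz))
    used, matched = set(), 0
    for di, ii in sorted(zip(d, idx)):
        if di <= tol and ii not in used:
            matched += 1
            used.add(ii)
    return matched
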