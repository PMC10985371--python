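import numpy as np
import pytest

import eyemetrics as em

# a fast phantom for unit tests: ~120 cones, 1 μm voxels
SMALL_SPEC = em.SyntheticEyeSpec(cap_half_angle_deg=8.0, voxel_size_um=1.0)


@pytest.fixture(scope="session")
def small_phantom():
    return em.generate_phantom(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_results(small_phantom):
    vol, truth = small_phantom
    cfg = em.PipelineConfig(voxel_size_um=SMALL_SPEC.voxel_size_um)
    return em.analyze_volume(vol, cfg), truth


@pytest.fixture(scope="session")
def default_phantom_results():
    """Full-resolution default phantom (0.6 μm voxels, 15° cap) end to end."""
    vol, truth = em.generate_phantom(em.DEFAULT_SPEC)
    res = em.analyze_volume(vol, em.PipelineConfig())
    return res, truth


@pytest.fixture(scope="session")
def jittered_cones():
    """Aligned voxel sets from a jittered phantom, for consensus tests."""
    spec = em.SyntheticEyeSpec(
        cap_half_angle_deg=6.0, voxel_size_um=1.0, center_jitter_um=1.0, seed=7
    )
    vol, truth = em.generate_phantom(spec)
    cones = em.compute_centers(vol)
    centers = np.array([c.center_of_mass_um for c in cones])
    axes = centers / np.linalg.norm(centers, axis=1, keepdims=True)
    return [em.align_cone(c, a) for c, a in zip(cones, axes)], spec
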