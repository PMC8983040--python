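import numpy as np
import pytest

import centropol as cp


def small_params(**overrides):
    """A quick-to-render particle for unit tests (short, coarse, noiseless)."""
    kw = dict(centriole_length_nm=240.0, voxel_pitch_nm=40.0,
              voxel_pitch_z_nm=120.0, noise=cp.NoiseModel(peak_snr=None))
    kw.update(overrides)
    return cp.preset_centriole(**kw)


@pytest.fixture(scope="session")
def canonical_small():
    return cp.CanonicalFrame(lateral_shape=64, n_planes=24)


@pytest.fixture(scope="session")
def noiseless_particle():
    # full-length wall so the axial second moment dominates the lateral one
    stack, truth = cp.generate_centriole(small_params(
        seed=1, centriole_length_nm=427.0))
    return stack, truth


@pytest.fixture(scope="session")
def tilted_particle():
    pose = cp.Pose(tilt_deg=30.0, tilt_direction_deg=55.0, rotation_deg=0.0)
    stack, truth = cp.generate_centriole(small_params(
        seed=2, centriole_length_nm=427.0, pose=pose,
        psf_sigma_z_nm=80.0, voxel_pitch_z_nm=40.0))
    return stack, truth


def standardize_cohort(pairs, canonical, reference_mode="brightest", **kw):
    out = []
    for i, (stack, truth) in enumerate(pairs):
        ann = truth.to_annotation(f"p{i:03d}", reference_mode=reference_mode)
        particle, transform = cp.standardize(stack, ann, canonical,
                                             reference_mode=reference_mode, **kw)
        out.append((particle, transform, truth))
    return out


def rng_for(*key):
    return np.random.default_rng(np.random.SeedSequence(list(key)))
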