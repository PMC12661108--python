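"""Shared fixtures.

The expensive artifacts (a phantom atlas cohort and its MRI/CT atlases) are
built once per session and shared by the atlas, registration and acceptance
tests. All randomness is seeded so the suite is deterministic.
"""

import numpy as np
import pytest

from prostalign.atlas import build_atlas
from prostalign.phantom import generate_phantom_pair, offset_spec, random_spec

ATLAS_SEED = 20250921
N_ATLAS_CASES = 8


@pytest.fixture(scope="session")
def atlas_cohort():
    """Phantom training cases with realistic anatomical variation."""
    rng = np.random.default_rng(ATLAS_SEED)
    return [generate_phantom_pair(random_spec(rng)) for _ in range(N_ATLAS_CASES)]


@pytest.fixture(scope="session")
def mri_atlas(atlas_cohort):
    return build_atlas([(c.mri, c.prostate_mask_mri) for c in atlas_cohort], "MRI")


@pytest.fixture(scope="session")
def ct_atlas(atlas_cohort):
    return build_atlas([(c.ct, c.prostate_mask_ct) for c in atlas_cohort], "CT")


@pytest.fixture(scope="session")
def held_out_case():
    """One held-out phantom with a known rigid offset (default anatomy)."""
    rng = np.random.default_rng(ATLAS_SEED + 1)
    return generate_phantom_pair(offset_spec(rng))


def random_rigid(rng: np.random.Generator, with_rotation: bool = True):
    """Random rigid transform for algebra property tests."""
    from scipy.spatial.transform import Rotation

    from prostalign.geometry import RigidTransform

    t = rng.uniform(-50.0, 50.0, size=3)
    if with_rotation:
        r = Rotation.random(rng=rng).as_matrix()
        return RigidTransform(translation=t, rotation=r)
    return RigidTransform.from_translation(t)
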