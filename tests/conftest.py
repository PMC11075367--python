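import numpy as np
import pytest

from petac.phantom import PhantomSpec, generate_sample
from petac.preprocess import clip_scale
from petac.volume import PETVolume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(grid_shape=(1, 64, 64), n_lesions=3, seed=7)


@pytest.fixture(scope="session")
def sample(small_spec):
    """One noise-free phantom with its simulated PET pair."""
    return generate_sample(small_spec, noise=False)


def make_cohort(n_studies: int, slices_per: int, seed0: int,
                noise: bool = True, n_lesions: int = 3):
    """Paired scaled (NAC, AC) studies built from single-slice phantoms."""
    pairs, samples = [], []
    for i in range(n_studies):
        nacs, acs, per_study = [], [], []
        for j in range(slices_per):
            spec = PhantomSpec(seed=seed0 + i * 1000 + j, n_lesions=n_lesions)
            s = generate_sample(spec, noise=noise)
            nacs.append(s.nac_pet.voxels[0])
            acs.append(s.ac_pet.voxels[0])
            per_study.append(s)
        pairs.append((PETVolume(np.stack(nacs)), PETVolume(np.stack(acs))))
        samples.append(per_study)
    return pairs, samples


def scale_pairs(pairs):
    return [(clip_scale(n), clip_scale(a)) for n, a in pairs]
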