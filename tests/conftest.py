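"""Shared fixtures: small deterministic phantoms and random VOIs."""

import numpy as np
import pytest

from psma_radiomics.synthetic import PhantomSpec, generate_nema_phantom, generate_tumor_phantom
from psma_radiomics.volume import PETVolume, VOI


@pytest.fixture(scope="session")
def noiseless_spec():
    """Blurred but noise- and texture-free tumor phantom spec."""
    return PhantomSpec(noise_sd=0.0, texture_amplitude=0.0, psf_fwhm_mm=7.0, seed=11)


@pytest.fixture(scope="session")
def noiseless_phantom(noiseless_spec):
    return generate_tumor_phantom(noiseless_spec, aggressiveness=0.0)


@pytest.fixture(scope="session")
def textured_phantom():
    spec = PhantomSpec(seed=21)
    return generate_tumor_phantom(spec, aggressiveness=0.5)


@pytest.fixture(scope="session")
def nema_phantom():
    """Noise-free NEMA-style sphere phantom blurred at 7 mm FWHM."""
    return generate_nema_phantom(psf_fwhm_mm=7.0, noise_sd=0.0)


def random_voi(rng, shape=(8, 8, 8), n_levels=6, spacing=(2.0, 2.0, 2.0), p_fill=0.7):
    """Random discretized VOI with holes, for texture oracle checks."""
    mask = rng.uniform(size=shape) < p_fill
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    levels = np.zeros(shape, dtype=np.int64)
    levels[mask] = rng.integers(1, n_levels + 1, size=int(mask.sum()))
    return levels, mask


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_volume(values, spacing=(2.0, 2.0, 2.0), **kw):
    return PETVolume(np.asarray(values, dtype=float), spacing, **kw)


def make_voi(mask, spacing=(2.0, 2.0, 2.0), **kw):
    return VOI(np.asarray(mask, dtype=bool), spacing, **kw)
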