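import numpy as np
import pytest

from xdiscreen import (
    DensityMap,
    NoiseAndMaskSpec,
    PhantomSpec,
    generate_phantom,
    simulate_pattern,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def three_disk_map():
    """Small asymmetric 3-disk phantom (64x64), handy wherever an
    orientation-free object would make reflection/shift tests vacuous."""
    spec = PhantomSpec(kind="disk_cluster", n_particles=3, particle_radius_px=4.0,
                       support_fraction=0.45, seed=7)
    return generate_phantom(spec, 64)


@pytest.fixture
def noiseless_pattern(three_disk_map):
    """Full-coverage, noise-free pattern of the 3-disk phantom."""
    noise = NoiseAndMaskSpec(total_photons=None, beamstop_halfwidth_px=0,
                             apply_poisson=False)
    return simulate_pattern(three_disk_map, noise)


@pytest.fixture
def random_map_pair(rng):
    a = DensityMap(values=rng.random((64, 64)), pixel_size=20.0)
    b = DensityMap(values=rng.random((64, 64)), pixel_size=20.0)
    return a, b
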