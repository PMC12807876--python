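import numpy as np
import pytest

from nemquant.synth import NoiseSpec, NucleusSpec, SynthScene, synth_nucleus_timelapse


@pytest.fixture(scope="session")
def clean_nucleus():
    """One noise-free nucleus (rho = 2) with its ground truth."""
    scene = SynthScene(
        fov_shape=(24, 96, 96), n_frames=1, seed=1,
        nuclei=[NucleusSpec(centre=(12, 48, 48), semi_axes=(9, 22, 22), rim_enrichment=2.0)],
        noise=NoiseSpec.none(),
    )
    return synth_nucleus_timelapse(scene)


@pytest.fixture(scope="session")
def noisy_nucleus():
    """The same nucleus under the default noise model."""
    scene = SynthScene(
        fov_shape=(24, 96, 96), n_frames=1, seed=1,
        nuclei=[NucleusSpec(centre=(12, 48, 48), semi_axes=(9, 22, 22), rim_enrichment=2.0)],
        noise=NoiseSpec(),
    )
    return synth_nucleus_timelapse(scene)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
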