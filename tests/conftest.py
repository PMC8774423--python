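import numpy as np
import pytest

from nucleiclust.synthdata import PatchSpec, generate_patch


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def default_patch():
    """One deterministic synthetic patch shared across tests."""
    return generate_patch(PatchSpec(seed=7))


@pytest.fixture(scope="session")
def small_patch():
    """A small, quick patch for pipeline-level tests."""
    spec = PatchSpec(
        size=224,
        n_clusters=3,
        nuclei_per_cluster=(5, 7),
        cluster_spread=24.0,
        min_cluster_separation=90.0,
        radius_range=(4.0, 7.0),
        seed=11,
    )
    return generate_patch(spec)
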