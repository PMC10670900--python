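import numpy as np
import pytest

from cbctsynth import ArtifactSpec, PhantomSpec, generate_dataset, generate_phantom_ct


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(image_size=64)


@pytest.fixture(scope="session")
def phantom_slice(small_spec):
    return generate_phantom_ct(small_spec, seed=7)


@pytest.fixture(scope="session")
def clinical_pair(small_spec, phantom_slice):
    from cbctsynth import degrade_to_cbct

    cbct = degrade_to_cbct(phantom_slice, ArtifactSpec.clinical(seed=7))
    return cbct, phantom_slice


@pytest.fixture(scope="session")
def tiny_dataset(small_spec):
    return generate_dataset(
        5, 2, spec=small_spec, artifact=ArtifactSpec.clinical(), seed=11
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
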