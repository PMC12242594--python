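import numpy as np
import pytest

from lumpsplit import CfpsSimConfig, DescriptorCollection, FacialDescriptorSet, generate
from lumpsplit.descriptors import N_DIM, N_SLOTS


def random_descriptor_set(rng, image_id="img", patient_id="pat", syndrome_id="syn"):
    return FacialDescriptorSet(
        image_id=image_id,
        patient_id=patient_id,
        syndrome_id=syndrome_id,
        descriptors=rng.standard_normal((N_SLOTS, N_DIM)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_collection(rng):
    """Six random images: three patients in two syndromes."""
    items = []
    for i, (pat, syn) in enumerate(
        [("p1", "sA"), ("p1", "sA"), ("p2", "sA"), ("p2", "sA"), ("p3", "sB"), ("p3", "sB")]
    ):
        items.append(random_descriptor_set(rng, f"im{i}", pat, syn))
    return DescriptorCollection(items)


@pytest.fixture(scope="session")
def separated_collection():
    """Well-separated synthetic CFPS: 12 syndromes, 3 patients x 2 images."""
    return generate(CfpsSimConfig(n_syndromes=12, seed=11))
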