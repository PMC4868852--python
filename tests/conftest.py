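import numpy as np
import pytest

from neurofuse import CohortSpec, DescriptorSet, generate_paired_volumes


@pytest.fixture(scope="session")
def tiny_records():
    """Small volume cohort shared by the slower integration tests."""
    spec = CohortSpec(n_per_class=5, volume_shape=(24, 24, 24), seed=7)
    return generate_paired_volumes(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_dset(descriptors, locations=None, slice_shape=(64, 64), seed=0):
    """Build a DescriptorSet around an explicit descriptor matrix."""
    descriptors = np.atleast_2d(np.asarray(descriptors, dtype=float))
    if locations is None:
        g = np.random.default_rng(seed)
        locations = np.column_stack(
            [
                np.zeros(len(descriptors), dtype=int),
                g.integers(0, slice_shape[0], len(descriptors)),
                g.integers(0, slice_shape[1], len(descriptors)),
            ]
        )
    return DescriptorSet(
        descriptors=descriptors,
        locations=np.asarray(locations, dtype=int),
        slice_shape=slice_shape,
    )
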