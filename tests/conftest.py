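import pytest

from mitovar import bundled_reference
from mitovar.haplogroups import bundled_tree


@pytest.fixture(scope="session")
def reference():
    return bundled_reference()


@pytest.fixture(scope="session")
def tree():
    return bundled_tree()


@pytest.fixture(scope="session")
def pairing_maps():
    from mitovar.io import load_pairing_maps

    return load_pairing_maps()


@pytest.fixture(scope="session")
def small_cohort(reference, tree):
    """A small simulated cohort shared by round-trip tests."""
    from mitovar.simulate import SimConfig, generate_cohort

    config = SimConfig(seed=42, n_pairs=6, n_controls=10, n_normal_thyroid=2)
    return config, generate_cohort(config, reference, tree)
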