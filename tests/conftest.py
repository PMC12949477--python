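import warnings

import numpy as np
import pytest

import sfsim
from sfsim.io import ReservedSeedWarning


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def small_truths():
    """A small progressing truth population shared across tests."""
    cfg = sfsim.SeedConfig(n_eyes=12, rng_seed=11)
    truths, persons = sfsim.truth_population(cfg)
    return truths, persons


@pytest.fixture(scope="session")
def small_bundle_pair(small_truths):
    """Matched progressing/stable Reliable bundles (12 eyes)."""
    truths, persons = small_truths
    stable = [sfsim.make_stable(t) for t in truths]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ReservedSeedWarning)
        prog = sfsim.measure_bundle(truths, "Reliable", 1, "progressing",
                                    persons)
        stab = sfsim.measure_bundle(stable, "Reliable", 5, "stable", persons)
    return prog, stab
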