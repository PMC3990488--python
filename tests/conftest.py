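import numpy as np
import pytest

from rsatools.rdm import RDM, PatternSet, RDMCollection, n_pairs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def labels(n):
    return tuple(f"c{i}" for i in range(n))


def random_rdm(rng, n_conditions=6, name="", measure="other"):
    vec = rng.random(n_pairs(n_conditions))
    return RDM(labels(n_conditions), vec, measure=measure, name=name)


def random_collection(rng, n_rdms=5, n_conditions=6, roles=None):
    rdms = tuple(
        random_rdm(rng, n_conditions, name=f"rdm{i}") for i in range(n_rdms)
    )
    return RDMCollection(rdms=rdms, roles=roles or ())


def random_patterns(rng, n_conditions=5, n_channels=8, name="pat"):
    return PatternSet(
        labels(n_conditions), rng.standard_normal((n_conditions, n_channels)), name=name
    )


@pytest.fixture
def patterns(rng):
    return random_patterns(rng)
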