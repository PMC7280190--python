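import numpy as np
import pytest

from amf_otufree import simulate as sim


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


@pytest.fixture(scope="session")
def small_truth():
    """8 reference taxa + 2 withheld, 400 bp, well separated (8% divergence)."""
    return sim.simulate_reference(8, length=400, divergence=0.08, seed=7, n_withheld=2)


@pytest.fixture(scope="session")
def small_refdb(small_truth):
    from amf_otufree.refdb import ReferenceRecord

    return [
        ReferenceRecord(small_truth.accessions[name], name, small_truth.taxa[name])
        for name in small_truth.in_db
    ]
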