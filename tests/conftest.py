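import numpy as np
import pytest

from pbmine import synthetic
from pbmine.references import load_clade_profiles, load_references


@pytest.fixture(scope="session")
def refs():
    return load_references()


@pytest.fixture(scope="session")
def search_refs(refs):
    return [r for r in refs if r.role != "outgroup"]


@pytest.fixture(scope="session")
def profiles(refs):
    return load_clade_profiles(refs)


@pytest.fixture(scope="session")
def small_genome():
    """One-family, three-copy, zero-divergence genome (noise-free plants)."""
    spec = synthetic.FamilySpec(clade_label="A", copy_count=3)
    cfg = synthetic.GeneratorConfig(
        genome_length=120_000, families=(spec,), seed=11
    )
    return synthetic.generate_genome(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


def random_dna(rng, n, gc=0.4):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.random.default_rng(rng).choice(list("ACGT"), size=n, p=p)) \
        if isinstance(rng, int) else \
        "".join(rng.choice(list("ACGT"), size=n, p=p))
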