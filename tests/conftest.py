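import numpy as np
import pytest
from hypothesis import settings

import loglinsup as ll

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def toy22():
    """2x2 table with counts 4,3,2,1 and the mutual-independence model."""
    rows = [(0, 0)] * 4 + [(0, 1)] * 3 + [(1, 0)] * 2 + [(1, 1)] * 1
    O = ll.observed_support(rows, (2, 2))
    B = ll.make_support(O, "A")
    spec = ll.ModelSpec("two_way", (2, 2), order=1)
    return O, B, spec


@pytest.fixture
def parity_partition(toy22):
    """Partition of the 2x2 cube into even and odd parity cells."""
    _, B, _ = toy22
    even = [p for p in B.patterns if sum(p) % 2 == 0]
    odd = [p for p in B.patterns if sum(p) % 2 == 1]
    return ll.Partition([B.restrict(even), B.restrict(odd)], "subvector", B,
                        labels=["even", "odd"])


@pytest.fixture(scope="session")
def cner5_sample():
    """One exact cn-ER k=5 dataset at n=250 with its observed support."""
    spec, th0 = ll.build_cn_er(5)
    S = ll.enumerate_full_support((2,) * 5)
    data = ll.sample_dataset(ll.GeneratorConfig(spec, th0, S, 250, seed=7))
    O = ll.observed_support(data, (2,) * 5)
    return spec, th0, S, data, O
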