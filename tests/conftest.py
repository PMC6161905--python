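import pytest

import rfbound as rb


@pytest.fixture
def quartet_12_34():
    """Unrooted quartet with split {1,2}|{3,4}."""
    return rb.read_newick("((1,2),(3,4));", "unrooted")


@pytest.fixture
def quartet_13_24():
    return rb.read_newick("((1,3),(2,4));", "unrooted")


@pytest.fixture
def star4():
    return rb.read_newick("(1,2,3,4);", "unrooted")


@pytest.fixture
def star3():
    return rb.read_newick("(1,2,3);", "unrooted")


def random_pair(n, rooted2, seed, rooted1=None, resolution=1.0, k=0):
    """Seeded pair of same-n random labeled trees (helper, not a fixture)."""
    if rooted1 is None:
        rooted1 = rooted2
    t1 = rb.label_canonically(
        rb.random_topology(n, rooted=rooted1, resolution=resolution, k=k, seed=seed)
    )
    t2 = rb.label_canonically(
        rb.random_topology(n, rooted=rooted2, resolution=resolution, k=k, seed=seed + 10_000)
    )
    return t1, t2
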