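import pytest

import spurnet as sp


@pytest.fixture
def triangle():
    """1->2 (w3), 2->3 (w4), 1->3 (w7): the minimal cascade-effect motif."""
    return sp.from_edges([("1", "2", 3), ("2", "3", 4), ("1", "3", 7)])


@pytest.fixture
def cascade():
    """Chain 1->2->3->4 (2+3+4=9) shadowed by the direct edge 1->4 (w9)."""
    return sp.from_edges(
        [("1", "2", 2), ("2", "3", 3), ("3", "4", 4), ("1", "4", 9)]
    )


@pytest.fixture
def looped():
    """A weight-4 walk 1->2->3->2->4 exists but revisits vertex 2, so the
    direct edge 1->4 (w4) has no valid alternative path."""
    return sp.from_edges(
        [("1", "2", 1), ("2", "3", 1), ("3", "2", 1), ("2", "4", 1), ("1", "4", 4)]
    )


@pytest.fixture
def diamond():
    """Two disjoint length-2 detours 1->2->3 and 1->4->3 around 1->3 (w7)."""
    return sp.from_edges(
        [
            ("1", "2", 3),
            ("1", "4", 3),
            ("2", "3", 4),
            ("4", "3", 4),
            ("1", "3", 7),
        ]
    )


def random_graph(seed, n_vertices=6, rho=0.4, w_max=6):
    return sp.gen_random(
        sp.RandomGraphParams(n_vertices, rho, w_max=w_max, seed=seed)
    )
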