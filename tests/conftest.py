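import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


def make_graph(n, pairs, z=6, coords=None, **kw):
    """AtomGraph from undirected (u, v) pairs; both directions stored."""
    from atomgps.graph_core import AtomGraph

    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    if pairs.size:
        both = np.concatenate([pairs, pairs[:, ::-1]], axis=0)
        order = np.lexsort((both[:, 1], both[:, 0]))
        edge_index = both[order].T.copy()
    else:
        edge_index = np.empty((2, 0), dtype=np.int64)
    zs = np.full(n, z) if np.isscalar(z) else np.asarray(z)
    return AtomGraph(atomic_numbers=zs, edge_index=edge_index,
                     coords=coords, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def path3():
    return make_graph(3, [(0, 1), (1, 2)])


@pytest.fixture
def triangle():
    return make_graph(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def k2():
    return make_graph(2, [(0, 1)])


def random_connected_graph(n, rng):
    """Random connected graph: spanning tree + extra edges."""
    pairs = {(int(min(i, a)), int(max(i, a)))
             for i, a in ((i, rng.integers(i)) for i in range(1, n))}
    n_extra = int(rng.integers(0, n))
    for _ in range(n_extra):
        u, v = rng.integers(n), rng.integers(n)
        if u != v:
            pairs.add((int(min(u, v)), int(max(u, v))))
    return make_graph(n, sorted(pairs))


def rigid_motion(coords, rng):
    """Random rotation (QR-based) + translation applied row-wise."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.normal(scale=5.0, size=3)
    return coords @ q.T + t
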