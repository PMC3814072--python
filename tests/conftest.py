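import numpy as np
import pandas as pd
import pytest

from mwnet.network import StateMatrix


def brute_force_network(states: StateMatrix):
    """Independent O(N*M^2) enumeration of the coexpression network.

    Walks every gene pair and every sample with plain Python loops, counting
    joint over/silenced states directly.  Deliberately structured differently
    from the per-sample accumulation in the package (per-pair outer loop) so
    it can serve as an oracle.
    """
    genes = sorted(states.data.columns)
    vals = {g: states.data[g].to_numpy() for g in genes}
    nodes = {g for g in genes if (vals[g] != 0).any()}
    edges = {}
    for ai in range(len(genes)):
        for bi in range(ai + 1, len(genes)):
            a, b = genes[ai], genes[bi]
            w = [0, 0, 0, 0]
            for sa, sb in zip(vals[a], vals[b]):
                if sa != 0 and sb != 0:
                    w[(0 if sa > 0 else 2) + (0 if sb > 0 else 1)] += 1
            if sum(w) > 0:
                edges[(a, b)] = tuple(w)
    return nodes, edges


def network_as_dict(net):
    """Nodes and canonical-order edge weight tuples of a built network."""
    from mwnet.network import edge_weight_vector

    edges = {}
    for u, v in net.edges:
        a, b = sorted((str(u), str(v)))
        edges[(a, b)] = tuple(int(x) for x in edge_weight_vector(net, a, b))
    return set(net.nodes), edges


def random_state_matrix(rng: np.random.Generator, n_max: int = 10, m_max: int = 12):
    """A random ternary state matrix with N <= n_max samples, M <= m_max genes."""
    n = int(rng.integers(1, n_max + 1))
    m = int(rng.integers(2, m_max + 1))
    states = rng.choice([-1, 0, 1], size=(n, m), p=[0.3, 0.4, 0.3])
    genes = [f"g{j:03d}" for j in range(m)]
    df = pd.DataFrame(states, index=[f"s{i}" for i in range(n)], columns=genes)
    return StateMatrix(df, epsilon=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(186282)


@pytest.fixture
def small_gem_df():
    """A tiny samples x genes log-ratio matrix with one missing value."""
    return pd.DataFrame(
        [[1.0, -0.5, 0.2], [0.2, 0.0, -1.3], [np.nan, 2.0, 0.7], [0.5, -2.0, 0.1]],
        index=["s1", "s2", "s3", "s4"],
        columns=["gA", "gB", "gC"],
    )
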