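import numpy as np
import pytest

from rnncluster.synthetic import generate_feature_table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def separable_table():
    """Well-separated two-class feature table (effect size 3)."""
    return generate_feature_table(
        n_per_group=30, p=10, planted_features=range(10), effect_size=3.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def moderate_table():
    """Moderate planted effect in a minority of features."""
    return generate_feature_table(
        n_per_group=46, p=50, planted_features=range(5), effect_size=2.0,
        seed=3,
    )


def random_graph(rng, n, p):
    """Random symmetric adjacency matrix with edge probability p."""
    a = (rng.random((n, n)) < p).astype(np.int8)
    a = np.triu(a, k=1)
    return a + a.T


def brute_force_metrics(adj, local_distances="subgraph"):
    """Independent oracle: exhaustive BFS + direct neighbour-edge counting."""
    n = adj.shape[0]

    def bfs(a, src):
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in range(a.shape[0]):
                    if a[u, v] and v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        return dist

    adj = np.asarray(adj, dtype=int)
    degree = np.array([sum(int(adj[i, j]) for j in range(n)) for i in range(n)])
    sp = np.full((n, n), float(n))
    for i in range(n):
        for j, d in bfs(adj, i).items():
            sp[i, j] = d
    clustering = np.zeros(n)
    local_eff = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        ni = len(nbrs)
        if ni < 2:
            continue
        e = sum(adj[u, v] for ui, u in enumerate(nbrs) for v in nbrs[ui + 1:])
        clustering[i] = 2 * e / (ni * (ni - 1))
        if local_distances == "subgraph":
            sub = adj[np.ix_(nbrs, nbrs)]
            total = 0.0
            for a in range(ni):
                d = bfs(sub, a)
                for b in range(ni):
                    if b != a and b in d:
                        total += 1.0 / d[b]
        else:
            total = 0.0
            for a in nbrs:
                d = bfs(adj, a)
                for b in nbrs:
                    if b != a and b in d:
                        total += 1.0 / d[b]
        local_eff[i] = total / (ni * (ni - 1))
    return degree, clustering, sp, local_eff
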