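import numpy as np
import pytest

from vagalnet.connectome import ConnectivityMatrix


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240601)


def random_connectivity(rng, n, density=0.7):
    """Random symmetric weighted graph in [0,1] with zero diagonal."""
    w = np.triu(rng.random((n, n)) * (rng.random((n, n)) < density), 1)
    w = w + w.T
    return ConnectivityMatrix(weights=w, region_ids=[f"r{i}" for i in range(n)])


def brute_force_clustering(W):
    """Direct triple enumeration of the geometric-mean clustering formula."""
    n = W.shape[0]
    wmax = W.max()
    out = np.zeros(n)
    if wmax == 0:
        return out
    wh = W / wmax
    for i in range(n):
        k = int((W[i] > 0).sum())
        if k < 2:
            continue
        s = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    s += (wh[i, j] * wh[i, h] * wh[j, h]) ** (1.0 / 3.0)
        out[i] = s / (k * (k - 1))
    return out


def brute_force_efficiency(W):
    """Floyd-Warshall all-pairs shortest paths on 1/w lengths."""
    n = W.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if W[i, j] > 0:
                d[i, j] = 1.0 / W[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    e = np.zeros(n)
    for i in range(n):
        vals = [1.0 / d[i, j] if np.isfinite(d[i, j]) else 0.0 for j in range(n) if j != i]
        e[i] = float(np.mean(vals))
    return e
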