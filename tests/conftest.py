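"""Shared fixtures: small random tensors and deterministic RNG helpers."""

import numpy as np
import pytest
import scipy.sparse as sp

from rhsminer import NetworkTensor


def random_tensor(n, d, rng, density=1.0):
    """Random non-negative tensor with weights in [0, 1)."""
    iu, ju = np.triu_indices(n, k=1)
    slices = []
    for _ in range(d):
        w = rng.random(iu.size)
        if density < 1.0:
            w *= rng.random(iu.size) < density
        slices.append(sp.csr_matrix((w, (iu, ju)), shape=(n, n)))
    genes = [f"g{i}" for i in range(n)]
    nets = [f"n{k}" for k in range(d)]
    return NetworkTensor(genes, nets, slices)


def block_tensor(n, d, block_genes, block_nets, weight=1.0, background=0.0):
    """Tensor that is ``background`` everywhere except a uniform block."""
    full = np.full((n, n), background)
    slices = []
    bg = sorted(block_genes)
    for k in range(d):
        a = full.copy()
        if k in set(block_nets):
            for x, i in enumerate(bg):
                for j in bg[x + 1:]:
                    a[i, j] = weight
        a = np.triu(a, k=1)
        slices.append(sp.csr_matrix(a))
    genes = [f"g{i}" for i in range(n)]
    nets = [f"n{k}" for k in range(d)]
    return NetworkTensor(genes, nets, slices)


def brute_force_H(t, g, d):
    """Triple-loop oracle for the heaviness objective."""
    total = 0.0
    for k in range(t.n_networks):
        a = t.symmetric(k).toarray()
        for i in range(t.n_genes):
            for j in range(i + 1, t.n_genes):
                total += d[k] * a[i, j] * g[i] * g[j]
    return total


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_tensor(rng):
    return random_tensor(6, 3, rng)
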