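"""Synthetic data: background tensors, planted heavy blocks, factor-model
expression matrices.

The background emulates the co-expression pipeline's null: standardized
Fisher z-scores are standard normal, so absolute back-transformed
correlations follow |tanh(Z)|, Z ~ N(0, 1).  Its mean edge weight is
E|tanh(Z)| ~= 0.556 with standard deviation ~= 0.292 (see
:func:`expected_background_weight`).  Heavy blocks of controlled size,
recurrence and mean weight are planted by redrawing block edges, so the
realized heaviness is controlled directly and all other entries are
conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy import integrate

from .coexpr import ExpressionDataset
from .tensor_model import RHS, NetworkTensor, heaviness

__all__ = [
    "PlantSpec",
    "background_tensor",
    "plant_rhs",
    "factor_expression",
    "expected_background_weight",
]


def expected_background_weight() -> tuple[float, float]:
    """Mean and standard deviation of |tanh(Z)|, Z ~ N(0,1), by quadrature."""
    phi = lambda z: np.exp(-z * z / 2) / np.sqrt(2 * np.pi)
    m1, _ = integrate.quad(lambda z: abs(np.tanh(z)) * phi(z), -12, 12)
    m2, _ = integrate.quad(lambda z: np.tanh(z) ** 2 * phi(z), -12, 12)
    return float(m1), float(np.sqrt(m2 - m1 * m1))


@dataclass
class PlantSpec:
    """A planted block: m genes x r networks with target mean weight h.

    ``h`` must exceed the background mean (~0.556) for the block to be heavy;
    ``spread`` is the half-width of the uniform weight noise around h
    (clipped to [0, 1]).
    """

    n_genes: int = 8
    n_networks: int = 10
    heaviness: float = 0.85
    spread: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 2 or self.n_networks < 1:
            raise ValueError("block needs >= 2 genes and >= 1 network")
        if not 0 < self.heaviness < 1:
            raise ValueError("target heaviness must be in (0, 1)")
        if self.spread < 0:
            raise ValueError("spread must be >= 0")


def background_tensor(N: int, D: int, seed: int = 0) -> NetworkTensor:
    """Null tensor: every edge weight i.i.d. |tanh(Z)|, Z ~ N(0,1).

    Symmetric, zero-diagonal, fully dense slices; deterministic under seed.
    """
    if N < 2 or D < 1:
        raise ValueError("need N >= 2 genes and D >= 1 networks")
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(N, k=1)
    slices = []
    for _ in range(D):
        w = np.abs(np.tanh(rng.standard_normal(iu.size)))
        slices.append(sp.csr_matrix((w, (iu, ju)), shape=(N, N)))
    genes = [f"G{i:04d}" for i in range(N)]
    nets = [f"net{k:03d}" for k in range(D)]
    return NetworkTensor(genes, nets, slices)


def plant_rhs(t: NetworkTensor, spec: PlantSpec) -> tuple[NetworkTensor, RHS]:
    """Plant one heavy block into a tensor; returns (tensor, ground truth).

    Gene and network subsets are chosen uniformly at random; block edge
    weights are redrawn as h + Uniform(-spread, spread), clipped to [0, 1].
    Entries outside the block are untouched.  Overlap with a previously
    planted block is allowed (the caller sees the realized truth).
    """
    if spec.n_genes > t.n_genes or spec.n_networks > t.n_networks:
        raise ValueError("planted block does not fit in the tensor")
    rng = np.random.default_rng(spec.seed)
    gi = np.sort(rng.choice(t.n_genes, size=spec.n_genes, replace=False))
    ki = np.sort(rng.choice(t.n_networks, size=spec.n_networks, replace=False))
    out = t.copy()
    iu, ju = np.triu_indices(spec.n_genes, k=1)
    rows, cols = gi[iu], gi[ju]
    for k in ki:
        w = spec.heaviness + rng.uniform(-spec.spread, spec.spread, size=iu.size)
        np.clip(w, 0.0, 1.0, out=w)
        a = out.slices[k].tolil()
        for r, c, wv in zip(rows, cols, w):
            lo, hi = (r, c) if r < c else (c, r)
            a[lo, hi] = wv
        out.slices[k] = a.tocsr()
        out._invalidate(k)
    genes = frozenset(out.gene_ids[i] for i in gi)
    nets = frozenset(out.network_ids[k] for k in ki)
    truth = RHS(genes=genes, networks=nets, heaviness=heaviness(out, genes, nets))
    return out, truth


def factor_expression(
    N: int,
    S: int,
    module_genes,
    noise_sd: float = 0.5,
    seed: int = 0,
    dataset_id: str = "synthetic",
) -> ExpressionDataset:
    """Factor-model expression matrix for end-to-end pipeline tests.

    Module genes share one latent per-sample factor plus Gaussian noise of
    standard deviation ``noise_sd``; all other genes are independent standard
    normals.  Gene ids follow the ``G%04d`` convention of
    :func:`background_tensor`.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(N)]
    gset = set(module_genes)
    unknown = gset - set(genes)
    if unknown:
        raise ValueError(f"module genes outside the universe: {sorted(unknown)}")
    factor = rng.standard_normal(S)
    values = rng.standard_normal((N, S))
    for i, g in enumerate(genes):
        if g in gset:
            values[i] = factor + noise_sd * rng.standard_normal(S)
    samples = [f"s{j:03d}" for j in range(S)]
    return ExpressionDataset(dataset_id, genes, samples, values)
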