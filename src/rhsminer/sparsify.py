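"""Non-uniform edge sampling (graph sparsification) with bias correction.

Heavy subgraphs are carried by heavy edges, so edges are kept with a
probability that grows with their weight:

    p(w) = 1                  if w >= w0
         = min(1, c * w**alpha)  otherwise

Kept edges are reweighted to w / p(w) so the sparsified tensor is an unbiased
estimator of the original; a corrected weight exceeding 1 when the original
weight was <= 1 is capped at 1 to avoid inflated single edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .tensor_model import NetworkTensor

__all__ = ["SamplingConfig", "sample_probability", "sparsify_tensor"]


@dataclass
class SamplingConfig:
    """Edge-sampling parameters.

    w0: weight above which edges are always kept (default 0.5, keeps all
        strong edges).  c, alpha: below w0 the keep probability is
        min(1, c * w**alpha); the defaults (4, 2) retain light edges roughly in
        proportion to w^2.  cap_at_one: apply the cap on corrected weights.
    """

    w0: float = 0.5
    c: float = 4.0
    alpha: float = 2.0
    seed: int = 0
    cap_at_one: bool = True

    def __post_init__(self):
        if not (0 < self.w0 <= 1):
            raise ValueError("w0 must be in (0, 1]")
        if self.c <= 0 or self.alpha <= 0:
            raise ValueError("c and alpha must be positive")


def sample_probability(w, cfg: SamplingConfig):
    """Keep probability of an edge of weight ``w`` (vectorized, monotone in w)."""
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    p = np.where(w >= cfg.w0, 1.0, np.minimum(1.0, cfg.c * np.power(w, cfg.alpha)))
    return float(p) if p.ndim == 0 else p


def sparsify_tensor(t: NetworkTensor, cfg: SamplingConfig) -> NetworkTensor:
    """Sample each edge independently and reweight kept edges by 1/p.

    Deterministic under a fixed ``cfg.seed``.  Symmetry is preserved because
    sampling acts on the stored upper triangle.
    """
    rng = np.random.default_rng(cfg.seed)
    slices = []
    for k in range(t.n_networks):
        coo = t.slices[k].tocoo()
        if coo.nnz == 0:
            slices.append(t.slices[k].copy())
            continue
        p = sample_probability(coo.data, cfg)
        keep = rng.random(coo.nnz) < p
        w_hat = coo.data[keep] / p[keep]
        if cfg.cap_at_one:
            over = (w_hat > 1.0) & (coo.data[keep] <= 1.0)
            w_hat[over] = 1.0
        a = sp.csr_matrix(
            (w_hat, (coo.row[keep], coo.col[keep])), shape=t.slices[k].shape
        )
        slices.append(a)
    return NetworkTensor(list(t.gene_ids), list(t.network_ids), slices)
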