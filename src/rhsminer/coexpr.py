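"""Weighted co-expression network construction from expression matrices.

Per dataset, every gene pair goes through the pipeline

    leave-one-out Pearson r  ->  Fisher z = atanh(r)
    ->  standardize z over all pairs (zero mean, unit variance)
    ->  r' = tanh(z')  ->  edge weight |r'|  in [0, 1)

The leave-one-out estimate is the Pearson correlation of minimal absolute
value over all single-sample deletions: conservative, and robust to a single
shared experimental outlier that would otherwise inflate the plain Pearson
correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .tensor_model import NetworkTensor

__all__ = [
    "ExpressionDataset",
    "load_expression",
    "loo_correlation",
    "fisher_z",
    "build_network",
]

#: correlations are clamped to +/- (1 - CLAMP_EPS) before the Fisher transform
CLAMP_EPS = 1e-6


@dataclass
class ExpressionDataset:
    """A genes x samples expression matrix with identifiers.

    At least 3 samples are required (leave-one-out needs non-degenerate
    subsets); 20+ samples are recommended for robust correlation estimates.
    Duplicate probes for one gene are assumed to be averaged upstream.
    """

    dataset_id: str
    genes: list
    samples: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("matrix shape does not match gene/sample ids")
        if len(self.samples) < 3:
            raise ValueError("need at least 3 samples for leave-one-out estimates")


def load_expression(path: str, dataset_id: str | None = None) -> ExpressionDataset:
    """Read a TSV with gene ids in the first column and a sample-id header row."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if dataset_id is None:
        import os

        dataset_id = os.path.splitext(os.path.basename(path))[0]
    return ExpressionDataset(
        dataset_id, [str(g) for g in df.index], [str(s) for s in df.columns], df.to_numpy()
    )


def _loo_pearson_all(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """All S leave-one-out Pearson correlations of two sample vectors.

    Uses downdated sufficient statistics, O(S) total.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    s = x.size
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    n = s - 1
    mx = (sx - x) / n
    my = (sy - y) / n
    vx = (sxx - x * x) / n - mx * mx
    vy = (syy - y * y) / n - my * my
    cov = (sxy - x * y) / n - mx * my
    vx = np.maximum(vx, 0.0)
    vy = np.maximum(vy, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / np.sqrt(vx * vy)
    return r


def loo_correlation(x, y) -> float:
    """Conservative leave-one-out Pearson estimate.

    Computes the S correlations obtained by deleting each sample once and
    returns the one with the smallest absolute value (sign retained), clamped
    to +/- (1 - 1e-6).  If any leave-one-out subset has zero variance the
    result is defined as 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    r = _loo_pearson_all(x, y)
    if not np.isfinite(r).all():
        warnings.warn("zero variance in a leave-one-out subset; correlation set to 0")
        return 0.0
    idx = int(np.argmin(np.abs(r)))
    return float(np.clip(r[idx], -(1 - CLAMP_EPS), 1 - CLAMP_EPS))


def fisher_z(r: float):
    """Fisher's variance-stabilizing transform z = atanh(r) = 0.5 ln((1+r)/(1-r))."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| must be < 1 (clamp before transforming)")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def build_network(ds: ExpressionDataset) -> tuple:
    """Build one co-expression network slice from an expression dataset.

    Returns ``(gene_ids, upper_triangular_weight_matrix)`` with weights
    ``|tanh(z')|`` where z' are the dataset-standardized Fisher z-scores of the
    leave-one-out correlations.  Needs at least 3 genes (>= 2 gene pairs, so
    the z-scores have nonzero variance to standardize).
    """
    n = len(ds.genes)
    n_pairs = n * (n - 1) // 2
    if n_pairs < 2:
        raise ValueError("need at least 3 genes (2 gene pairs) to standardize z-scores")
    iu, ju = np.triu_indices(n, k=1)
    z = np.empty(n_pairs)
    for t, (i, j) in enumerate(zip(iu, ju)):
        r = loo_correlation(ds.values[i], ds.values[j])
        z[t] = np.arctanh(r)
    mu = z.mean()
    sd = z.std(ddof=0)
    if sd == 0.0:
        raise ValueError("degenerate dataset: all pairwise z-scores identical")
    w = np.abs(np.tanh((z - mu) / sd))
    mat = sp.csr_matrix((w, (iu, ju)), shape=(n, n))
    return list(ds.genes), mat


def build_tensor(datasets) -> NetworkTensor:
    """Stack co-expression networks from datasets sharing one gene universe."""
    datasets = list(datasets)
    genes0 = list(datasets[0].genes)
    for ds in datasets[1:]:
        if list(ds.genes) != genes0:
            raise ValueError("datasets must share one ordered gene universe")
    slices = [build_network(ds)[1] for ds in datasets]
    return NetworkTensor(genes0, [ds.dataset_id for ds in datasets], slices)
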