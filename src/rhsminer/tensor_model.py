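"""Network-stack (third-order tensor) data model, heaviness objective, and masking.

A stack of ``D`` undirected, weighted networks over one shared universe of
``N`` genes is stored as a third-order tensor ``W`` with entries
``w(i, j, k)`` = weight of edge (i, j) in network ``k``.  Each slice is
symmetric, non-negative and has a zero diagonal.  Internally every slice is
kept as a sparse upper-triangular matrix (``i < j``); the symmetric form is
materialised lazily and cached for linear-algebra work.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "NetworkTensor",
    "MembershipPair",
    "RHS",
    "load_networks",
    "save_networks",
    "objective_H",
    "heaviness",
    "mask_rhs",
]

#: Largest N for which dense slice reconstruction is allowed by default.
DENSE_BOUND = 2000


class TensorDataError(ValueError):
    """Raised for malformed edge lists or inconsistent tensor inputs."""


@dataclass
class NetworkTensor:
    """D symmetric non-negative weighted networks over one gene universe.

    Parameters
    ----------
    gene_ids
        Ordered unique gene identifiers (length N).
    network_ids
        Ordered unique network identifiers (length D).
    slices
        Per-network upper-triangular sparse matrices of shape (N, N) with
        entries only at ``i < j``.
    """

    gene_ids: list
    network_ids: list
    slices: list
    _sym_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise TensorDataError("duplicate gene ids")
        if len(set(self.network_ids)) != len(self.network_ids):
            raise TensorDataError("duplicate network ids")
        if len(self.slices) != len(self.network_ids):
            raise TensorDataError("one slice per network required")
        n = self.n_genes
        for k, a in enumerate(self.slices):
            a = sp.csr_matrix(a)
            if a.shape != (n, n):
                raise TensorDataError(f"slice {k} has shape {a.shape}, expected {(n, n)}")
            if a.nnz and a.data.min() < 0:
                raise TensorDataError(f"negative weight in network {self.network_ids[k]}")
            if a.diagonal().any():
                raise TensorDataError(
                    f"self-loop weight in network {self.network_ids[k]}"
                )
            upper = sp.triu(a, k=1).tocsr()
            lower = sp.triu(a.T, k=1).tocsr()  # lower triangle folded up
            if lower.nnz:
                if upper.nnz:
                    if (upper != lower).nnz:
                        raise TensorDataError(
                            f"asymmetric weights in network {self.network_ids[k]}"
                        )
                    a = upper  # symmetric input: keep one triangle
                else:
                    a = lower
            else:
                a = upper
            a.eliminate_zeros()
            self.slices[k] = sp.csr_matrix(a)
        self._sym_cache = {}

    # -- basic geometry ----------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_networks(self) -> int:
        return len(self.network_ids)

    def gene_index(self, genes) -> np.ndarray:
        lookup = self._gene_lookup()
        try:
            return np.asarray([lookup[g] for g in genes], dtype=int)
        except KeyError as e:
            raise TensorDataError(f"unknown gene id {e.args[0]!r}") from None

    def network_index(self, networks) -> np.ndarray:
        lookup = {nid: k for k, nid in enumerate(self.network_ids)}
        try:
            return np.asarray([lookup[nid] for nid in networks], dtype=int)
        except KeyError as e:
            raise TensorDataError(f"unknown network id {e.args[0]!r}") from None

    def _gene_lookup(self):
        if not hasattr(self, "_glut") or len(self._glut) != self.n_genes:
            self._glut = {g: i for i, g in enumerate(self.gene_ids)}
        return self._glut

    # -- access ------------------------------------------------------------
    def symmetric(self, k: int) -> sp.csr_matrix:
        """Full symmetric adjacency of network ``k`` (cached)."""
        if k not in self._sym_cache:
            u = self.slices[k]
            self._sym_cache[k] = (u + u.T).tocsr()
        return self._sym_cache[k]

    def dense(self, k: int) -> np.ndarray:
        if self.n_genes > DENSE_BOUND:
            raise TensorDataError(f"dense reconstruction disabled for N > {DENSE_BOUND}")
        return self.symmetric(k).toarray()

    def total_weight(self) -> float:
        """Sum of all (unordered) edge weights over all networks."""
        return float(sum(a.sum() for a in self.slices))

    def copy(self) -> "NetworkTensor":
        return NetworkTensor(
            list(self.gene_ids), list(self.network_ids), [a.copy() for a in self.slices]
        )

    def _invalidate(self, k: int):
        self._sym_cache.pop(k, None)


@dataclass
class MembershipPair:
    """Continuous non-negative gene (g, length N) and network (d, length D) scores."""

    g: np.ndarray
    d: np.ndarray

    def __post_init__(self):
        self.g = np.asarray(self.g, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if (self.g < 0).any() or (self.d < 0).any():
            raise ValueError("membership values must be non-negative")


@dataclass(frozen=True)
class RHS:
    """A recurrent heavy subgraph: a gene set, the networks it recurs in, and
    its heaviness (mean edge weight over all member-gene pairs and member
    networks)."""

    genes: frozenset
    networks: frozenset
    heaviness: float

    def __post_init__(self):
        if len(self.genes) < 2:
            raise ValueError("an RHS needs at least 2 genes")
        if len(self.networks) < 1:
            raise ValueError("an RHS needs at least 1 network")


# ---------------------------------------------------------------------------
# I/O: per-network edge-list TSV + manifest
# ---------------------------------------------------------------------------

def load_networks(edge_list_files, gene_universe_policy: str = "union") -> NetworkTensor:
    """Load a tensor from per-network edge-list TSVs.

    Parameters
    ----------
    edge_list_files
        Mapping ``network_id -> path`` or a list of paths (network ids then
        default to the file basenames without extension).
    gene_universe_policy
        ``"union"`` (genes absent from a network get zero-weight pairs) or
        ``"intersection"`` (only genes present in every network are kept).
    """
    if gene_universe_policy not in ("union", "intersection"):
        raise TensorDataError(f"unknown gene universe policy {gene_universe_policy!r}")
    if not isinstance(edge_list_files, dict):
        edge_list_files = {
            os.path.splitext(os.path.basename(p))[0]: p for p in edge_list_files
        }
    if not edge_list_files:
        raise TensorDataError("no edge-list files given")

    per_net = {}
    for nid, path in edge_list_files.items():
        df = pd.read_csv(
            path, sep="\t", header=None, names=["gene_i", "gene_j", "weight"],
            dtype={"gene_i": str, "gene_j": str}, float_precision="round_trip",
        )
        if df["weight"].isna().any():
            row = int(df.index[df["weight"].isna()][0]) + 1
            raise TensorDataError(f"{path}:{row}: unparseable weight")
        if (df["weight"] < 0).any():
            row = int(df.index[df["weight"] < 0][0]) + 1
            raise TensorDataError(f"{path}:{row}: negative weight")
        if (df["gene_i"] == df["gene_j"]).any():
            row = int(df.index[df["gene_i"] == df["gene_j"]][0]) + 1
            raise TensorDataError(f"{path}:{row}: self-loop")
        per_net[nid] = df

    gene_sets = [set(df["gene_i"]) | set(df["gene_j"]) for df in per_net.values()]
    if gene_universe_policy == "union":
        universe = set().union(*gene_sets)
    else:
        universe = set.intersection(*gene_sets)
    gene_ids = sorted(universe)
    lookup = {g: i for i, g in enumerate(gene_ids)}
    n = len(gene_ids)

    slices = []
    for nid, df in per_net.items():
        if gene_universe_policy == "intersection":
            df = df[df["gene_i"].isin(lookup) & df["gene_j"].isin(lookup)]
        ii = df["gene_i"].map(lookup).to_numpy()
        jj = df["gene_j"].map(lookup).to_numpy()
        lo, hi = np.minimum(ii, jj), np.maximum(ii, jj)
        key = lo * n + hi
        order = np.argsort(key, kind="stable")
        key_s, w_s = key[order], df["weight"].to_numpy()[order]
        dup = key_s[1:] == key_s[:-1]
        if dup.any():
            conflict = dup & (w_s[1:] != w_s[:-1])
            if conflict.any():
                raise TensorDataError(
                    f"{edge_list_files[nid]}: conflicting duplicate edge "
                    f"(pair index {int(key_s[1:][conflict][0])})"
                )
            keep = np.concatenate([[True], ~dup])
            key_s, w_s = key_s[keep], w_s[keep]
        a = sp.csr_matrix((w_s, (key_s // n, key_s % n)), shape=(n, n))
        slices.append(a)
    return NetworkTensor(gene_ids, list(per_net.keys()), slices)


def save_networks(t: NetworkTensor, out_dir: str, manifest: str = "manifest.tsv"):
    """Write one edge-list TSV per network plus a manifest mapping id -> path."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for k, nid in enumerate(t.network_ids):
        path = os.path.join(out_dir, f"{nid}.tsv")
        coo = t.slices[k].tocoo()
        df = pd.DataFrame(
            {
                "gene_i": [t.gene_ids[i] for i in coo.row],
                "gene_j": [t.gene_ids[j] for j in coo.col],
                "weight": coo.data,
            }
        )
        df.to_csv(path, sep="\t", header=False, index=False, float_format="%.17g")
        rows.append((nid, path))
    pd.DataFrame(rows).to_csv(
        os.path.join(out_dir, manifest), sep="\t", header=False, index=False
    )
    return os.path.join(out_dir, manifest)


def load_manifest(manifest_path: str, gene_universe_policy: str = "union") -> NetworkTensor:
    """Load a tensor from a manifest TSV (network_id <TAB> edge-list path)."""
    df = pd.read_csv(manifest_path, sep="\t", header=None, names=["id", "path"], dtype=str)
    base = os.path.dirname(os.path.abspath(manifest_path))
    files = {
        r.id: (r.path if os.path.isabs(r.path) else os.path.join(base, os.path.basename(r.path)))
        for r in df.itertuples()
    }
    # fall back to manifest-relative resolution when stored paths moved with the dir
    for nid, p in files.items():
        if not os.path.exists(p):
            alt = os.path.join(base, os.path.basename(p))
            if os.path.exists(alt):
                files[nid] = alt
    return load_networks(files, gene_universe_policy)


# ---------------------------------------------------------------------------
# Heaviness objective and block heaviness
# ---------------------------------------------------------------------------

def objective_H(t: NetworkTensor, m: MembershipPair) -> float:
    """Summed-weight objective H(g, d) = sum_k d_k * sum_{i<j} w(i,j,k) g_i g_j.

    Each unordered gene pair is counted once.  This is the quantity the
    continuous relaxation maximises; for binary memberships selecting a block
    it equals heaviness times the number of edge slots in the block.
    """
    if m.g.shape != (t.n_genes,) or m.d.shape != (t.n_networks,):
        raise ValueError(
            f"membership dimensions {m.g.shape}/{m.d.shape} do not match tensor "
            f"({t.n_genes} genes, {t.n_networks} networks)"
        )
    total = 0.0
    for k in range(t.n_networks):
        if m.d[k] == 0.0:
            continue
        total += m.d[k] * float(m.g @ t.slices[k].dot(m.g))
    return total


def heaviness(t: NetworkTensor, genes, networks) -> float:
    """Mean edge weight over all ``|networks| * C(|genes|, 2)`` edge slots.

    Absent edges count as weight zero (they occupy a slot in the denominator).
    """
    gi = t.gene_index(set(genes))
    ki = t.network_index(set(networks))
    if len(gi) < 2:
        raise ValueError("heaviness needs at least 2 genes")
    if len(ki) < 1:
        raise ValueError("heaviness needs at least 1 network")
    n_slots = len(ki) * len(gi) * (len(gi) - 1) // 2
    total = 0.0
    for k in ki:
        sub = t.slices[k][np.ix_(gi, gi)]
        total += float(sub.sum())  # upper-tri storage counts each pair once
    return total / n_slots


def block_weight_sums(t: NetworkTensor, genes) -> np.ndarray:
    """Per-network sum of edge weights within a gene set (helper for
    extraction and activity profiles)."""
    gi = t.gene_index(set(genes))
    return np.array([float(t.slices[k][np.ix_(gi, gi)].sum()) for k in range(t.n_networks)])


def mask_rhs(t: NetworkTensor, r: RHS, inplace: bool = False) -> NetworkTensor:
    """Zero out every member-gene-pair edge inside every member network.

    All other entries are untouched; symmetry is preserved by construction
    (only the upper triangle is stored).  Idempotent.
    """
    out = t if inplace else t.copy()
    gi = out.gene_index(r.genes)
    ki = out.network_index(r.networks)
    for k in ki:
        a = out.slices[k].tolil()
        a[np.ix_(gi, gi)] = 0.0
        out.slices[k] = a.tocsr()
        out.slices[k].eliminate_zeros()
        out._invalidate(k)
    return out
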