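"""Hypergeometric enrichment of module gene sets and of network phenotypes.

A module of n genes drawn from a universe of N genes overlaps a K-gene
annotation set in k genes; significance is the upper hypergeometric tail
P(X >= k).  Benjamini-Hochberg correction is applied per module across the
tested sets; a module is "homogeneous" for a set when the adjusted q-value
is at most 0.05.  Over-general annotation sets (more than 500 genes) are
excluded before testing.  The same machinery applied to per-network
phenotype labels scores phenotype specificity of a pattern's recurrence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "hypergeom_tail",
    "enrich_module",
    "phenotype_enrichment",
    "random_modules",
]

DEFAULT_MAX_SET_SIZE = 500
DEFAULT_Q_CUT = 0.05

RESULT_COLUMNS = ["module", "set", "overlap", "p", "q", "flag"]


@dataclass
class GeneSetCollection:
    """Named gene sets over an annotation universe."""

    sets: dict  # name -> frozenset of genes
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for name, genes in self.sets.items():
            gs = frozenset(genes)
            if not gs:
                raise ValueError(f"gene set {name!r} is empty")
            clean[name] = gs
        self.sets = clean

    def __len__(self):
        return len(self.sets)

    def filtered(self, max_set_size: int) -> "GeneSetCollection":
        kept = {n: s for n, s in self.sets.items() if len(s) <= max_set_size}
        return GeneSetCollection(kept, {n: self.descriptions.get(n, "") for n in kept})


def read_gmt(path: str) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...`` per line."""
    sets, descs = {}, {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, genes")
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set id {name!r}")
            sets[name] = frozenset(genes)
            descs[name] = desc
    return GeneSetCollection(sets, descs)


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    ``k`` genes of an ``n``-gene module fall in a ``K``-gene annotation set
    within an ``N``-gene universe.
    """
    if not (0 <= k <= min(n, K) and n <= N and K <= N and n >= 0 and K >= 0):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    # sf(k-1) = P(X >= k)
    return float(min(1.0, hypergeom.sf(k - 1, N, K, n)))


def _bh_frame(rows, q_cut: float) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS[:4])
    if df.empty:
        df["q"] = pd.Series(dtype=float)
        df["flag"] = pd.Series(dtype=bool)
        return df
    _, qvals, _, _ = multipletests(df["p"].to_numpy(), method="fdr_bh")
    df["q"] = qvals
    df["flag"] = df["q"] <= q_cut
    return df.sort_values(["q", "p", "set"], kind="stable").reset_index(drop=True)


def enrich_module(
    genes,
    coll: GeneSetCollection,
    universe,
    module_id: str = "module",
    max_set_size: int = DEFAULT_MAX_SET_SIZE,
    q_cut: float = DEFAULT_Q_CUT,
) -> pd.DataFrame:
    """Test one module against every (size-filtered) set in a collection.

    The universe is normally the tensor's gene list (the discovery universe).
    Module genes outside the universe are dropped with a warning.  Returns a
    tidy frame with per-set overlap, raw p, BH q, and the homogeneity flag.
    """
    universe = frozenset(universe)
    module = frozenset(genes)
    outside = module - universe
    if outside:
        warnings.warn(f"{len(outside)} module genes outside the universe were dropped")
        module = module & universe
    coll_f = coll.filtered(max_set_size)
    if not coll_f.sets:
        warnings.warn("no gene sets left after the size filter")
        return _bh_frame([], q_cut).assign(module=module_id)[RESULT_COLUMNS]
    rows = []
    n, N = len(module), len(universe)
    for name, s in sorted(coll_f.sets.items()):
        s_in = s & universe
        if not s_in:
            continue
        k = len(module & s_in)
        rows.append((module_id, name, k, hypergeom_tail(k, n, len(s_in), N)))
    return _bh_frame(rows, q_cut)[RESULT_COLUMNS]


def phenotype_enrichment(
    rhs_networks,
    labels: pd.DataFrame,
    network_universe,
    module_id: str = "module",
    q_cut: float = DEFAULT_Q_CUT,
) -> pd.DataFrame:
    """Label enrichment of the networks a pattern recurs in.

    ``labels`` has columns (network_id, label); multi-label networks are
    allowed (one row per label), including precomputed ancestor labels.
    Each label is tested hypergeometrically over the network universe, with
    BH correction across labels.
    """
    if list(labels.columns[:2]) != ["network_id", "label"]:
        labels = labels.rename(
            columns={labels.columns[0]: "network_id", labels.columns[1]: "label"}
        )
    universe = list(dict.fromkeys(network_universe))
    uset = frozenset(universe)
    member = frozenset(rhs_networks)
    unknown = member - uset
    if unknown:
        raise ValueError(f"unknown network ids: {sorted(unknown)}")
    labels = labels[labels["network_id"].isin(uset)]
    rows = []
    n, N = len(member), len(uset)
    for label, grp in labels.groupby("label", sort=True):
        carriers = frozenset(grp["network_id"])
        k = len(member & carriers)
        rows.append((module_id, label, k, hypergeom_tail(k, n, len(carriers), N)))
    return _bh_frame(rows, q_cut)[RESULT_COLUMNS]


def random_modules(size_distribution, universe, n_draws: int, seed: int = 0) -> list:
    """Draw random modules matching an observed size distribution.

    Used as the background ensemble for enrichment-rate comparisons: gene
    sets sampled uniformly without replacement, with sizes resampled from
    ``size_distribution``.
    """
    universe = list(universe)
    sizes = np.asarray(list(size_distribution), dtype=int)
    if len(sizes) == 0 and n_draws > 0:
        raise ValueError("empty size distribution")
    if (sizes < 2).any():
        raise ValueError("module sizes must be >= 2")
    if sizes.size and sizes.max() > len(universe):
        raise ValueError("module size exceeds universe size")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_draws):
        size = int(rng.choice(sizes))
        out.append(frozenset(rng.choice(len(universe), size=size, replace=False).tolist()))
    return [frozenset(universe[i] for i in m) for m in out]
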