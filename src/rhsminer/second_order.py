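"""Module activity profiles and second-order (cooperativity) analysis.

A module's first-order activity in one dataset is the heaviness of its gene
set in that network: the mean co-expression weight over all gene pairs.  The
vector of heaviness values across all D datasets is the module's activity
profile.  The Pearson correlation between two profiles — the second-order
correlation — quantifies how coordinately the two modules switch on and off
across conditions; thresholding it yields a cooperativity network over
modules.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .tensor_model import NetworkTensor, block_weight_sums

__all__ = [
    "ActivityProfile",
    "activity_profile",
    "second_order_corr",
    "cooperativity_network",
    "write_profiles",
    "write_cooperativity",
]

logger = logging.getLogger(__name__)

#: profiles with variance below this are excluded from cooperativity analysis
VARIANCE_FLOOR = 1e-12


class ActivityProfile:
    """Modules x datasets matrix of heaviness values.

    Column order equals the tensor's network order; entries are >= 0.
    """

    def __init__(self, module_ids, network_ids, values):
        self.module_ids = list(module_ids)
        self.network_ids = list(network_ids)
        self.values = np.asarray(values, dtype=float)
        if self.values.shape != (len(self.module_ids), len(self.network_ids)):
            raise ValueError("profile shape does not match ids")
        if (self.values < 0).any():
            raise ValueError("heaviness values must be non-negative")

    def row(self, module_id) -> np.ndarray:
        return self.values[self.module_ids.index(module_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.module_ids, columns=self.network_ids)


def activity_profile(t: NetworkTensor, modules) -> ActivityProfile:
    """Heaviness of each module's gene set in every network of the tensor.

    ``modules`` maps module id -> gene set.  Every entry spans all D networks
    (not only those where the module was called), so profiles of different
    modules are directly comparable.
    """
    if isinstance(modules, (list, tuple)):
        modules = {f"module_{i}": m for i, m in enumerate(modules)}
    rows, ids = [], []
    for mid, genes in modules.items():
        gset = set(genes)
        gi = t.gene_index(gset)
        if len(gi) < 2:
            raise ValueError(f"module {mid!r} has fewer than 2 resolvable genes")
        slots = len(gi) * (len(gi) - 1) / 2.0
        rows.append(block_weight_sums(t, gset) / slots)
        ids.append(mid)
    return ActivityProfile(ids, list(t.network_ids), np.vstack(rows))


def second_order_corr(a, b) -> float:
    """Pearson correlation between two activity profiles (length D >= 3)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("profiles must be 1-D, equal length >= 3")
    if a.var() <= VARIANCE_FLOOR or b.var() <= VARIANCE_FLOOR:
        raise ValueError("zero-variance profile: second-order correlation undefined")
    return float(np.clip(np.corrcoef(a, b)[0, 1], -1.0, 1.0))


def cooperativity_network(profiles: ActivityProfile, threshold: float = 0.7) -> nx.Graph:
    """Graph of modules linked by super-threshold second-order correlation.

    Nodes are modules with at least one partner whose correlation exceeds the
    threshold; edge weights are the correlations.  Near-constant profiles are
    excluded (their correlation is undefined) with a logged warning.
    """
    if len(profiles.module_ids) < 2:
        raise ValueError("need at least 2 modules")
    usable = []
    for mid in profiles.module_ids:
        if profiles.row(mid).var() <= VARIANCE_FLOOR:
            logger.warning("module %s has a near-constant activity profile; excluded", mid)
        else:
            usable.append(mid)
    g = nx.Graph()
    for i, mi in enumerate(usable):
        for mj in usable[i + 1:]:
            r = second_order_corr(profiles.row(mi), profiles.row(mj))
            if r > threshold:
                g.add_edge(mi, mj, weight=r)
    return g


def write_profiles(profiles: ActivityProfile, path: str):
    """Module x dataset heaviness table as TSV."""
    profiles.to_frame().to_csv(path, sep="\t", index_label="module")


def write_cooperativity(g: nx.Graph, edge_path: str, graphml_path: str | None = None):
    """Edge-list TSV (module_a, module_b, correlation) and optional GraphML."""
    with open(edge_path, "w") as fh:
        for u, v, data in sorted(g.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data['weight']:.6g}\n")
    if graphml_path is not None:
        nx.write_graphml(g, graphml_path)
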