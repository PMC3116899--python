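"""From membership vectors to discrete patterns: towers, families, mining loop.

A solved membership pair ranks genes and networks; prefixes of those rankings
define candidate blocks ("the heaviest pattern occupies a corner of the
reordered tensor").  For each gene-prefix size the largest network-prefix
size whose block heaviness clears the threshold is recorded; the Pareto
frontier of those candidates is the nested "tower" of patterns — more genes,
fewer networks — called an RHS family.  Its two extremes (fewest genes /
most networks, and most genes / fewest networks) are the representatives.
Mining iterates: solve, extract, mask the representatives' edges, repeat.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .mscr import MSCRConfig, NormConfig, solve
from .tensor_model import RHS, MembershipPair, NetworkTensor, mask_rhs

__all__ = [
    "RHSFilter",
    "RHSFamily",
    "extract_family",
    "representatives",
    "mine_all",
    "binarize",
    "write_families_jsonl",
    "write_gmt",
]


@dataclass
class RHSFilter:
    """Pattern filter: minimum gene count, recurrence, heaviness threshold,
    and a cap on the gene-prefix scan."""

    min_genes: int = 5
    min_networks: int = 5
    min_heaviness: float = 0.4
    max_genes: int = 100

    def __post_init__(self):
        if self.min_genes < 2:
            raise ValueError("min_genes must be >= 2")
        if self.min_heaviness <= 0:
            raise ValueError("min_heaviness must be positive")
        if self.min_networks < 1:
            raise ValueError("min_networks must be >= 1")


@dataclass
class RHSFamily:
    """The nested tower of patterns from one membership pair.

    ``tower`` is ordered by increasing gene count (hence non-increasing
    network count); ``provenance`` records solver metadata.
    """

    tower: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        genes_prev, nets_prev = None, None
        for r in self.tower:
            if genes_prev is not None:
                if not genes_prev < r.genes:
                    raise ValueError("tower gene sets must be strictly nested increasing")
                if not r.networks < nets_prev:
                    raise ValueError("tower network sets must be strictly nested decreasing")
            genes_prev, nets_prev = r.genes, r.networks

    def __len__(self):
        return len(self.tower)

    @property
    def representatives(self):
        return representatives(self)


def _ranked(values: np.ndarray, ids: list) -> list:
    """Indices sorted by membership value, descending; ties broken by index
    order (stable)."""
    order = np.argsort(-np.asarray(values), kind="stable")
    return [int(i) for i in order]


def extract_family(t: NetworkTensor, m: MembershipPair, f: RHSFilter | None = None) -> RHSFamily:
    """Extract the tower of patterns from one membership pair.

    For each gene-prefix size ``n_g`` from ``min_genes`` to ``max_genes``,
    finds the largest network-prefix size ``n_d >= min_networks`` whose block
    heaviness is at least the threshold, then prunes dominated candidates
    (another candidate with at least as many genes and networks) down to the
    maximal tower.  May be empty.
    """
    f = f or RHSFilter()
    n, D = t.n_genes, t.n_networks
    gene_order = _ranked(m.g, t.gene_ids)
    net_order = _ranked(m.d, t.network_ids)
    max_g = min(f.max_genes, n)

    # cumulative within-prefix block weight per network, built incrementally:
    # adding the r-th ranked gene contributes its edges to the first r-1.
    in_prefix = np.zeros(n, dtype=bool)
    block_sum = np.zeros((max_g + 1, D))
    syms = [t.symmetric(k) for k in range(D)]
    for r, gi in enumerate(gene_order[:max_g], start=1):
        if r > 1:
            for k in range(D):
                row = syms[k].getrow(gi)
                if row.nnz:
                    block_sum[r, k] = block_sum[r - 1, k] + row.toarray().ravel()[in_prefix].sum()
                else:
                    block_sum[r, k] = block_sum[r - 1, k]
        in_prefix[gi] = True

    candidates = []  # (n_g, n_d)
    net_order_arr = np.asarray(net_order)
    for n_g in range(f.min_genes, max_g + 1):
        slots_per_net = n_g * (n_g - 1) / 2.0
        cum = np.cumsum(block_sum[n_g, net_order_arr])
        n_d_range = np.arange(1, D + 1)
        heavy = cum / (n_d_range * slots_per_net)
        ok = np.flatnonzero(heavy >= f.min_heaviness)
        ok = ok[ok + 1 >= f.min_networks]
        if ok.size:
            candidates.append((n_g, int(ok[-1]) + 1))

    # Pareto prune to the maximal tower: scan from most genes down, keep a
    # candidate only if it recurs in strictly more networks than all kept ones.
    kept = []
    best_nd = 0
    for n_g, n_d in reversed(candidates):
        if n_d > best_nd:
            kept.append((n_g, n_d))
            best_nd = n_d
    kept.reverse()

    tower = []
    for n_g, n_d in kept:
        genes = frozenset(t.gene_ids[i] for i in gene_order[:n_g])
        nets = frozenset(t.network_ids[k] for k in net_order[:n_d])
        h = float(block_sum[n_g, net_order_arr[:n_d]].sum() / (n_d * n_g * (n_g - 1) / 2.0))
        tower.append(RHS(genes=genes, networks=nets, heaviness=h))
    return RHSFamily(tower=tower)


def representatives(fam: RHSFamily) -> list:
    """The family's extreme patterns: fewest genes (maximal recurrence) and
    fewest networks (maximal gene count).  A singleton family represents
    itself; identical extremes collapse to one."""
    if not fam.tower:
        raise ValueError("empty family has no representatives")
    first, last = fam.tower[0], fam.tower[-1]
    return [first] if first is last else [first, last]


def _jaccard(a: frozenset, b: frozenset) -> float:
    return len(a & b) / len(a | b) if (a or b) else 1.0


def mine_all(
    t: NetworkTensor,
    nc: NormConfig | None = None,
    cfg: MSCRConfig | None = None,
    f: RHSFilter | None = None,
    max_patterns: int = 1000,
    max_empty_runs: int = 3,
    jaccard_merge: float = 0.8,
) -> list:
    """Iteratively mine families: solve, extract, mask representatives, repeat.

    Stops after ``max_patterns`` families or ``max_empty_runs`` consecutive
    empty extractions.  A new representative whose gene set has Jaccard
    similarity >= ``jaccard_merge`` with an earlier one recurring in
    essentially the same networks is treated as a rediscovery and merged
    (not reported again); its edges are still masked so mining progresses.
    """
    nc = nc or NormConfig()
    cfg = cfg or MSCRConfig()
    f = f or RHSFilter()
    work = t.copy()
    families = []
    seen_reps = []
    empty_run = 0
    round_no = 0
    while len(families) < max_patterns:
        if work.total_weight() <= 0.0:
            break
        pair, state = solve(work, nc, cfg)
        fam = extract_family(work, pair, f)
        round_no += 1
        if not fam.tower:
            empty_run += 1
            if empty_run >= max_empty_runs:
                break
            continue
        empty_run = 0
        reps = representatives(fam)
        novel = all(
            not (
                _jaccard(rep.genes, old.genes) >= jaccard_merge
                and _jaccard(rep.networks, old.networks) >= jaccard_merge
            )
            for rep in reps
            for old in seen_reps
        )
        if novel:
            fam.provenance = {
                "round": round_no,
                "seed": cfg.seed,
                "init": cfg.init,
                "n_stages": state.n_stages,
                "objective_trace": [float(v) for v in state.objective_trace],
                "converged": state.converged,
            }
            families.append(fam)
        seen_reps.extend(reps)
        for rep in reps:
            work = mask_rhs(work, rep, inplace=True)
    return families


def binarize(t: NetworkTensor, cutoff: float) -> NetworkTensor:
    """Dichotomize a weighted tensor: weights >= cutoff become 1, others 0.

    Enables weighted-versus-unweighted comparison experiments; idempotent for
    cutoff <= 1.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    slices = []
    for k in range(t.n_networks):
        a = t.slices[k].copy()
        a.data = (a.data >= cutoff).astype(float)
        a.eliminate_zeros()
        slices.append(a)
    return NetworkTensor(list(t.gene_ids), list(t.network_ids), slices)


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def _rhs_dict(r: RHS) -> dict:
    return {
        "genes": sorted(r.genes),
        "networks": sorted(r.networks),
        "heaviness": r.heaviness,
    }


def write_families_jsonl(families, path: str):
    """One JSON object per line: family id, tower, representatives, provenance."""
    with open(path, "w") as fh:
        for i, fam in enumerate(families):
            rec = {
                "family_id": i,
                "rhs": [_rhs_dict(r) for r in fam.tower],
                "representatives": [_rhs_dict(r) for r in representatives(fam)],
                "provenance": fam.provenance,
            }
            fh.write(json.dumps(rec) + "\n")


def write_gmt(families, path: str, prefix: str = "RHS"):
    """Export representative gene sets in GMT format (name, description, genes)."""
    with open(path, "w") as fh:
        for i, fam in enumerate(families):
            for j, rep in enumerate(representatives(fam)):
                name = f"{prefix}_{i}_{j}"
                desc = f"recurs_in_{len(rep.networks)}_networks_heaviness_{rep.heaviness:.3f}"
                fh.write("\t".join([name, desc] + sorted(rep.genes)) + "\n")
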