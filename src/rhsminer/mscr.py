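"""Multi-stage convex relaxation (MSCR) solver for heavy-subtensor discovery.

The discrete problem — pick a gene set and a network set whose induced block
has maximal total edge weight — is relaxed to continuous non-negative
membership vectors g (genes) and d (networks) maximising

    H(g, d) = sum_k d_k * sum_{i<j} w(i,j,k) g_i g_j

subject to mixed-norm constraints.  The gene norm combines a sparsity
exponent p < 1 (few nonzero entries) with a uniformity exponent s >= 2
(similar nonzero entries); the network norm is an l_q norm with large q,
approximating l_inf so that as many networks as possible participate.

The non-convex sparse constraint sum_i g_i^p is handled by concave duality:
each stage replaces it with the weighted quadratic surrogate
sum_i lambda_i g_i^2 (its tangent majorant at the current iterate), solves the
resulting convex-constrained problem by alternating closed-form updates

    g-step: leading generalized eigenvector of  M(d) g = rho * Lambda g,
            M(d) = sum_k d_k A_k, by power iteration (non-negativity is
            automatic: M is entrywise non-negative, the start is positive)
    d-step: d_k ∝ c_k^{1/(q-1)}, c_k = g' U_k g, normalized to unit l_q

and then refreshes the dual coefficients in closed form,
lambda_i = (p/2) g_i^{p-2}.  Each stage tightens the relaxation; the
normalized objective H(g/||g||_p, d/||d||_q) is non-decreasing across stages
(a majorize-minimize ascent).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .tensor_model import MembershipPair, NetworkTensor

__all__ = [
    "NormConfig",
    "MSCRConfig",
    "MSCRState",
    "gene_norm",
    "network_norm",
    "update_network_vector",
    "update_gene_vector",
    "update_duals",
    "edge_seeds",
    "solve",
    "load_config",
]

logger = logging.getLogger(__name__)

#: switch to dense slice stacking below this many tensor entries (N*N*D)
_DENSE_ENTRY_BOUND = 5e7


@dataclass
class NormConfig:
    """Mixed-norm exponents: p in (0,1) sparsifies genes, s >= 2 smooths the
    nonzero gene block, q >= 2 controls how evenly network memberships spread
    (large q approximates l_inf / uniform spread; q = 2 concentrates d on the
    networks where the gene block is actually heavy, which sharpens gene
    discrimination when many background networks are present).  Defaults
    calibrated on planted-block recovery simulations."""

    p: float = 0.99
    s: float = 2.0
    q: float = 2.0

    def __post_init__(self):
        if not 0 < self.p <= 2:
            # p < 1 gives the sparse regime; p = 2 degenerates to a single
            # convex stage and is allowed for comparison runs
            raise ValueError("p must be in (0, 2]")
        if self.s < 2:
            raise ValueError("s must be >= 2")
        if self.q < 2:
            raise ValueError("q must be >= 2")


@dataclass
class MSCRConfig:
    """Solver controls.

    Norm constraints are enforced as unit-norm projections each step (the
    Lagrange multipliers alpha_g / beta_d are absorbed into the
    normalization — same stationary points, simpler contract).
    """

    alpha_g: float = 1.0
    beta_d: float = 1.0
    inner_tol: float = 1e-6
    stage_tol: float = 1e-5
    max_inner: int = 500
    max_stages: int = 300
    init: str = "seeded"  # "seeded", "uniform" or "random"
    seed: int = 0
    n_restarts: int = 1
    n_seed_edges: int = 16
    seed_floor: float = 0.05
    lambda_floor: float = 1e-8

    def __post_init__(self):
        if self.alpha_g <= 0 or self.beta_d <= 0:
            raise ValueError("multipliers must be positive")
        if self.inner_tol <= 0 or self.stage_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.init not in ("seeded", "uniform", "random"):
            raise ValueError("init must be 'seeded', 'uniform' or 'random'")
        if self.n_seed_edges < 1:
            raise ValueError("n_seed_edges must be >= 1")
        if not 0 < self.seed_floor < 1:
            raise ValueError("seed_floor must be in (0, 1)")


@dataclass
class MSCRState:
    """Trace of one solve: final memberships, duals, and per-stage objectives."""

    membership: MembershipPair
    duals: np.ndarray
    n_stages: int
    objective_trace: list = field(default_factory=list)
    inner_iterations: list = field(default_factory=list)
    converged: bool = False
    restart_seed: int | None = None


# ---------------------------------------------------------------------------
# Norms and closed-form updates
# ---------------------------------------------------------------------------

def gene_norm(g, nc: NormConfig) -> float:
    """Mixed gene norm (sum_i (g_i^s)^(p/s))^(1/p) = (sum_i g_i^p)^(1/p).

    Degree-1 homogeneous; reduces to the Euclidean norm at p = s = 2.
    """
    g = np.asarray(g, dtype=float)
    if (g < 0).any():
        raise ValueError("gene memberships must be non-negative")
    return float(np.power(np.power(g, nc.p).sum(), 1.0 / nc.p))


def network_norm(d, nc: NormConfig) -> float:
    """l_q norm of the network membership vector."""
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("network memberships must be non-negative")
    return float(np.power(np.power(d, nc.q).sum(), 1.0 / nc.q))


class _TensorOps:
    """Cached linear-algebra kernels over one tensor.

    Provides M(d) = sum_k d_k A_k (symmetric) and c(g) with
    c_k = sum_{i<j} w(i,j,k) g_i g_j.  Uses a stacked dense array when the
    tensor is small enough, sparse matvecs otherwise — either way each stored
    edge is touched a constant number of times per operation.
    """

    def __init__(self, t: NetworkTensor):
        self.t = t
        n, D = t.n_genes, t.n_networks
        self.dense = n * n * D <= _DENSE_ENTRY_BOUND
        if self.dense:
            self.W = np.stack([t.symmetric(k).toarray() for k in range(D)])
            # flat (D, n*n) view of the same buffer: turns M(d) and c(g) into
            # single BLAS products with no per-call reshapes or copies
            self.W_flat = self.W.reshape(D, n * n)
        else:
            self.syms = [t.symmetric(k) for k in range(D)]
            self.uppers = t.slices

    def M(self, d: np.ndarray):
        if self.dense:
            n = self.t.n_genes
            return (d @ self.W_flat).reshape(n, n)
        m = None
        for k, dk in enumerate(d):
            if dk == 0.0:
                continue
            m = dk * self.syms[k] if m is None else m + dk * self.syms[k]
        if m is None:
            m = 0.0 * self.syms[0]
        return m

    def c(self, g: np.ndarray) -> np.ndarray:
        if self.dense:
            return 0.5 * ((self.W @ g) @ g)
        return np.array([float(g @ u.dot(g)) for u in self.uppers])


def update_network_vector(t, g, nc: NormConfig) -> np.ndarray:
    """Closed-form d-step: argmax of c . d over the unit l_q sphere, d >= 0.

    ``t`` may be a NetworkTensor or a precomputed per-network score vector c.
    The maximizer of a linear objective on the l_q ball is d_k ∝ c_k^{1/(q-1)};
    an all-zero score vector yields the uniform feasible point.
    """
    if isinstance(t, NetworkTensor):
        g = np.asarray(g, dtype=float)
        c = _TensorOps(t).c(g)
    else:
        c = np.asarray(t, dtype=float)
    if c.max() <= 0.0:
        D = c.size
        return np.full(D, D ** (-1.0 / nc.q))
    d = np.power(c / c.max(), 1.0 / (nc.q - 1.0))
    return d / np.power(np.power(d, nc.q).sum(), 1.0 / nc.q)


def update_gene_vector(
    t,
    d: np.ndarray,
    lam: np.ndarray,
    cfg: MSCRConfig,
    g0: np.ndarray | None = None,
) -> np.ndarray:
    """g-step: leading generalized eigenvector of M(d) g = rho Lambda g.

    Power-type iteration g <- Lambda^{-1} M(d) g with renormalization to
    sum_i lambda_i g_i^2 = 1; converged when the relative vector change drops
    below ``cfg.inner_tol``.  ``t`` may be a NetworkTensor or a _TensorOps.
    """
    ops = t if isinstance(t, _TensorOps) else _TensorOps(t)
    lam = np.asarray(lam, dtype=float)
    n = ops.t.n_genes
    m = ops.M(np.asarray(d, dtype=float))
    norm_c = lambda v: v / np.sqrt(float(lam @ (v * v)))
    g = norm_c(np.ones(n) if g0 is None else np.asarray(g0, dtype=float))
    mg = m @ g
    if not np.any(mg > 0):
        warnings.warn("M(d) has no signal; returning uniform feasible g")
        return norm_c(np.ones(n))
    for _ in range(cfg.max_inner):
        g_new = norm_c(mg / lam)
        delta = np.abs(g_new - g).max() / max(np.abs(g).max(), 1e-300)
        g = g_new
        mg = m @ g
        if delta < cfg.inner_tol:
            break
    return g


def update_duals(g: np.ndarray, nc: NormConfig, cfg: MSCRConfig) -> np.ndarray:
    """Closed-form dual refresh lambda_i = (p/2) g_i^(p-2), clamped.

    This is the derivative of the concave surrogate u -> u^{p/2} at u = g_i^2:
    the tangent point that makes the weighted quadratic majorant tight at g.
    Larger memberships get smaller penalties (monotone reweighting); zeros are
    absorbed by the upper clamp 1/lambda_floor.
    """
    g = np.asarray(g, dtype=float)
    if (g < 0).any():
        raise ValueError("gene memberships must be non-negative")
    hi = 1.0 / cfg.lambda_floor
    with np.errstate(divide="ignore"):
        lam = 0.5 * nc.p * np.power(g, nc.p - 2.0)
    lam = np.where(np.isfinite(lam), lam, hi)
    return np.clip(lam, cfg.lambda_floor, hi)


# ---------------------------------------------------------------------------
# The full solver
# ---------------------------------------------------------------------------

#: edges screened by the probe score before seed selection
_SEED_POOL = 512
#: probe-block size used to score seed candidates
_PROBE_GENES = 8


def edge_seeds(t: NetworkTensor, n_seeds: int, floor: float) -> list[np.ndarray]:
    """Initialization candidates anchored on the strongest recurrent edges.

    Edges are ranked by the squared-weight recurrence score
    B(i, j) = sum_k w(i,j,k)^2 (squaring favors edges that are heavy in some
    networks over edges that are mediocre everywhere).  A single extreme
    background edge can outrank a true recurrent-block edge, so the top
    ``_SEED_POOL`` edges are re-screened.  Each candidate edge (i, j) implies
    a probe gene set: genes are profiled by their recurrence with the two
    endpoints, with every network's contribution weighted by the candidate
    edge's own squared weight in that network — so the profile is measured on
    the networks where the edge is actually heavy instead of being diluted by
    the rest of the stack — and the top ``_PROBE_GENES`` genes by
    min(profile_i, profile_j) plus the endpoints form the probe.  The
    candidate is scored by the mean recurrence score inside the probe block —
    high only when the candidate sits in a coherent recurrent module, not
    merely on one lucky edge.  The ``n_seeds`` best-scoring candidates
    (deduplicated by
    probe overlap) become starts with g0[i] = g0[j] = 1 and all other genes at
    ``floor`` (above the absorbing zero state of the sparse surrogate).  A
    start deliberately carries no graded profile: grading by recurrence score
    would pre-weight lucky background genes into the basin, whereas a pure
    two-endpoint start lets the objective decide the support.
    """
    per_net = []
    B = None
    for k in range(t.n_networks):
        a = t.symmetric(k)
        sq = a.multiply(a).tocsc()
        per_net.append(sq)
        B = sq if B is None else B + sq
    B = B.tocsc()
    upper = sp.triu(B, k=1).tocoo()
    if upper.nnz == 0:
        raise ValueError("no signal: tensor has no positive weight")
    order = np.argsort(-upper.data, kind="stable")[: max(n_seeds, _SEED_POOL)]
    m = min(_PROBE_GENES, t.n_genes)
    stack = None
    if t.n_networks * t.n_genes * t.n_genes <= _DENSE_ENTRY_BOUND:
        stack = np.stack([np.asarray(sq.todense()) for sq in per_net])
    cands = []
    for idx in order:
        i, j = int(upper.row[idx]), int(upper.col[idx])
        if stack is not None:
            wk = stack[:, i, j]
            prof_i = np.einsum("k,kn->n", wk, stack[:, :, i])
            prof_j = np.einsum("k,kn->n", wk, stack[:, :, j])
        else:
            prof_i = np.zeros(t.n_genes)
            prof_j = np.zeros(t.n_genes)
            for sq in per_net:
                wk = sq[i, j]
                if wk > 0.0:
                    prof_i += wk * np.asarray(sq[:, i].todense()).ravel()
                    prof_j += wk * np.asarray(sq[:, j].todense()).ravel()
        prof = np.minimum(prof_i, prof_j)
        prof[i] = prof[j] = np.inf
        probe = np.argsort(-prof, kind="stable")[:m]
        sub = np.asarray(B[np.ix_(probe, probe)].todense())
        n_pairs = max(1, m * (m - 1))
        score = float((sub.sum() - np.trace(sub)) / n_pairs)
        g0 = np.full(t.n_genes, floor)
        g0[i] = g0[j] = 1.0
        cands.append((score, frozenset(probe.tolist()), g0))
    cands.sort(key=lambda c: -c[0])
    out, probes, skipped = [], [], []
    for score, probe, g0 in cands:
        if len(out) >= n_seeds:
            break
        if any(len(probe & prev) > len(probe) // 2 for prev in probes):
            skipped.append(g0)
            continue
        out.append(g0)
        probes.append(probe)
    out.extend(skipped[: n_seeds - len(out)])
    return out


def solve(t: NetworkTensor, nc: NormConfig | None = None,
          cfg: MSCRConfig | None = None) -> tuple[MembershipPair, MSCRState]:
    """Run MSCR on a tensor; returns the best membership pair and its trace.

    Deterministic under fixed config.  The default ``init='seeded'`` runs an
    ensemble of starts — one uniform start plus ``cfg.n_seed_edges``
    edge-anchored starts from :func:`edge_seeds`, each with its dual vector
    evaluated at the start (so the sparse surrogate, not only the first
    eigenproblem, sees the initialization) — and keeps the run with the best
    normalized objective.  ``init='uniform'``/``'random'`` run single-start;
    ``cfg.n_restarts > 1`` appends extra random positive starts in any mode.
    """
    nc = nc or NormConfig()
    cfg = cfg or MSCRConfig()
    if t.total_weight() <= 0.0:
        raise ValueError("no signal: tensor has no positive weight")
    ops = _TensorOps(t)
    rng = np.random.default_rng(cfg.seed)
    starts: list[tuple[np.ndarray, np.ndarray | None]] = []
    if cfg.init == "seeded":
        starts.append((np.ones(t.n_genes), None))
        for g0 in edge_seeds(t, cfg.n_seed_edges, cfg.seed_floor):
            lam0 = update_duals(g0 / gene_norm(g0, nc), nc, cfg)
            starts.append((g0, lam0))
    elif cfg.init == "uniform":
        starts.append((np.ones(t.n_genes), None))
    else:
        starts.append((0.5 + rng.random(t.n_genes), None))
    for _ in range(max(1, cfg.n_restarts) - 1):
        starts.append((0.5 + rng.random(t.n_genes), None))
    best = None
    for g0, lam0 in starts:
        state = _solve_once(ops, nc, cfg, g0, lam0)
        state.restart_seed = cfg.seed
        if best is None or state.objective_trace[-1] > best.objective_trace[-1]:
            best = state
    return best.membership, best


def _solve_once(ops: _TensorOps, nc: NormConfig, cfg: MSCRConfig,
                g0: np.ndarray, lam0: np.ndarray | None = None) -> MSCRState:
    t = ops.t
    g = np.asarray(g0, dtype=float)
    g = g / gene_norm(g, nc)
    # default first stage: convex relaxation (p = 2 surrogate); a seeded start
    # passes duals evaluated at g0 instead, which is what lets the start
    # survive the first generalized eigenproblem
    lam = np.ones(t.n_genes) if lam0 is None else np.asarray(lam0, dtype=float)
    d = np.full(t.n_networks, t.n_networks ** (-1.0 / nc.q))
    trace, inner_counts = [], []
    converged = False
    for stage in range(cfg.max_stages):
        prev_h = None
        n_inner = 0
        for _ in range(cfg.max_inner):
            g = update_gene_vector(ops, d, lam, cfg, g0=g)
            c = ops.c(g)
            d = update_network_vector(c, None, nc)
            h = float(c @ d)
            n_inner += 1
            if prev_h is not None and abs(h - prev_h) <= cfg.inner_tol * max(abs(prev_h), 1e-300):
                break
            prev_h = h
        obj = h / gene_norm(g, nc) ** 2
        trace.append(obj)
        inner_counts.append(n_inner)
        logger.debug("stage %d: objective %.10g (%d inner iterations)", stage, obj, n_inner)
        if stage > 0 and abs(obj - trace[-2]) <= cfg.stage_tol * max(abs(trace[-2]), 1e-300):
            converged = True
            break
        # tighten the relaxation: renormalize to the true mixed-norm sphere,
        # refresh duals at the tangent point
        g = g / gene_norm(g, nc)
        lam = update_duals(g, nc, cfg)
    g_final = g / gene_norm(g, nc)
    pair = MembershipPair(g_final, d)
    return MSCRState(
        membership=pair,
        duals=lam,
        n_stages=len(trace),
        objective_trace=trace,
        inner_iterations=inner_counts,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# key = value config files
# ---------------------------------------------------------------------------

_NORM_KEYS = {"p", "s", "q"}
_INT_KEYS = {"max_inner", "max_stages", "seed", "n_restarts", "n_seed_edges"}


def load_config(path: str) -> tuple[NormConfig, MSCRConfig]:
    """Parse a ``key = value`` config file into (NormConfig, MSCRConfig).

    Unknown keys are rejected; '#' starts a comment.
    """
    norm_kwargs, cfg_kwargs = {}, {}
    valid = set(MSCRConfig.__dataclass_fields__)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key in _NORM_KEYS:
                norm_kwargs[key] = float(val)
            elif key in valid:
                if key == "init":
                    cfg_kwargs[key] = val
                elif key in _INT_KEYS:
                    cfg_kwargs[key] = int(val)
                else:
                    cfg_kwargs[key] = float(val)
            else:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
    return NormConfig(**norm_kwargs), MSCRConfig(**cfg_kwargs)
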