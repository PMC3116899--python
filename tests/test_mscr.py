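"""MSCR solver: norms, closed-form updates vs numeric oracles, monotonicity."""

import numpy as np
import pytest
from scipy.optimize import minimize

from rhsminer import (
    MembershipPair,
    MSCRConfig,
    NormConfig,
    gene_norm,
    network_norm,
    update_network_vector,
    update_gene_vector,
    update_duals,
    edge_seeds,
    solve,
)
from rhsminer.mscr import _TensorOps, load_config

from conftest import random_tensor, block_tensor


# -- norms -------------------------------------------------------------------

def test_gene_norm_one_hot():
    for p in (0.5, 0.8, 0.99):
        nc = NormConfig(p=p)
        g = np.zeros(5)
        g[2] = 1.0
        assert gene_norm(g, nc) == pytest.approx(1.0)


def test_gene_norm_two_equal_components():
    nc = NormConfig(p=0.8)
    g = np.array([0.0, 0.3, 0.3])
    assert gene_norm(g, nc) == pytest.approx(0.3 * 2 ** (1 / 0.8))


def test_gene_norm_euclidean_limit(rng):
    nc = NormConfig(p=2.0, s=2.0)
    for _ in range(5):
        g = rng.random(6)
        assert gene_norm(g, nc) == pytest.approx(float(np.linalg.norm(g)))


def test_gene_norm_homogeneous(rng):
    nc = NormConfig(p=0.7)
    g = rng.random(5)
    assert gene_norm(3.5 * g, nc) == pytest.approx(3.5 * gene_norm(g, nc))


def test_gene_norm_rejects_negative():
    with pytest.raises(ValueError):
        gene_norm(np.array([-0.1, 1.0]), NormConfig())


def test_network_norm_uniform():
    nc = NormConfig(q=5.0)
    d = np.full(7, 0.3)
    assert network_norm(d, nc) == pytest.approx(0.3 * 7 ** (1 / 5.0))


def test_network_norm_large_q_approaches_max(rng):
    nc = NormConfig(q=64.0)
    d = rng.random(10)
    assert network_norm(d, nc) == pytest.approx(float(d.max()), rel=0.01)


def test_network_norm_one_hot():
    d = np.zeros(4)
    d[1] = 1.0
    assert network_norm(d, NormConfig(q=3.0)) == pytest.approx(1.0)


def test_norm_config_validation():
    with pytest.raises(ValueError):
        NormConfig(p=0.0)
    with pytest.raises(ValueError):
        NormConfig(s=1.5)
    with pytest.raises(ValueError):
        NormConfig(q=1.0)


# -- update_network_vector ---------------------------------------------------

def _numeric_d_star(c, q):
    """Numeric oracle: maximize c.d on the unit l_q sphere, d >= 0."""
    D = len(c)

    def neg(d):
        return -float(np.dot(c, d))

    cons = {"type": "eq", "fun": lambda d: np.power(np.abs(d), q).sum() - 1.0}
    best = None
    for trial in range(3):
        x0 = np.full(D, D ** (-1.0 / q)) if trial == 0 else np.random.default_rng(trial).random(D)
        x0 = x0 / np.power(np.power(x0, q).sum(), 1.0 / q)
        res = minimize(neg, x0, bounds=[(0, None)] * D, constraints=[cons],
                       method="SLSQP", options={"maxiter": 500, "ftol": 1e-14})
        if best is None or res.fun < best.fun:
            best = res
    return best.x


def test_network_update_single_support():
    for q in (2.0, 10.0):
        d = update_network_vector(np.array([1.0, 0.0, 0.0]), None, NormConfig(q=q))
        assert np.allclose(d, [1.0, 0.0, 0.0])


def test_network_update_uniform_scores():
    d = update_network_vector(np.ones(4), None, NormConfig(q=10.0))
    assert np.allclose(d, 4 ** (-1 / 10.0))


def test_network_update_closed_form_two_scores():
    nc = NormConfig(q=10.0)
    d = update_network_vector(np.array([2.0, 1.0]), None, nc)
    expect = np.array([2 ** (1 / 9.0), 1.0])
    expect /= np.power(np.power(expect, 10).sum(), 0.1)
    assert np.allclose(d, expect, atol=1e-12)


def test_network_update_matches_numeric_optimizer(rng):
    for q in (2.0, 5.0, 10.0, 50.0):
        nc = NormConfig(q=q)
        for _ in range(3):
            c = rng.random(5) + 0.05
            d = update_network_vector(c, None, nc)
            d_star = _numeric_d_star(c, q)
            assert float(c @ d) >= float(c @ d_star) - 1e-6
            assert np.allclose(d, d_star, atol=1e-4)
            assert network_norm(d, nc) == pytest.approx(1.0, abs=1e-10)


def test_network_update_all_zero_scores_uniform():
    d = update_network_vector(np.zeros(6), None, NormConfig(q=4.0))
    assert np.allclose(d, 6 ** (-1 / 4.0))


def test_network_update_from_tensor(rng):
    t = random_tensor(6, 3, rng)
    g = rng.random(6)
    c = _TensorOps(t).c(g)
    assert np.allclose(
        update_network_vector(t, g, NormConfig()),
        update_network_vector(c, None, NormConfig()),
    )


# -- update_gene_vector ------------------------------------------------------

def _dense_generalized_leading(m, lam):
    """Dense oracle for the leading eigenvector of M g = rho * diag(lam) g."""
    half = np.diag(1.0 / np.sqrt(lam))
    sym = half @ m @ half
    w, v = np.linalg.eigh(sym)
    lead = v[:, -1]
    g = half @ lead
    if g.sum() < 0:
        g = -g
    return g / np.sqrt(float(lam @ (g * g)))


def test_gene_update_clique_uniform():
    t = block_tensor(5, 1, [0, 1, 2], [0], weight=1.0)
    g = update_gene_vector(t, np.array([1.0]), np.ones(5), MSCRConfig())
    assert g[0] == pytest.approx(g[1]) == pytest.approx(g[2])
    assert g[3] == pytest.approx(0.0, abs=1e-6)
    assert g[4] == pytest.approx(0.0, abs=1e-6)


def test_gene_update_matches_dense_eigensolver(rng):
    cfg = MSCRConfig(inner_tol=1e-12, max_inner=5000)
    for _ in range(5):
        n = int(rng.integers(3, 9))
        t = random_tensor(n, 2, rng)
        d = rng.random(2) + 0.1
        lam = rng.random(n) + 0.5
        g = update_gene_vector(t, d, lam, cfg)
        m = sum(d[k] * t.symmetric(k).toarray() for k in range(2))
        expected = _dense_generalized_leading(m, lam)
        assert np.allclose(g, expected, atol=1e-6)


def test_gene_update_scale_invariance(rng):
    t = random_tensor(6, 2, rng)
    d = np.array([0.4, 0.6])
    lam = np.ones(6)
    cfg = MSCRConfig(inner_tol=1e-12, max_inner=5000)
    g1 = update_gene_vector(t, d, lam, cfg)
    g2 = update_gene_vector(t, 2 * d, lam, cfg)
    assert np.allclose(g1, g2, atol=1e-9)


def test_gene_update_zero_matrix_warns_uniform():
    t = block_tensor(4, 2, [0, 1], [0], weight=1.0)
    with pytest.warns(UserWarning, match="no signal"):
        g = update_gene_vector(t, np.array([0.0, 1.0]), np.ones(4), MSCRConfig())
    assert np.allclose(g, g[0])


def test_gene_update_constraint_satisfied(rng):
    t = random_tensor(5, 2, rng)
    lam = rng.random(5) + 0.2
    g = update_gene_vector(t, np.array([1.0, 0.5]), lam, MSCRConfig())
    assert float(lam @ (g * g)) == pytest.approx(1.0, abs=1e-9)
    assert np.all(g >= 0)


# -- update_duals ------------------------------------------------------------

def test_duals_p2_all_ones():
    lam = update_duals(np.array([0.1, 0.5, 2.0]), NormConfig(p=2.0), MSCRConfig())
    assert np.allclose(lam, 1.0)


def test_duals_closed_form_value():
    lam = update_duals(np.array([0.5]), NormConfig(p=0.8), MSCRConfig())
    assert lam[0] == pytest.approx(0.4 * 0.5 ** (-1.2), abs=1e-4)
    assert lam[0] == pytest.approx(0.9190, abs=1e-4)


def test_duals_tangent_point_minimizes_surrogate():
    # numeric cross-check: lambda = argmin_l (l*u - phi*(l)) at u = g^2, where
    # the surrogate's value at the tangent point equals u^{p/2}
    p, g = 0.8, 0.5
    u = g * g
    lam_grid = np.linspace(0.1, 5.0, 20001)
    # concave conjugate: phi*(l) = min_u (l*u - u^{p/2}) attained at
    # u*(l) = (p / (2 l))^{2/(2-p)}
    ustar = np.power(p / (2 * lam_grid), 2 / (2 - p))
    phi_star = lam_grid * ustar - np.power(ustar, p / 2)
    vals = lam_grid * u - phi_star
    lam_best = lam_grid[np.argmin(vals)]
    lam = update_duals(np.array([g]), NormConfig(p=p), MSCRConfig())
    assert lam[0] == pytest.approx(lam_best, abs=2e-4)


def test_duals_zero_hits_upper_clamp():
    cfg = MSCRConfig()
    lam = update_duals(np.array([0.0, 1.0]), NormConfig(p=0.8), cfg)
    assert lam[0] == pytest.approx(1.0 / cfg.lambda_floor)
    assert np.isfinite(lam).all()


def test_duals_monotone_reweighting(rng):
    g = np.sort(rng.random(8)) + 0.01
    lam = update_duals(g, NormConfig(p=0.9), MSCRConfig())
    assert np.all(np.diff(lam) <= 0)
    assert np.all(lam > 0)


# -- solve -------------------------------------------------------------------

def test_solve_single_block_support():
    # single all-ones block -> g supported exactly on the block
    t = block_tensor(10, 4, [1, 4, 6, 8], [0, 2, 3], weight=1.0)
    pair, state = solve(t)
    on = t.gene_index(["g1", "g4", "g6", "g8"])
    off = [i for i in range(10) if i not in set(on.tolist())]
    assert np.all(pair.g[on] > 0.1)
    assert np.all(pair.g[off] < 1e-6)
    # d ranks block networks first
    top3 = set(np.argsort(-pair.d)[:3].tolist())
    assert top3 == {0, 2, 3}


def test_solve_trace_monotone(rng):
    for _ in range(5):
        t = random_tensor(12, 4, rng)
        _, state = solve(t, NormConfig(p=0.9), MSCRConfig(max_stages=40))
        trace = np.asarray(state.objective_trace)
        assert np.all(np.diff(trace) >= -1e-8)


def test_solve_deterministic():
    t = block_tensor(8, 3, [0, 1, 2], [0, 1], weight=0.9, background=0.1)
    p1, s1 = solve(t)
    p2, s2 = solve(t)
    assert np.array_equal(p1.g, p2.g)
    assert np.array_equal(p1.d, p2.d)
    assert s1.objective_trace == s2.objective_trace


def test_solve_equivariance_under_permutation(rng):
    t = random_tensor(7, 3, rng)
    perm = rng.permutation(7)
    slices = [t.symmetric(k).toarray()[np.ix_(perm, perm)] for k in range(3)]
    import scipy.sparse as sp

    t_perm = type(t)([t.gene_ids[i] for i in perm], list(t.network_ids),
                     [sp.csr_matrix(np.triu(a, 1)) for a in slices])
    cfg = MSCRConfig(init="uniform")
    p1, _ = solve(t, cfg=cfg)
    p2, _ = solve(t_perm, cfg=cfg)
    assert np.allclose(p2.g, p1.g[perm], atol=1e-6)


def test_solve_all_zero_tensor_errors():
    import scipy.sparse as sp

    t = type(block_tensor(3, 1, [0, 1], [0]))(
        ["a", "b", "c"], ["n"], [sp.csr_matrix((3, 3))]
    )
    with pytest.raises(ValueError, match="no signal"):
        solve(t)


def test_solve_p2_matches_power_iteration(rng):
    # p = s = q = 2 degenerates to plain tensor power iteration
    t = random_tensor(6, 3, rng)
    nc = NormConfig(p=2.0, s=2.0, q=2.0)
    pair, _ = solve(t, nc, MSCRConfig(init="uniform", inner_tol=1e-12, max_inner=5000))
    g = np.ones(6) / np.sqrt(6)
    d = np.ones(3) / np.sqrt(3)
    ops = _TensorOps(t)
    for _ in range(5000):
        m = ops.M(d)
        g_new = m @ g
        g_new /= np.linalg.norm(g_new)
        c = ops.c(g_new)
        d_new = c / np.linalg.norm(c)
        if np.abs(g_new - g).max() < 1e-13 and np.abs(d_new - d).max() < 1e-13:
            g, d = g_new, d_new
            break
        g, d = g_new, d_new
    assert np.allclose(pair.g, g, atol=1e-5)
    assert np.allclose(pair.d, d, atol=1e-5)


def test_solve_final_memberships_unit_norm(rng):
    t = random_tensor(9, 3, rng)
    nc = NormConfig()
    pair, _ = solve(t, nc)
    assert gene_norm(pair.g, nc) == pytest.approx(1.0, abs=1e-8)
    assert network_norm(pair.d, nc) == pytest.approx(1.0, abs=1e-8)


def test_edge_seeds_prefer_recurrent_block():
    t = block_tensor(20, 6, [2, 5, 9, 11], [0, 1, 2, 3], weight=0.9, background=0.2)
    seeds = edge_seeds(t, 4, 0.05)
    assert len(seeds) >= 1
    block = {2, 5, 9, 11}
    # each start is a pure two-endpoint vector; the best one sits in the block
    endpoints = set(np.where(seeds[0] == 1.0)[0].tolist())
    assert len(endpoints) == 2
    assert endpoints <= block
    assert np.all(seeds[0] >= 0.05)


def test_mscr_config_validation():
    with pytest.raises(ValueError):
        MSCRConfig(init="bogus")
    with pytest.raises(ValueError):
        MSCRConfig(inner_tol=0.0)
    with pytest.raises(ValueError):
        MSCRConfig(seed_floor=0.0)


# -- config files ------------------------------------------------------------

def test_load_config_round_trip(tmp_path):
    path = tmp_path / "cfg.txt"
    path.write_text(
        "p = 0.9\nq = 4\n# comment\nmax_stages = 25\ninit = uniform\nseed = 3\n"
    )
    nc, cfg = load_config(str(path))
    assert nc.p == 0.9 and nc.q == 4.0
    assert cfg.max_stages == 25 and cfg.init == "uniform" and cfg.seed == 3


def test_load_config_unknown_key(tmp_path):
    path = tmp_path / "cfg.txt"
    path.write_text("bogus = 1\n")
    with pytest.raises(ValueError, match="unknown key"):
        load_config(str(path))
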