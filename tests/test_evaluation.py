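"""Graph-level indices, structural summaries, GOF envelopes, Hamming CV."""

import numpy as np
import pytest

from ergmpool import (
    ConjugatePrior,
    FitConfig,
    Graph,
    GraphSet,
    ModelSpec,
    SamplerConfig,
    TermSpec,
    bernoulli_tau,
    expected_sq_hamming,
    free_dyads,
    gli_suite,
    gof_compare,
    hamming_distance,
    loo_cv_hamming,
    m_eccentricity,
    pooled_mle,
    simulate,
    statistics,
    structure_summaries,
)
from ergmpool.evaluation import loo_cv_hamming as _loo
from conftest import random_graph


def _graph(n, edges):
    A = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        A[i, j] = A[j, i] = 1
    return Graph(node_ids=[f"v{k}" for k in range(n)], adjacency=A)


def test_gli_complete_triangle():
    g = _graph(3, [(0, 1), (0, 2), (1, 2)])
    r = gli_suite(g)
    assert r.transitivity == 1.0
    assert r.sd_degree == 0.0
    assert r.sd_core_number == 0.0
    assert r.sd_m_eccentricity == 0.0


def test_gli_star():
    g = _graph(4, [(0, 1), (0, 2), (0, 3)])
    r = gli_suite(g)
    assert r.transitivity == 0.0
    assert r.sd_degree == pytest.approx(np.sqrt(0.75), abs=1e-12)  # degrees 3,1,1,1


def test_gli_path_hand_values():
    g = _graph(3, [(0, 1), (1, 2)])
    r = gli_suite(g)
    assert r.sd_core_number == 0.0  # all core number 1
    # M-eccentricities (1.5, 1, 1.5) -> population sd sqrt(1/18)
    assert r.sd_m_eccentricity == pytest.approx(np.sqrt(1 / 18), abs=1e-12)


def test_m_eccentricity_unreachable_convention():
    g = _graph(4, [(0, 1)])  # two isolated vertices
    me = m_eccentricity(g)
    # vertex 0: distances (1, 4, 4) / 3
    assert me[0] == pytest.approx(3.0)
    me2 = m_eccentricity(g, unreachable=10.0)
    assert me2[0] == pytest.approx(7.0)


def test_transitivity_identity_with_statistics():
    m = ModelSpec([TermSpec("twostars"), TermSpec("triangles")])
    for seed in range(4):
        g = random_graph(10, 0.4, seed=seed, with_attrs=False)
        s2, tri = statistics(m, g)
        r = gli_suite(g)
        if s2 > 0:
            assert r.transitivity == pytest.approx(3 * tri / s2)
        assert 0.0 <= r.transitivity <= 1.0


@pytest.mark.parametrize("seed", range(3))
def test_gli_against_brute_force(seed):
    """Core numbers by repeated minimum-degree deletion; geodesics by BFS."""
    g = random_graph(11, 0.3, seed=seed, with_attrs=False)
    n = g.n
    # brute-force k-core
    core = np.zeros(n, dtype=int)
    for k in range(1, n):
        A = g.adjacency.copy().astype(int)
        alive = np.ones(n, dtype=bool)
        changed = True
        while changed:
            deg = (A * alive).sum(axis=1) * alive
            kill = alive & (deg < k)
            changed = bool(kill.any())
            alive[kill] = False
            A[kill] = 0
            A[:, kill] = 0
        core[alive] = k
    # brute-force BFS mean distances
    me = np.zeros(n)
    for v in range(n):
        dist = np.full(n, n, dtype=float)  # unreachable -> n
        dist[v] = 0
        frontier = [v]
        d = 0
        seen = {v}
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for w in np.nonzero(g.adjacency[u])[0]:
                    if w not in seen:
                        seen.add(w)
                        dist[w] = d
                        nxt.append(w)
            frontier = nxt
        me[v] = np.delete(dist, v).mean()
    r = gli_suite(g)
    assert r.sd_core_number == pytest.approx(core.std())
    assert r.sd_m_eccentricity == pytest.approx(me.std())


def test_triad_census_and_esp():
    g = _graph(3, [(0, 1), (0, 2), (1, 2)])
    s = structure_summaries(g)
    assert list(s["triad_census"]) == [0, 0, 0, 1]
    k4 = _graph(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
    s4 = structure_summaries(k4)
    assert s4["esp"][2] == 6 and s4["esp"].sum() == 6  # all mass at 2
    for seed in range(3):
        g = random_graph(9, 0.35, seed=seed, with_attrs=False)
        s = structure_summaries(g)
        assert s["triad_census"].sum() == 9 * 8 * 7 // 6
        assert s["degree"].sum() == 9
        assert s["geodesic"].sum() == 9 * 8 // 2


def test_sq_hamming_point_mass_zero():
    g = random_graph(7, 0.4, seed=1, with_attrs=False)
    assert expected_sq_hamming(g, [g, g, g]) == 0.0


def test_expected_hamming_closed_form_edges_only():
    """Edges-only predictive: E[Hamming to held-out graph] has the closed
    form e(1-p) + (Nd-e)p; the simulated mean must match within MC error."""
    tmpl = _graph(6, [])
    m = ModelSpec([TermSpec("edges")])
    p_hat = 0.35
    theta = [np.log(p_hat / (1 - p_hat))]
    held = random_graph(6, 0.5, seed=2, with_attrs=False)
    e = held.n_edges
    Nd = 15
    expect = e * (1 - p_hat) + (Nd - e) * p_hat
    sim = simulate(m, theta, tmpl, SamplerConfig(n_draws=2000, seed=3),
                   return_graphs=True)
    dists = [hamming_distance(held, g) for g in sim.graphs]
    assert np.mean(dists) == pytest.approx(expect, abs=3 * np.std(dists) / np.sqrt(2000))


def test_gof_envelopes_self_consistency_and_misfit():
    tmpl = _graph(10, [])
    m = ModelSpec([TermSpec("edges")])
    theta = np.array([-1.0])
    gs = GraphSet(simulate(m, theta, tmpl, SamplerConfig(n_draws=20, seed=4),
                           return_graphs=True).graphs)
    ok = gof_compare(gs, m, theta, n_sim=150, seed=5)
    frac_out = ok["outside"].mean()
    assert frac_out < 0.2  # most bins inside their envelopes
    bad = gof_compare(gs, m, theta + 2.0, n_sim=150, seed=5)
    # edge-dominated bins must now fall outside: density badly wrong
    assert bad.loc["triad.empty", "outside"] or bad.loc["triad.one_edge", "outside"]


def test_loo_cv_prior_pull_and_boundary_rescue():
    m = ModelSpec([TermSpec("edges")])
    g = random_graph(7, 0.75, seed=6, with_attrs=False)
    gs = GraphSet([g] * 4)  # identical graphs: truth is the empirical rate
    tau_far = np.array([2.0])  # far below the observed ~15 edges
    cfg = FitConfig(seed=7, phase1_draws=50, subphase_count=2, subphase_draws=25,
                    phase3_draws=300, max_restarts=8)
    out = loo_cv_hamming(gs, m, tau_far, [0.0, 2.0, 8.0], n_sim=60, cfg=cfg, seed=8)
    tab = out.table
    assert tab["ok"].all()
    # a strongly wrong prior only hurts: error rises with n0
    assert tab.cv_error.iloc[-1] > tab.cv_error.iloc[0]
    assert out.selected_n0 == 0.0


def test_loo_cv_flags_boundary_rows():
    """A nodemix cell at 0 in every graph breaks the n0 = 0 fit; small-n0
    rows still succeed -- regularization is what makes CV possible."""
    tmpl = random_graph(8, 0.0, seed=9)
    tmpl.vertex_attrs["group"] = ["A"] * 4 + ["B"] * 4
    m = ModelSpec([TermSpec("edges"),
                   TermSpec("nodemix", attribute="group", reference_cell=("A", "A"))])
    graphs = []
    rng = np.random.default_rng(10)
    for s in range(3):
        A = np.zeros((8, 8), dtype=np.int8)
        for i, j in [(0, 1), (0, 2), (1, 3), (4, 5), (5, 6), (6, 7), (4, 6)]:
            if rng.random() < 0.85:
                A[i, j] = A[j, i] = 1
        graphs.append(tmpl.with_adjacency(A))
    gs = GraphSet(graphs)
    tau = bernoulli_tau(m, tmpl, mean_degree=2.0, n_draws=300, seed=11)
    cfg = FitConfig(seed=12, phase1_draws=50, subphase_count=2, subphase_draws=25,
                    phase3_draws=300, max_restarts=8)
    with pytest.warns(UserWarning, match="excluded"):
        out = loo_cv_hamming(gs, m, tau, [0.0, 0.2], n_sim=40, cfg=cfg, seed=13)
    tab = out.table.set_index("n0")
    assert not tab.loc[0.0, "ok"]
    assert tab.loc[0.2, "ok"]
    assert out.selected_n0 == 0.2
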