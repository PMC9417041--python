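"""Pooled MLE, conjugate MAP, Laplace posterior, posterior predictive."""

import numpy as np
import pytest

from ergmpool import (
    BoundaryTargetError,
    ConjugatePrior,
    FitConfig,
    Graph,
    GraphSet,
    ModelSpec,
    SamplerConfig,
    TermSpec,
    conjugate_map,
    laplace_posterior,
    pooled_mle,
    posterior_predictive,
    sample_posterior,
    simulate,
)
from conftest import random_graph


def _empty(n):
    return Graph(node_ids=[f"v{k}" for k in range(n)], adjacency=np.zeros((n, n), dtype=int))


def _edges_set(edge_counts, n=5, seed=0):
    """Graph set with prescribed edge counts on an n-node template."""
    rng = np.random.default_rng(seed)
    tmpl = _empty(n)
    iu = np.column_stack(np.triu_indices(n, k=1))
    graphs = []
    for e in edge_counts:
        pick = rng.choice(len(iu), size=e, replace=False)
        A = np.zeros((n, n), dtype=np.int8)
        for i, j in iu[pick]:
            A[i, j] = A[j, i] = 1
        graphs.append(tmpl.with_adjacency(A))
    return GraphSet(graphs)


EDGES = ModelSpec([TermSpec("edges")])


def test_pooled_mle_closed_form_and_m_scaling():
    """Graphs with 4 and 6 edges on Nd=10: theta-hat -> logit(0.5) = 0 and
    cov -> (1/m) / (Nd p (1-p)) = 0.2."""
    gs = _edges_set([4, 6])
    res = pooled_mle(gs, EDGES, FitConfig(seed=1, phase3_draws=2000))
    assert res.fit.converged
    assert res.theta[0] == pytest.approx(0.0, abs=0.1)
    assert res.cov[0, 0] == pytest.approx(0.2, rel=0.2)
    assert res.delta == 0.0
    # m = 1 gives the single-graph MLE with cov = I^-1
    single = GraphSet([gs[0]])
    res1 = pooled_mle(single, EDGES, FitConfig(seed=2, phase3_draws=2000))
    assert res1.theta[0] == pytest.approx(np.log(4 / 6), abs=0.12)
    assert res1.cov[0, 0] == pytest.approx(res1.fit.info_inv[0, 0])


def test_pooled_se_shrinks_as_sqrt_m():
    """SE scales as 1/sqrt(m): identical information, m in {1, 10}."""
    g = _edges_set([5], seed=3)[0]
    gs1 = GraphSet([g])
    gs10 = GraphSet([g] * 10)
    r1 = pooled_mle(gs1, EDGES, FitConfig(seed=4))
    r10 = pooled_mle(gs10, EDGES, FitConfig(seed=4))
    # same target, same seed -> same fit; covariance divided by 10
    assert np.allclose(r1.theta, r10.theta)
    assert r10.cov[0, 0] == pytest.approx(r1.cov[0, 0] / 10)
    assert r10.se[0] == pytest.approx(r1.se[0] / np.sqrt(10))


def test_boundary_target_raises_and_directs_to_map():
    gs = _edges_set([0, 0])
    with pytest.raises(BoundaryTargetError, match="conjugate MAP"):
        pooled_mle(gs, EDGES, FitConfig(seed=5))


def test_map_blend_closed_form():
    """Nd=10, tau=2, gbar=4, delta=0.5 -> target 3, theta = logit(0.3)."""
    gs = _edges_set([4], seed=6)
    prior = ConjugatePrior(tau_bar=np.array([2.0]), n0=1.0)  # delta = 1/(1+1)
    res = conjugate_map(gs, EDGES, prior, FitConfig(seed=7, phase3_draws=2000))
    assert res.delta == pytest.approx(0.5)
    assert res.fit.target[0] == pytest.approx(3.0)
    assert res.theta[0] == pytest.approx(np.log(0.3 / 0.7), abs=0.12)
    # cov = I^-1 / (m + n0)
    assert res.cov[0, 0] == pytest.approx(res.fit.info_inv[0, 0] / 2)


def test_map_n0_zero_routes_to_mle():
    gs = _edges_set([4, 6], seed=8)
    prior = ConjugatePrior(tau_bar=np.array([2.0]), n0=0.0)
    r_map = conjugate_map(gs, EDGES, prior, FitConfig(seed=9))
    r_mle = pooled_mle(gs, EDGES, FitConfig(seed=9))
    assert np.allclose(r_map.theta, r_mle.theta)
    assert r_map.delta == 0.0


def test_map_delta_one_limit_matches_prior_natural_parameter():
    """Huge n0: data ignored, theta matches the prior mean's logit."""
    gs = _edges_set([4], seed=10)
    prior = ConjugatePrior(tau_bar=np.array([2.0]), n0=1e6)
    res = conjugate_map(gs, EDGES, prior, FitConfig(seed=11, phase3_draws=2000))
    assert res.fit.target[0] == pytest.approx(2.0, abs=1e-3)
    assert res.theta[0] == pytest.approx(np.log(0.2 / 0.8), abs=0.12)


def test_map_regularizes_boundary_data():
    """Boundary g-bar (zero nodemix cell) with interior tau_bar: MAP with
    small delta converges where the MLE does not exist."""
    rng = np.random.default_rng(12)
    tmpl = random_graph(8, 0.0, seed=12)
    tmpl.vertex_attrs["group"] = ["A"] * 4 + ["B"] * 4
    m = ModelSpec([TermSpec("edges"),
                   TermSpec("nodemix", attribute="group", reference_cell=("A", "A"))])
    # graphs with no A-B edges at all
    graphs = []
    for s in range(3):
        A = np.zeros((8, 8), dtype=np.int8)
        for i, j in [(0, 1), (2, 3), (4, 5), (6, 7), (4, 6)]:
            if rng.random() < 0.8:
                A[i, j] = A[j, i] = 1
        graphs.append(tmpl.with_adjacency(A))
    gs = GraphSet(graphs)
    with pytest.raises(BoundaryTargetError):
        pooled_mle(gs, m, FitConfig(seed=13))
    from ergmpool import bernoulli_tau

    tau = bernoulli_tau(m, tmpl, mean_degree=2.0, n_draws=400, seed=14)
    res = conjugate_map(gs, m, ConjugatePrior(tau_bar=tau, n0=0.05),
                        FitConfig(seed=15))
    assert res.fit.converged
    assert np.all(np.isfinite(res.theta))
    # the zero-cell coefficient is negative (ties suppressed) but finite
    k = m.stat_names(tmpl).index("nodemix.group.A.B")
    assert res.theta[k] < 0


def test_map_interpolates_monotonically_edges_only():
    """As delta sweeps 0 -> 1 the MAP target moves linearly from g-bar to
    tau-bar and the estimate moves monotonically (closed form: logit)."""
    gs = _edges_set([6], seed=16)
    tau = np.array([2.0])
    thetas, targets = [], []
    for n0 in [0.0, 0.5, 1.0, 3.0, 20.0]:
        res = conjugate_map(gs, EDGES, ConjugatePrior(tau_bar=tau, n0=n0),
                            FitConfig(seed=17))
        thetas.append(res.theta[0])
        targets.append(res.fit.target[0])
    deltas = np.array([0, 1 / 3, 0.5, 0.75, 20 / 21])
    assert np.allclose(targets, 6.0 + deltas * (2.0 - 6.0))
    assert np.all(np.diff(thetas) < 0.05)  # decreasing toward logit(0.2)


def test_laplace_posterior_and_sampling():
    gs = _edges_set([4, 6], seed=18)
    res = pooled_mle(gs, EDGES, FitConfig(seed=19))
    mean, cov = laplace_posterior(res)
    assert np.allclose(mean, res.theta)
    assert np.sqrt(cov[0, 0]) == pytest.approx(res.se[0])
    draws = sample_posterior(res, 100_000, seed=20)
    assert draws.mean(axis=0)[0] == pytest.approx(mean[0], abs=4 * res.se[0] / np.sqrt(1e5))
    assert draws.var(axis=0)[0] == pytest.approx(cov[0, 0], rel=0.05)
    # doubling m + n0 at fixed info halves the variance
    res2 = pooled_mle(GraphSet(list(gs.graphs) * 2), EDGES, FitConfig(seed=19))
    assert res2.cov[0, 0] == pytest.approx(res.cov[0, 0] / 2)


def test_posterior_predictive_inflates_variance():
    """Law of total variance: predictive edge-count spread exceeds the
    fixed-theta simulation spread."""
    gs = _edges_set([7, 9, 8], n=6, seed=21)
    res = pooled_mle(gs, EDGES, FitConfig(seed=22))
    pred = posterior_predictive(res, EDGES, gs.template, 300, seed=23)
    fixed = simulate(EDGES, res.theta, gs.template,
                     SamplerConfig(n_draws=300, seed=23))
    assert pred.stats[:, 0].var() > fixed.stats[:, 0].var()
    # predictive mean statistics track the fitting target
    assert pred.stats[:, 0].mean() == pytest.approx(res.fit.target[0], abs=0.6)
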