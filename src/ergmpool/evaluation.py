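"""Model adequacy and structural-variability summaries, plus CV tuning.

Graph-level indices (GLIs) characterise structural variability: transitivity
(triadic closure), and the population standard deviations of the degree
distribution, the k-core numbers, and the M-eccentricities (a vertex's mean
geodesic distance to all others).  Structure summaries (degree, edgewise
shared partners, geodesic distances, 4-class triad census) back simulation
envelope checks.  Leave-one-out Hamming cross-validation tunes the
conjugate-prior weight n0: for each grid value, each graph is held out, the
MAP is refit on the rest, and the mean squared Hamming distance (over free
dyads) between predictive draws and the held-out graph is accumulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .fit import BoundaryTargetError, FitConfig, mple
from .graph import Graph, GraphSet, free_dyads, hamming_distance
from .pooled import ConjugatePrior, PooledResult, conjugate_map, posterior_predictive
from .sampler import SamplerConfig, simulate
from .terms import ModelSpec, mean_statistics, statistics


@dataclass
class GLIReport:
    """Graph-level indices; SDs are population (ddof=0) standard deviations."""

    transitivity: float
    sd_degree: float
    sd_core_number: float
    sd_m_eccentricity: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.transitivity, self.sd_degree, self.sd_core_number, self.sd_m_eccentricity]
        )

    names = ("transitivity", "sd_degree", "sd_core_number", "sd_m_eccentricity")


def _to_nx(g: Graph) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(g.n))
    G.add_edges_from(g.edges())
    return G


def m_eccentricity(g: Graph, unreachable: float | None = None) -> np.ndarray:
    """Mean geodesic distance from each vertex to all others.

    Unreachable pairs count as ``unreachable`` (default n, one more than any
    possible geodesic).
    """
    if unreachable is None:
        unreachable = float(g.n)
    G = _to_nx(g)
    out = np.full(g.n, np.nan)
    for v in range(g.n):
        dist = nx.single_source_shortest_path_length(G, v)
        total = sum(dist.values()) + unreachable * (g.n - len(dist))
        out[v] = total / (g.n - 1)
    return out


def gli_suite(g: Graph, unreachable: float | None = None) -> GLIReport:
    """Transitivity + SDs of degree, core number, and M-eccentricity."""
    if g.n < 3:
        raise ValueError("GLIs need at least 3 nodes")
    A = g.adjacency.astype(np.int64)
    deg = A.sum(axis=1)
    twostars = int((deg * (deg - 1) // 2).sum())
    triangles = int(np.trace(A @ A @ A) // 6)
    transitivity = 3.0 * triangles / twostars if twostars > 0 else 0.0
    G = _to_nx(g)
    core = np.array([nx.core_number(G)[v] for v in range(g.n)], dtype=float)
    mecc = m_eccentricity(g, unreachable)
    return GLIReport(
        transitivity=transitivity,
        sd_degree=float(deg.std()),
        sd_core_number=float(core.std()),
        sd_m_eccentricity=float(mecc.std()),
    )


def structure_summaries(g: Graph) -> dict[str, np.ndarray]:
    """Degree, edgewise-shared-partner, geodesic, and triad-census summaries.

    Returns dense count vectors: ``degree[k]`` = #nodes with degree k,
    ``esp[k]`` = #edges with k shared partners, ``geodesic[d-1]`` = #pairs at
    distance d with a trailing "unreachable" bucket, and ``triad_census`` =
    (empty, one-edge, two-path, triangle) counts over all node triples.
    """
    if g.n < 3:
        raise ValueError("structure summaries need at least 3 nodes")
    n = g.n
    A = g.adjacency.astype(np.int64)
    deg = A.sum(axis=1)
    degree = np.bincount(deg, minlength=n)

    iu = np.triu_indices(n, k=1)
    cn = (A @ A)[iu]
    is_edge = A[iu] == 1
    esp = np.bincount(cn[is_edge], minlength=max(n - 1, 1)) if is_edge.any() \
        else np.zeros(max(n - 1, 1), dtype=np.int64)

    G = _to_nx(g)
    geod = np.zeros(n + 1, dtype=np.int64)  # index d-1 for distance d; [-1] unreachable
    reached_pairs = 0
    for v, dist in nx.all_pairs_shortest_path_length(G):
        for u, d in dist.items():
            if u > v:
                geod[d - 1] += 1
                reached_pairs += 1
    geod[-1] = len(iu[0]) - reached_pairs

    n_edges = int(is_edge.sum())
    triangles = int(np.trace(A @ A @ A) // 6)
    twostars = int((deg * (deg - 1) // 2).sum())
    n2 = twostars - 3 * triangles
    n1 = n_edges * (n - 2) - 2 * n2 - 3 * triangles
    n_triples = n * (n - 1) * (n - 2) // 6
    n0 = n_triples - n1 - n2 - triangles
    census = np.array([n0, n1, n2, triangles], dtype=np.int64)

    return {"degree": degree, "esp": esp, "geodesic": geod, "triad_census": census}


# ---------------------------------------------------------------------------
# Simulation envelopes
# ---------------------------------------------------------------------------


def _summary_vector(g: Graph, max_deg: int, max_esp: int) -> np.ndarray:
    s = structure_summaries(g)
    parts = [
        np.pad(s["degree"], (0, max(0, max_deg + 1 - s["degree"].size)))[: max_deg + 1],
        np.pad(s["esp"], (0, max(0, max_esp + 1 - s["esp"].size)))[: max_esp + 1],
        s["geodesic"],
        s["triad_census"],
    ]
    gli = gli_suite(g).as_array()
    return np.concatenate(parts + [gli])


def gof_compare(
    observed: GraphSet,
    model: ModelSpec,
    theta_or_result,
    n_sim: int = 100,
    cfg: SamplerConfig = SamplerConfig(),
    seed: int = 0,
) -> pd.DataFrame:
    """95% simulation envelopes for structural summaries vs observed means.

    ``theta_or_result`` is either a coefficient vector (fixed-theta
    simulation) or a :class:`PooledResult` (posterior-predictive
    simulation).  Returns a table with the observed mean, envelope bounds,
    and an ``outside`` flag per summary bin.
    """
    template = observed.template
    max_deg = template.n - 1
    max_esp = template.n - 2
    obs = np.mean([_summary_vector(g, max_deg, max_esp) for g in observed], axis=0)

    if isinstance(theta_or_result, PooledResult):
        draws = posterior_predictive(theta_or_result, model, template, n_sim, cfg, seed)
        sim_graphs = draws.graphs
    else:
        one = SamplerConfig(burn_in=cfg.burn_in, thin=cfg.thin, n_draws=n_sim,
                            seed=seed, proposal=cfg.proposal)
        sim_graphs = simulate(model, theta_or_result, template, one, return_graphs=True).graphs
    sims = np.array([_summary_vector(g, max_deg, max_esp) for g in sim_graphs])

    lo = np.percentile(sims, 2.5, axis=0)
    hi = np.percentile(sims, 97.5, axis=0)
    names = (
        [f"degree.{k}" for k in range(max_deg + 1)]
        + [f"esp.{k}" for k in range(max_esp + 1)]
        + [f"geodesic.{d}" for d in range(1, template.n + 1)]
        + ["geodesic.unreachable"]
        + ["triad.empty", "triad.one_edge", "triad.two_path", "triad.triangle"]
        + list(GLIReport.names)
    )
    return pd.DataFrame(
        {
            "observed_mean": obs,
            "sim_low": lo,
            "sim_high": hi,
            "sim_mean": sims.mean(axis=0),
            "outside": (obs < lo) | (obs > hi),
        },
        index=names,
    )


# ---------------------------------------------------------------------------
# Leave-one-out Hamming cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVTable:
    """Per-n0 CV errors; rows flagged ``ok=False`` had non-converged fits."""

    table: pd.DataFrame          # columns: n0, delta, cv_error, ok
    selected_n0: float | None


def expected_sq_hamming(held_out: Graph, predictive_graphs, dyads=None) -> float:
    """Mean over predictive draws of the squared Hamming distance (free dyads)."""
    if dyads is None:
        dyads = free_dyads(held_out)
    return float(np.mean([hamming_distance(held_out, g, dyads) ** 2
                          for g in predictive_graphs]))


def loo_cv_hamming(
    gs: GraphSet,
    model: ModelSpec,
    tau_bar,
    n0_grid,
    n_sim: int = 100,
    cfg: FitConfig = FitConfig(),
    sampler_cfg: SamplerConfig = SamplerConfig(),
    seed: int = 0,
) -> CVTable:
    """Tune n0 by leave-one-out expected squared Hamming error.

    For each grid value and each held-out graph i, a conjugate MAP is fit on
    the remaining m-1 graphs (delta recomputed with m-1), ``n_sim`` graphs
    are simulated at the fitted coefficients, and the mean squared Hamming
    distance to graph i is accumulated.  The selected n0 minimises the total
    (ties break to the smaller n0); rows with any non-converged or
    boundary-failing held-out fit are flagged and excluded from the argmin.
    """
    if gs.m < 2:
        raise ValueError("leave-one-out CV needs m >= 2")
    n0_grid = sorted(float(v) for v in n0_grid)
    if not n0_grid:
        raise ValueError("empty n0 grid")
    tau_bar = np.asarray(tau_bar, dtype=float)
    dyads = free_dyads(gs.template)
    rng = np.random.default_rng(seed)

    # shared warm start: estimates change little when one graph is dropped
    theta_warm = mple(model, gs.template)

    rows = []
    for n0 in n0_grid:
        total = 0.0
        ok = True
        for i in range(gs.m):
            rest = GraphSet([g for k, g in enumerate(gs.graphs) if k != i])
            try:
                res = conjugate_map(
                    rest, model, ConjugatePrior(tau_bar=tau_bar, n0=n0),
                    cfg, theta_init=theta_warm,
                )
            except BoundaryTargetError:
                ok = False
                break
            if not res.fit.converged:
                ok = False
                break
            theta_warm = res.theta
            sim = simulate(
                model, res.theta, gs.template,
                SamplerConfig(burn_in=sampler_cfg.burn_in, thin=sampler_cfg.thin,
                              n_draws=n_sim, seed=int(rng.integers(0, 2**31 - 1)),
                              proposal=sampler_cfg.proposal),
                return_graphs=True,
            )
            total += expected_sq_hamming(gs[i], sim.graphs, dyads)
        delta = n0 / (n0 + (gs.m - 1))
        rows.append({"n0": n0, "delta": delta,
                     "cv_error": total if ok else np.nan, "ok": ok})

    table = pd.DataFrame(rows)
    usable = table[table["ok"]]
    selected = None if usable.empty else float(usable.loc[usable["cv_error"].idxmin(), "n0"])
    if not table["ok"].all():
        warnings.warn("some CV rows had non-converged held-out fits and were excluded")
    return CVTable(table=table, selected_n0=selected)
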