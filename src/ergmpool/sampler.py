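"""Draw graphs from an ERGM by Metropolis-Hastings dyad toggling.

The chain proposes toggles of *free* dyads only (support-constrained dyads
never change), accepting with probability min(1, exp(theta' dg)) times the
Hastings correction of the proposal.  Two proposals are available: uniform
over free dyads, and tie/no-tie (TNT) which picks an existing edge half the
time -- much more efficient on sparse graphs and the default.

Burn-in and thinning default to multiples of the free-dyad count Nd
(20*Nd and 2*Nd respectively), so the defaults adapt to network size;
both are overridable for production-scale runs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _engine
from .graph import FIXED_PRESENT, Graph, free_dyads
from .terms import CompiledModel, ModelSpec, compile_model, statistics

_MAX_SEED = 2**31 - 1


def _spawn_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, _MAX_SEED))


@dataclass
class SamplerConfig:
    """MH sampler settings. ``burn_in``/``thin`` of None mean 20*Nd / 2*Nd."""

    burn_in: int | None = None
    thin: int | None = None
    n_draws: int = 100
    seed: int = 0
    proposal: str = "tnt"

    def __post_init__(self):
        if self.thin is not None and self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.proposal not in {"tnt", "uniform"}:
            raise ValueError("proposal must be 'tnt' or 'uniform'")

    def resolve(self, n_free: int) -> tuple[int, int]:
        burn = self.burn_in if self.burn_in is not None else 20 * n_free
        thin = self.thin if self.thin is not None else max(1, 2 * n_free)
        return int(burn), int(thin)


@dataclass
class SampleStats:
    """Simulated statistic draws: row k is g(model, draw k)."""

    stats: np.ndarray
    names: list[str]
    final_graph: Graph
    graphs: list[Graph] | None = None
    accept_rate: float = np.nan


class ChainState:
    """Mutable MH chain state over a compiled model on one template."""

    def __init__(self, graph: Graph, compiled: CompiledModel):
        self.compiled = compiled
        self.node_ids = list(graph.node_ids)
        self._template = graph
        self.A = graph.adjacency.copy()
        self.deg = self.A.sum(axis=1).astype(np.int64)
        fd = free_dyads(graph)
        if fd.shape[0] == 0:
            raise ValueError("graph has no free dyads to sample over")
        self.fi = np.ascontiguousarray(fd[:, 0])
        self.fj = np.ascontiguousarray(fd[:, 1])
        Nd = fd.shape[0]
        self.estack = np.zeros(Nd, dtype=np.int64)
        self.epos = np.full(Nd, -1, dtype=np.int64)
        self.ne_box = np.zeros(1, dtype=np.int64)
        for d in range(Nd):
            if self.A[self.fi[d], self.fj[d]] == 1:
                self.estack[self.ne_box[0]] = d
                self.epos[d] = self.ne_box[0]
                self.ne_box[0] += 1
        self.cur_stats = statistics(compiled.model, graph)

    @property
    def n_free(self) -> int:
        return self.fi.shape[0]

    def run(self, theta: np.ndarray, burn: int, thin: int, n_draws: int,
            proposal: str, seed: int) -> tuple[np.ndarray, int]:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.compiled.p,):
            raise ValueError(
                f"theta has length {theta.size}, model has {self.compiled.p} statistics"
            )
        out = np.zeros((n_draws, self.compiled.p))
        cm = self.compiled
        accepted = _engine.run_chain(
            self.A, self.deg, self.fi, self.fj, self.estack, self.epos, self.ne_box,
            theta, cm.kinds, cm.offsets, cm.decays, cm.node_int, cm.node_float,
            cm.dyad, cm.mix_idx, self.cur_stats,
            int(burn), int(thin), out, 1 if proposal == "tnt" else 0, int(seed),
        )
        return out, accepted

    def graph(self) -> Graph:
        return self._template.with_adjacency(self.A.copy())


def simulate(
    model: ModelSpec,
    theta,
    template_or_init: Graph,
    cfg: SamplerConfig = SamplerConfig(),
    return_graphs: bool = False,
) -> SampleStats:
    """Simulate ``cfg.n_draws`` graphs from the ERGM (model, theta).

    The chain starts at ``template_or_init`` (which must respect its own
    support mask -- guaranteed by Graph invariants).  Identical config and
    seed give bitwise-identical statistic matrices.
    """
    cm = compile_model(model, template_or_init)
    state = ChainState(template_or_init, cm)
    burn, thin = cfg.resolve(state.n_free)
    rng = np.random.default_rng(cfg.seed)
    graphs = [] if return_graphs else None
    if return_graphs:
        stats = np.zeros((cfg.n_draws, cm.p))
        total_acc = 0
        for k in range(cfg.n_draws):
            _, acc = state.run(theta, burn if k == 0 else 0, thin, 1,
                               cfg.proposal, _spawn_seed(rng))
            stats[k] = state.cur_stats
            graphs.append(state.graph())
            total_acc += acc
        n_prop = burn + cfg.n_draws * thin
    else:
        stats, total_acc = state.run(theta, burn, thin, cfg.n_draws,
                                     cfg.proposal, _spawn_seed(rng))
        n_prop = burn + cfg.n_draws * thin
    return SampleStats(
        stats=stats,
        names=cm.names,
        final_graph=state.graph(),
        graphs=graphs,
        accept_rate=total_acc / max(n_prop, 1),
    )


def bernoulli_graph(template: Graph, p: float, seed) -> Graph:
    """Exact draw of a (conditional) Bernoulli graph on the template.

    Each free dyad is an independent Bernoulli(p) edge; fixed_present dyads
    are edges and fixed_absent dyads non-edges.  ``seed`` may be an int or a
    numpy Generator.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = template.n
    A = np.zeros((n, n), dtype=np.int8)
    fd = free_dyads(template)
    if fd.shape[0]:
        hit = rng.random(fd.shape[0]) < p
        i, j = fd[hit, 0], fd[hit, 1]
        A[i, j] = 1
        A[j, i] = 1
    fp = template.support_mask == FIXED_PRESENT
    A[fp] = 1
    return template.with_adjacency(A)
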