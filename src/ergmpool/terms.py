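"""ERGM sufficient statistics g(y) and local change statistics.

The term suite covers the statistics used for brain-connectivity and
protein-structure-network models: edge count, categorical homophily
(nodematch) and mixing (nodemix, with optional level grouping and a
reference cell), additive numeric node covariates (nodecov, sum form
x_i + x_j per edge), dyadic covariates (edgecov), 2-stars, triangles,
geometrically weighted edgewise shared partners (GWESP, decay fixed by the
user), and graphlet1 (induced two-paths, a local-bridging statistic).

Full statistics are computed by direct matrix counting; change statistics
(the difference from toggling one dyad) are computed locally in O(n) per
dyad by the numba kernels in :mod:`ergmpool._engine`.  The two routes are
independent, so the identity ``change == after - before`` is a meaningful
cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .graph import Graph, GraphSet

TERM_KINDS = (
    "edges",
    "nodematch",
    "nodemix",
    "nodecov",
    "edgecov",
    "twostars",
    "triangles",
    "gwesp",
    "graphlet1",
)

# integer codes shared with the numba engine
KIND_CODE = {k: i for i, k in enumerate(TERM_KINDS)}


@dataclass(frozen=True)
class TermSpec:
    """One term of an ERGM model.

    ``attribute`` names a vertex-attribute column (nodematch / nodemix /
    nodecov), ``covariate`` a dyadic covariate matrix (edgecov).  ``decay``
    is the fixed GWESP decay phi > 0.  For nodemix, ``mix_levels``
    optionally maps raw attribute levels to grouped levels (e.g. collapsing
    small categories to "Others") and ``reference_cell`` names the omitted
    cell as a (level, level) pair; by default the first cell in sorted order
    is the reference.
    """

    kind: str
    attribute: str | None = None
    covariate: str | None = None
    decay: float | None = None
    reference_cell: tuple[str, str] | None = None
    mix_levels: Mapping[str, str] | None = None

    def __post_init__(self):
        if self.kind not in TERM_KINDS:
            raise ValueError(f"unknown term kind {self.kind!r}; expected one of {TERM_KINDS}")
        if self.kind in {"nodematch", "nodemix", "nodecov"} and not self.attribute:
            raise ValueError(f"term {self.kind!r} needs an attribute name")
        if self.kind == "edgecov" and not self.covariate:
            raise ValueError("term 'edgecov' needs a covariate name")
        if self.kind == "gwesp":
            if self.decay is None or not self.decay > 0:
                raise ValueError("gwesp needs a positive fixed decay")
        if self.mix_levels is not None:
            object.__setattr__(self, "mix_levels", dict(self.mix_levels))
        if self.reference_cell is not None:
            a, b = self.reference_cell
            object.__setattr__(self, "reference_cell", tuple(sorted((str(a), str(b)))))


def _grouped_levels(term: TermSpec, graph: Graph) -> tuple[np.ndarray, list[str]]:
    """Per-node grouped level codes and the sorted level list for nodemix."""
    raw = graph.vertex_attrs[term.attribute].astype(str)
    if term.mix_levels:
        raw = raw.map(lambda v: term.mix_levels.get(v, v))
    levels = sorted(raw.unique())
    codes = raw.map({v: k for k, v in enumerate(levels)}).to_numpy(dtype=np.int64)
    return codes, levels


def _mix_cells(term: TermSpec, graph: Graph) -> tuple[list[tuple[str, str]], tuple[str, str]]:
    """Emitted cells (sorted unordered level pairs, reference excluded)."""
    _, levels = _grouped_levels(term, graph)
    cells = [
        (levels[a], levels[b])
        for a in range(len(levels))
        for b in range(a, len(levels))
    ]
    ref = term.reference_cell if term.reference_cell is not None else cells[0]
    if ref not in cells:
        raise ValueError(f"nodemix reference cell {ref!r} not among cells {cells}")
    return [c for c in cells if c != ref], ref


@dataclass(frozen=True)
class ModelSpec:
    """Ordered term list; expands to a p-vector of named statistics."""

    terms: tuple[TermSpec, ...]

    def __init__(self, terms: Sequence[TermSpec]):
        object.__setattr__(self, "terms", tuple(terms))
        if not self.terms:
            raise ValueError("a model needs at least one term")

    def stat_names(self, template: Graph) -> list[str]:
        names: list[str] = []
        for t in self.terms:
            if t.kind == "nodemix":
                cells, _ = _mix_cells(t, template)
                names.extend(f"nodemix.{t.attribute}.{a}.{b}" for a, b in cells)
            elif t.kind in {"nodematch", "nodecov"}:
                names.append(f"{t.kind}.{t.attribute}")
            elif t.kind == "edgecov":
                names.append(f"edgecov.{t.covariate}")
            elif t.kind == "gwesp":
                names.append(f"gwesp.{t.decay:g}")
            else:
                names.append(t.kind)
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate statistic names: {names}")
        return names

    def n_stats(self, template: Graph) -> int:
        return len(self.stat_names(template))

    def validate(self, template: Graph) -> None:
        for t in self.terms:
            if t.attribute is not None and t.attribute not in template.vertex_attrs.columns:
                raise ValueError(
                    f"term {t.kind!r}: attribute {t.attribute!r} not in the template"
                )
            if t.covariate is not None and t.covariate not in template.dyad_covariates:
                raise ValueError(
                    f"term {t.kind!r}: covariate {t.covariate!r} not in the template"
                )


def gwesp_weight(k, decay: float):
    """Weight of an edge with k shared partners: e^phi * (1 - (1-e^-phi)^k)."""
    k = np.asarray(k, dtype=float)
    return np.exp(decay) * (1.0 - (1.0 - np.exp(-decay)) ** k)


# ---------------------------------------------------------------------------
# Full statistics (direct counting)
# ---------------------------------------------------------------------------


def statistics(model: ModelSpec, graph: Graph) -> np.ndarray:
    """Sufficient-statistic vector g(y), aligned with ``model.stat_names``.

    Statistics count over *all* edges, including fixed_present ones (support
    constraints restrict the sample space, not the statistics).
    """
    model.validate(graph)
    A = graph.adjacency.astype(np.int64)
    iu = np.triu_indices(graph.n, k=1)
    deg = A.sum(axis=1)
    out: list[float] = []
    for t in model.terms:
        if t.kind == "edges":
            out.append(A[iu].sum())
        elif t.kind == "nodematch":
            vals = graph.vertex_attrs[t.attribute].astype(str).to_numpy()
            eq = vals[:, None] == vals[None, :]
            out.append((A[iu] * eq[iu]).sum())
        elif t.kind == "nodemix":
            codes, levels = _grouped_levels(t, graph)
            cells, _ = _mix_cells(t, graph)
            cell_idx = {c: k for k, c in enumerate(cells)}
            counts = np.zeros(len(cells))
            ei, ej = np.nonzero(np.triu(A, k=1))
            for i, j in zip(ei, ej):
                c = tuple(sorted((levels[codes[i]], levels[codes[j]])))
                if c in cell_idx:
                    counts[cell_idx[c]] += 1
            out.extend(counts)
        elif t.kind == "nodecov":
            x = graph.vertex_attrs[t.attribute].astype(float).to_numpy()
            out.append(float(deg @ x))
        elif t.kind == "edgecov":
            W = graph.dyad_covariates[t.covariate]
            out.append(float((A[iu] * W[iu]).sum()))
        elif t.kind == "twostars":
            out.append(float((deg * (deg - 1) // 2).sum()))
        elif t.kind == "triangles":
            out.append(float(np.trace(A @ A @ A) / 6))
        elif t.kind == "gwesp":
            cn = A @ A
            esp = cn[iu][A[iu] == 1]
            out.append(float(gwesp_weight(esp, t.decay).sum()))
        elif t.kind == "graphlet1":
            # induced two-paths: common neighbours summed over non-adjacent pairs
            cn = A @ A
            out.append(float(cn[iu][A[iu] == 0].sum()))
    return np.asarray(out, dtype=float)


def mean_statistics(model: ModelSpec, gs: GraphSet) -> np.ndarray:
    """Arithmetic mean of member statistic vectors, g-bar(y_obs)."""
    return np.mean([statistics(model, g) for g in gs], axis=0)


# ---------------------------------------------------------------------------
# Compilation for the numba engine
# ---------------------------------------------------------------------------


@dataclass
class CompiledModel:
    """Flat array view of a model against a fixed template, for the kernels."""

    model: ModelSpec
    names: list[str]
    p: int
    kinds: np.ndarray       # (nterms,) int64 codes
    offsets: np.ndarray     # (nterms,) int64 first stat index of each term
    decays: np.ndarray      # (nterms,) float64 (0 where unused)
    node_int: np.ndarray    # (nterms, n) int64 attr codes (0 where unused)
    node_float: np.ndarray  # (nterms, n) float64 (0 where unused)
    dyad: np.ndarray        # (nterms, n, n) float64 edgecov matrices
    mix_idx: np.ndarray     # (nterms, n, n) int64 stat index per dyad, -1 = none


def compile_model(model: ModelSpec, template: Graph) -> CompiledModel:
    model.validate(template)
    n = template.n
    nt = len(model.terms)
    kinds = np.zeros(nt, dtype=np.int64)
    offsets = np.zeros(nt, dtype=np.int64)
    decays = np.zeros(nt, dtype=np.float64)
    node_int = np.zeros((nt, n), dtype=np.int64)
    node_float = np.zeros((nt, n), dtype=np.float64)
    dyad = np.zeros((nt, n, n), dtype=np.float64)
    mix_idx = np.full((nt, n, n), -1, dtype=np.int64)
    off = 0
    for k, t in enumerate(model.terms):
        kinds[k] = KIND_CODE[t.kind]
        offsets[k] = off
        width = 1
        if t.kind in {"nodematch"}:
            vals = template.vertex_attrs[t.attribute].astype(str)
            levels = sorted(vals.unique())
            node_int[k] = vals.map({v: i for i, v in enumerate(levels)}).to_numpy()
        elif t.kind == "nodemix":
            codes, levels = _grouped_levels(t, template)
            cells, _ = _mix_cells(t, template)
            cell_idx = {c: off + i for i, c in enumerate(cells)}
            width = len(cells)
            for i in range(n):
                for j in range(n):
                    c = tuple(sorted((levels[codes[i]], levels[codes[j]])))
                    mix_idx[k, i, j] = cell_idx.get(c, -1)
        elif t.kind == "nodecov":
            node_float[k] = template.vertex_attrs[t.attribute].astype(float).to_numpy()
        elif t.kind == "edgecov":
            dyad[k] = template.dyad_covariates[t.covariate]
        elif t.kind == "gwesp":
            decays[k] = t.decay
        off += width
    return CompiledModel(
        model=model,
        names=model.stat_names(template),
        p=off,
        kinds=kinds,
        offsets=offsets,
        decays=decays,
        node_int=node_int,
        node_float=node_float,
        dyad=dyad,
        mix_idx=mix_idx,
    )


def change_statistics(model: ModelSpec, graph: Graph, dyad: tuple[int, int]) -> np.ndarray:
    """g(y + dyad) - g(y - dyad): the change from toggling one free dyad on.

    The returned vector is the *add* delta regardless of the dyad's current
    state (toggling an existing edge off changes g by the negative of this).
    Computed locally (no full recount).
    """
    from ._engine import add_delta

    i, j = int(dyad[0]), int(dyad[1])
    if i == j:
        raise ValueError("dyad must join two distinct nodes")
    if graph.support_mask[i, j] != 0:
        raise ValueError(f"dyad ({i}, {j}) is constrained and cannot be toggled")
    cm = compile_model(model, graph)
    A = graph.adjacency.copy()
    had_edge = A[i, j] == 1
    if had_edge:
        A[i, j] = A[j, i] = 0
    deg = A.sum(axis=1).astype(np.int64)
    out = np.zeros(cm.p)
    add_delta(
        A, deg, i, j, cm.kinds, cm.offsets, cm.decays,
        cm.node_int, cm.node_float, cm.dyad, cm.mix_idx, out,
    )
    return out
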