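"""Binary undirected graphs on a labeled node set, and sets of such graphs.

A :class:`Graph` bundles an adjacency structure with the vertex attributes,
symmetric dyadic covariates, and per-dyad support constraints that an ERGM
needs.  A :class:`GraphSet` is an ordered collection of graphs sharing one
node set, attribute table, covariate stack, and support mask ("equivalent
vertices"): the setting in which pooled mean-value inference applies.

Support-mask convention: each unordered dyad is ``FREE`` (may be toggled by
samplers and contributes to the likelihood), ``FIXED_PRESENT`` (always an
edge, e.g. a covalent protein backbone bond), or ``FIXED_ABSENT`` (never an
edge).  On disk, graphs are edge lists or 0/1 adjacency matrices keyed by
string node labels; in memory nodes are 0-based indices in attribute-table
row order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

FREE = 0
FIXED_PRESENT = 1
FIXED_ABSENT = -1

_MASK_STATES = {"free": FREE, "fixed_present": FIXED_PRESENT, "fixed_absent": FIXED_ABSENT}
_MASK_NAMES = {v: k for k, v in _MASK_STATES.items()}


class GraphValidationError(ValueError):
    """Raised when a graph (or graph file) violates a structural invariant."""


@dataclass
class Graph:
    """One binary undirected network on a labeled node set.

    Parameters
    ----------
    node_ids
        Ordered string labels, length ``n``.
    adjacency
        ``n x n`` symmetric 0/1 matrix with zero diagonal.
    vertex_attrs
        Table of categorical/numeric columns, one row per node, indexed by
        ``node_ids`` (row order defines the node order).
    dyad_covariates
        Named symmetric real ``n x n`` matrices (diagonal ignored).
    support_mask
        ``n x n`` symmetric matrix over {FREE, FIXED_PRESENT, FIXED_ABSENT}.
    """

    node_ids: list[str]
    adjacency: np.ndarray
    vertex_attrs: pd.DataFrame = None
    dyad_covariates: dict[str, np.ndarray] = field(default_factory=dict)
    support_mask: np.ndarray = None

    def __post_init__(self):
        n = len(self.node_ids)
        self.node_ids = [str(v) for v in self.node_ids]
        if len(set(self.node_ids)) != n:
            raise GraphValidationError("duplicate node labels")
        A = np.asarray(self.adjacency)
        if A.shape != (n, n):
            raise GraphValidationError(f"adjacency shape {A.shape} != ({n}, {n})")
        if not np.array_equal(A, A.T):
            raise GraphValidationError("adjacency matrix is not symmetric")
        if np.any(np.diag(A) != 0):
            raise GraphValidationError("self-loops are not allowed")
        if not np.isin(A, (0, 1)).all():
            raise GraphValidationError("adjacency entries must be 0/1")
        self.adjacency = A.astype(np.int8)
        if self.vertex_attrs is None:
            self.vertex_attrs = pd.DataFrame(index=pd.Index(self.node_ids, name="node"))
        else:
            if len(self.vertex_attrs) != n:
                raise GraphValidationError(
                    f"attribute table has {len(self.vertex_attrs)} rows for {n} nodes"
                )
            self.vertex_attrs = self.vertex_attrs.copy()
            self.vertex_attrs.index = pd.Index(self.node_ids, name="node")
        for name, M in self.dyad_covariates.items():
            M = np.asarray(M, dtype=float)
            if M.shape != (n, n):
                raise GraphValidationError(f"covariate {name!r} shape {M.shape} != ({n}, {n})")
            off = ~np.eye(n, dtype=bool)
            if not np.allclose(M[off], M.T[off]):
                raise GraphValidationError(f"covariate {name!r} is not symmetric")
            self.dyad_covariates[name] = M
        if self.support_mask is None:
            self.support_mask = np.zeros((n, n), dtype=np.int8)
        else:
            S = np.asarray(self.support_mask)
            if S.shape != (n, n) or not np.array_equal(S, S.T):
                raise GraphValidationError("support mask must be a symmetric n x n matrix")
            if not np.isin(S, (FREE, FIXED_PRESENT, FIXED_ABSENT)).all():
                raise GraphValidationError("support mask entries must be in {-1, 0, 1}")
            self.support_mask = S.astype(np.int8)
        iu = np.triu_indices(n, k=1)
        bad = (self.support_mask[iu] == FIXED_PRESENT) & (self.adjacency[iu] == 0)
        if bad.any():
            i, j = iu[0][bad][0], iu[1][bad][0]
            raise GraphValidationError(
                f"dyad ({self.node_ids[i]}, {self.node_ids[j]}) is fixed_present but not an edge"
            )
        bad = (self.support_mask[iu] == FIXED_ABSENT) & (self.adjacency[iu] == 1)
        if bad.any():
            i, j = iu[0][bad][0], iu[1][bad][0]
            raise GraphValidationError(
                f"edge on fixed_absent dyad ({self.node_ids[i]}, {self.node_ids[j]})"
            )

    # -- basic accessors -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edges(self) -> list[tuple[int, int]]:
        """Edge set as sorted (i, j) index pairs with i < j."""
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(i.tolist(), j.tolist()))

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)

    def index_of(self, label: str) -> int:
        return self.node_ids.index(str(label))

    def with_adjacency(self, adjacency: np.ndarray) -> "Graph":
        """New graph sharing this graph's template but with new edges."""
        return Graph(
            node_ids=list(self.node_ids),
            adjacency=adjacency,
            vertex_attrs=self.vertex_attrs,
            dyad_covariates=dict(self.dyad_covariates),
            support_mask=self.support_mask,
        )

    def template_equal(self, other: "Graph") -> bool:
        """True if node set, attributes, covariates, and mask all match."""
        if self.node_ids != other.node_ids:
            return False
        if not self.vertex_attrs.equals(other.vertex_attrs):
            return False
        if set(self.dyad_covariates) != set(other.dyad_covariates):
            return False
        for name, M in self.dyad_covariates.items():
            if not np.allclose(M, other.dyad_covariates[name]):
                return False
        return np.array_equal(self.support_mask, other.support_mask)


def free_dyads(graph: Graph) -> np.ndarray:
    """Unconstrained dyads of ``graph`` as an (Nd, 2) index array, i < j.

    Order is deterministic (row-major over the upper triangle), so every
    member of a :class:`GraphSet` yields the identical list.
    """
    i, j = np.triu_indices(graph.n, k=1)
    keep = graph.support_mask[i, j] == FREE
    return np.column_stack([i[keep], j[keep]]).astype(np.int64)


def n_free_dyads(graph: Graph) -> int:
    return int(free_dyads(graph).shape[0])


def hamming_distance(a: Graph, b: Graph, dyads: np.ndarray | None = None) -> int:
    """Number of free dyads on which two graphs on one template disagree."""
    if dyads is None:
        dyads = free_dyads(a)
    i, j = dyads[:, 0], dyads[:, 1]
    return int(np.sum(a.adjacency[i, j] != b.adjacency[i, j]))


@dataclass
class GraphSet:
    """m graphs on a shared template (equivalent vertex sets)."""

    graphs: list[Graph]

    def __post_init__(self):
        if len(self.graphs) < 1:
            raise GraphValidationError("a GraphSet needs at least one graph")
        t = self.graphs[0]
        for k, g in enumerate(self.graphs[1:], start=2):
            if g.node_ids != t.node_ids:
                mism = next(
                    (a for a, b in zip(g.node_ids, t.node_ids) if a != b),
                    "node count differs",
                )
                raise GraphValidationError(
                    f"graph {k} violates node-set equivalence (first mismatch: {mism})"
                )
            if not t.template_equal(g):
                raise GraphValidationError(
                    f"graph {k} differs from the shared template "
                    "(attributes, covariates, or support mask)"
                )

    @property
    def m(self) -> int:
        return len(self.graphs)

    @property
    def template(self) -> Graph:
        return self.graphs[0]

    def __iter__(self):
        return iter(self.graphs)

    def __getitem__(self, k):
        return self.graphs[k]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, dtype=str, header=None)


def _read_edge_list(path, labels: list[str] | None):
    df = _read_table(path)
    if df.shape[1] < 2:
        raise GraphValidationError(f"{path}: edge list needs two columns")
    df = df.iloc[:, :2]
    # header row is optional; drop it if it does not name known labels
    first = tuple(df.iloc[0])
    if labels is not None and (first[0] not in labels or first[1] not in labels):
        df = df.iloc[1:]
    elif labels is None and first in {("from", "to"), ("source", "target"), ("a", "b")}:
        df = df.iloc[1:]
    return [(str(a), str(b)) for a, b in df.itertuples(index=False)]


def read_graph(
    edge_list_path=None,
    adjacency_path=None,
    attr_path=None,
    covariate_paths: Mapping[str, object] | None = None,
    mask_path=None,
) -> Graph:
    """Read one graph from disk.

    Exactly one of ``edge_list_path`` / ``adjacency_path`` must be given.
    Node order follows the attribute-table row order when an attribute table
    is supplied; otherwise labels are taken from the adjacency header or
    enumerated from the edge list in order of first appearance.
    """
    if (edge_list_path is None) == (adjacency_path is None):
        raise ValueError("give exactly one of edge_list_path or adjacency_path")

    attrs = None
    labels: list[str] | None = None
    if attr_path is not None:
        raw = pd.read_csv(attr_path)
        labels = [str(v) for v in raw.iloc[:, 0]]
        attrs = raw.iloc[:, 1:]
        attrs.index = labels

    if adjacency_path is not None:
        df = pd.read_csv(adjacency_path, index_col=0)
        adj_labels = [str(v) for v in df.index]
        if [str(c) for c in df.columns] != adj_labels:
            raise GraphValidationError(f"{adjacency_path}: row/column labels disagree")
        if labels is None:
            labels = adj_labels
        elif set(adj_labels) != set(labels):
            raise GraphValidationError(f"{adjacency_path}: labels differ from attribute table")
        A = df.to_numpy(dtype=float)
        if not np.array_equal(A, A.T):
            raise GraphValidationError(f"{adjacency_path}: asymmetric adjacency matrix")
        # reorder to attribute-table order
        order = [adj_labels.index(v) for v in labels]
        A = A[np.ix_(order, order)]
        edges_idx = None
    else:
        pairs = _read_edge_list(edge_list_path, labels)
        if labels is None:
            labels = []
            for a, b in pairs:
                for v in (a, b):
                    if v not in labels:
                        labels.append(v)
        lut = {v: k for k, v in enumerate(labels)}
        edges_idx = []
        for a, b in pairs:
            if a not in lut or b not in lut:
                missing = a if a not in lut else b
                raise GraphValidationError(
                    f"{edge_list_path}: unknown node {missing!r} (not in attribute table)"
                )
            if a == b:
                raise GraphValidationError(f"{edge_list_path}: self-loop on node {a!r}")
            edges_idx.append((lut[a], lut[b]))
        A = np.zeros((len(labels), len(labels)), dtype=np.int8)
        seen = set()
        dups = 0
        for i, j in edges_idx:
            key = (min(i, j), max(i, j))
            if key in seen:
                dups += 1
                continue
            seen.add(key)
            A[i, j] = A[j, i] = 1
        if dups:
            logger.warning("%s: %d duplicate edge(s) collapsed", edge_list_path, dups)
            warnings.warn(f"{edge_list_path}: {dups} duplicate edge(s) collapsed", stacklevel=2)

    covs: dict[str, np.ndarray] = {}
    for name, p in (covariate_paths or {}).items():
        df = pd.read_csv(p, index_col=0)
        cov_labels = [str(v) for v in df.index]
        M = df.to_numpy(dtype=float)
        if not np.allclose(M[~np.eye(len(M), dtype=bool)], M.T[~np.eye(len(M), dtype=bool)]):
            raise GraphValidationError(f"{p}: asymmetric covariate matrix {name!r}")
        order = [cov_labels.index(v) for v in labels]
        covs[name] = M[np.ix_(order, order)]

    mask = None
    if mask_path is not None:
        mask = np.zeros((len(labels), len(labels)), dtype=np.int8)
        mdf = pd.read_csv(mask_path, dtype=str)
        lut = {v: k for k, v in enumerate(labels)}
        for a, b, state in mdf.itertuples(index=False):
            s = _MASK_STATES.get(str(state).strip())
            if s is None:
                raise GraphValidationError(f"{mask_path}: unknown mask state {state!r}")
            i, j = lut[str(a)], lut[str(b)]
            mask[i, j] = mask[j, i] = s

    return Graph(
        node_ids=labels,
        adjacency=A,
        vertex_attrs=attrs,
        dyad_covariates=covs,
        support_mask=mask,
    )


def write_graph(graph: Graph, directory, stem: str = "graph") -> dict[str, Path]:
    """Write a graph (edge list + attrs + covariates + mask) under ``directory``.

    Returns the mapping of written roles to paths; ``read_graph`` on these
    paths reproduces the graph exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ep = directory / f"{stem}_edges.csv"
    with ep.open("w") as fh:
        fh.write("from,to\n")
        for i, j in graph.edges():
            fh.write(f"{graph.node_ids[i]},{graph.node_ids[j]}\n")
    paths["edge_list"] = ep

    ap = directory / f"{stem}_attrs.csv"
    out = graph.vertex_attrs.reset_index()
    out.to_csv(ap, index=False)
    paths["attrs"] = ap

    for name, M in graph.dyad_covariates.items():
        cp = directory / f"{stem}_cov_{name}.csv"
        pd.DataFrame(M, index=graph.node_ids, columns=graph.node_ids).to_csv(cp)
        paths[f"cov:{name}"] = cp

    if np.any(graph.support_mask != FREE):
        mp = directory / f"{stem}_mask.csv"
        with mp.open("w") as fh:
            fh.write("from,to,state\n")
            iu = np.triu_indices(graph.n, k=1)
            for i, j in zip(*iu):
                s = graph.support_mask[i, j]
                if s != FREE:
                    fh.write(f"{graph.node_ids[i]},{graph.node_ids[j]},{_MASK_NAMES[s]}\n")
        paths["mask"] = mp
    return paths


def write_graph_set(gs: GraphSet, directory, stem: str = "set") -> Path:
    """Write a graph set plus a YAML manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    t = gs.template
    tpaths = write_graph(t, directory, stem=f"{stem}_template")
    manifest = {
        "template": {"attributes": tpaths["attrs"].name},
        "graphs": [],
    }
    covs = {k.split(":", 1)[1]: v.name for k, v in tpaths.items() if k.startswith("cov:")}
    if covs:
        manifest["template"]["covariates"] = covs
    if "mask" in tpaths:
        manifest["template"]["mask"] = tpaths["mask"].name
    for k, g in enumerate(gs.graphs):
        p = write_graph(g, directory, stem=f"{stem}_g{k}")["edge_list"]
        manifest["graphs"].append(p.name)
    mpath = directory / f"{stem}_manifest.yaml"
    with mpath.open("w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return mpath


def load_graph_set(manifest_path) -> GraphSet:
    """Load a graph set from a YAML manifest naming graph files + template."""
    manifest_path = Path(manifest_path)
    with manifest_path.open() as fh:
        manifest = yaml.safe_load(fh)
    base = manifest_path.parent
    tmpl = manifest.get("template", {}) or {}
    attr_path = base / tmpl["attributes"] if "attributes" in tmpl else None
    cov_paths = {k: base / v for k, v in (tmpl.get("covariates") or {}).items()}
    mask_path = base / tmpl["mask"] if tmpl.get("mask") else None
    files = manifest.get("graphs") or []
    if not files:
        raise GraphValidationError(f"{manifest_path}: manifest lists no graphs")
    graphs = []
    for k, f in enumerate(files, start=1):
        try:
            g = read_graph(
                edge_list_path=base / f,
                attr_path=attr_path,
                covariate_paths=cov_paths,
                mask_path=mask_path,
            )
        except GraphValidationError as exc:
            raise GraphValidationError(f"graph file {k} ({f}): {exc}") from exc
        graphs.append(g)
    return GraphSet(graphs)
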