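import numpy as np
import pandas as pd
import pytest

from ergmpool import Graph, ModelSpec, TermSpec


def random_graph(n, p, seed, with_attrs=True, with_cov=False, mask=None):
    """Erdos-Renyi test graph with optional attributes/covariate/mask."""
    rng = np.random.default_rng(seed)
    A = np.zeros((n, n), dtype=np.int8)
    iu = np.triu_indices(n, k=1)
    hit = rng.random(iu[0].size) < p
    A[iu[0][hit], iu[1][hit]] = 1
    A += A.T
    labels = [f"v{k}" for k in range(n)]
    attrs = None
    if with_attrs:
        attrs = pd.DataFrame(
            {
                "group": rng.choice(["A", "B"], size=n),
                "x": rng.normal(size=n).round(3),
            },
            index=labels,
        )
    covs = {}
    if with_cov:
        W = rng.normal(size=(n, n))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        covs["w"] = W
    if mask is not None:
        A = np.where(mask == 1, 1, A)
        A = np.where(mask == -1, 0, A)
    return Graph(node_ids=labels, adjacency=A, vertex_attrs=attrs,
                 dyad_covariates=covs, support_mask=mask)


@pytest.fixture
def empty5():
    return Graph(node_ids=list("abcde"), adjacency=np.zeros((5, 5), dtype=int))


@pytest.fixture
def triangle():
    A = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
    return Graph(node_ids=list("abc"), adjacency=A)


@pytest.fixture
def path3():
    """Path a-b-c with attributes (A, A, B)."""
    A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
    attrs = pd.DataFrame({"grp": ["A", "A", "B"]}, index=list("abc"))
    return Graph(node_ids=list("abc"), adjacency=A, vertex_attrs=attrs)


@pytest.fixture
def full_model():
    """One term of every attribute-free kind plus attribute terms."""
    return ModelSpec([
        TermSpec("edges"),
        TermSpec("nodematch", attribute="group"),
        TermSpec("nodemix", attribute="group"),
        TermSpec("nodecov", attribute="x"),
        TermSpec("twostars"),
        TermSpec("triangles"),
        TermSpec("gwesp", decay=0.5),
        TermSpec("graphlet1"),
    ])
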