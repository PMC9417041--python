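"""Conjugate-prior hyperparameter construction.

The default weakly informative prior shrinks towards the homogeneous
Bernoulli graph: given a prior expected mean degree d-bar, set
p = d-bar/(n-1) and take tau_bar as the mean statistics of (conditional)
Bernoulli(p) draws on the template -- Monte Carlo by default, analytic
closed forms where they are simple.  For protein structure networks, the
mean degree itself can be derived from molecular mass alone via empirical
surface-area models: a fully buried residue packs about 12 contacts, and
the fraction lost to solvent is the folded/unfolded surface-area ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .graph import FIXED_PRESENT, FREE, Graph, GraphSet, free_dyads
from .sampler import bernoulli_graph
from .terms import ModelSpec, mean_statistics, statistics

_DYAD_INDEPENDENT = {"edges", "nodematch", "nodemix", "nodecov", "edgecov"}


@dataclass
class ProteinPriorInputs:
    """Inputs for the surface-area mean-degree approximation.

    molecular_mass in Daltons; contacts_buried is the sphere-packing contact
    number of a fully buried residue (default 12).
    """

    molecular_mass: float
    contacts_buried: float = 12.0

    def __post_init__(self):
        if self.molecular_mass <= 0:
            raise ValueError("molecular mass must be positive")
        if self.contacts_buried <= 0:
            raise ValueError("contacts_buried must be positive")


def unfolded_surface_area(molecular_mass: float) -> float:
    """Empirical unfolded surface area A_u = 1.48 M + 21 (Angstrom^2)."""
    return 1.48 * molecular_mass + 21.0


def folded_surface_area(molecular_mass: float) -> float:
    """Empirical folded surface area A_f = 6.3 M^0.73 (Angstrom^2)."""
    return 6.3 * molecular_mass**0.73


def protein_mean_degree(inputs: ProteinPriorInputs) -> tuple[float, float, float, float]:
    """(A_u, A_f, d_bar, fraction_lost) from molecular mass.

    d_bar = contacts_buried * (1 - A_f/A_u): the buried-contact number
    discounted by the fraction of contact surface lost to solvent.
    """
    au = unfolded_surface_area(inputs.molecular_mass)
    af = folded_surface_area(inputs.molecular_mass)
    if af >= au:
        raise ValueError(
            "folded surface area >= unfolded surface area: mass outside the "
            "validity range of the empirical formulas"
        )
    frac_lost = af / au
    dbar = inputs.contacts_buried * (1.0 - frac_lost)
    return au, af, dbar, frac_lost


def bernoulli_edge_coefficient(mean_degree: float, n: int) -> float:
    """Edges coefficient of the Bernoulli graph with the given mean degree:
    logit(p) with p = d_bar/(n-1), i.e. log(d_bar / (n - d_bar - 1))."""
    if not 0 < mean_degree < n - 1:
        raise ValueError("mean_degree must be in (0, n-1)")
    return math.log(mean_degree / (n - mean_degree - 1))


def bernoulli_tau(
    model: ModelSpec,
    template: Graph,
    mean_degree: float,
    n_draws: int = 500,
    seed: int = 0,
    analytic: bool = False,
) -> np.ndarray:
    """Prior mean statistics tau_bar of the Bernoulli(p) graph, p = d_bar/(n-1).

    Monte Carlo mode (default) averages statistics over ``n_draws``
    conditional Bernoulli draws respecting the support mask -- exactly the
    construction used to centre the prior on the null model.  Analytic mode
    returns closed forms: exact per-dyad sums for dyad-independent terms
    (under any mask), and the unconstrained-template polynomials in p for
    2-stars / triangles / gwesp / graphlet1; dependence terms under support
    constraints fall back to Monte Carlo per term.
    """
    n = template.n
    if not 0 < mean_degree < n - 1:
        raise ValueError("mean_degree must be in (0, n-1)")
    p = mean_degree / (n - 1)
    model.validate(template)
    if not analytic:
        rng = np.random.default_rng(seed)
        acc = np.zeros(model.n_stats(template))
        for _ in range(n_draws):
            acc += statistics(model, bernoulli_graph(template, p, rng))
        return acc / n_draws

    constrained = bool(np.any(template.support_mask != FREE))
    mc_cache: np.ndarray | None = None

    def mc_column(stat_slice):
        nonlocal mc_cache
        if mc_cache is None:
            mc_cache = bernoulli_tau(model, template, mean_degree,
                                     n_draws=n_draws, seed=seed, analytic=False)
        return mc_cache[stat_slice]

    fd = free_dyads(template)
    iu = np.triu_indices(n, k=1)
    fixed = template.support_mask[iu] == FIXED_PRESENT
    # per-dyad edge probabilities: p on free dyads, 1 on fixed_present, 0 else
    P = np.zeros((n, n))
    P[fd[:, 0], fd[:, 1]] = p
    P[fd[:, 1], fd[:, 0]] = p
    fp = template.support_mask == FIXED_PRESENT
    P[fp] = 1.0

    out: list[float] = []
    off = 0
    for t in model.terms:
        if t.kind in _DYAD_INDEPENDENT:
            if t.kind == "edges":
                out.append(float(P[iu].sum()))
                off += 1
            elif t.kind == "nodematch":
                vals = template.vertex_attrs[t.attribute].astype(str).to_numpy()
                eq = vals[:, None] == vals[None, :]
                out.append(float((P[iu] * eq[iu]).sum()))
                off += 1
            elif t.kind == "nodemix":
                from .terms import _grouped_levels, _mix_cells

                codes, levels = _grouped_levels(t, template)
                cells, _ = _mix_cells(t, template)
                idx = {c: k for k, c in enumerate(cells)}
                counts = np.zeros(len(cells))
                for i, j in zip(*iu):
                    c = tuple(sorted((levels[codes[i]], levels[codes[j]])))
                    if c in idx:
                        counts[idx[c]] += P[i, j]
                out.extend(counts.tolist())
                off += len(cells)
            elif t.kind == "nodecov":
                x = template.vertex_attrs[t.attribute].astype(float).to_numpy()
                s = x[:, None] + x[None, :]
                out.append(float((P[iu] * s[iu]).sum()))
                off += 1
            else:  # edgecov
                W = template.dyad_covariates[t.covariate]
                out.append(float((P[iu] * W[iu]).sum()))
                off += 1
        elif not constrained and t.kind == "twostars":
            out.append(float(n * math.comb(n - 1, 2) * p**2))
            off += 1
        elif not constrained and t.kind == "triangles":
            out.append(float(math.comb(n, 3) * p**3))
            off += 1
        elif not constrained and t.kind == "graphlet1":
            # E[induced 2-paths] = 3 C(n,3) p^2 (1-p)
            out.append(float(3 * math.comb(n, 3) * p**2 * (1 - p)))
            off += 1
        elif not constrained and t.kind == "gwesp":
            # E sum over edges of w(esp); esp | edge ~ Binomial(n-2, p^2)
            k = np.arange(n - 1)
            from scipy.stats import binom

            pmf = binom.pmf(k, n - 2, p**2)
            from .terms import gwesp_weight

            ew = float((pmf * gwesp_weight(k, t.decay)).sum())
            out.append(float(math.comb(n, 2) * p * ew))
            off += 1
        else:
            # dependence term under support constraints: Monte Carlo per term
            width = 1
            out.extend(np.atleast_1d(mc_column(slice(off, off + width))).tolist())
            off += width
    return np.asarray(out, dtype=float)


def empirical_tau(model: ModelSpec, comparison: GraphSet) -> np.ndarray:
    """Informative tau_bar: mean statistics of a comparison graph set."""
    return mean_statistics(model, comparison)
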