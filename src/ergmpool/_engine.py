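"""Numba kernels: local change statistics and the Metropolis-Hastings chain.

These kernels are the hot path shared by the sampler and the moment-matching
fitter.  They operate on flat arrays produced by
:func:`ergmpool.terms.compile_model` and mutate the chain state (adjacency,
degrees, free-edge stack, running statistic vector) in place.

Term codes (must match ``ergmpool.terms.KIND_CODE``): 0 edges, 1 nodematch,
2 nodemix, 3 nodecov, 4 edgecov, 5 twostars, 6 triangles, 7 gwesp,
8 graphlet1.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _common_neighbors(A, i, j):
    n = A.shape[0]
    cn = 0
    for k in range(n):
        if A[i, k] == 1 and A[j, k] == 1:
            cn += 1
    return cn


@njit(cache=True)
def _esp(A, i, k):
    """Shared-partner count of the (i, k) pair in the current adjacency."""
    n = A.shape[0]
    s = 0
    for l in range(n):
        if A[i, l] == 1 and A[k, l] == 1:
            s += 1
    return s


@njit(cache=True)
def _gw(k, decay):
    return np.exp(decay) * (1.0 - (1.0 - np.exp(-decay)) ** k)


@njit(cache=True)
def add_delta(A, deg, i, j, kinds, offsets, decays, node_int, node_float, dyad, mix_idx, out):
    """Change in g from adding edge (i, j); requires A[i, j] == 0 on entry.

    Adds the delta into ``out`` (callers zero it first).
    """
    nterms = kinds.shape[0]
    cn = -1  # computed lazily, shared by triangle-family terms
    for t in range(nterms):
        kind = kinds[t]
        off = offsets[t]
        if kind == 0:  # edges
            out[off] += 1.0
        elif kind == 1:  # nodematch
            if node_int[t, i] == node_int[t, j]:
                out[off] += 1.0
        elif kind == 2:  # nodemix
            s = mix_idx[t, i, j]
            if s >= 0:
                out[s] += 1.0
        elif kind == 3:  # nodecov (sum form)
            out[off] += node_float[t, i] + node_float[t, j]
        elif kind == 4:  # edgecov
            out[off] += dyad[t, i, j]
        elif kind == 5:  # twostars
            out[off] += deg[i] + deg[j]
        elif kind == 6:  # triangles
            if cn < 0:
                cn = _common_neighbors(A, i, j)
            out[off] += cn
        elif kind == 7:  # gwesp
            if cn < 0:
                cn = _common_neighbors(A, i, j)
            d = decays[t]
            delta = _gw(cn, d)
            for k in range(A.shape[0]):
                if A[i, k] == 1 and A[j, k] == 1:
                    # edges (i,k) and (j,k) each gain one shared partner
                    eik = _esp(A, i, k)
                    ejk = _esp(A, j, k)
                    delta += _gw(eik + 1, d) - _gw(eik, d)
                    delta += _gw(ejk + 1, d) - _gw(ejk, d)
            out[off] += delta
        elif kind == 8:  # graphlet1 = twostars - 3 * triangles
            if cn < 0:
                cn = _common_neighbors(A, i, j)
            out[off] += deg[i] + deg[j] - 3.0 * cn


@njit(cache=True)
def run_chain(
    A, deg, fi, fj, estack, epos, ne_box,
    theta, kinds, offsets, decays, node_int, node_float, dyad, mix_idx,
    cur_stats, burn, thin, out_stats, tnt, seed,
):
    """Advance the MH dyad-toggle chain in place.

    Runs ``burn`` proposals, then (if ``out_stats`` has rows) records
    ``out_stats.shape[0]`` draws separated by ``thin`` proposals each.
    Proposals are uniform over free dyads, or tie/no-tie (``tnt``) with the
    exact Hastings correction.  Fixed dyads are never touched because only
    free dyads are enumerated in ``fi``/``fj``.  Returns accepted count.
    """
    np.random.seed(seed)
    Nd = fi.shape[0]
    p = cur_stats.shape[0]
    ndraws = out_stats.shape[0]
    delta = np.zeros(p)
    accepted = 0
    total = burn + ndraws * thin
    drawn = 0
    next_record = burn + thin if ndraws > 0 else -1
    for step in range(1, total + 1):
        ne = ne_box[0]
        if tnt == 1 and ne > 0 and np.random.random() < 0.5:
            d = estack[np.random.randint(ne)]
        else:
            d = np.random.randint(Nd)
        i = fi[d]
        j = fj[d]
        is_edge = A[i, j] == 1
        if is_edge:
            A[i, j] = 0
            A[j, i] = 0
            deg[i] -= 1
            deg[j] -= 1
        for q in range(p):
            delta[q] = 0.0
        add_delta(A, deg, i, j, kinds, offsets, decays, node_int, node_float, dyad, mix_idx, delta)
        lr = 0.0
        for q in range(p):
            lr += theta[q] * delta[q]
        if is_edge:
            lr = -lr
        if not np.isfinite(lr):
            raise ValueError("non-finite log acceptance ratio (theta * change-statistic)")
        if tnt == 1:
            # forward/reverse proposal probabilities for dyad d
            if is_edge:
                q_fwd = 0.5 / Nd + 0.5 / ne
                ne1 = ne - 1
                q_rev = 0.5 / Nd if ne1 > 0 else 1.0 / Nd
            else:
                q_fwd = 0.5 / Nd if ne > 0 else 1.0 / Nd
                q_rev = 0.5 / Nd + 0.5 / (ne + 1)
            lr += np.log(q_rev) - np.log(q_fwd)
        accept = lr >= 0.0 or np.random.random() < np.exp(lr)
        if accept:
            accepted += 1
            if is_edge:
                pos = epos[d]
                last = estack[ne - 1]
                estack[pos] = last
                epos[last] = pos
                epos[d] = -1
                ne_box[0] = ne - 1
                for q in range(p):
                    cur_stats[q] -= delta[q]
            else:
                A[i, j] = 1
                A[j, i] = 1
                deg[i] += 1
                deg[j] += 1
                estack[ne] = d
                epos[d] = ne
                ne_box[0] = ne + 1
                for q in range(p):
                    cur_stats[q] += delta[q]
        else:
            if is_edge:
                A[i, j] = 1
                A[j, i] = 1
                deg[i] += 1
                deg[j] += 1
        if step == next_record:
            for q in range(p):
                out_stats[drawn, q] = cur_stats[q]
            drawn += 1
            next_record = step + thin if drawn < ndraws else -1
    return accepted
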