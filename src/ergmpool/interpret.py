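"""Conditional log-odds interpretation of fitted ERGM coefficients.

An ERGM coefficient vector theta acts on the conditional log-odds of a
single dyad: logit P(Y_ij = 1 | rest) = theta' dg(i, j), where dg is the
change-statistic vector of that dyad.  These helpers evaluate such
conditional quantities for hand-specified configurations -- e.g. the edge
probability at a given covariate value, or the net effect of one more
shared partner under combined GWESP + triangle terms.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .terms import gwesp_weight


def conditional_log_odds(coefficients, change_stats) -> float:
    """theta' dg for a single dyad's change-statistic vector."""
    c = np.asarray(coefficients, dtype=float)
    d = np.asarray(change_stats, dtype=float)
    if c.shape != d.shape:
        raise ValueError("coefficients and change statistics differ in length")
    return float(c @ d)


def conditional_edge_probability(coefficients, change_stats) -> float:
    """Logistic conditional probability of an edge given the rest of the graph."""
    return float(expit(conditional_log_odds(coefficients, change_stats)))


def esp_transition_log_odds(
    gwesp_coef: float,
    decay: float,
    k: int,
    triangle_coef: float = 0.0,
) -> float:
    """Net conditional log-odds change for an edge going from k to k+1
    shared partners, combining the direct GWESP weight difference with the
    one triangle the new shared partner closes.

    The direct GWESP contribution of an edge with k shared partners is
    ``gwesp_coef * e^decay * (1 - (1 - e^-decay)^k)``; side-effects on the
    partner edges' own weights are deliberately excluded (this is the
    per-edge interpretation, not a full change statistic).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    dw = gwesp_weight(k + 1, decay) - gwesp_weight(k, decay)
    return float(gwesp_coef * dw + triangle_coef)
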