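# ergmpool

Scalable pooled maximum-likelihood and conjugate-Bayesian inference for
exponential-family random graph models (ERGMs) on *graph sets with
equivalent vertices* — collections of binary undirected networks observed
on one common labeled node set, such as brain functional-connectivity
networks across subjects or residue contact networks from replicated
protein crystal structures.

## The idea

An ERGM assigns a graph `y` probability

```
P_θ(Y = y) ∝ exp{ θᵀ g(y) }
```

where `g(y)` is a vector of p sufficient statistics (edge count,
homophily, geometrically weighted edgewise shared partners, …).  For m IID
draws `y¹,…,yᵐ` on the same node set, the joint log-likelihood depends on
the data *only through the mean statistic vector* `ḡ = (1/m) Σ g(yⁱ)`:

```
θ̂ = argmax_θ  θᵀ ḡ − ψ(θ),        Var θ̂ ≈ (1/m) I(θ̂)⁻¹
```

so pooled estimation costs exactly one single-graph fit, followed by a
1/m rescaling of the covariance (`I(θ) = Var_θ g(Y)`, the Fisher
information, estimated by simulation).  The same trick yields Bayesian
answers: a conjugate prior in the mean-value space — prior mean statistics
`τ̄` worth `n₀` pseudo-observations, relative weight `δ = n₀/(n₀+m)` —
makes the MAP estimate the single-graph fit to the blended target
`δ τ̄ + (1−δ) ḡ`, with Laplace posterior covariance `I⁻¹/(m+n₀)`.  Small
`δ` also acts as a regularizer that restores estimability when observed
statistics lie on the convex-hull boundary (e.g. a mixing cell with zero
observed edges, for which the MLE does not exist).

The package provides the full stack around this idea: a graph/graph-set
data model with support constraints (e.g. a fixed protein backbone),
a sufficient- and change-statistic engine, a Metropolis–Hastings tie/no-tie
sampler, a stochastic-approximation + Newton moment-matching fitter, prior
construction (Bernoulli-graph τ̄, surface-area protein mean-degree,
empirical τ̄), goodness-of-fit envelopes and graph-level indices, and
leave-one-out Hamming cross-validation for tuning `n₀`.

## Worked example

```python
import numpy as np
from ergmpool import (ModelSpec, TermSpec, FitConfig, ConjugatePrior,
                      pooled_mle, conjugate_map, bernoulli_tau)
from ergmpool.fixtures import fmhs_style_recipe, make_graph_set

# 20 IID graphs on 30 nodes from a known sparse 3-term model
recipe = fmhs_style_recipe(n=30, m=20, seed=7)
gs, truth = make_graph_set(recipe)

mle = pooled_mle(gs, recipe.model, FitConfig(seed=1))
print(truth["theta_true"].round(3))   # [-3.963  0.532  1.867]
print(mle.theta.round(3))             # [-3.695  0.616  1.623]
print(mle.se.round(3))                # [0.192  0.043  0.132]

# weakly informative Bernoulli prior at mean degree 2, delta = 0.005
tau = bernoulli_tau(recipe.model, gs.template, mean_degree=2.0, seed=2)
mp = conjugate_map(gs, recipe.model, ConjugatePrior(tau_bar=tau, n0=0.1),
                   FitConfig(seed=3))
print(round(mp.delta, 4))             # 0.005
print(mp.theta.round(3))              # [-3.651  0.619  1.592]
```

The pooled MLE recovers the generating coefficients to within about two
standard errors each (the residual is the sampling noise of a 20-graph
set), and the weakly weighted conjugate MAP shifts the estimate only
slightly toward the sparser Bernoulli prior — the behaviour expected of a
`δ = 0.005` prior.

A command-line interface mirrors the library
(`ergmpool fit|map|simulate|prior|cv|gof|make-fixtures`); see
`ergmpool --help` and `docs/methods.md` for the config schema.

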