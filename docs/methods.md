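# Methods

## Model and scope

`ergmpool` models sets of binary undirected graphs `y¹,…,yᵐ` on one common
labeled node set as IID draws from an exponential-family random graph
model (ERGM) with counting reference measure,

    P_θ(Y = y) ∝ exp{ θᵀ g(y) },

and performs inference entirely in the *mean-value space*: the pooled
log-likelihood depends on the data only through `ḡ = (1/m) Σᵢ g(yⁱ)`, so
the pooled MLE is the single-graph moment-matching solution of
`E_θ g(Y) = ḡ` with covariance `I(θ̂)⁻¹/m`, where `I(θ) = Var_θ g(Y)` is
the Fisher information.  A conjugate prior is parameterized by prior mean
statistics `τ̄` and pseudo-sample-size `n₀ > 0`; with relative weight
`δ = n₀/(n₀+m)` the MAP estimate solves `E_θ g(Y) = δτ̄ + (1−δ)ḡ`, and the
Laplace (Gaussian) posterior has covariance `I(θ̃)⁻¹/(m+n₀)`.  `n₀ = 0` is
accepted and routes to the MLE.

All graphs are binary, undirected, loop-free; the canonical map is the
identity (`η(θ) = θ` — no curved families, all GWESP decays are
user-fixed).  Directed/valued graphs, non-counting references,
missing-data EM, and hierarchical/mixture extensions are out of scope.

## Term suite

`edges`; `nodematch(attr)`; `nodemix(attr)` with optional level grouping
(declarative collapsing of small categories, e.g. to "Others") and an
excluded reference cell (first cell in sorted order unless specified);
`nodecov(attr)` in the additive form Σ_(i,j)∈E (xᵢ+xⱼ); `edgecov(w)`;
`twostars` = Σᵥ C(deg v, 2); `triangles`; `gwesp(φ)` with per-edge weight
`e^φ(1−(1−e^{−φ})^k)` for an edge whose endpoints share k partners; and
`graphlet1`, the count of induced 3-node paths.  `graphlet1` is computed
independently (common neighbours summed over non-adjacent pairs) so its
identity with `twostars − 3·triangles` serves as a genuine cross-check.
Statistics always count fixed-present edges; support constraints restrict
the sample space, not `g`.  GWNSP is not implemented (a registry extension
point); whether reference implementations count induced or non-induced
two-paths for graphlet statistics varies, so comparisons against other
software should check this convention.

Change statistics are computed locally in O(n) per dyad by numba kernels
and are the exact add-deltas used by the sampler, the MPLE design matrix,
and tests (change ≡ difference of full statistics is asserted over random
graphs).

## Sampling

Metropolis–Hastings single-dyad toggling over the free dyads only.  The
default proposal is tie/no-tie (TNT: with probability ½ a uniform free
dyad, otherwise a uniform current free edge, with the exact Hastings
correction), which mixes far better on sparse graphs; a uniform-dyad
proposal is retained for validation against exact enumeration (empirical
vs exact pmf total-variation distance on n ≤ 4 is part of the test suite).
Defaults scale with the free-dyad count Nd: burn-in 20·Nd proposals,
thinning 2·Nd (both overridable — production-scale runs on hundreds of
nodes warrant more).  One seeded generator per call; identical seed and
configuration reproduce the statistic matrix bitwise.

## Estimation

`fit_to_targets` solves `E_θ g(Y) = target` without ever evaluating the
log-partition function:

1. **Phase 1** — `phase1_draws` (default 100) draws at `θ_init` (MPLE by
   default, computed by a logistic fit of dyad states on change statistics
   via statsmodels; complete separation falls back to θ = 0 with a
   warning) estimate a diagonal scaling `D` of statistic variances.
2. **Phase 2** — Robbins–Monro subphases (default 4), gain
   `a_s = 0.1/2ˢ`, subphase length `50·2ˢ` updates of
   `θ ← θ + a_s D⁻¹(target − g(Y_t))` with per-coordinate steps clipped at
   0.3; θ is averaged over the second half of each subphase.
3. **Phase 3** — a chain of `phase3_draws` (default 600, thinned 2·Nd)
   at the current θ gives `Î = Var g(Y)` (sample covariance), and an
   autocorrelation-adjusted Hotelling T² test compares the simulated mean
   with the target; convergence requires p > 0.5.  On failure the fit
   takes a damped Newton step `θ ← θ + Î⁻¹(target − ḡ_sim)` (exact
   method-of-moments refinement, since `Var g` is the Jacobian `dμ/dθ` of
   an exponential family; steps are capped at Euclidean norm 0.5) and
   repeats phase 3, up to `max_restarts` (default 15) times.  Diagonal
   scaling alone stalls along strongly correlated statistic directions
   (edges vs GWESP); the Newton polish is what drives the simulated mean
   onto the target within Monte Carlo error.

The T² adjustment is our own choice (reference software applies an
unspecified MCMC error correction): the mean covariance is `Î·n_eff⁻¹`
with `n_eff` the minimum over coordinates of a Geyer
initial-positive-sequence effective sample size, and the statistic is
referred to an F(p, n_eff−p) distribution.  `n_eff` is reported in every
result rather than silently folded into the covariance.

**Convex-hull diagnosis** is bound-based (cheap necessary conditions, not
an LP membership test): statistics of the minimal graph (fixed edges only)
and maximal graph (all free dyads present) bracket every edge-monotone
statistic; sign-definite nodecov/edgecov terms are bracketed the same way;
sign-mixed covariates and `graphlet1` report "unknown".  Targets strictly
outside bounds raise immediately; `pooled_mle` raises a
`BoundaryTargetError` for on-boundary targets (the MLE does not exist) and
directs the user to conjugate MAP, which errors only if the *blended*
target is still on the boundary.  Non-convergence after all restarts
returns a flagged result rather than raising.  When `m` exceeds the
phase-3 effective sample size, a warning notes that Monte Carlo error may
dominate the reported statistical error.

## Prior construction

- **Bernoulli τ̄**: given prior mean degree d̄, set `p = d̄/(n−1)` and take
  τ̄ as the mean statistics of conditional Bernoulli(p) draws on the
  template (fixed-present dyads always tied, fixed-absent never) — Monte
  Carlo with 500 draws by default, matching how such priors are built in
  practice; analytic closed forms (exact per-dyad sums for
  dyad-independent terms under any mask; binomial/combinatorial forms for
  2-stars, triangles, gwesp, graphlet1 on unconstrained templates) are
  available mainly as test oracles.  Dependence terms under support
  constraints always fall back to Monte Carlo.
- **Edges coefficient**: `log(d̄/(n−d̄−1)) = logit(p)`, the natural
  parameter of the Bernoulli family the prior shrinks toward.
- **Protein mean degree**: from molecular mass M (Da), unfolded surface
  area `A_u = 1.48·M + 21` Å², folded `A_f = 6.3·M^0.73` Å², and
  `d̄ = c·(1 − A_f/A_u)` with `c = 12` buried contacts by default (sphere
  packing); errors if `A_f ≥ A_u` (outside the empirical formulas'
  validity).
- **Empirical τ̄**: mean statistics of a comparison graph set.

## Evaluation

Graph-level indices: transitivity `3·triangles / connected triples` (0
when no triples); population (ddof = 0) standard deviations of degrees,
k-core numbers, and M-eccentricity (a vertex's mean geodesic distance to
all others; unreachable pairs count as distance n, one more than any
possible geodesic — a documented, configurable convention, since reference
conventions differ).  Structure summaries: degree, edgewise-shared-partner
and geodesic distributions (with an unreachable bucket), and the 4-class
undirected triad census (empty / one-edge / two-path / triangle, by closed
form).  `gof_compare` wraps these in 95% simulation envelopes from either
fixed-θ or posterior-predictive draws.

Leave-one-out Hamming CV for `n₀`: for each grid value and held-out graph,
a conjugate MAP is refit on the remaining m−1 graphs (δ recomputed with
m−1, warm-started from the previous fit since estimates change little when
one graph is dropped), and the *mean over predictive draws of the squared
Hamming distance* over free dyads to the held-out graph is accumulated;
the selected n₀ minimizes the total, ties to the smaller value, and rows
with non-converged or boundary-failing fits are flagged and excluded.
Squaring per draw before averaging (mean-of-squares) is our reading of
"expected squared error"; squaring the averaged distance is the noted
alternative.

## Synthetic data

Fixture recipes generate templates (a binary categorical attribute with
stated proportions, optional standard-normal numeric attribute, optional
log-pairwise-distance covariate from a smooth random 3D chain, optional
fixed-present backbone) and draw each member graph from its own
independently seeded chain with 30·Nd burn-in, making IID-ness
unambiguous; a single thinned chain is available as an option.  The
protein template mimics a residue contact network's covariate structure
(backbone constraint, log Cα distances, size, polarity) without parsing
structure files.

The reference study conditions emulated at reduced scale are a sparse
3-term friendship model (edges + binary-attribute nodematch +
GWESP(0.25)) with truth θ₀ = (−5.885, 0.532, 1.867) on 205 nodes.  Desk
runs use n = 30 with the edges coefficient offset by +log(205/30) — the
sparse-graph size adjustment that approximately preserves mean degree —
and K = 200 replicates for the coverage study (nominal 95% Wald intervals
from the pooled MLE at m = 1; binomial error at K = 200 is ±0.046 at 3
SDs).  What passing shows: the pooling algebra, moment matching, and
interval construction are correctly calibrated under the model's own
assumptions.  What it does not show: robustness to the heterogeneity,
measurement error, and cross-graph dependence of real brain or protein
data, which violate the IID-equivalent-vertices assumption to varying
degrees.

## Numerical choices and limitations

- Wald/credible quantile fixed at 1.96; intervals are symmetric.
- `Î` pseudo-inverse is used wherever statistics are collinear or
  constant (with a warning), e.g. a nodemix cell with no realizable dyads.
- Coefficients are written at 6 significant digits, with a full-precision
  CSV sidecar; every CLI output records the seed.
- The Hotelling p > 0.5 criterion is strict; on hard targets (boundary
  proximity, tiny expected counts) expect several Newton restarts, and
  occasionally a flagged non-converged result that a larger
  `phase3_draws`/`max_restarts` resolves.
- Estimation cost is independent of m (the point of the method), but
  grows with n through the per-proposal change-statistic cost (O(n) for
  GWESP) and the Nd-scaled burn-in/thinning defaults.

## CLI config schema

```yaml
manifest: set_manifest.yaml      # graph-set manifest (template + graphs)
model:                           # ordered term list
  - {kind: edges}
  - {kind: nodematch, attribute: group}
  - {kind: gwesp, decay: 0.25}
prior:                           # map/cv only
  n0: 0.1
  tau: {source: bernoulli, mean_degree: 2.0, n_draws: 500}
       # or {source: empirical, manifest: comp.yaml} / {source: values, values: [...]}
fit: {phase3_draws: 600}         # optional FitConfig overrides
sampler: {proposal: tnt}         # optional SamplerConfig overrides (simulate)
theta: [-3.0, 0.5, 1.0]          # simulate/gof only
cv: {n0_grid: [0, 0.1, 1], n_sim: 100}
protein: {molecular_mass: 14300, n: 129}   # prior protein
```

Exit codes: 0 success, 2 config/validation error, 3 non-convergence.
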