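"""Pooled maximum likelihood and conjugate MAP inference for graph sets.

For m IID ERGM draws on one node set, the pooled log-likelihood depends on
the data only through the mean statistic vector g-bar, so the pooled MLE is
the single-graph fit to g-bar with the covariance rescaled by 1/m.  A
conjugate prior in the mean-value space -- prior mean statistics tau-bar
worth n0 pseudo-observations -- turns the same machinery into MAP
estimation: fit to the convex blend delta*tau_bar + (1-delta)*g_bar with
delta = n0/(n0+m), and rescale the covariance by 1/(m+n0).  The Laplace
approximation then gives a Gaussian posterior centred at the MAP with that
covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .fit import BoundaryTargetError, FitConfig, FitResult, convex_hull_check, fit_to_targets, mple
from .graph import Graph, GraphSet
from .sampler import SamplerConfig, SampleStats, simulate
from .terms import ModelSpec, mean_statistics

Z_95 = 1.959963984540054  # normal 0.975 quantile: Wald / credible intervals


@dataclass
class ConjugatePrior:
    """Mean-value conjugate prior: tau_bar pseudo-statistics, weight n0.

    n0 is the number of pseudo-observations (in units of graphs); n0 = 0 is
    permitted as the MLE limit.
    """

    tau_bar: np.ndarray
    n0: float

    def __post_init__(self):
        self.tau_bar = np.asarray(self.tau_bar, dtype=float)
        if not np.all(np.isfinite(self.tau_bar)):
            raise ValueError("tau_bar must be finite")
        if self.n0 < 0:
            raise ValueError("n0 must be >= 0")

    def delta(self, m: int) -> float:
        return self.n0 / (self.n0 + m)


@dataclass
class PooledResult:
    """Point estimate (MLE or MAP) with sample-size-corrected covariance."""

    theta: np.ndarray
    cov: np.ndarray            # I-hat^-1 / m  (MLE)  or  I-hat^-1 / (m + n0)  (MAP)
    delta: float
    m: int
    intervals: np.ndarray      # (p, 2) 95% Wald / credible bounds
    fit: FitResult
    kind: str = "mle"

    @property
    def names(self) -> list[str]:
        return self.fit.names

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def summary(self) -> "pd.DataFrame":
        import pandas as pd

        return pd.DataFrame(
            {
                "estimate": self.theta,
                "se": self.se,
                "ci_low": self.intervals[:, 0],
                "ci_high": self.intervals[:, 1],
            },
            index=self.names,
        )


def _wald(theta: np.ndarray, cov: np.ndarray) -> np.ndarray:
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return np.column_stack([theta - Z_95 * se, theta + Z_95 * se])


def _finish(fit: FitResult, weight: float, m: int, delta: float, kind: str) -> PooledResult:
    cov = fit.info_inv / weight
    if m > fit.n_eff:
        warnings.warn(
            f"m = {m} exceeds the phase-3 effective sample size ({fit.n_eff:.0f}); "
            "Monte Carlo error may dominate the reported statistical error"
        )
    return PooledResult(
        theta=fit.theta, cov=cov, delta=delta, m=m,
        intervals=_wald(fit.theta, cov), fit=fit, kind=kind,
    )


def pooled_mle(gs: GraphSet, model: ModelSpec, cfg: FitConfig = FitConfig(),
               theta_init=None) -> PooledResult:
    """Pooled MLE: fit to mean statistics, rescale covariance by 1/m.

    Raises :class:`BoundaryTargetError` when the mean statistics sit on the
    convex-hull boundary (the MLE does not exist; use conjugate MAP).
    """
    target = mean_statistics(model, gs)
    hull = convex_hull_check(target, model, gs.template)
    if hull.any_boundary:
        raise BoundaryTargetError(hull.recommendation)
    if theta_init is None:
        theta_init = mple(model, gs.template)
    fit = fit_to_targets(model, gs.template, target, cfg, theta_init=theta_init)
    return _finish(fit, weight=gs.m, m=gs.m, delta=0.0, kind="mle")


def conjugate_map(gs: GraphSet, model: ModelSpec, prior: ConjugatePrior,
                  cfg: FitConfig = FitConfig(), theta_init=None) -> PooledResult:
    """Conjugate MAP: fit to delta*tau_bar + (1-delta)*g_bar, covariance
    I-hat^-1 / (m + n0).  With n0 = 0 this is exactly the pooled MLE."""
    if prior.n0 == 0:
        return pooled_mle(gs, model, cfg, theta_init=theta_init)
    gbar = mean_statistics(model, gs)
    if prior.tau_bar.shape != gbar.shape:
        raise ValueError("tau_bar length does not match the model's statistic count")
    delta = prior.delta(gs.m)
    prior_hull = convex_hull_check(prior.tau_bar, model, gs.template)
    if prior_hull.any_boundary or prior_hull.any_outside:
        warnings.warn(f"prior tau_bar is not interior: {prior_hull.recommendation}")
    target = delta * prior.tau_bar + (1.0 - delta) * gbar
    hull = convex_hull_check(target, model, gs.template)
    if hull.any_boundary:
        raise BoundaryTargetError(
            "blended target still on the boundary (tau_bar itself is boundary): "
            + hull.recommendation
        )
    if theta_init is None:
        theta_init = mple(model, gs.template)
    fit = fit_to_targets(model, gs.template, target, cfg, theta_init=theta_init)
    return _finish(fit, weight=gs.m + prior.n0, m=gs.m, delta=delta, kind="map")


def laplace_posterior(res: PooledResult) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian (Laplace) posterior: mean theta, covariance I-hat^-1/(m+n0)."""
    if not res.fit.converged:
        warnings.warn("Laplace posterior from a non-converged fit")
    cov = res.cov
    eig = np.linalg.eigvalsh(cov)
    if eig.min() < -1e-10 * max(abs(eig.max()), 1.0):
        warnings.warn("posterior covariance not PSD; clipping negative eigenvalues")
        w, V = np.linalg.eigh(cov)
        cov = (V * np.clip(w, 0, None)) @ V.T
    return res.theta.copy(), cov


def sample_posterior(res: PooledResult, k: int, seed) -> np.ndarray:
    """k reproducible draws from the Laplace posterior (k x p matrix)."""
    mean, cov = laplace_posterior(res)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multivariate_normal(mean, cov, size=k, method="svd")


def posterior_predictive(
    res: PooledResult,
    model: ModelSpec,
    template: Graph,
    n_graph_draws: int,
    cfg: SamplerConfig = SamplerConfig(),
    seed: int = 0,
) -> SampleStats:
    """Graphs drawn as theta ~ Laplace posterior, then Y | theta ~ ERGM.

    Parameter uncertainty propagates into the predictive: each retained
    graph uses its own posterior coefficient draw.
    """
    rng = np.random.default_rng(seed)
    thetas = sample_posterior(res, n_graph_draws, rng)
    graphs = []
    stats_rows = []
    names = None
    for t in range(n_graph_draws):
        one = SamplerConfig(
            burn_in=cfg.burn_in, thin=cfg.thin, n_draws=1,
            seed=int(rng.integers(0, 2**31 - 1)), proposal=cfg.proposal,
        )
        out = simulate(model, thetas[t], template, one, return_graphs=True)
        graphs.append(out.graphs[0])
        stats_rows.append(out.stats[0])
        names = out.names
    return SampleStats(
        stats=np.asarray(stats_rows), names=names,
        final_graph=graphs[-1], graphs=graphs,
    )
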