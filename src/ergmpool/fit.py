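"""Moment-equation solver for ERGMs: find theta with E_theta g(Y) = target.

This is the engine behind both pooled maximum likelihood and conjugate MAP
estimation: because the log-partition function is intractable, theta is
found by Robbins-Monro stochastic approximation (Snijders-style method of
moments) rather than by evaluating the likelihood.  The scheme is:

phase 1   short simulation at theta_init to estimate a diagonal scaling
          matrix D (variances of the statistics);
phase 2   ``subphase_count`` subphases of updates
          theta <- theta + a_t D^-1 (target - g(Y_t)), with the gain a_t
          halved and the subphase length doubled at each subphase, and
          theta averaged over the second half of each subphase trajectory;
phase 3   a long chain at the current theta; its sample covariance is the
          estimated Fisher information I-hat = Var g(Y), and an
          autocorrelation-adjusted Hotelling T^2 test of the simulated mean
          against the target decides convergence (p > threshold).  On
          failure the fit restarts phase 3 after a damped Newton update
          theta <- theta + S^-1 (target - g-bar) -- exact method-of-moments
          refinement, since S = Var g is the Jacobian d mu / d theta of an
          exponential family -- up to ``max_restarts`` times.  Diagonal
          scaling alone stalls along strongly correlated statistic
          directions (e.g. edges vs GWESP); the Newton polish is what
          brings the simulated mean onto the target within Monte Carlo
          error.

The T^2 autocorrelation adjustment scales the mean covariance by
n / n_eff, where n_eff comes from a Geyer initial-positive-sequence
estimate per coordinate (the most conservative coordinate wins).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from . import _engine
from .graph import FIXED_PRESENT, Graph, free_dyads
from .sampler import ChainState, _spawn_seed
from .terms import ModelSpec, compile_model, statistics

_MONOTONE_KINDS = {"edges", "nodematch", "nodemix", "twostars", "triangles", "gwesp"}


class BoundaryTargetError(ValueError):
    """Target statistics on the convex-hull boundary: the MLE does not exist.

    Use conjugate MAP with a small prior weight delta to regularize.
    """


@dataclass
class FitConfig:
    """Stochastic-approximation settings (counts are draws, not toggles)."""

    phase1_draws: int = 100
    subphase_count: int = 4
    subphase_draws: int = 50   # base length; doubled at each subphase
    phase3_draws: int = 600
    initial_gain: float = 0.1
    hotelling_p_threshold: float = 0.5
    max_restarts: int = 15     # phase-3 Newton refinements
    seed: int = 0
    burn_in: int | None = None       # toggles; default 20 * Nd
    thin: int | None = None          # toggles between draws; default 2 * Nd
    rm_step_toggles: int | None = None  # toggles per RM update; default Nd
    proposal: str = "tnt"
    max_step: float = 0.3            # per-coordinate clip on RM updates

    def __post_init__(self):
        for name in ("phase1_draws", "subphase_count", "subphase_draws", "phase3_draws"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.hotelling_p_threshold < 1:
            raise ValueError("hotelling_p_threshold must be in (0, 1)")
        if self.initial_gain <= 0:
            raise ValueError("initial_gain must be positive")


@dataclass
class FitResult:
    """Moment-matching solution with simulated Fisher information."""

    theta: np.ndarray
    info: np.ndarray          # I-hat = Var_theta g(Y) from phase-3 draws
    converged: bool
    hotelling_p: float
    target: np.ndarray
    sim_mean: np.ndarray
    n_eff: float
    names: list[str]
    restarts: int = 0
    accept_rate: float = np.nan

    @property
    def info_inv(self) -> np.ndarray:
        """Pseudo-inverse of I-hat (tolerates collinear statistics)."""
        return np.linalg.pinv(self.info, hermitian=True)


def _change_matrix(graph: Graph, cm) -> tuple[np.ndarray, np.ndarray]:
    """Add-deltas for every free dyad (holding the rest of the graph fixed)."""
    fd = free_dyads(graph)
    A = graph.adjacency.copy()
    X = np.zeros((fd.shape[0], cm.p))
    y = np.zeros(fd.shape[0])
    deg = A.sum(axis=1).astype(np.int64)
    for d, (i, j) in enumerate(fd):
        had = A[i, j] == 1
        y[d] = had
        if had:
            A[i, j] = A[j, i] = 0
            deg[i] -= 1
            deg[j] -= 1
        _engine.add_delta(A, deg, int(i), int(j), cm.kinds, cm.offsets, cm.decays,
                          cm.node_int, cm.node_float, cm.dyad, cm.mix_idx, X[d])
        if had:
            A[i, j] = A[j, i] = 1
            deg[i] += 1
            deg[j] += 1
    return X, y


def mple(model: ModelSpec, graph: Graph) -> np.ndarray:
    """Maximum pseudo-likelihood estimate: logistic fit of dyad states on
    change statistics.  Used as an initializer; falls back to zeros with a
    warning under complete separation."""
    import statsmodels.api as sm

    cm = compile_model(model, graph)
    X, y = _change_matrix(graph, cm)
    if y.min() == y.max():
        warnings.warn("MPLE separation (all free dyads identical); using theta = 0")
        return np.zeros(cm.p)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        theta = np.asarray(res.params, dtype=float)
    except Exception:  # separation / singular design
        warnings.warn("MPLE did not converge; using theta = 0")
        return np.zeros(cm.p)
    if not np.all(np.isfinite(theta)) or np.max(np.abs(theta)) > 1e3:
        warnings.warn("MPLE separation detected; using theta = 0")
        return np.zeros(cm.p)
    return theta


@dataclass
class HullDiagnosis:
    """Per-statistic boundary diagnosis of a mean-value target."""

    names: list[str]
    status: list[str]          # below / boundary_low / interior / boundary_high / above / unknown
    lower: np.ndarray
    upper: np.ndarray

    @property
    def any_boundary(self) -> bool:
        return any(s.startswith("boundary") for s in self.status)

    @property
    def any_outside(self) -> bool:
        return any(s in {"below", "above"} for s in self.status)

    @property
    def recommendation(self) -> str:
        if self.any_outside:
            return "target is outside the achievable statistic range; check the data/model"
        if self.any_boundary:
            flagged = [n for n, s in zip(self.names, self.status) if s.startswith("boundary")]
            return (
                f"target on the convex-hull boundary ({', '.join(flagged)}); "
                "the MLE does not exist -- use conjugate MAP with a small delta"
            )
        return "target strictly inside simple bounds"


def convex_hull_check(target, model: ModelSpec, template: Graph) -> HullDiagnosis:
    """Cheap necessary boundary conditions for a mean-value target.

    Bounds are taken from the statistics of the minimal graph (fixed_present
    edges only) and the maximal graph (all free dyads filled), which bracket
    every monotone count statistic.  Sign-definite nodecov/edgecov terms are
    bracketed the same way; sign-mixed covariates and graphlet1 (which is
    not edge-monotone) report "unknown".
    """
    target = np.asarray(target, dtype=float)
    names = model.stat_names(template)
    if target.shape != (len(names),):
        raise ValueError(f"target has length {target.size}, model has {len(names)} statistics")
    n = template.n
    A_min = np.where(template.support_mask == FIXED_PRESENT, 1, 0).astype(np.int8)
    np.fill_diagonal(A_min, 0)
    A_max = 1 - np.eye(n, dtype=np.int8)
    fa = template.support_mask == -1
    A_max[fa] = 0
    g_min = statistics(model, template.with_adjacency(A_min))
    g_max = statistics(model, template.with_adjacency(A_max))

    # which coordinates are monotone in added edges?
    monotone = []
    for t in model.terms:
        width = 1
        if t.kind == "nodemix":
            from .terms import _mix_cells

            width = len(_mix_cells(t, template)[0])
        if t.kind in _MONOTONE_KINDS:
            monotone.extend([True] * width)
        elif t.kind == "nodecov":
            x = template.vertex_attrs[t.attribute].astype(float).to_numpy()
            monotone.append(bool(np.all(x >= 0) or np.all(x <= 0)))
        elif t.kind == "edgecov":
            W = template.dyad_covariates[t.covariate]
            off = ~np.eye(n, dtype=bool)
            monotone.append(bool(np.all(W[off] >= 0) or np.all(W[off] <= 0)))
        else:  # graphlet1
            monotone.append(False)

    lower = np.minimum(g_min, g_max)
    upper = np.maximum(g_min, g_max)
    status = []
    for k in range(len(names)):
        if not monotone[k]:
            status.append("unknown")
            continue
        lo, hi = lower[k], upper[k]
        tol = 1e-9 * max(1.0, abs(hi - lo))
        if target[k] < lo - tol:
            status.append("below")
        elif target[k] > hi + tol:
            status.append("above")
        elif target[k] <= lo + tol:
            status.append("boundary_low")
        elif target[k] >= hi - tol:
            status.append("boundary_high")
        else:
            status.append("interior")
    return HullDiagnosis(names=names, status=status, lower=lower, upper=upper)


def effective_sample_size(draws: np.ndarray) -> float:
    """Minimum-over-coordinates ESS by Geyer's initial positive sequence."""
    draws = np.asarray(draws, dtype=float)
    n, p = draws.shape
    ess = float(n)
    for k in range(p):
        x = draws[:, k] - draws[:, k].mean()
        v = x @ x / n
        if v <= 0:
            continue  # constant statistic carries no autocorrelation information
        # FFT autocovariance
        m = 1 << (2 * n - 1).bit_length()
        f = np.fft.rfft(x, m)
        acov = np.fft.irfft(f * np.conjugate(f), m)[:n].real / n
        rho = acov / acov[0]
        tau = 1.0
        t = 1
        while t + 1 < n:
            pair = rho[t] + rho[t + 1]
            if pair < 0:
                break
            tau += 2.0 * pair
            t += 2
        ess = min(ess, n / max(tau, 1.0))
    return max(ess, 4.0)


def _hotelling_pvalue(draws: np.ndarray, target: np.ndarray) -> tuple[float, float]:
    """Autocorrelation-adjusted T^2 p-value of mean(draws) vs target."""
    n, p = draws.shape
    neff = effective_sample_size(draws)
    diff = draws.mean(axis=0) - target
    S = np.cov(draws, rowvar=False).reshape(p, p)
    S_mean = S / neff
    t2 = float(diff @ np.linalg.pinv(S_mean, hermitian=True) @ diff)
    dof = max(neff - p, 1.0)
    fstat = t2 * dof / (p * max(neff - 1.0, 1.0))
    pval = float(sps.f.sf(fstat, p, dof))
    return pval, neff


def fit_to_targets(
    model: ModelSpec,
    template: Graph,
    target,
    cfg: FitConfig = FitConfig(),
    theta_init=None,
) -> FitResult:
    """Solve E_theta g(Y) = target by stochastic approximation.

    ``template`` supplies the node set, attributes, covariates, support
    mask, and the chain's starting adjacency.  Raises ValueError when the
    target is outside the achievable statistic bounds; targets *on* the
    boundary are the caller's concern (see :class:`BoundaryTargetError`).
    """
    cm = compile_model(model, template)
    target = np.asarray(target, dtype=float)
    if target.shape != (cm.p,):
        raise ValueError(f"target has length {target.size}, model has {cm.p} statistics")
    hull = convex_hull_check(target, model, template)
    if hull.any_outside:
        raise ValueError(hull.recommendation)

    rng = np.random.default_rng(cfg.seed)
    theta = np.zeros(cm.p) if theta_init is None else np.asarray(theta_init, dtype=float).copy()
    state = ChainState(template, cm)
    Nd = state.n_free
    burn = cfg.burn_in if cfg.burn_in is not None else 20 * Nd
    thin = cfg.thin if cfg.thin is not None else max(1, 2 * Nd)
    step_toggles = cfg.rm_step_toggles if cfg.rm_step_toggles is not None else Nd

    # phase 1: scaling matrix from statistic variances at theta_init
    draws, _ = state.run(theta, burn, thin, cfg.phase1_draws, cfg.proposal, _spawn_seed(rng))
    D = draws.var(axis=0, ddof=1)
    D = np.where(D > 1e-8, D, np.nanmax([np.max(D), 1.0]))

    # phase 2: Robbins-Monro subphases with halving gain, doubling length
    for s in range(cfg.subphase_count):
        a = cfg.initial_gain / (2.0**s)
        length = cfg.subphase_draws * 2**s
        trail = []
        for _ in range(length):
            state.run(theta, step_toggles, 1, 0, cfg.proposal, _spawn_seed(rng))
            step = a * (target - state.cur_stats) / D
            np.clip(step, -cfg.max_step, cfg.max_step, out=step)
            theta = theta + step
            trail.append(theta)
        trail = np.asarray(trail)
        theta = trail[len(trail) // 2:].mean(axis=0)

    # phase 3: sample, test, and Newton-refine until the simulated mean
    # matches the target within Monte Carlo error
    pval, neff, info, sim_mean, acc = np.nan, np.nan, None, None, np.nan
    restarts = 0
    converged = False
    p3_burn = cfg.burn_in if cfg.burn_in is not None else 10 * Nd
    while True:
        draws, acc_n = state.run(theta, p3_burn, thin, cfg.phase3_draws, cfg.proposal,
                                 _spawn_seed(rng))
        acc = acc_n / (p3_burn + cfg.phase3_draws * thin)
        info = np.cov(draws, rowvar=False).reshape(cm.p, cm.p)
        sim_mean = draws.mean(axis=0)
        pval, neff = _hotelling_pvalue(draws, target)
        if pval > cfg.hotelling_p_threshold:
            converged = True
            break
        if restarts >= cfg.max_restarts:
            warnings.warn(
                f"moment matching did not converge after {restarts} restarts "
                f"(Hotelling p = {pval:.3g})"
            )
            break
        step = np.linalg.pinv(info, hermitian=True) @ (target - sim_mean)
        norm = np.linalg.norm(step)
        if norm > 0.5:
            step *= 0.5 / norm
        theta = theta + step
        restarts += 1

    return FitResult(
        theta=theta,
        info=info,
        converged=converged,
        hotelling_p=pval,
        target=target,
        sim_mean=sim_mean,
        n_eff=neff,
        names=cm.names,
        restarts=restarts,
        accept_rate=acc,
    )


def fisher_information(model: ModelSpec, theta, template: Graph,
                       cfg: FitConfig = FitConfig()) -> np.ndarray:
    """Simulated Fisher information I(theta) = Var_theta g(Y)."""
    cm = compile_model(model, template)
    state = ChainState(template, cm)
    Nd = state.n_free
    burn = cfg.burn_in if cfg.burn_in is not None else 20 * Nd
    thin = cfg.thin if cfg.thin is not None else max(1, 2 * Nd)
    rng = np.random.default_rng(cfg.seed)
    draws, _ = state.run(np.asarray(theta, dtype=float), burn, thin, cfg.phase3_draws,
                         cfg.proposal, _spawn_seed(rng))
    info = np.cov(draws, rowvar=False).reshape(cm.p, cm.p)
    eig = np.linalg.eigvalsh(info)
    if eig.min() <= 1e-10 * max(eig.max(), 1.0):
        warnings.warn(
            "Fisher information is rank-deficient (collinear or constant statistics); "
            "downstream covariances use the pseudo-inverse"
        )
    return info
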