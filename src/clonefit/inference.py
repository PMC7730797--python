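"""Mean-field variational inference for the over-complete finite mixture.

Generative model for N mutations in M samples with K mixture components:

    pi | alpha        ~ Dirichlet(alpha 1_K)
    z_i | pi          ~ Categorical(pi)
    phi_kj            ~ Discrete(uniform over the CCF grid)
    b_ij | z_i=k, phi ~ h(. | phi_kj, theta_ij)

K is set larger than the number of clones expected; surplus components end
up unoccupied, so model selection happens inside a single fit.  The
variational posterior factorizes as q(pi | kappa) prod_i q(z_i | rho_i)
prod_kj q(phi_kj | gamma_kj) and is optimized by coordinate ascent on the
evidence lower bound (ELBO).  All emission terms come from the precomputed
:class:`~clonefit.emissions.LogLikCache`, so one sweep costs
O(N K M (F+1)).  The ELBO must be non-decreasing across sweeps — a decrease
beyond numerical slack signals an implementation bug and raises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln, logsumexp, xlogy

from .data import CCFGrid, Dataset
from .emissions import EmissionConfig, LogLikCache, build_loglik_cache

__all__ = [
    "FitConfig",
    "VariationalParams",
    "FitResult",
    "ElboDecreaseError",
    "init_responsibilities",
    "update_kappa",
    "update_rho",
    "update_gamma",
    "compute_elbo",
    "fit_single",
    "fit",
    "assign_clusters",
    "cluster_ccf_estimates",
]

#: tolerated numerical slack for the monotone-ELBO diagnostic
ELBO_SLACK = 1e-6

_NORM_TOL = 1e-8


class ElboDecreaseError(RuntimeError):
    """The ELBO decreased beyond numerical slack: a correctness canary."""


@dataclass(frozen=True)
class FitConfig:
    """Settings of one variational fit.

    ``K`` should exceed the number of clones expected in the data; ``alpha``
    weakly controls how many components get used (values below one favour
    fewer).  Convergence is declared when the relative ELBO change
    ``|dELBO| / (|ELBO| + 1)`` drops below ``elbo_rel_tol``.
    """

    K: int
    alpha: float = 1.0
    max_iters: int = 10_000
    elbo_rel_tol: float = 1e-6
    num_restarts: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")
        if self.max_iters < 1 or self.num_restarts < 1:
            raise ValueError("max_iters and num_restarts must be >= 1")
        if not self.elbo_rel_tol > 0:
            raise ValueError("elbo_rel_tol must be > 0")


@dataclass
class VariationalParams:
    """Variational parameters: kappa (K,), rho (N, K), gamma (K, M, G)."""

    kappa: np.ndarray
    rho: np.ndarray
    gamma: np.ndarray

    def validate(self) -> None:
        if np.any(self.kappa <= 0):
            raise ValueError("kappa must be positive")
        if np.max(np.abs(self.rho.sum(axis=1) - 1.0)) > _NORM_TOL:
            raise ValueError("rho rows must sum to 1")
        if np.max(np.abs(self.gamma.sum(axis=2) - 1.0)) > _NORM_TOL:
            raise ValueError("gamma (k, j) slices must sum to 1")


@dataclass
class FitResult:
    """Best-restart variational fit plus MAP post-processing.

    ``labels`` are MAP cluster assignments relabelled to consecutive ids
    0..num_clones-1 in order of decreasing cluster size;
    ``label_components[c]`` gives the original mixture-component index of
    relabelled cluster ``c``.  ``cluster_ccf_mean``/``std`` are posterior
    moments of phi_kj for every component (K x M, original indexing).
    """

    params: VariationalParams
    elbo_trace: np.ndarray
    best_elbo: float
    labels: np.ndarray
    label_components: np.ndarray
    cluster_ccf_mean: np.ndarray
    cluster_ccf_std: np.ndarray
    num_clones: int
    seed_used: int

    @property
    def mutation_ccf_mean(self) -> np.ndarray:
        """(N, M) posterior-mean CCF of each mutation's assigned cluster."""
        return self.cluster_ccf_mean[self.label_components[self.labels]]

    @property
    def mutation_ccf_std(self) -> np.ndarray:
        return self.cluster_ccf_std[self.label_components[self.labels]]

    @property
    def assignment_prob(self) -> np.ndarray:
        """(N,) probability of each mutation's MAP cluster assignment."""
        return self.params.rho.max(axis=1)


def init_responsibilities(N: int, K: int, rng: np.random.Generator) -> np.ndarray:
    """Random responsibilities: each row a flat-Dirichlet draw over K."""
    if N < 1 or K < 1:
        raise ValueError("N and K must be >= 1")
    if K == 1:
        return np.ones((N, 1))
    return rng.dirichlet(np.ones(K), size=N)


def update_kappa(alpha: float, rho: np.ndarray) -> np.ndarray:
    """kappa_k = alpha + sum_i rho_ik."""
    return alpha + rho.sum(axis=0)


def _expected_loglik(gamma: np.ndarray, cache: LogLikCache) -> np.ndarray:
    """(N, K) array of sum_jf gamma_kjf * log h_ijf."""
    return np.einsum("kjf,ijf->ik", gamma, cache.values)


def update_rho(kappa: np.ndarray, gamma: np.ndarray,
               cache: LogLikCache) -> np.ndarray:
    """Responsibility update, normalized per mutation with a log-sum-exp."""
    log_rho = digamma(kappa) - digamma(kappa.sum())
    log_rho = log_rho[None, :] + _expected_loglik(gamma, cache)
    if not np.all(np.isfinite(log_rho)):
        raise FloatingPointError("non-finite unnormalized log responsibility")
    return np.exp(log_rho - logsumexp(log_rho, axis=1, keepdims=True))


def update_gamma(rho: np.ndarray, cache: LogLikCache) -> np.ndarray:
    """Grid-posterior update, normalized per (component, sample) slice.

    The prior mass over the grid is uniform, so it drops out of the
    normalization; emissions are evaluated at the grid CCFs f/F.
    """
    log_gamma = np.einsum("ik,ijf->kjf", rho, cache.values)
    if not np.all(np.isfinite(log_gamma)):
        raise FloatingPointError("non-finite unnormalized log grid posterior")
    return np.exp(log_gamma - logsumexp(log_gamma, axis=2, keepdims=True))


def compute_elbo(params: VariationalParams, cache: LogLikCache,
                 alpha: float) -> float:
    """Evidence lower bound E_q[log p(X, pi, z, phi)] - E_q[log q].

    Assembled from the Dirichlet prior/posterior terms for pi (via digamma
    expectations of log pi), the categorical terms for z, the discrete
    terms for phi against its uniform grid prior, and the cached expected
    log emission.
    """
    kappa, rho, gamma = params.kappa, params.rho, params.gamma
    K = kappa.shape[0]
    G = gamma.shape[2]

    elog_pi = digamma(kappa) - digamma(kappa.sum())
    # E[log p(pi)] - E[log q(pi)]
    log_c_prior = gammaln(K * alpha) - K * gammaln(alpha)
    log_c_post = gammaln(kappa.sum()) - gammaln(kappa).sum()
    elbo = log_c_prior - log_c_post + np.dot(alpha - kappa, elog_pi)
    # E[log p(z | pi)] - E[log q(z)]
    elbo += float(rho.sum(axis=0) @ elog_pi) - float(xlogy(rho, rho).sum())
    # E[log p(phi)] - E[log q(phi)]; the prior over the grid is uniform
    elbo += -np.log(G) * gamma.shape[0] * gamma.shape[1]
    elbo -= float(xlogy(gamma, gamma).sum())
    # E[log p(b | z, phi)]
    elbo += float(np.einsum("ik,ik->", rho, _expected_loglik(gamma, cache)))
    if not np.isfinite(elbo):
        raise FloatingPointError("non-finite ELBO")
    return float(elbo)


def fit_single(cache: LogLikCache, config: FitConfig,
               restart_seed: int) -> tuple[VariationalParams, np.ndarray]:
    """One coordinate-ascent run from a random start.

    Sweep order kappa -> gamma -> rho, ELBO recorded after each full sweep.
    Iterates until the relative ELBO change falls below ``elbo_rel_tol`` or
    ``max_iters`` sweeps.  Raises :class:`ElboDecreaseError` if the trace
    decreases by more than the numerical slack.
    """
    rng = np.random.default_rng(restart_seed)
    N = cache.n_mutations
    rho = init_responsibilities(N, config.K, rng)

    trace: list[float] = []
    for _ in range(config.max_iters):
        kappa = update_kappa(config.alpha, rho)
        gamma = update_gamma(rho, cache)
        rho = update_rho(kappa, gamma, cache)
        elbo = compute_elbo(
            VariationalParams(kappa=kappa, rho=rho, gamma=gamma), cache,
            config.alpha,
        )
        if trace and elbo < trace[-1] - ELBO_SLACK:
            raise ElboDecreaseError(
                f"ELBO decreased from {trace[-1]:.8f} to {elbo:.8f}"
            )
        converged = bool(trace) and (
            abs(elbo - trace[-1]) / (abs(elbo) + 1.0) < config.elbo_rel_tol
        )
        trace.append(elbo)
        if converged:
            break
    params = VariationalParams(kappa=kappa, rho=rho, gamma=gamma)
    params.validate()
    return params, np.asarray(trace)


def assign_clusters(rho: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """MAP labels, relabelled 0..num_clones-1 by decreasing cluster size.

    Ties in the argmax go to the lowest component index; size ties keep the
    original component order.  Returns ``(labels, label_components)`` where
    ``label_components[c]`` is the original component index of cluster c.
    """
    raw = rho.argmax(axis=1)
    used, counts = np.unique(raw, return_counts=True)
    order = np.lexsort((used, -counts))
    label_components = used[order]
    remap = {int(comp): new for new, comp in enumerate(label_components)}
    labels = np.array([remap[int(c)] for c in raw], dtype=np.int64)
    return labels, label_components


def cluster_ccf_estimates(gamma: np.ndarray,
                          grid: CCFGrid) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and standard deviation of phi_kj under gamma."""
    values = grid.values
    mean = gamma @ values
    second = gamma @ values**2
    var = np.maximum(second - mean**2, 0.0)
    return mean, np.sqrt(var)


def _restart_seed(seed: int, restart: int) -> np.random.SeedSequence:
    # counter-based derivation: restart r gets an independent stream, so
    # results are identical whether restarts run serially or in parallel
    return np.random.SeedSequence(entropy=seed, spawn_key=(restart,))


def _run_restart(cache, config, r):
    seq = _restart_seed(config.seed, r)
    seed_used = int(seq.generate_state(1)[0] % (2**31))
    params, trace = fit_single(cache, config, seed_used)
    return params, trace, seed_used


def fit(
    dataset: Dataset,
    emission_config: EmissionConfig,
    fit_config: FitConfig,
    *,
    cache: LogLikCache | None = None,
    num_threads: int = 1,
    progress=None,
) -> FitResult:
    """Fit the mixture with random restarts and keep the best ELBO.

    ``progress``, if given, is called with ``(restart_index, final_elbo)``
    after each restart.  Ties in final ELBO go to the lowest restart index.
    """
    if cache is None:
        cache = build_loglik_cache(dataset, emission_config)

    runs = []
    if num_threads > 1:
        from joblib import Parallel, delayed

        runs = Parallel(n_jobs=num_threads)(
            delayed(_run_restart)(cache, fit_config, r)
            for r in range(fit_config.num_restarts)
        )
        if progress is not None:
            for r, (_, trace, _) in enumerate(runs):
                progress(r, trace[-1])
    else:
        for r in range(fit_config.num_restarts):
            run = _run_restart(cache, fit_config, r)
            runs.append(run)
            if progress is not None:
                progress(r, run[1][-1])

    best = max(range(len(runs)), key=lambda r: (runs[r][1][-1], -r))
    params, trace, seed_used = runs[best]

    labels, label_components = assign_clusters(params.rho)
    mean, std = cluster_ccf_estimates(params.gamma, emission_config.grid)
    return FitResult(
        params=params,
        elbo_trace=trace,
        best_elbo=float(trace[-1]),
        labels=labels,
        label_components=label_components,
        cluster_ccf_mean=mean,
        cluster_ccf_std=std,
        num_clones=int(len(label_components)),
        seed_used=seed_used,
    )
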