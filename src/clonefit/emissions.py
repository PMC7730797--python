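"""Allele-count emission densities and the precomputed log-likelihood cache.

The observed variant read count b of a mutation in a sample is modelled as
Binomial (or over-dispersed Beta-Binomial) with success probability equal to
the expected VAF xi.  xi is obtained by mixing three cell populations at a
locus: contaminating normal cells (copy number c_N, variant reads only from
sequencing error), malignant cells not carrying the mutation (copy number
c_T, error only), and malignant cells carrying the mutation on m of their
c_T copies.  The CCF phi is the fraction of malignant cells in the third
population.  Because the genotype (m) is not observed, the emission density
marginalizes over the candidate genotype states with their prior weights.

CCFs live on a finite uniform grid, so the log emission density of every
(mutation, sample, grid point) triple can be evaluated once up front and
cached; model fitting then never touches the raw counts again.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, gammaln, logsumexp, xlog1py, xlogy

from .data import CCFGrid, Dataset, GenotypeState, MutationObservation

__all__ = [
    "EmissionConfig",
    "LogLikCache",
    "expected_vaf",
    "log_binomial_pmf",
    "log_beta_binomial_pmf",
    "log_emission",
    "build_loglik_cache",
]

#: clipping bound keeping xi inside (0, 1) so log-pmfs stay finite
VAF_CLIP = 1e-10

DENSITIES = ("binomial", "beta-binomial")
DEFAULT_PRECISION = 200.0


@dataclass(frozen=True)
class EmissionConfig:
    """Choice of emission density, its fixed precision, and the CCF grid.

    ``precision`` is the Beta-Binomial precision (shape parameters are
    ``xi * precision`` and ``(1 - xi) * precision``); it is fixed, never
    estimated, which is what makes the log-likelihood cache valid.  It is
    ignored for the plain Binomial.
    """

    grid: CCFGrid
    density: str = "beta-binomial"
    precision: float = DEFAULT_PRECISION

    def __post_init__(self) -> None:
        if self.density not in DENSITIES:
            raise ValueError(
                f"density must be one of {DENSITIES}, got {self.density!r}"
            )
        if self.density == "beta-binomial" and not self.precision > 0:
            raise ValueError("Beta-Binomial precision must be > 0")


@dataclass(frozen=True)
class LogLikCache:
    """Immutable (N, M, F+1) array of cached log emission densities."""

    values: np.ndarray = field(compare=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 3:
            raise ValueError("cache must be a 3-d (N, M, grid) array")
        vals = vals.copy()
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    @property
    def n_mutations(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_grid(self) -> int:
        return self.values.shape[2]


def expected_vaf(ccf, state: GenotypeState, tumour_content, error_rate,
                 clip: float = VAF_CLIP):
    """Expected variant allele frequency at CCF ``ccf`` for one genotype state.

    xi = [(1-t) c_N eps + t (1-phi) c_T eps + t phi m]
         / [(1-t) c_N + t c_T]

    i.e. copy-number-weighted mixing of normal cells, malignant reference
    cells and malignant variant cells (the latter contributing their m
    variant copies).  The result is clipped to [clip, 1 - clip].  Accepts
    scalar or array ``ccf``/``tumour_content``/``error_rate``.
    """
    phi = np.asarray(ccf, dtype=float)
    t = np.asarray(tumour_content, dtype=float)
    eps = np.asarray(error_rate, dtype=float)
    c_n, c_t, m = state.normal_cn, state.tumour_cn, state.multiplicity
    if c_t < 1:
        raise ValueError("tumour copy number must be >= 1")
    denom = (1.0 - t) * c_n + t * c_t
    if np.any(denom <= 0):
        raise ValueError("population copy number mixture has zero total mass")
    num = (1.0 - t) * c_n * eps + t * (1.0 - phi) * c_t * eps + t * phi * m
    xi = np.clip(num / denom, clip, 1.0 - clip)
    if xi.ndim == 0:
        return float(xi)
    return xi


def log_binomial_pmf(b, d, xi):
    """Log Binomial(b | d, xi) via log-gamma functions; vectorized."""
    b = np.asarray(b, dtype=float)
    d = np.asarray(d, dtype=float)
    xi = np.asarray(xi, dtype=float)
    if np.any(b < 0) or np.any(b > d):
        raise ValueError("need 0 <= b <= d")
    out = (
        gammaln(d + 1) - gammaln(b + 1) - gammaln(d - b + 1)
        + xlogy(b, xi) + xlog1py(d - b, -xi)
    )
    if out.ndim == 0:
        return float(out)
    return out


def log_beta_binomial_pmf(b, d, xi, precision):
    """Log Beta-Binomial(b | d, a=xi*precision, b'=(1-xi)*precision)."""
    b = np.asarray(b, dtype=float)
    d = np.asarray(d, dtype=float)
    xi = np.asarray(xi, dtype=float)
    if np.any(b < 0) or np.any(b > d):
        raise ValueError("need 0 <= b <= d")
    if not np.all(np.asarray(precision) > 0):
        raise ValueError("precision must be > 0")
    a1 = xi * precision
    a2 = (1.0 - xi) * precision
    out = (
        gammaln(d + 1) - gammaln(b + 1) - gammaln(d - b + 1)
        + betaln(b + a1, d - b + a2) - betaln(a1, a2)
    )
    if out.ndim == 0:
        return float(out)
    return out


def _log_pmf(b, d, xi, config: EmissionConfig):
    if config.density == "binomial":
        return log_binomial_pmf(b, d, xi)
    return log_beta_binomial_pmf(b, d, xi, config.precision)


def log_emission(obs: MutationObservation, ccf: float,
                 config: EmissionConfig) -> float:
    """Log emission density of one observation at one CCF value.

    Marginalizes the chosen pmf over the genotype states of the observation
    with a log-sum-exp:  log sum_s w_s pmf(b | d, xi(ccf, s)).
    """
    from .data import build_genotype_states

    states = build_genotype_states(
        int(obs.major_cn), int(obs.minor_cn), obs.normal_cn
    )
    terms = [
        np.log(s.prior_weight)
        + _log_pmf(
            obs.alt_count, obs.depth,
            expected_vaf(ccf, s, obs.tumour_content, obs.error_rate),
            config,
        )
        for s in states
    ]
    return float(logsumexp(terms))


def build_loglik_cache(dataset: Dataset, config: EmissionConfig) -> LogLikCache:
    """Evaluate the log emission density on the whole CCF grid, vectorized.

    Requires a filtered dataset (all copy numbers present, major_cn >= 1).
    Raises on any non-finite entry, naming the offending triple.
    """
    major = dataset.major_cn
    if np.any(np.isnan(major)) or np.any(np.isnan(dataset.minor_cn)):
        raise ValueError("dataset contains missing copy numbers; filter first")
    if np.any(major < 1):
        raise ValueError("dataset contains major_cn < 1 mutations; filter first")

    grid = config.grid.values  # (G,)
    b = dataset.alt[..., None]          # (N, M, 1)
    d = dataset.depth[..., None]
    t = dataset.tumour_content[..., None]
    eps = dataset.error_rate[..., None]
    c_n = dataset.normal_cn[..., None].astype(float)
    c_t = dataset.total_cn[..., None]
    phi = grid[None, None, :]

    denom = (1.0 - t) * c_n + t * c_t
    max_mult = int(major.max())
    shape = (dataset.n_mutations, dataset.n_samples, grid.size)
    state_logs = np.full((max_mult,) + shape, -np.inf)
    # weights (2, 1, ..., 1)/(major+1): the late-event hypothesis folds into
    # the multiplicity-1 state (see data.build_genotype_states)
    log_norm = -np.log(major + 1.0)[..., None]
    for m in range(1, max_mult + 1):
        valid = (major >= m)[..., None]
        log_weight = log_norm + (np.log(2.0) if m == 1 else 0.0)
        num = (1.0 - t) * c_n * eps + t * (1.0 - phi) * c_t * eps + t * phi * m
        xi = np.clip(num / denom, VAF_CLIP, 1.0 - VAF_CLIP)
        logpmf = _log_pmf(b, d, xi, config)
        state_logs[m - 1] = np.where(valid, log_weight + logpmf, -np.inf)

    values = logsumexp(state_logs, axis=0)
    if not np.all(np.isfinite(values)):
        i, j, f = np.argwhere(~np.isfinite(values))[0]
        raise FloatingPointError(
            "non-finite log emission for "
            f"(mutation {dataset.mutation_ids[i]}, sample {dataset.sample_ids[j]}, "
            f"grid point {grid[f]:.4f})"
        )
    return LogLikCache(values=values)
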