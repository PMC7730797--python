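"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.special import gammaln, logsumexp

from clonefit.data import Dataset
from clonefit.emissions import expected_vaf
from clonefit.data import GenotypeState
from clonefit.simulate import _sample_genotype


def brute_force_log_evidence(cache_values: np.ndarray, K: int,
                             alpha: float) -> float:
    """Exact log marginal likelihood by enumeration over assignments.

    Sums over all K^N assignment vectors z.  Given z, the grid value of
    each (component, sample) integrates out independently against its
    uniform prior, and the mixture weights integrate out to a
    Dirichlet-multinomial term.  Only feasible for tiny N and K.
    """
    N, M, G = cache_values.shape
    log_terms = []
    log_b_alpha = gammaln(K * alpha) - K * gammaln(alpha)
    for z in itertools.product(range(K), repeat=N):
        z = np.asarray(z)
        counts = np.bincount(z, minlength=K)
        log_pz = (
            log_b_alpha
            + gammaln(alpha + counts).sum() - gammaln(K * alpha + N)
        )
        log_px_given_z = 0.0
        for k in range(K):
            members = cache_values[z == k]  # (n_k, M, G)
            per_sample = members.sum(axis=0)  # (M, G)
            log_px_given_z += (logsumexp(per_sample, axis=1) - np.log(G)).sum()
        log_terms.append(log_pz + log_px_given_z)
    return float(logsumexp(log_terms))


def make_clustered_dataset(
    labels: np.ndarray,
    ccf: np.ndarray,
    *,
    mean_depth: float = 100.0,
    tumour_content: float = 1.0,
    total_cn_range: tuple[int, int] = (1, 4),
    error_rate: float = 1e-3,
    seed: int = 0,
) -> tuple[Dataset, np.ndarray]:
    """Simulate read counts for a prescribed clustering and CCF matrix.

    Follows the same generative steps as the simulator but with the
    clustering and cluster CCFs fixed, which lets tests place clones at
    chosen separations.  Returns the dataset and the true per-mutation CCF.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    ccf = np.atleast_2d(np.asarray(ccf, dtype=float))
    n, m = len(labels), ccf.shape[1]
    tc = np.full(m, tumour_content)

    major = np.empty(n, dtype=np.int64)
    minor = np.empty(n, dtype=np.int64)
    vaf = np.empty((n, m))
    for i in range(n):
        total = int(rng.integers(total_cn_range[0], total_cn_range[1] + 1))
        major[i], minor[i], mult, _ = _sample_genotype(total, rng)
        state = GenotypeState(normal_cn=2, tumour_cn=int(major[i] + minor[i]),
                              multiplicity=int(mult), prior_weight=1.0)
        vaf[i] = expected_vaf(ccf[labels[i]], state, tc, error_rate, clip=0.0)

    depth = rng.poisson(mean_depth, size=(n, m))
    while np.any(depth == 0):
        zero = depth == 0
        depth[zero] = rng.poisson(mean_depth, size=int(zero.sum()))
    alt = rng.binomial(depth, vaf)
    dataset = Dataset(
        mutation_ids=[f"m{i}" for i in range(n)],
        sample_ids=[f"S{j + 1}" for j in range(m)],
        alt=alt.astype(np.int64),
        ref=(depth - alt).astype(np.int64),
        major_cn=np.tile(major[:, None], (1, m)).astype(float),
        minor_cn=np.tile(minor[:, None], (1, m)).astype(float),
        normal_cn=np.full((n, m), 2, dtype=np.int64),
        tumour_content=np.tile(tc, (n, 1)),
        error_rate=np.full((n, m), error_rate),
    )
    return dataset, ccf[labels]


@pytest.fixture
def two_clone_dataset():
    """100 mutations in two well-separated clones (CCF 0.2 / 0.9), deep reads.

    Diploid loci only: amplified loci admit (multiplicity, CCF) combinations
    that are genuinely ambiguous between distant CCFs, which is a property
    of the model, not of the separation being tested here.
    """
    labels = np.repeat([0, 1], 50)
    ccf = np.array([[0.2, 0.2], [0.9, 0.9]])
    dataset, true_ccf = make_clustered_dataset(
        labels, ccf, mean_depth=1000.0, total_cn_range=(2, 2), seed=42
    )
    return dataset, labels, true_ccf
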