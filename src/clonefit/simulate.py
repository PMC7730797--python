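"""Generative simulator for multi-sample SNV read-count data.

Ground truth is built top-down: mutations are clustered by a Chinese
restaurant process (the marginal clustering of a Dirichlet process), each
cluster receives a CCF per sample drawn uniformly on [0, 1], each mutation
receives a locus copy-number profile and a genotype, and reads are drawn
Binomially at the expected VAF given all of the above.  Genotypes follow the
early/late dichotomy: a late mutation arises after any copy-number change
and sits on a single chromosome copy (multiplicity 1); an early mutation
predates the change and sits on every copy of the major or minor allele
(multiplicity = major or minor copy number).

Optionally the expected VAF can be perturbed uniformly within +/- epsilon
before reads are drawn, emulating mis-specification of the VAF model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import Dataset, GenotypeState
from .emissions import expected_vaf

__all__ = [
    "SimConfig",
    "GroundTruth",
    "sample_clustering_crp",
    "perturb_vaf",
    "sample_dataset",
    "write_ground_truth",
    "benchmark_configs",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults mirror the multi-sample benchmark protocol: 4 samples, CRP
    concentration 1.0, total copy number uniform on 1..4, Poisson(100)
    depth.  ``tumour_content`` may be a single value applied to every
    sample or a ``(low, high)`` interval sampled per sample.
    ``vaf_perturbation`` is the half-width epsilon of the uniform VAF
    perturbation (0 disables it); ``sequencing_error`` is the per-base
    error rate written to the output table and used in the VAF model.
    """

    num_mutations: int
    num_samples: int = 4
    concentration: float = 1.0
    mean_depth: float = 100.0
    tumour_content: float | tuple[float, float] = 1.0
    total_cn_range: tuple[int, int] = (1, 4)
    sequencing_error: float = 1e-3
    vaf_perturbation: float = 0.0
    shared_ccf: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_mutations < 1 or self.num_samples < 1:
            raise ValueError("need at least one mutation and one sample")
        if not self.concentration > 0:
            raise ValueError("concentration must be > 0")
        if not self.mean_depth > 0:
            raise ValueError("mean_depth must be > 0")
        lo, hi = self.total_cn_range
        if lo < 1 or hi < lo:
            raise ValueError("total_cn_range must satisfy 1 <= low <= high")
        tc = self.tumour_content
        vals = (tc,) if np.isscalar(tc) else tuple(tc)
        if any(not 0.0 <= v <= 1.0 for v in vals):
            raise ValueError("tumour_content values must lie in [0, 1]")
        if self.vaf_perturbation < 0:
            raise ValueError("vaf_perturbation must be >= 0")


@dataclass
class GroundTruth:
    """True clustering and CCFs underlying one simulated dataset."""

    labels: np.ndarray            # (N,) cluster id per mutation
    ccf: np.ndarray               # (num_clusters, M)
    multiplicity: np.ndarray      # (N,)
    is_early: np.ndarray          # (N,) bool
    expected_vaf_true: np.ndarray  # (N, M), before perturbation

    @property
    def num_clusters(self) -> int:
        return self.ccf.shape[0]

    @property
    def mutation_ccf(self) -> np.ndarray:
        """(N, M) true CCF of each mutation."""
        return self.ccf[self.labels]


def sample_clustering_crp(n: int, concentration: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Chinese restaurant process clustering of ``n`` items.

    Item i (0-based) joins an existing cluster c with probability
    n_c / (i + concentration) and opens a new cluster with probability
    concentration / (i + concentration).  Labels are in order of first
    appearance.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    labels = np.zeros(n, dtype=np.int64)
    counts = [1]
    for i in range(1, n):
        probs = np.array(counts + [concentration]) / (i + concentration)
        choice = rng.choice(len(probs), p=probs)
        if choice == len(counts):
            counts.append(1)
        else:
            counts[choice] += 1
        labels[i] = choice
    return labels


def perturb_vaf(f, epsilon: float, rng: np.random.Generator):
    """Uniform draw on [max(0, f - eps), min(1, f + eps)]; vectorized."""
    f = np.asarray(f, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("f must lie in [0, 1]")
    if epsilon == 0:
        return f.copy() if f.ndim else float(f)
    lo = np.maximum(0.0, f - epsilon)
    hi = np.minimum(1.0, f + epsilon)
    out = rng.uniform(lo, hi)
    return out if f.ndim else float(out)


def _sample_genotype(total_cn: int, rng: np.random.Generator
                     ) -> tuple[int, int, int, bool]:
    """Draw (major, minor, multiplicity, is_early) for one locus."""
    major = int(rng.integers((total_cn + 1) // 2, total_cn + 1))
    minor = total_cn - major
    early = bool(rng.integers(2))
    if early:
        options = [major] + ([minor] if minor > 0 else [])
        mult = int(options[rng.integers(len(options))])
    else:
        mult = 1
    return major, minor, mult, early


def sample_dataset(config: SimConfig,
                   rng: np.random.Generator | None = None
                   ) -> tuple[Dataset, GroundTruth]:
    """Simulate one dataset with its ground truth.

    Zero-depth Poisson draws are resampled so every observation carries at
    least one read.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, m = config.num_mutations, config.num_samples

    labels = sample_clustering_crp(n, config.concentration, rng)
    num_clusters = int(labels.max()) + 1
    if config.shared_ccf:
        ccf = np.tile(rng.uniform(0.0, 1.0, size=(num_clusters, 1)), (1, m))
    else:
        ccf = rng.uniform(0.0, 1.0, size=(num_clusters, m))

    if np.isscalar(config.tumour_content):
        tumour_content = np.full(m, float(config.tumour_content))
    else:
        lo, hi = config.tumour_content
        tumour_content = rng.uniform(lo, hi, size=m)

    lo_cn, hi_cn = config.total_cn_range
    major = np.empty(n, dtype=np.int64)
    minor = np.empty(n, dtype=np.int64)
    mult = np.empty(n, dtype=np.int64)
    early = np.empty(n, dtype=bool)
    for i in range(n):
        total = int(rng.integers(lo_cn, hi_cn + 1))
        major[i], minor[i], mult[i], early[i] = _sample_genotype(total, rng)

    vaf_true = np.empty((n, m))
    for i in range(n):
        state = GenotypeState(
            normal_cn=2, tumour_cn=int(major[i] + minor[i]),
            multiplicity=int(mult[i]), prior_weight=1.0,
        )
        vaf_true[i] = expected_vaf(
            ccf[labels[i]], state, tumour_content, config.sequencing_error,
            clip=0.0,
        )

    vaf_obs = perturb_vaf(vaf_true, config.vaf_perturbation, rng)

    depth = rng.poisson(config.mean_depth, size=(n, m))
    while np.any(depth == 0):
        zero = depth == 0
        depth[zero] = rng.poisson(config.mean_depth, size=int(zero.sum()))
    alt = rng.binomial(depth, vaf_obs)

    width = len(str(n))
    dataset = Dataset(
        mutation_ids=[f"m{i:0{width}d}" for i in range(n)],
        sample_ids=[f"S{j + 1}" for j in range(m)],
        alt=alt.astype(np.int64),
        ref=(depth - alt).astype(np.int64),
        major_cn=np.tile(major[:, None], (1, m)).astype(float),
        minor_cn=np.tile(minor[:, None], (1, m)).astype(float),
        normal_cn=np.full((n, m), 2, dtype=np.int64),
        tumour_content=np.tile(tumour_content, (n, 1)),
        error_rate=np.full((n, m), config.sequencing_error),
    )
    truth = GroundTruth(
        labels=labels, ccf=ccf, multiplicity=mult, is_early=early,
        expected_vaf_true=vaf_true,
    )
    return dataset, truth


def write_ground_truth(truth: GroundTruth, dataset: Dataset, path) -> None:
    """Write ground truth as a long TSV keyed by (mutation_id, sample_id)."""
    n, m = truth.expected_vaf_true.shape
    frame = pd.DataFrame({
        "mutation_id": np.repeat(dataset.mutation_ids, m),
        "sample_id": np.tile(dataset.sample_ids, n),
        "true_cluster": np.repeat(truth.labels, m),
        "true_ccf": truth.mutation_ccf.reshape(-1),
    })
    frame.to_csv(path, sep="\t", index=False)


def benchmark_configs(
    mutation_counts: tuple[int, ...] = (50, 100, 1000),
    repetitions: int = 100,
    seed: int = 0,
    **overrides,
):
    """Yield SimConfigs for the accuracy benchmark protocol.

    The protocol crosses mutation counts {50, 100, 1000} with 100
    repetitions each (300 datasets), 4 samples at tumour content 1.0, CRP
    concentration 1.0, total copy number 1..4 and Poisson(100) depth.
    """
    counter = 0
    for num_mutations in mutation_counts:
        for _ in range(repetitions):
            yield SimConfig(
                num_mutations=num_mutations,
                seed=seed + counter,
                **overrides,
            )
            counter += 1
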