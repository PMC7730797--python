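# Methods

## Problem and model

`clonefit` deconvolves bulk tumour sequencing data into clonal populations
using only SNV read counts plus per-locus context. Each mutation `i` has an
observation in every sample `j`: variant count `b_ij`, total depth `d_ij`,
major/minor tumour copy number, normal copy number `c_N` (default 2),
tumour content `t_j` and a per-base error rate `e` (default 1e-3). The
model assumes:

- **Shared CCF within a cluster.** Mutations in one cluster have the same
  cancer cell fraction `phi_kj` in every sample. Clusters are exchangeable;
  no phylogeny is inferred.
- **Gridded CCFs.** `phi` takes values on the uniform grid
  `{0, 1/F, ..., 1}` with `F + 1` points. The default `F = 100` resolves
  CCFs to within 0.01, which matches what 50–1000x sequencing can support;
  the resolution is a parameter (`--num-grid-points` = `F + 1`).
- **Clonal copy number.** The copy-number profile of a locus is the same in
  all malignant cells (sub-clonal CNVs are out of scope) and in all
  samples of a patient.
- **Finite over-complete mixture.** A Dirichlet prior
  `pi ~ Dir(alpha 1_K)` with `alpha = 1` and `K` set generously (default
  40) replaces an infinite clustering prior. Coordinate-ascent variational
  inference leaves surplus components unoccupied, so the number of clones
  is selected within a single fit rather than by sweeping `K`.

### Emission density

The expected VAF at CCF `phi` for a genotype state with multiplicity `m`
is the copy-number-weighted mixture of three populations (normal,
malignant-reference, malignant-variant):

```
xi = [ (1-t) c_N e + t (1-phi) c_T e + t phi m ] / [ (1-t) c_N + t c_T ]
```

`xi` is clipped to `[1e-10, 1 - 1e-10]` so that log-pmfs stay finite at
`phi = 0` with `e = 0`; the clip is far below read-count resolution.
Counts follow either `Binomial(d, xi)` or `BetaBinomial(d, xi*beta,
(1-xi)*beta)` with a fixed precision `beta` (default 200). `beta` is a
convention, not an estimate: fixing it (together with the grid) is what
allows the log emission of every (mutation, sample, grid point) triple to
be precomputed once, which is the source of the method's speed. The
Beta-Binomial converges to the Binomial as `beta -> inf` (tested).

### Genotype-state elicitation

The multiplicity `m` of a mutation is unobserved. For a locus with major
copy number `M >= 1` the candidate hypotheses are: the mutation arose
*before* the copy-number change on 1..M copies (M states), or *after* it on
a single copy (one further state). All `M + 1` hypotheses get equal prior
mass; under the shared VAF formula the post-change state coincides with the
`m = 1` pre-change state, so the implementation folds them into weights
`(2, 1, ..., 1) / (M + 1)` over `m = 1..M`. The emission marginalizes the
states by log-sum-exp.

This down-weighting of high multiplicities is load-bearing. With a uniform
prior over `m = 1..M` alone, a cluster of single-copy mutations at
amplified loci can be re-explained wholesale at multiplicity `m' > 1` and
CCF `phi/m'` — the likelihood is nearly identical in *every* sample, so the
mixture happily splits true clusters into scaled-down ghosts. On the
4-sample benchmark below, the uniform rule yields median V-measure ≈ 0.75;
the `(2,1,...,1)` rule ≈ 0.94 with mean |CCF error| 0.014.

Mutations whose copy number is missing (`NA`, `.` or empty in the input),
or with major or total copy number zero in any sample, admit no valid
state and are removed from all samples before fitting (reported in the
removal report; the filter is idempotent).

## Inference

Mean-field factorization `q(pi|kappa) prod_i q(z_i|rho_i) prod_kj
q(phi_kj|gamma_kj)` with closed-form updates:

```
kappa_k   = alpha + sum_i rho_ik
rho_ik    ∝ exp( psi(kappa_k) - psi(sum kappa) + sum_jf gamma_kjf L_ijf )
gamma_kjf ∝ exp( sum_i rho_ik L_ijf )            (uniform grid prior)
```

where `L_ijf` is the cached log emission and `psi` the digamma function.
Numerical choices:

- **Sweep order** kappa → gamma → rho, ELBO evaluated after the full sweep.
  Any fixed order is valid coordinate ascent; fixing one makes traces
  reproducible.
- **Normalization** of rho rows and gamma slices by log-sum-exp.
- **Initialization**: rho rows drawn from a flat Dirichlet.
- **Convergence**: `|dELBO| / (|ELBO| + 1) < 1e-6`, at most 10,000 sweeps.
- **Correctness canary**: the ELBO must be non-decreasing; a drop beyond
  1e-6 raises an error rather than being papered over. The ELBO is
  assembled from the Dirichlet cross-entropy terms for `pi` (via digamma
  expectations), the categorical terms for `z`, the discrete terms for
  `phi` against the uniform grid prior, and the cached expected log
  emission. Its closed form is validated two independent ways in the test
  suite: it equals the exact log evidence when the variational family
  contains the posterior (`K = 1`), and it never exceeds the log evidence
  computed by exhaustive enumeration over all assignments on tiny
  instances (Dirichlet-multinomial marginal for `z`, independent grid
  integration per component and sample).
- **Restarts**: seeds are derived from the top-level seed by a counter
  scheme (`SeedSequence(seed, spawn_key=(r,))`), so results are identical
  whether restarts run serially or in parallel (`--num-threads`, via
  joblib). Best final ELBO wins; ties go to the lowest restart index.
- **Degenerate inputs**: `N < K` is allowed (surplus clusters stay empty);
  a one-point grid and `K = 1` collapse to exact computations.

Post-processing: MAP labels `argmax_k rho_ik` (ties to the lowest index),
relabelled consecutively by decreasing cluster size; cluster CCF point
estimate is the posterior mean under `gamma` with its standard deviation
reported alongside. Posterior means are preferred to the grid argmax
because they minimize expected absolute error and vary smoothly; note that
variational posteriors underestimate variance, so the reported std is a
lower bound on the real uncertainty and the assignment probabilities are
over-confident. Users needing calibrated uncertainty should treat only the
point estimates as reliable.

## Synthetic-data generator

`simulate.sample_dataset` reproduces the benchmark protocol used throughout
the tests:

1. Cluster mutations by a Chinese restaurant process with concentration
   1.0 (expected cluster count for 100 mutations ≈ 5.2).
2. Draw each cluster's CCF per sample from Uniform[0, 1], independently
   across samples (a `shared_ccf` option ties them; independent draws match
   a product-of-uniforms base measure).
3. Per mutation: total copy number uniform on 1..4 (configurable); major
   copy number uniform over the admissible splits `{ceil(total/2)..total}`,
   minor = total − major.
4. Genotype: with probability 1/2 the mutation is a *late* event
   (multiplicity 1), otherwise an *early* event on the major or minor
   allele (multiplicity = that allele's copy number, chosen uniformly among
   the valid options). The 1/2 split is a choice of convention; the
   protocol specifies only the dichotomy.
5. Expected VAF from the emission formula with the sample's tumour content
   (fixed at 1.0 by default, or drawn per sample from a given interval)
   and sequencing error 1e-3.
6. Optional mis-specification noise: the VAF is redrawn uniformly from
   `[max(0, f - eps), min(1, f + eps)]`.
7. Depth ~ Poisson(100) (zero depths resampled, a slight deviation from a
   pure Poisson that keeps every observation informative),
   `alt ~ Binomial(depth, VAF)`.

What the generator does **not** emulate: sub-clonal or sample-varying copy
number, mis-called copy number, correlated errors along the genome,
strand/mapping artefacts, or tree-constrained CCFs. Passing the recovery
benchmarks therefore demonstrates correctness of the inference machinery
under the model's own assumptions, not robustness to the ways real
copy-number calls fail.

## Benchmarks in the test suite

Problem sizes are scaled to keep the whole suite fast while leaving the
generative conditions (4 samples, 100 mutations, Poisson(100) depth,
copy number 1–4, concentration 1.0) untouched; fits use `K = 10` and
10–20 restarts:

- 10 replicates at tumour content 1.0: median V-measure ≥ 0.9 and mean
  absolute CCF error ≤ 0.05.
- Accuracy falls as tumour content drops (1.0 → 0.2), falls as VAF
  perturbation grows (0 → 0.1), and rises with more samples (1 → 8).
- Mean absolute CCF error shrinks as depth grows (100x → 1000x).
- Two well-separated clones (CCF 0.2/0.9, 1000x, diploid loci) are
  recovered exactly (V-measure 1.0, CCFs within two grid spacings); with
  `K = 10` the fit occupies exactly 2 components.

## Known limitations

- Variational posteriors are over-confident (see above); no credible
  intervals are reported.
- Multiplicity/CCF combinations can be genuinely unidentifiable at
  amplified loci (e.g. `m = c_T` at CCF `phi` versus `m = 1` at
  `phi * c_T`-ish); the genotype prior mitigates but cannot remove this.
- The grid bounds CCF resolution at `1/(2F)`; deeply sequenced small
  panels may warrant a finer grid or a continuous-CCF method.
- One copy-number profile per mutation across samples; loci with
  sample-discordant copy number should be pre-filtered or given their
  worst-case call.
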