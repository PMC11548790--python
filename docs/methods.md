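# Methods

This note documents the statistical model, the sampling algorithms, the
design generators, the synthetic-data generator, and the numerical and
design choices behind `sparsemet`.

## Model

The response is the adjusted phenotype (BLUE) `y_ij` of line `j`
(`j = 1..J`) in environment `i` (`i = 1..I`):

```
y_ij = μ + L_i + g_j + gL_ij + ε_ij
```

* `μ` — grand mean, flat prior.
* `L = (L_1..L_I)' ~ N(0, σ²_E Ω_E)` — environment effects; `Ω_E` is the
  environment covariance kernel.
* `g = (g_1..g_J)' ~ N(0, σ²_g G)` — additive line effects; `G` is the
  VanRaden genomic relationship matrix built from centered SNP dosages.
  The posterior means of `g` are the GEBVs.
* `gL ~ N(0, σ²_gL (Z_g G Z_g') ∘ (Z_E Ω_E Z_E'))` — genotype-by-
  environment interaction with the Hadamard-product kernel; over the full
  `J × I` grid (environment-major order) this kernel is the Kronecker
  product `Ω_E ⊗ G`, which is positive semidefinite whenever both factors
  are (Schur product theorem).
* `ε_ij ~ iid N(0, σ²_ε)`.

Throughout the package `i` indexes environments and `j` lines; every
effect vector is keyed to explicit identifier lists, never to positional
convention.

### Environment-kernel constructions

Six method tags select `Ω_E`:

| tag            | Ω_E                                   |
|----------------|----------------------------------------|
| GBLUP          | identity                               |
| GBLUP_CE       | first-stage genetic covariance Ω̂      |
| GBLUP_CE_Abs   | elementwise \|Ω̂\|                     |
| GBLUP_CE_mean  | (Ω̂ + R̂)/2                            |
| GBLUP_CE_Res   | first-stage residual covariance R̂     |
| GBLUP_TRN      | identity (no cell-level prediction)    |

Ω̂ and R̂ come from a first-stage multi-response fit of the wide `J × I`
table `Y = 1μ' + U + E`, where rows of `U` are matrix-normal with row
covariance `G` and column covariance Ω (unstructured), and rows of `E` are
i.i.d. `N(0, R)`. Both Ω and R carry inverse-Wishart priors with 5
degrees of freedom and identity scale. The first stage is re-fitted per
cross-validation partition with that partition's test cells masked, so no
test information leaks into the kernels. Posterior means (not last
samples) of Ω and R are used.

Elementwise absolute values and averages of covariance matrices need not
stay positive semidefinite, so every derived kernel is repaired by
clipping negative eigenvalues at zero and adding a `1e-8` ridge; the
clipped eigenvalue mass is recorded on the returned object.

GBLUP_TRN fits the same model as GBLUP on the training cells but skips
prediction: every test cell of line `j` is scored with the across-TPE
genomic estimate `μ̂ + ĝ_j`. This is the natural reading of "adjusting
observed phenotypes with genomic information rather than predicting
missing cells", and it is the only reading under which test-set COR and
NRMSE are computable for the method; since the score is a monotone shift
of the GEBV, rankings (and hence PM) are unaffected by the choice of
constant.

## Sampling algorithms

### Single-response sampler

Each random effect with kernel `K` is re-parameterized in the eigenbasis
`K = U D U'` (numerically-zero eigenvalues dropped at relative tolerance
`1e-10`): the effect is `U D^{1/2} a` with whitened coefficients
`a ~ N(0, σ² I_q)`. The data-side covariate matrix `W = Z U D^{1/2}` is
fixed, so its Gram matrix is eigendecomposed once (`W'W = V S V'`) and
every blocked Gibbs update

```
a | rest ~ N(C⁻¹ W'y*, σ²_ε C⁻¹),   C = W'W + (σ²_ε/σ²) I
```

costs two dense multiplications — exact blocked sampling with no
per-iteration factorization. The interaction block uses the Kronecker
eigenstructure `eig(Ω_E ⊗ G) = eig(Ω_E) ⊗ eig(G)` over the full grid, so
test cells are latent coordinates of the same block and their posterior
means are available for prediction without refitting.

Variance components carry scaled-inverse-chi-square priors with 5 degrees
of freedom. Prior scales are set so the prior modes partition the
observed phenotypic variance: a fraction (default 0.5) is shared equally
by the three effect terms and the remainder goes to the residual. With a
degenerate (constant) response the scale targets are floored at `1e-6`,
which lets the sampler shrink all effects to zero gracefully. Variance
draws are floored at `1e-12` to keep precision ratios finite. Any subset
of the four components can be pinned to fixed values, which turns the
sampler into a Monte-Carlo solver of the classic mixed-model equations —
the test suite exploits this to compare posterior means against a
closed-form GLS/BLUP oracle (Pearson r ≥ 0.99 per effect block).

Default chain lengths are 20 000 iterations with 10 000 burn-in (the
production setting); tests and the bundled experiment configurations use
1 200–5 000 iterations, which the oracle and recovery checks show to be
sufficient at desk-scale problem sizes (J ≤ 300).

### Multi-response sampler

The first stage rotates the wide table by `U_G'` (the eigenvectors of
`G`), making the `q = rank(G)` coefficient rows conditionally independent
with `I × I` full conditionals; those are drawn with batched Cholesky
solves. Masked cells are data-augmented from their row-conditional normal
given the observed cells of the same line (grouped by missingness
pattern). Ω is updated from an inverse-Wishart with `df0 + q` degrees of
freedom, R with `df0 + J`.

Reproducibility: all samplers consume a single `numpy` Generator seeded
from the configuration, so identical inputs and seeds give bitwise
identical posterior means. Permuting line order is equivalent only in
the Monte-Carlo limit (the eigenbasis changes), which the test suite
checks at statistical rather than bitwise accuracy.

## Design generators

**Incomplete block.** `find_incomplete_block(J, I, k)` requires `I·k`
divisible by `J` (exact replication `r = I·k/J`) and `k < J`. The start
is a random near-equireplicate layout: a shuffled line order is cycled
into a sequence of length `I·k` and chunked into blocks; copies of a line
sit exactly `J` apart, so blocks never contain duplicates. A swap-descent
then repeatedly exchanges a pair of lines between two blocks whenever the
exchange reduces the concurrence variance `Σ_{j<j'}(λ_jj' − λ̄)²`
(`λ̄` is swap-invariant because block sizes are fixed); the objective
trace is monotone non-increasing by construction. The search restarts
from fresh seeded layouts (default 30) and stops early when the
combinatorial lower bound on the objective is reached — for `(J,I,k) =
(7,7,3)` that bound is zero and the descent reliably finds the Fano-plane
BIBD with λ = 1. Balance is not guaranteed in general; the best design
found is returned with its diagnostics.

**Constrained random.** Block size is `k = ⌈J·r/I⌉`. Environments are
filled sequentially with `k` lines drawn uniformly without replacement
from lines currently below the cap `r`. When fewer than `k` candidates
remain, the shortfall is filled deterministically from the
least-replicated capped lines (ties by line index), allowing at most one
extra replicate; the overflow is logged per line. `k ≥ J` is rejected as
not sparse.

**Cross-validation.** A partition's training cells form an allocation
with `k = round(train_frac · J)` lines per environment; the complement is
the test set. Partition `p` uses seed `seed + p`, regenerating the
allocation fresh each partition. With the incomplete-block method the
same chunked construction is used even when `I·k` is not divisible by `J`
(per-line counts then differ by at most one — the odd-environment rule);
with the random method lines are capped at `⌈train_frac · I⌉` and any
line left with zero training cells is swapped in for the most-replicated
donor, so the "every line observed in at least one training environment"
invariant always holds or construction fails loudly. With `I = 4` and
`train_frac = 0.5` every line trains in exactly two environments under
the incomplete-block method.

## Marker pipeline

Missingness is filtered before MAF (a marker is counted under one removal
reason only), both with strict inequalities: removed if missing fraction
> 0.5 or minor allele frequency < 0.05 (defaults). Allele frequencies
are always computed from non-missing calls. Imputation draws from the
marginal genotype distribution; the default is `Binomial(2, p̂_j)`, which
preserves the diploid 0/1/2 coding, with `impute_model="bernoulli"`
available for data coded 0/1 (e.g. presence/absence GBS calls — both
codings are supported, dosage is the documented default). The VanRaden
denominator uses the same `p̂_j`; a minimum eigenvalue in `(−1e-8, 0)` is
repaired with a `1e-8` ridge, anything more negative raises (a
construction bug, not noise).

## Synthetic generator

`simulate_met` draws one complete `J × I` grid from the model above; the
interaction surface is sampled exactly via the matrix-normal form
`A Z B'` with `A` and `B` symmetric square roots of Ω and `G` (equivalent
to the Kronecker eigendecomposition, exact rather than approximate). The
default scenario is 166 lines × 4 environments with 2000 markers (MAF
uniform on [0.1, 0.5]), variance components (σ²_E, σ²_g, σ²_gL, σ²_ε) =
(1, 1, 0.5, 0.5) — across-environment heritability 0.5 — and an
exchangeable environment correlation of 0.5. This mirrors the shape of a
single real TPE-year (one to two hundred lines, a handful of locations,
moderate G×E) at a marker density sufficient for a stable `G`.

What the generator does **not** emulate: linkage disequilibrium and
population structure (markers are i.i.d. across loci and lines),
selection over cycles, unbalanced field layouts, non-Gaussian traits and
heteroscedastic residuals across environments. Passing recovery tests
therefore demonstrate correctness of the estimation machinery under the
model's own assumptions, not robustness to the ways real wheat data
violate them.

## Evaluation stack

COR and NRMSE are computed over test cells; NRMSE is normalized by the
mean of the observed test values by default (`sd` and `range` are config
options) — the conventional choice for strictly positive yield traits,
and the error message points to the `sd` normalizer when the mean is
zero. PM is computed at the line level: a line's observed score is the
mean of its test-cell BLUEs and its predicted score the mean of its
predicted test cells (for GBLUP_TRN, the across-TPE score itself); using
test cells only avoids training-data leakage into the "true" ranking.
The top set holds `⌈frac·J⌉` lines with ties broken by line identifier.
Relative efficiencies are computed from per-method means across
partitions (never per partition) and reported both as the ×100 ratio and
as the gain (ratio − 100), since both presentations are in common use.
Across-dataset summaries are unweighted means of dataset-level means.

## Problem sizes used in tests and the acceptance script

Design checks run at the worked sizes (12×4×9, 7×7×3) and fuzzed small
sizes. The oracle comparison uses J = 50, I = 3 with 5000 iterations;
variance recovery uses 10 replicates of J = 200, I = 4 (1200 iterations);
genetic-correlation recovery J = 300, I = 2 (1500 iterations); and the
end-to-end experiment runs the default 166 × 4 scenario with 2 partitions
and 1500-iteration chains. These sizes were chosen so the estimates they
produce are stable (the oracle correlation and recovery intervals have
comfortable margins) while a full run stays in the minutes range on a
single CPU.

## Known limitations

* The incomplete-block search is a heuristic; it certifies optimality
  only when the combinatorial lower bound is attained.
* GBLUP_TRN requires every line observed at least once; the engine
  refuses rather than silently extrapolating to unobserved lines.
* Each dataset (year × TPE) is fitted independently; there is no
  multi-year joint model, by design.
* REML/frequentist fitting, marker-effect models (Bayes A/B/Cπ) and
  non-Gaussian responses are out of scope.
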