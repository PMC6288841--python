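# Methods

## The model

`gxepred` analyses multi-environment plant-breeding trials in which J lines
are phenotyped in I environments.  The phenotype of line j in environment i
is decomposed as

    y_ij = E_i + g_j + gE_ij + e_ij

where E_i is a fixed per-environment mean, the genomic main effects follow
g = (g_1, …, g_J)' ~ N(0, σ₁² G), the genotype-by-environment interaction
follows gE ~ N(0, σ₂² I_I ⊗ G), and e_ij ~ N(0, σ²) i.i.d.  G is the
genomic relationship matrix computed from the J × p marker matrix W as
G = W_c W_c' / p with column-centered W_c (centering is the default; a
`center=False` path reproduces the raw cross-product, and a VanRaden
2Σp_k(1−p_k) scaling is available as a flag — the default /p scaling keeps
the variance components on the scale of the mean GRM diagonal).

Because G = L L' for a lower-triangular Cholesky factor L, the random
effects have an exact fixed-feature representation: using row j of L as J
genomic covariates, ridge regression with penalty σ²/σ₁² on those columns
is identical to GBLUP.  Both estimators in the package consume exactly
these covariates: a one-hot environment block (no intercept, since the E_i
are per-environment means), the J columns of L, and optionally I blocks of
J columns holding the same L row in the cell's own environment block and
zeros elsewhere (the G×E covariates).  For an I=3, J=5 problem this gives
3 + 5 (+ 15) columns.

When G is numerically singular — column centering alone makes it rank
J − 1 — the factorization adds jitter ε·mean(diag G)·I with ε escalating
from 1e-10 to 1e-6 in decade steps, recording the jitter used; a matrix
that still fails is reported with its minimum eigenvalue rather than
silently repaired.

## GBLUP fitting

Variance components are estimated by REML.  Writing γ_k = σ_k²/σ² and
H(γ) = I + γ₁ K₁ + γ₂ K₂ with cell-level kernels K₁[c,c′] = G[j_c, j_c′]
and K₂ = K₁ ⊙ 1{same environment}, the residual variance is profiled out
analytically and

    −2ℓ_R ∝ (n−q)·log(y'Py) + log|H| + log|X'H⁻¹X|

is minimised over log₁₀ γ ∈ [−6, 6] by L-BFGS-B from two starts (γ = 1 and
γ = 10⁻³); the bounded log-scale search makes degenerate fits (γ → 0 or
γ → ∞, i.e. no genetic signal or no noise) well-behaved.  Fixed effects are
re-solved by GLS inside every likelihood evaluation; an environment with no
training records aborts with an explicit error instead of being dropped.
BLUPs follow from û_g = γ₁ G Z' H⁻¹(y − Xβ̂) (and the per-environment
analogue for the interaction), which yields predictions for any line with a
GRM row — an unphenotyped line is predicted purely through relatedness, and
a line with a zero GRM row falls back to the environment mean.

This REML route deliberately replaces an MCMC fit: it is deterministic and
directly testable, and its point predictions coincide with Bayesian
posterior means under flat priors.  The central correctness oracle — kept
independent in the test suite — is the exact equivalence (≤ 1e-6) between
GBLUP with fixed variance ratios and closed-form penalized least squares on
the Cholesky features, with and without the G×E block.

## The dense network

A from-scratch multilayer perceptron shares those covariates: 1–3 hidden
layers of U ReLU units, a ReLU output unit, inverted dropout (rate 0.3 by
default) on hidden activations during training only, MSE loss, and
mini-batch Adam (learning rate 0.001, batch 32 — the optimiser, rate and
batch size are this package's defaults, chosen as the common framework
defaults for small regression problems, and all are exposed in `NetConfig`).
Inputs are standardised per column and targets standardised using
training-set statistics only.  A ReLU output cannot produce negative
values, so standardised training targets are shifted by max(0, −min z)
before training and the shift is inverted at prediction; a `linear` output
activation is available as an escape hatch, and is also what the
linear-network convergence tests use.  Analytic gradients are verified
against central finite differences to 1e-5 relative error — the module's
core oracle.  Training for E epochs consumes one seeded generator for
shuffling and dropout, so a 2E-epoch run's loss trace prefixes the E-epoch
run's and prediction is bitwise repeatable.

## Cross-validation and accuracy

The outer loop mimics incomplete field trials.  With N = J·I cells and test
fraction p_test = 0.35, round(p_test·N) lines are drawn — without
replacement when J ≥ p_test·N, with replacement otherwise — and each drawn
line contributes one uniformly chosen environment; duplicate cells under
with-replacement sampling are redrawn so the test set has exactly its
nominal size.  Ten outer replicates use seeds base_seed + r, and a cell may
be tested in several replicates.

Networks are tuned per outer replicate by full-factorial grid search over
units × epochs × layers (default levels 6 × 5 × 3 = 90 configurations) on a
random seeded 80/20 inner split of the outer training cells, selecting
minimal validation MSE with ties broken by enumeration order.  The tuned
network used on the outer test set is the one trained on training-inner
(matching tuning via a held-out validation fraction during fit); `refit=True`
retrains it on the full outer training set instead.  The inner split is
random rather than "trailing rows" because row order in this data model is
arbitrary.  GBLUP has no tuned hyperparameters and uses the full outer
training set.

Accuracy is the per-environment Pearson correlation between observed and
predicted test-cell values, divided by √h² of that environment (so values
may exceed 1 when the raw correlation approaches the h² ceiling; the raw
table is always reported alongside).  Replicate values are averaged into
the APC with SE = sd(n−1)/√n, reported as 0 for a single replicate.  An
environment with fewer than 3 test cells, or a constant vector, is skipped
for that replicate with a log entry.

## Synthetic data

The simulator draws exactly from the model above: independent biallelic
SNPs with frequencies uniform in a MAF range (monomorphic columns redrawn
so p is exact), genomic and interaction effects via the shared
Cholesky-of-GRM path (the I interaction blocks are drawn as independent
N(0, σ₂²G) vectors — the same distribution as the block-diagonal Kronecker
covariance without materialising it), and i.i.d. residuals.  It reports the
true heritability implied by its own parameters,

    h² = (σ₁² + σ₂²)·d̄ / ((σ₁² + σ₂²)·d̄ + σ²),   d̄ = mean(diag G),

identical across environments because the variance components are shared;
when both genetic variances are zero `true_heritability` raises (h² is
undefined) while the simulator itself records h² = 0 so degenerate
pure-noise runs remain constructible.  For real data h² must be supplied
per environment by the user.

What the simulator does **not** emulate: linkage disequilibrium, pedigree
or population structure, selection, missing genotypes or phenotypes,
environment-specific variance components, and non-Gaussian residuals.
Passing tests therefore demonstrate correctness of the estimators under
the stated model, not robustness to the full messiness of field data.

## Problem sizes and numerical choices

The test and acceptance runs use deliberately modest sizes chosen so each
check measures what it claims: REML parameter recovery averages 20
replicates at J=400, I=3, p=500 (replicate-mean estimates land within a few
percent of truth; 20% is the asserted band because single-replicate
interaction-variance estimates are noisy at I=3); the G×E-advantage
comparison runs 10 outer replicates at J=100, I=3 with σ₂² = σ₁²; the
end-to-end nested CV uses J=60, I=3 with a reduced 2×2×2 grid whose levels
are drawn from the full grid (units {50,100}, epochs {50,100}, layers
{1,2}).  At that sample size the network trails GBLUP — roughly a hundred
training-inner cells against 63–243 covariates is exactly the scarce-data
regime where the mixed model's explicit covariance assumptions pay off —
and the reported APCs reflect that honestly.  Ratio search tolerance is ftol
1e-12 on the objective; Cholesky jitter as above; ties in grid search break
to enumeration order; duplicate-cell redraw fixes the test-set size
exactly.

## Known limitations

- REML with two variance ratios uses a dense n×n Cholesky per likelihood
  evaluation: fine to a few thousand cells, not engineered beyond that.
- The h²-adjusted APC can exceed 1; it is reported as computed.
- No Bayesian sampler, no multi-trait model, no forward (across-generation)
  prediction, no convolutional or recurrent architectures, and no
  marker-effect back-solving.
- Accuracy under with-replacement line sampling depends on the documented
  duplicate-redraw rule; other conventions would change test-set overlap
  across replicates.
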