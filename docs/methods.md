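# Methods

## The data model

The package targets the classic multi-environment quantitative-genetics
design: n fully inbred lines (allele dosages 0 or 2; heterozygous calls
are accepted with a warning), each phenotyped once in every one of r
discrete environments, giving q = n·r records. The reference design is
176 lines × (2 sexes × 3 temperatures) = 1,056 lifespan records, with
variant filters MAF ≥ 0.05 and missing-call rate ≤ 0.2 and remaining
missing dosages imputed to the variant mean. Phenotype files are reduced
to complete cases by line: a line missing any environment is dropped, so
the retained table is balanced.

## Kernels

* **G** — VanRaden genomic relationship matrix from filtered dosages,
  `G = WWᵀ / 2Σⱼ pⱼ(1−pⱼ)`. For inbred dosages the diagonal averages ≈ 2.
  When kernels are assembled for model fitting, G is rescaled to unit mean
  diagonal; with E likewise scaled (below), every variance component is
  then on the phenotypic scale and the ratio `σ²ₖ/Σσ²` reads directly as a
  proportion of variance explained. The rescaling is absorbed by the
  variance components and moves no likelihood optimum.
* **E** — environmental similarity `E = X_q X_qᵀ / c` with X_q the
  record-level matrix of c = 2 covariates (sex coded 0/1, temperature in
  °C, each standardized to mean 0 and variance 1 across records). The
  division by c fixes the otherwise arbitrary proportionality constant so
  the mean diagonal is 1. E has rank ≤ c; records of one environment have
  identical rows. No intercept column enters X — the models carry a global
  intercept.
* **ZGZᵀ** and **ZGZᵀ ∘ E** — record-level expansion through the 0/1
  incidence Z and the Hadamard interaction kernel, PSD by the Schur
  product theorem. Kernels whose smallest eigenvalue falls below
  −1e−8·(largest) but above −1e−6·(largest) are repaired by clipping
  negative eigenvalues; anything worse raises.

## REML for the kernel models

All four RKHS models maximize the restricted log-likelihood

    l_R = −½ [ log|V| + log|XᵀV⁻¹X| + yᵀPy ] − (q − rank X)/2 · log 2π

with `V = Σₖ σ²ₖ Kₖ + σ²_ε I` and X = 1. Optimization is L-BFGS-B on
log-variances with analytic gradients
(`dl/dθₖ = −½[tr(P dV/dθₖ) − yᵀP (dV/dθₖ) Py]`), run from three
deterministic starts — equal split, residual-dominant (90% residual) and
kernel-dominant — keeping the best optimum; convergence tolerance 1e−8 on
the relative likelihood change, at most 500 iterations per start.
Single-kernel models take an eigen-rotated path where every likelihood
evaluation is O(q); multi-kernel models use one Cholesky factorization and
one explicit inverse per iteration (dense solves are comfortable at
q ≈ 1,000).

Two boundary rules keep zero-variance components honest. The log-scale
lower bound sits at 1e−10 of the phenotypic variance, and any component
below 1e−9 of the total is reported as exactly 0. On top of that, a
component below 1e−5 of the total is profiled out: if removing it costs no
restricted likelihood within the convergence tolerance it is set to
exactly 0. Without this refinement the optimizer can stall on the flat
shoulder of a zero-optimum component (e.g. the genetic variance in G-BLUP
when the environment is unmodelled), leaving numerical dust that turns a
constant prediction into noise. A constant prediction vector is scored
R² = 0, so "the model predicts nothing" is represented stably.

Out-of-sample prediction extends each random effect by
`ûₖ = σ̂²ₖ Kₖ[test, train] V̂_train⁻¹ (y_train − μ̂)` and sums
`ŷ = μ̂ + Σₖ ûₖ`; kernels are built once from the full record structure
(genotypes and the design carry no phenotype information) while every
phenotype-derived quantity comes from training records only.

## The multi-trait model

`Y = 1Mᵀ + A + R` with `A ~ MN(0, G, Σ_A)` and row-wise residuals
`N(0, Σ_R)`, Σ_R diagonal as the one-record-per-cell design cannot
separate a richer residual. The Gibbs sampler rotates A into the
eigenbasis of G once (`G = UDUᵀ`), making the rotated rows conditionally
independent — one sweep costs a batch of n r×r solves. Sweeps update, in
order: missing cells (data augmentation from the Gaussian predictive),
intercepts (flat prior), rotated genetic values, `Σ_A` from its
Inverse-Wishart full conditional `IW(ν₀+n, S₀ + ÃᵀD⁻¹Ã)`, and each
residual variance from a scaled-inverse-χ². A numerically singular G gets
a ridge of 1e−8·tr(G)/n with a warning. The chain is fully determined by
its seed.

Priors follow common Bayesian genomic-model defaults: `ν₀ = r + 2` with S₀
chosen so the prior mode of each genetic variance is half the trait's
phenotypic variance, and residual scaled-inverse-χ² with 5 df and mode at
half the phenotypic variance. One consequence worth knowing: the
Inverse-Wishart leaves essentially no mass near zero, so on truly
heritability-free data the posterior genetic variance settles around
0.2–0.3 of the phenotypic variance rather than at zero — the test suite
checks for shrinkage well below the prior mode, not for an unreachable
zero. Desk-scale chain defaults are 6,000 sweeps, 1,000 burn-in, thinning
5; the full-scale setting (300,000 / 200,000 / 50) is a config choice.

Prediction returns posterior means `M[j] + A[i,j]`; lines absent from the
fit are extended by the genomic conditional expectation
`G[new, old] G[old, old]⁻¹ Â`, so a line unrelated to every fitted line
predicts the trait intercept. The model cannot predict into an environment
it never observed (no intercept or covariance estimates exist for it), and
the CV layer rejects that combination explicitly.

## The reaction-norm model

`y_ij = Σₜ βₜ Pₜ(x_j) + Σₜ a_itPₜ(x_j) + ε_ij` with plain (unnormalized)
Legendre polynomials, default order T = 1; the normalized variant only
rescales coefficients. The environmental value x_j is the training-mean
phenotype of environment j mapped to [−1, 1] by min–max over training
environments. For an environment absent from training, the raw mean is
extrapolated by OLS of the training environment means on the standardized
sex/temperature covariates, then mapped with the training bounds and
clipped to [−1, 1]; using the test environment's own observed mean would
leak test information and exists only behind an explicit flag.

The record covariance has the Hadamard form
`V = (Φ Σₐ Φᵀ) ∘ ZGZᵀ + D`, D diagonal with one residual variance per
environment (floored at 1e−8 of the phenotypic variance). REML runs on a
log-Cholesky parameterization of Σₐ plus log residual variances, with
analytic gradients, through the same engine as the kernel models. With the
slope row of Σₐ at zero and a shared residual variance the model reduces
exactly to a genomic model with a fixed linear environmental trend — the
test suite verifies the two prediction paths agree to 1e−6.

## Cross-validation

17% is interpreted as round-half-up counts (30 of 176 lines; 180 of 1,056
records). RandomLines and RandomObservations draw 6 independent replicates
with seeds `seed+1 … seed+6` (the alternative 6-disjoint-folds reading is
not used); NewEnvironment is deterministic with exactly one fold per
environment and also reports R² per held-out environment. Accuracy is the
squared Pearson correlation of observed and predicted test phenotypes; a
degenerate (constant to machine precision) prediction vector scores 0 with
a warning rather than aborting a sweep.

## The synthetic generator

Genotypes: per variant a frequency from Uniform(0.05, 0.5), dosage 2 with
that probability else 0, monomorphic draws rejected. No linkage, no
population structure, no dominance — the lines are exchangeable, which is
the one feature of real panels (local LD, cryptic relatedness) the
generator deliberately lacks; passing tests therefore demonstrate the
estimation machinery, not robustness to structure.

Phenotypes follow the G×E-BLUP generative law: `a ~ N(0, ZGZᵀ)`,
`e = X_q γ` with `γ ~ N(0, I_c)` drawn once (environments are a fixed
factor realized through its random-effect representation),
`ae ~ N(0, ZGZᵀ ∘ E)`, `ε ~ N(0, I)`. Each vector is rescaled so its
*realized* variance equals its target fraction of the total (default
0.12 / 0.72 / 0.08 / 0.08 of 1 day², grand mean 50 days) — empirical
rather than expected-variance scaling, so recovery tests have exact
truths; it slightly distorts the multivariate law since components stay
only near-orthogonal. One record per line × environment; within-line
replicate flies are out of scope because the reference records are
line-level means.

Because e lives in the rank-2 span of the environmental covariates, the
E kernel can represent it exactly; E-BLUP's accuracy ceiling equals the
environmental PVE. Within a held-out environment E-BLUP predicts a
constant, hence its R² of 0 in the NewEnvironment scheme.

## Sizes and checks used by the test suite

Recovery and CV checks simulate 200 lines × 3,000 variants (q = 1,200);
the acceptance script runs the reference-scale 176 × 3,000 design. The
multi-trait recovery simulation uses within-trait heritability 0.75,
matching the within-environment genetic PVE (~72–80%) the multi-trait
model estimates on the real panel; at h² ≈ 0.5 the genetic/residual split
of near-unrelated lines is so weakly identified that the genetic
correlation attenuates regardless of sampler quality. REML correctness is
anchored to a closed-form two-record likelihood and a dense 200×200 grid
search on an 8-line instance; the sampler's scaled-inverse-χ² building
block is checked against its analytic distribution by Kolmogorov–Smirnov
distance.

## Known limitations

* Dense linear algebra throughout: practical to a few thousand records,
  not to biobank scale.
* No standard errors or likelihood-ratio tests on variance components; no
  fixed effects beyond the intercept (models of this design rarely need
  them).
* Σ_R diagonal in the multi-trait model; no unstructured residual.
* No LD pruning, annotation, or imputation beyond the variant mean.
* The RRM offers Legendre bases only, and its New-Environment
  extrapolation of x is a modelling choice the data cannot validate.
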