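# Methods

This note documents the models, algorithmic conventions and design choices
behind `grnjdr`, in the spirit of a package vignette: what is computed, under
which assumptions, and where the knobs are.

## Synthetic cohort model

The generator produces the statistical structure the analysis assumes, with
ground truth retained for scoring.

**Latent factors.** Z ∈ R^{n×K} with i.i.d. standard-normal entries,
column-centered. Factors are *not* orthogonalized: at the default n = 150
the empirical correlation between factor columns is O(1/√n) ≈ 0.08, which is
the main irreducible limit on factor-recovery fidelity (see "Identifiability"
below).

**Omics blocks.** X_m = Z[:, active_m] L_mᵀ + E with L_m entries
Normal(0, s²) per active factor and isotropic Gaussian noise (default sd
0.5 for the study cohort, 0.05 for the low-noise recovery checks). A
configurable fraction of constant features can be injected to exercise the
zero-variance filter.

**Identifiability / default factor geometry.** An SVD-based joint
factorization can only separate factors whose joint (cross-block) strengths
are distinct; because each block is rescaled by its first singular value,
the strongest factor in every block lands at strength ≈ 1, and symmetric
designs (each factor strong in the same number of blocks with equal
loading scales) produce degenerate singular values and rotationally mixed
factors. The default design therefore staggers the strengths: factor 1 is
a strong program shared by all three blocks (the survival- and
network-linked axis), and the remaining factors enter fewer blocks with
per-factor loading scales (1.0 / 0.5 / 0.28 / 0.22 pattern), giving joint
strengths ≈ (1.73, 0.73, 0.45, 0.22) — separated enough that recovery
survives the O(0.08) empirical factor correlations. The design was chosen
by its pass fraction over a batch of design-validation seeds and then
frozen.

**Regulatory networks.** Per-sample edge weights on prior-supported pairs:
w_q(t, g) = M(t,g)·(b + β_e·z_q·u_t·v_g) + ε, with u, v fixed non-negative
unit-norm patterns (drawn once per regulatory "program"; a separate
`structure_seed` lets replicate cohorts share priors and patterns while
drawing fresh samples) and z_q the sample's score on the coupling factor.
A gene-expression block coupled to the networks (gene value = column sum
of incoming weights + noise) is emitted alongside. Rank-1 multiplicative
coupling is the minimal mechanism that makes indegrees and outdegrees
informative about the factor.

**Survival.** Exponential proportional hazards: T ~ Exp(λ₀·exp(βᵀz)),
independent exponential censoring C, observed (min(T,C), 1[T ≤ C]).
Defaults λ₀ = 0.1, censor rate 0.03 (≈ 25% censoring), β = (1, 0, 0, 0):
the hazard rides on factor 1 only. Exponential forms keep sampling
closed-form and satisfy the proportional-hazards assumption of the Cox
analysis exactly.

**Clinical features.** Binary and three-level features are thresholded /
tertile-cut factors, plus one pure-noise binary negative control.

**What the generator does not emulate.** Count distributions (RNA-seq),
bounded beta-values (methylation), batch effects, missingness patterns, or
heavy-tailed noise — all blocks are Gaussian by design. Passing tests
therefore demonstrate correctness of the pipeline's logic and calibration
under its stated assumptions, not robustness to real-data pathologies.

## Aggregate network inference

Inputs (motif prior, TF-interaction prior, co-expression) are z-score
normalized as (row-z + column-z)/√2, with an overall z-score fallback for
constant rows/columns. The continuous Tanimoto similarity
T(x, y) = ⟨x,y⟩ / √(‖x‖² + ‖y‖² − |⟨x,y⟩|) defines a responsibility
R_ij = T(P_i·, W·_j) and availability A_ij = T(W_i·, C·_j);
W ← (1−α)W + α(R+A)/2 with α = 0.1. The helper networks are co-smoothed
from W's row/row and column/column similarities with the same α.

The raw diagonal of a self-similarity matrix equals each profile's norm and
feeds back into the next iteration's similarities; left in place it makes
the iteration diverge geometrically. The diagonal is therefore replaced by
the off-diagonal spread scaled by the matrix size and exp(2α·step), which
inflates the Tanimoto denominators and damps the updates — with this
damping the fit converges in ~20–30 iterations on the synthetic inputs.
Convergence is declared when the mean absolute edge change drops below
tol = 1e-3 (max 200 iterations); α = 0 reduces the update to the identity
and returns the normalized prior. Output weights live on a z-score-like
scale; the sign scores interaction likelihood, not activation versus
repression, and is deliberately not interpreted.

Outputs are method-faithful to the published message-passing scheme but not
expected to be bit-identical to any particular legacy implementation, whose
exact normalization constants are not public.

## Single-sample networks and degrees

e(q) = N·(e(all) − e(−q)) + e(−q) for any deterministic aggregate estimator
`network_fn`. Three estimators ship: the full message-passing fit, a
motif-masked TF-gene Pearson correlation (requires TF expression rows), and
a mean-of-contributions estimator used as the exact algebraic oracle
(e(q) = f(q) identically, verified to 1e-10). Networks can be streamed one
sample at a time into the degree accumulator; the samples × edges array
never needs to be materialized. Degrees sum signed weights without
thresholding; per sample Σ indegree = Σ outdegree = total edge weight.

## PCA filtering

Per block: exact-constancy filter (max = min, robust where a computed sd of
a constant feature picks up rounding noise), then SVD-based PCA on the
samples × features matrix. Default is center *and* scale to unit variance
per feature — the omics layers carry incommensurable signals, so
correlation-scale PCA is the defensible default; both flags are
configurable, and whether the original analyses scaled is unknowable from
the outside. Components are selected as
k = max(floor, smallest j with cumulative variance ≥ threshold), threshold
0.85 and floor 20 by default, floor capped at the block's rank (desk-scale
data have fewer than 20 meaningful components; a warning is emitted).
Component signs are fixed by making each component's largest-magnitude
loading positive, removing SVD sign ambiguity from all downstream
comparisons.

## Joint factorization

The default backend ("mfa_svd") is a deterministic multiple-factor-analysis
style joint SVD: per-block score matrices are centered, divided by their
own first singular value (equalizing block influence), concatenated along
features and decomposed; Z = top-K left singular vectors, A_m = per-block
slices of V·S. K = 5 by default, mirroring the study configuration; the
recorded seed (default 13) only matters for stochastic backends plugged in
through the adapter interface. Per-factor signs are fixed by the
largest-magnitude entry of the concatenated weight vector. Variance
explained is R²_{m,k} = 1 − ‖S_m − z_k a_{m,k}ᵀ‖²_F / ‖S_m‖²_F on the
centered, block-scaled score matrices.

Back-mapping multiplies PCA loadings with block weights, W_m = L_m A_m,
with no normalization. At full rank this equals fitting the backend on the
original standardized features up to per-factor sign (asserted at 1e-8);
after truncation it is an approximation whose *feature rankings* — the
quantity downstream interpretation uses — remain stable (rank correlation
≥ 0.9 at the default threshold on synthetic data).

Model variants mirror the study design: omics only, omics+indegree,
omics+outdegree, omics+both, with degree matrices passing through the same
sd-filter → PCA → factorization path as omics blocks (gene indegrees are
as numerous as genes, so the dimensionality argument applies to them
equally). In pipeline runs on synthetic cohorts the degree matrices are
computed from the cohort's single-sample networks directly; the
interpolation estimator's correctness is established separately by its
exact oracle, so re-running leave-one-out inference inside replicated
studies would add cost without information.

## Survival association

Univariate Cox proportional hazards per factor via lifelines (Efron ties,
Newton precision tightened to 1e-9 so estimates match an independent
partial-likelihood optimization to 1e-6), Wald p from β/se against the
standard normal. A constant covariate returns (β = 0, p = 1) with a
warning; fewer than two events is an error. Benjamini-Hochberg correction
is applied per family: across the K factors for survival, across all
factor × feature pairs for clinical tests. A factor with FDR < 0.05
(configurable) is flagged survival-associated (SAF). Clinical features
dispatch on arity: two levels → two-sided Wilcoxon rank-sum, more →
Kruskal-Wallis; single-level features are skipped with a warning.
Kaplan-Meier median splits assign ties to the low group (deterministic)
and compare groups with a two-group log-rank test. Samples with missing
survival are dropped and logged; complete-case selection across all blocks
of a variant happens before any filtering, and every drop is logged once.

## Enrichment and TF overlap

Preranked GSEA with exponent 1: genes sorted by decreasing weight, hits
increment by |weight| (normalized), misses decrement uniformly; ES is the
extreme deviation of the running sum. The null is gene-label permutation
(random same-size sets, cached per set size); p = (b+1)/(m+1) against the
m null scores of matching sign — strictly positive by construction and
calibrated (null rejection ≈ 0.05 at α = 0.05 in the acceptance checks).
NES divides ES by the mean |null ES| of matching sign. Defaults
n_perm = 1000, set-size window [15, 500] after intersection with the
ranked universe; no-overlap sets are skipped with a warning, constant
rankings are an error. Indegree weights feed enrichment; outdegree weights
feed the top-TF analysis.

Top-TF selection takes the n_top = 20 TFs by absolute weight per SAF
(boundary ties broken by TF identifier), reports per-SAF lists and their
union. Overlap between two cohorts' top-TF sets is tested one-sided
("greater") with the exact hypergeometric tail on the 2×2 table over the
intersection of the two models' TF universes; the sample odds ratio
a·d/(b·c) is reported (∞ when b·c = 0), with a two-sided p available for
secondary reporting.

## Problem sizes and numerical conventions

Tests and the acceptance script run at desk scale as the package's own
study conditions: cohorts of n = 150 (blocks 300/150/400 features, 40 TFs ×
300 genes), n = 200 for the Cox calibration (500 null replicates) and power
(100 replicates) studies, 50 replicate cohorts for the variant comparison,
500 random sets for enrichment calibration, and exhaustive 2×2 tables up to
universe 25 for the overlap oracle. Key tolerances: 1e-10 for algebraic
identities (interpolation recovery, one-step message passing), 1e-8 for
SVD-based equivalences, 99% binomial intervals for calibration rates.
Seeds: all randomness flows from explicit integer seeds; per-component
seeds are spawned from a master seed via `numpy.random.SeedSequence`, and
the canonical seed used in examples is 13.

## Known limitations

- Gaussian synthetic data only; no claim of robustness to real-omics noise
  models, missingness or batch structure.
- The joint factorization is linear and orthogonal; factors of a
  variational or sparse backend (pluggable via the adapter) will differ,
  and back-mapping equivalence is exact only for the linear backend.
- Factor recovery is bounded by the empirical non-orthogonality of the true
  factors at finite n; cohorts whose factor draws are unusually correlated
  can dip below the nominal recovery level.
- Message-passing output is method-faithful but not bit-compatible with
  legacy implementations.
- No multivariate or regularized Cox, no proportional-hazards diagnostics,
  no competing risks; the adaptive multilevel enrichment algorithms are not
  implemented (plain permutation GSEA with pinned conventions).
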