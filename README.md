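# grnjdr

Integration of sample-specific gene regulatory network (GRN) metrics with
multi-omics data through PCA-filtered joint dimensionality reduction (JDR),
with downstream survival association and interpretation. The package is
aimed at computational biologists who want to test whether patient-specific
regulatory information adds prognostic signal beyond the omics layers
themselves, and at methodologists who need a fully synthetic, ground-truthed
testbed for that question.

## The analysis in brief

1. **Aggregate GRN by message passing.** A TF-by-gene motif prior W, a
   TF-TF interaction prior P and gene co-expression C are z-score
   normalized and iterated to agreement: with the continuous Tanimoto
   similarity T(x, y) = ⟨x,y⟩ / √(‖x‖² + ‖y‖² − |⟨x,y⟩|), each step
   computes a responsibility R_ij = T(P_i·, W·_j), an availability
   A_ij = T(W_i·, C·_j) and updates W ← (1−α)W + α(R+A)/2 until the mean
   absolute change falls below tolerance. The result is a complete
   bipartite network whose signed weights score interaction likelihood.
2. **Single-sample networks by linear interpolation.** For N samples with
   aggregate e(all) and leave-one-out aggregate e(−q), sample q's network
   is e(q) = N·(e(all) − e(−q)) + e(−q). For any estimator that is a mean
   of per-sample contributions this recovers the contributions exactly.
3. **Degree summaries.** Per sample, a gene's *indegree* is the summed
   weight of its incoming edges; a TF's *outdegree* the summed weight of
   its outgoing edges. Degrees are computed on the signed weights as-is.
4. **PCA filtering.** Each block (omics or degrees) is centered, scaled,
   and reduced to k = max(floor, smallest j with cumulative R² ≥ 0.85)
   principal components (floor 20, capped at rank), keeping block
   dimensionalities within an order of magnitude of each other.
5. **Joint factorization.** Block score matrices are each scaled by their
   first singular value, concatenated, and decomposed by SVD; the top-K
   left singular vectors are the shared factors Z (K = 5 by default) and
   the per-block right-singular slices the weights A_m. Feature-level
   weights are recovered by back-mapping W_m = L_m A_m through the PCA
   loadings L_m — exactly equivalent to a direct fit when all components
   are retained.
6. **Survival and interpretation.** Each factor is tested with a
   univariate Cox model (Wald test, Benjamini-Hochberg correction across
   factors; a factor passing FDR < 0.05 is a survival-associated factor,
   SAF); four model variants are compared (omics only, +indegree,
   +outdegree, +both). SAFs are interpreted by Kaplan-Meier median splits,
   clinical-feature tests (Wilcoxon/Kruskal-Wallis), preranked gene set
   enrichment on indegree weights, and a one-sided Fisher test of top-TF
   overlap between cohorts.

A seeded synthetic-cohort generator provides multi-omics blocks sharing
latent factors, factor-dependent regulatory networks, proportional-hazards
survival, and categorical clinical features, so every stage is testable
against known truth.

## Worked example

The numbered scripts under `analysis/` run the study end to end on a
cohort whose hazard-linked factor drives only the network edge weights
(the omics blocks are decoupled from it). `python
analysis/03_fit_factor_models.py` prints:

```
per-variant summary:
  variant  saf_count  best_fdr
    omics          0  0.064377
 indegree          2  0.002407
outdegree          2  0.000066
     both          2  0.000034
```

The omics-only model finds no survival-associated factor, while every
variant that includes network degrees finds two — the survival signal
enters the factor space only through the regulatory networks.
`analysis/04_survival_interpretation.py` then shows the Kaplan-Meier
median split on the top SAF (log-rank p ≈ 8e-6), and preranked enrichment
of its indegree weights recovers the network-coupled gene program
(FDR ≈ 0.02) while 20 random gene sets stay flat.
`analysis/05_replication_tf_overlap.py` repeats the fit in a second cohort
sharing the same regulatory program and finds a significant top-TF overlap
(17 shared TFs, odds ratio 5.7, one-sided Fisher p ≈ 0.02).

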