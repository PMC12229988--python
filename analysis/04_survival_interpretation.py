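#!/usr/bin/env python
"""Interpret the survival-associated factors of the network model.

Reloads nothing: refits the 'both' variant on the same cohort as the
previous step, then (i) tests every factor against the categorical
clinical features, (ii) draws the Kaplan-Meier median split for the top
survival-associated factor, and (iii) runs preranked enrichment of the
back-mapped indegree weights against gene sets that include the true
network-coupled gene program.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import grnjdr as g
from grnjdr.grn import indegree, outdegree

OUT = Path("results")


def coupled_program(cohort: g.SyntheticCohort, n_genes: int = 30) -> set[str]:
    """Genes whose indegree tracks the network-coupled factor: the ground
    truth 'pathway' the enrichment analysis should recover."""
    indeg = indegree(cohort.networks).values
    z1 = cohort.truth["factors"].scores.iloc[:, 0].to_numpy()
    corr = indeg.apply(lambda col: np.corrcoef(col, z1)[0, 1])
    return set(corr.abs().nlargest(n_genes).index)


def main() -> None:
    sim = g.SimulationConfig(
        block_active_factors=((3,), (2, 3), (2, 4)),
        beta=(1.0, 0, 0, 0),
        edge_effect=1.0,
        seed=13,
    )
    cohort = g.simulate_cohort(sim)
    cfg = g.PipelineConfig(simulation=sim)
    res = g.run_variant(
        cohort.omics,
        cohort.survival,
        "both",
        indeg=indegree(cohort.networks),
        outdeg=outdegree(cohort.networks),
        config=cfg,
    )
    safs = [f for f, row in res.assoc.iterrows() if row["saf"]]
    print("survival-associated factors:", safs or "none")
    if not safs:
        return
    top_saf = res.assoc.loc[safs, "fdr"].idxmin()

    clin = g.clinical_assoc(res.model, cohort.clinical)
    clin.to_csv(OUT / "clinical_association.tsv", sep="\t", index=False)
    print("\nclinical associations (FDR < 0.05):")
    print(clin[clin.fdr < 0.05].to_string(index=False))

    km = g.km_median_split(res.model.factor_scores[top_saf], cohort.survival)
    for name, curve in km.curves.items():
        curve.to_csv(OUT / f"km_{top_saf}_{name}.tsv", sep="\t", index=False)
    print(
        f"\nKaplan-Meier median split on {top_saf}: "
        f"log-rank statistic {km.logrank_stat:.2f}, p = {km.logrank_p:.3g}"
    )

    program = coupled_program(cohort)
    rng = np.random.default_rng(13)
    sets = {"network_coupled_program": program}
    genes = list(cohort.networks.gene_ids)
    for i in range(20):
        sets[f"random_{i:02d}"] = set(rng.choice(genes, 30, replace=False))
    gsea = g.gsea_preranked(
        res.weights["indegree"].weights[top_saf],
        g.GeneSetCollection(sets),
        n_perm=1000,
        min_size=5,
        max_size=100,
        seed=13,
    )
    gsea.sort_values("p").to_csv(OUT / f"gsea_indegree_{top_saf}.tsv", sep="\t")
    print(f"\nenrichment of indegree weights for {top_saf} (top 5 sets):")
    print(gsea.sort_values("p").head()[["size", "es", "nes", "p", "fdr"]].to_string())


if __name__ == "__main__":
    main()
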