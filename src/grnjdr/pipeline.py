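"""End-to-end orchestration of the model variants.

Four factor models are fitted per dataset: omics blocks alone, omics plus
gene indegrees, omics plus TF outdegrees, and omics plus both degree
matrices. Degree matrices travel through the same zero-variance filter ->
PCA filter -> joint factorization path as the omics blocks, and every
variant's factors are tested against survival, giving the with-versus-
without-network comparison that is the point of the analysis.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import DegreeMatrix, OmicsBlock, SurvivalTable, SyntheticCohort
from .enrichment import gsea_preranked, overlap_fisher, read_gmt, top_tfs
from .factor import FactorModel, FeatureWeights, backmap_model, fit_jdr
from .grn import indegree, outdegree
from .pca import FilteredBlock, drop_zero_variance, filter_block
from .survival import survival_assoc_table
from .synth import SimulationConfig, simulate_cohort

__all__ = [
    "PipelineConfig",
    "RunLog",
    "VariantResult",
    "ModelComparison",
    "complete_case_samples",
    "run_variant",
    "compare_models",
    "run_pipeline",
]

log = logging.getLogger(__name__)

VARIANTS = ("omics", "indegree", "outdegree", "both")


class RunLog:
    """Structured, timestamped record of every filtering and fitting decision."""

    def __init__(self) -> None:
        self.records: list[dict] = []

    def record(self, event: str, **fields) -> None:
        rec = {"time": time.strftime("%Y-%m-%dT%H:%M:%S"), "event": event, **fields}
        self.records.append(rec)
        log.info("%s %s", event, fields)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.records, fh, sort_keys=False)


@dataclass
class PipelineConfig:
    """Everything one run needs; defaults mirror the study settings
    (variance threshold 0.85, 20-PC floor, K = 5 factors, seed 13)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    variants: tuple[str, ...] = VARIANTS
    pca_threshold: float = 0.85
    pca_floor: int = 20
    center: bool = True
    scale: bool = True
    k: int = 5
    jdr_method: str = "mfa_svd"
    jdr_seed: int = 13
    fdr_alpha: float = 0.05
    gmt_path: str | None = None
    gsea_n_perm: int = 1000
    gsea_min_size: int = 15
    gsea_max_size: int = 500
    n_top_tfs: int = 20
    second_simulation: SimulationConfig | None = None
    outdir: str = "results/pipeline"

    def __post_init__(self) -> None:
        bad = [v for v in self.variants if v not in VARIANTS]
        if bad:
            raise ValueError(f"unknown model variants: {bad}")
        if not 0 < self.pca_threshold <= 1:
            raise ValueError("pca_threshold must lie in (0, 1]")
        if self.k < 1 or self.pca_floor < 1:
            raise ValueError("k and pca_floor must be positive")
        if self.gmt_path is not None and not Path(self.gmt_path).exists():
            raise FileNotFoundError(f"gene set file not found: {self.gmt_path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("simulation", "second_simulation"):
            if isinstance(raw.get(key), dict):
                sim = dict(raw[key])
                for tup in ("block_features", "block_names", "beta"):
                    if tup in sim:
                        sim[tup] = tuple(sim[tup])
                for nested in ("block_active_factors", "block_loading_scales"):
                    if nested in sim:
                        sim[nested] = tuple(tuple(v) for v in sim[nested])
                raw[key] = SimulationConfig(**sim)
        if "variants" in raw:
            raw["variants"] = tuple(raw["variants"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class VariantResult:
    """Artifacts of one model variant."""

    variant: str
    model: FactorModel
    assoc: pd.DataFrame
    weights: dict[str, FeatureWeights]
    filtered: list[FilteredBlock]


@dataclass
class ModelComparison:
    """Per-factor survival association across variants, plus summaries."""

    table: pd.DataFrame  # rows: (variant, factor); p, fdr, neglog10_fdr, saf
    summary: pd.DataFrame  # per variant: saf count, best fdr


def complete_case_samples(
    blocks: list[OmicsBlock],
    degrees: list[DegreeMatrix],
    survival: SurvivalTable,
    run_log: RunLog | None = None,
) -> list[str]:
    """Samples observed in every input, in the first block's order."""
    keep = list(blocks[0].sample_ids)
    universes = [set(b.sample_ids) for b in blocks]
    universes += [set(d.values.index) for d in degrees]
    universes.append(set(survival.data.dropna(subset=["time", "event"]).index))
    shared = set(keep).intersection(*universes)
    selected = [s for s in keep if s in shared]
    if len(selected) < 4:
        raise ValueError(f"only {len(selected)} complete-case samples; need >= 4")
    if run_log is not None:
        run_log.record(
            "complete_case",
            n_input=len(keep),
            n_selected=len(selected),
            n_dropped=len(keep) - len(selected),
        )
    return selected


def _variant_blocks(
    variant: str,
    omics: list[OmicsBlock],
    indeg: DegreeMatrix | None,
    outdeg: DegreeMatrix | None,
) -> list[OmicsBlock]:
    blocks = list(omics)
    if variant in ("indegree", "both"):
        if indeg is None:
            raise ValueError(f"variant {variant!r} requires an indegree matrix")
        blocks.append(indeg.as_block("indegree"))
    if variant in ("outdegree", "both"):
        if outdeg is None:
            raise ValueError(f"variant {variant!r} requires an outdegree matrix")
        blocks.append(outdeg.as_block("outdegree"))
    return blocks


def run_variant(
    omics: list[OmicsBlock],
    survival: SurvivalTable,
    variant: str,
    indeg: DegreeMatrix | None = None,
    outdeg: DegreeMatrix | None = None,
    config: PipelineConfig | None = None,
    run_log: RunLog | None = None,
) -> VariantResult:
    """Complete-case selection -> sd filter -> PCA filter -> JDR -> survival.

    The degree matrices are used only by the variants that request them, so
    the omics-only variant is unaffected by their presence in the inputs.
    """
    cfg = config or PipelineConfig()
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    blocks = _variant_blocks(variant, omics, indeg, outdeg)
    used_degrees = [d for d in (indeg, outdeg) if d is not None] if variant != "omics" else []
    samples = complete_case_samples(blocks, used_degrees, survival, run_log)
    blocks = [b.subset_samples(samples) for b in blocks]

    filtered = []
    for blk in blocks:
        n_before = blk.n_features
        blk = drop_zero_variance(blk)
        fb = filter_block(
            blk,
            threshold=cfg.pca_threshold,
            floor=cfg.pca_floor,
            center=cfg.center,
            scale=cfg.scale,
        )
        if run_log is not None:
            run_log.record(
                "pca_filter",
                variant=variant,
                block=blk.name,
                n_features_in=n_before,
                n_zero_variance_dropped=n_before - blk.n_features,
                k_selected=fb.k_selected,
                retained_variance=round(fb.retained_variance, 4),
            )
        filtered.append(fb)

    model = fit_jdr(filtered, k=cfg.k, method=cfg.jdr_method, seed=cfg.jdr_seed)
    sub_survival = SurvivalTable(
        survival.data.dropna(subset=["time", "event"]).loc[samples]
    )
    assoc = survival_assoc_table(model, sub_survival, alpha=cfg.fdr_alpha)
    weights = backmap_model(model, filtered)
    if run_log is not None:
        run_log.record(
            "variant_fitted",
            variant=variant,
            k=cfg.k,
            n_samples=len(samples),
            saf=[f for f, row in assoc.iterrows() if row["saf"]],
        )
    return VariantResult(variant, model, assoc, weights, filtered)


def compare_models(results: dict[str, VariantResult]) -> ModelComparison:
    """Survival-association comparison across >= 2 fitted variants."""
    if len(results) < 2:
        raise ValueError("model comparison needs at least 2 variants")
    tiny = np.finfo(float).tiny
    rows = []
    for variant, res in results.items():
        for f, row in res.assoc.iterrows():
            rows.append(
                {
                    "variant": variant,
                    "factor": f,
                    "p": row["p"],
                    "fdr": row["fdr"],
                    "neglog10_fdr": float(-np.log10(max(row["fdr"], tiny))),
                    "saf": bool(row["saf"]),
                }
            )
    table = pd.DataFrame(rows)
    summary = (
        table.groupby("variant", sort=False)
        .agg(saf_count=("saf", "sum"), best_fdr=("fdr", "min"))
        .reset_index()
    )
    return ModelComparison(table=table, summary=summary)


def _cohort_degrees(cohort: SyntheticCohort) -> tuple[DegreeMatrix, DegreeMatrix]:
    return indegree(cohort.networks), outdegree(cohort.networks)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured variants end-to-end and write all artifacts.

    Returns a bundle with the per-variant results, the model comparison,
    optional enrichment of the survival-associated factors' indegree
    weights, the optional cross-dataset top-TF overlap test, and the run
    log. Partial results are written as each stage completes.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_log = RunLog()
    bundle: dict = {"run_log": run_log}

    cohort = simulate_cohort(config.simulation)
    run_log.record("simulated", n_samples=config.simulation.n_samples,
                   seed=config.simulation.seed)
    indeg, outdeg = _cohort_degrees(cohort)

    results: dict[str, VariantResult] = {}
    for variant in config.variants:
        res = run_variant(
            cohort.omics, cohort.survival, variant,
            indeg=indeg, outdeg=outdeg, config=config, run_log=run_log,
        )
        results[variant] = res
        vdir = outdir / variant
        vdir.mkdir(exist_ok=True)
        res.model.factor_scores.to_csv(vdir / "factor_scores.tsv", sep="\t",
                                       index_label="sample")
        res.assoc.to_csv(vdir / "survival_assoc.tsv", sep="\t")
        res.model.variance_explained.to_csv(vdir / "variance_explained.tsv", sep="\t",
                                            index_label="block")
        for name, fw in res.weights.items():
            fw.weights.to_csv(vdir / f"weights_{name}.tsv", sep="\t",
                              index_label="feature")
    bundle["results"] = results

    if len(results) >= 2:
        comparison = compare_models(results)
        comparison.table.to_csv(outdir / "model_comparison.tsv", sep="\t", index=False)
        comparison.summary.to_csv(outdir / "model_summary.tsv", sep="\t", index=False)
        bundle["comparison"] = comparison

    interp = results.get("both") or results[config.variants[-1]]
    safs = [f for f, row in interp.assoc.iterrows() if row["saf"]]
    bundle["safs"] = {interp.variant: safs}

    if config.gmt_path and safs and "indegree" in interp.weights:
        sets = read_gmt(config.gmt_path)
        gsea = {}
        for f in safs:
            gsea[f] = gsea_preranked(
                interp.weights["indegree"].weights[f],
                sets,
                n_perm=config.gsea_n_perm,
                min_size=config.gsea_min_size,
                max_size=config.gsea_max_size,
                seed=config.jdr_seed,
            )
            gsea[f].to_csv(outdir / f"gsea_{interp.variant}_{f}.tsv", sep="\t")
        bundle["gsea"] = gsea
        run_log.record("gsea", factors=safs, n_sets=len(sets.sets))

    if config.second_simulation is not None and safs and "outdegree" in interp.weights:
        cohort2 = simulate_cohort(config.second_simulation)
        indeg2, outdeg2 = _cohort_degrees(cohort2)
        res2 = run_variant(
            cohort2.omics, cohort2.survival, interp.variant,
            indeg=indeg2, outdeg=outdeg2, config=config, run_log=run_log,
        )
        safs2 = [f for f, row in res2.assoc.iterrows() if row["saf"]]
        if safs2:
            top_a, _ = top_tfs(interp.weights["outdegree"], safs, config.n_top_tfs)
            top_b, _ = top_tfs(res2.weights["outdegree"], safs2, config.n_top_tfs)
            universe = set(interp.weights["outdegree"].weights.index) & set(
                res2.weights["outdegree"].weights.index
            )
            overlap = overlap_fisher(top_a & universe, top_b & universe, universe)
            bundle["tf_overlap"] = overlap
            run_log.record(
                "tf_overlap",
                n_a=len(top_a), n_b=len(top_b), universe=len(universe),
                intersection=overlap.a,
                odds_ratio=None if not np.isfinite(overlap.odds_ratio)
                else round(overlap.odds_ratio, 4),
                p_greater=round(overlap.p_greater, 6),
            )
        bundle["second"] = res2

    run_log.write(outdir / "run_log.yaml")
    return bundle
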