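"""Synthetic multi-omics cohort generator with known latent structure.

The generator emulates the statistical structure the downstream analysis
assumes: several Gaussian omics blocks sharing latent factors, a bipartite
regulatory prior whose per-sample edge weights vary with one factor, survival
times whose hazard depends on a subset of factors, and categorical clinical
features obtained by discretizing factors. The truth (latent scores,
generating loadings, hazard coefficients) is retained so recovery can be
scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    LatentFactors,
    MotifPrior,
    OmicsBlock,
    PpiPrior,
    SampleNetworkSet,
    SurvivalTable,
    SyntheticCohort,
)

__all__ = [
    "SimulationConfig",
    "simulate_latent_factors",
    "simulate_omics_block",
    "simulate_priors",
    "simulate_factor_dependent_networks",
    "simulate_survival",
    "simulate_clinical",
    "simulate_cohort",
]


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:04d}" for i in range(n)]


def simulate_latent_factors(n_samples: int, k_true: int, seed: int) -> LatentFactors:
    """Draw i.i.d. standard-normal factor scores and center each column.

    Parameters
    ----------
    n_samples : number of samples (rows), at least 2.
    k_true : number of latent factors (columns), at least 1.
    seed : RNG seed; identical seeds give identical score matrices.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be at least 2")
    if k_true < 1:
        raise ValueError("k_true must be at least 1")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_samples, k_true))
    z -= z.mean(axis=0, keepdims=True)
    scores = pd.DataFrame(
        z, index=_sample_ids(n_samples), columns=[f"Z{j + 1}" for j in range(k_true)]
    )
    return LatentFactors(scores)


def simulate_omics_block(
    factors: LatentFactors,
    name: str,
    n_features: int,
    active_factors: list[int],
    loading_scale: float | tuple[float, ...] = 1.0,
    noise_sd: float = 0.5,
    inject_constant_fraction: float = 0.0,
    seed: int = 0,
) -> OmicsBlock:
    """Generate one omic layer X = Z[:, active] L^T + E (features x samples).

    ``active_factors`` uses 1-based factor indices. Loadings L are
    Normal(0, loading_scale^2); a per-active-factor sequence of scales makes
    the factors enter the block with different strengths, which is what
    keeps them identifiable to a joint factorization. Noise E is
    Normal(0, noise_sd^2). A fraction of constant (sd = 0) features can be
    injected to exercise the zero-variance filter downstream.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if not 0 <= inject_constant_fraction <= 1:
        raise ValueError("inject_constant_fraction must be in [0, 1]")
    scales = np.atleast_1d(np.asarray(loading_scale, dtype=float))
    if not active_factors and scales.max(initial=0.0) > 0:
        raise ValueError("active_factors is empty but loading_scale > 0")
    if scales.size == 1:
        scales = np.repeat(scales, max(len(active_factors), 1))
    if active_factors and scales.size != len(active_factors):
        raise ValueError("loading_scale sequence must match active_factors")
    bad = [j for j in active_factors if not 1 <= j <= factors.k]
    if bad:
        raise ValueError(f"active factor indices out of range: {bad}")

    rng = np.random.default_rng(seed)
    n = len(factors.sample_ids)
    z = factors.scores.to_numpy()[:, [j - 1 for j in active_factors]]
    loadings = (
        rng.standard_normal((n_features, len(active_factors)))
        * scales[None, : len(active_factors)]
    )
    x = loadings @ z.T + rng.normal(0.0, noise_sd, size=(n_features, n))

    n_const = int(round(inject_constant_fraction * n_features))
    if n_const:
        const_rows = rng.choice(n_features, size=n_const, replace=False)
        x[const_rows, :] = rng.normal(0.0, 1.0, size=(n_const, 1))

    values = pd.DataFrame(
        x,
        index=[f"{name}_f{i:04d}" for i in range(n_features)],
        columns=factors.sample_ids,
    )
    return OmicsBlock(name, values)


def simulate_priors(
    n_tfs: int,
    n_genes: int,
    motif_density: float = 0.2,
    ppi_density: float = 0.1,
    seed: int = 0,
) -> tuple[MotifPrior, PpiPrior]:
    """Bernoulli motif prior (TF x gene) and symmetric unit-diagonal PPI prior."""
    if n_tfs < 2 or n_genes < 2:
        raise ValueError("need at least 2 TFs and 2 genes")
    if not (0 <= motif_density <= 1 and 0 <= ppi_density <= 1):
        raise ValueError("densities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    tf_ids = [f"TF{i:03d}" for i in range(n_tfs)]
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]

    motif = (rng.random((n_tfs, n_genes)) < motif_density).astype(float)
    # keep every TF row usable: guarantee at least one target
    empty = motif.sum(axis=1) == 0
    if empty.any():
        motif[empty, rng.integers(0, n_genes, size=int(empty.sum()))] = 1.0

    upper = (rng.random((n_tfs, n_tfs)) < ppi_density).astype(float)
    ppi = np.triu(upper, k=1)
    ppi = ppi + ppi.T
    np.fill_diagonal(ppi, 1.0)

    return (
        MotifPrior(pd.DataFrame(motif, index=tf_ids, columns=gene_ids)),
        PpiPrior(pd.DataFrame(ppi, index=tf_ids, columns=tf_ids)),
    )


def simulate_factor_dependent_networks(
    factors: LatentFactors,
    motif_prior: MotifPrior,
    edge_effect: float = 1.0,
    noise_sd: float = 0.1,
    baseline: float = 1.0,
    coupling_factor: int = 1,
    expr_noise_sd: float | None = None,
    seed: int = 0,
    pattern_seed: int | None = None,
) -> tuple[SampleNetworkSet, OmicsBlock]:
    """Per-sample edge weights that vary with one latent factor.

    Edge weight for sample q: w_q(t, g) = motif(t, g) * (baseline +
    edge_effect * z_q * u_t * v_g) + noise, with u (TF pattern) and v (gene
    pattern) fixed non-negative unit-norm vectors and z_q the sample's score
    on ``coupling_factor`` (1-based). Also emits a gene expression block in
    which each gene's value is the column sum of its incoming edge weights
    plus noise, so expression and network truth are coupled.

    ``pattern_seed`` fixes u and v independently of the per-sample noise, so
    two cohorts can share the same underlying regulatory program (the
    replication design) while drawing fresh samples.
    """
    if motif_prior.weights.to_numpy().sum() == 0:
        raise ValueError("motif prior has no edges")
    if not 1 <= coupling_factor <= factors.k:
        raise ValueError("coupling_factor out of range")
    rng = np.random.default_rng(seed)
    m = motif_prior.weights.to_numpy()
    n_tfs, n_genes = m.shape
    n = len(factors.sample_ids)
    z = factors.scores.to_numpy()[:, coupling_factor - 1]

    rng_pattern = np.random.default_rng(seed if pattern_seed is None else pattern_seed)
    u = np.abs(rng_pattern.standard_normal(n_tfs))
    u /= np.linalg.norm(u)
    v = np.abs(rng_pattern.standard_normal(n_genes))
    v /= np.linalg.norm(v)

    uv = np.outer(u, v)
    w = m[None, :, :] * (baseline + edge_effect * z[:, None, None] * uv[None, :, :])
    if noise_sd > 0:
        w = w + rng.normal(0.0, noise_sd, size=w.shape)

    networks = SampleNetworkSet(
        weights=w,
        sample_ids=factors.sample_ids,
        tf_ids=motif_prior.tf_ids,
        gene_ids=motif_prior.gene_ids,
    )

    if expr_noise_sd is None:
        expr_noise_sd = noise_sd
    expr = w.sum(axis=1).T  # genes x samples: incoming weight per gene
    if expr_noise_sd > 0:
        expr = expr + rng.normal(0.0, expr_noise_sd, size=expr.shape)
    expr_block = OmicsBlock(
        "network_expression",
        pd.DataFrame(expr, index=motif_prior.gene_ids, columns=factors.sample_ids),
    )
    return networks, expr_block


def simulate_survival(
    factors: LatentFactors,
    beta: np.ndarray,
    baseline_rate: float = 0.1,
    censor_rate: float = 0.03,
    seed: int = 0,
) -> SurvivalTable:
    """Exponential proportional-hazards outcomes with exponential censoring.

    Event time T ~ Exp(baseline_rate * exp(beta' z)); independent censoring
    C ~ Exp(censor_rate); observed time = min(T, C), event = 1[T <= C].
    """
    beta = np.asarray(beta, dtype=float)
    if baseline_rate <= 0 or censor_rate <= 0:
        raise ValueError("rates must be positive")
    if beta.shape != (factors.k,):
        raise ValueError(f"beta must have length {factors.k}")
    rng = np.random.default_rng(seed)
    z = factors.scores.to_numpy()
    rate = baseline_rate * np.exp(z @ beta)
    t_event = rng.exponential(1.0 / rate)
    t_censor = rng.exponential(1.0 / censor_rate, size=len(rate))
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    data = pd.DataFrame({"time": time, "event": event}, index=factors.sample_ids)
    return SurvivalTable(data)


def simulate_clinical(
    factors: LatentFactors, binary_factor: int = 2, ternary_factor: int = 3, seed: int = 0
) -> pd.DataFrame:
    """Categorical clinical features made by discretizing factors.

    A binary feature thresholds one factor at its median, a three-level
    feature cuts another at tertiles, and one pure-noise binary feature is
    included as a negative control.
    """
    rng = np.random.default_rng(seed)
    z = factors.scores.to_numpy()
    binary_factor = min(binary_factor, factors.k)
    ternary_factor = min(ternary_factor, factors.k)
    zb = z[:, binary_factor - 1]
    zt = z[:, ternary_factor - 1]
    tert = np.quantile(zt, [1 / 3, 2 / 3])
    levels = np.digitize(zt, tert)
    return pd.DataFrame(
        {
            "stage_binary": np.where(zb > np.median(zb), "high", "low"),
            "grade_ternary": np.array(["g1", "g2", "g3"])[levels],
            "noise_binary": np.where(rng.random(len(zb)) < 0.5, "a", "b"),
        },
        index=factors.sample_ids,
    )


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults are sized so the whole pipeline runs in minutes on one CPU:
    150 samples, three omics blocks of 300/150/400 features, a 40 TF x 300
    gene regulatory prior, four latent factors, hazard on factor 1 only.
    """

    n_samples: int = 150
    k_true: int = 4
    block_features: tuple[int, ...] = (300, 150, 400)
    block_names: tuple[str, ...] = ("expression", "mirna", "methylation")
    # factor 1 is a strong shared program across all layers (the survival-
    # and network-linked axis); the others are weaker and layer-specific,
    # with distinct joint strengths so the factorization is identifiable
    block_active_factors: tuple[tuple[int, ...], ...] = ((1, 3), (1, 2, 3), (1, 2, 4))
    block_loading_scales: tuple[tuple[float, ...], ...] | None = None
    noise_sd: float = 0.5
    inject_constant_fraction: float = 0.0
    n_tfs: int = 40
    n_genes: int = 300
    motif_density: float = 0.2
    ppi_density: float = 0.1
    edge_effect: float = 1.0
    network_noise_sd: float = 0.1
    network_baseline: float = 1.0
    coupling_factor: int = 1
    beta: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0)
    baseline_rate: float = 0.1
    censor_rate: float = 0.03
    seed: int = 13
    # when set, the regulatory structure (priors and coupling patterns) is
    # drawn from this seed so replicate cohorts share one regulatory program
    structure_seed: int | None = None

    def __post_init__(self) -> None:
        if self.block_loading_scales is None:
            if self.block_active_factors == type(self).block_active_factors:
                # staggered strengths keep the default factors identifiable
                self.block_loading_scales = (
                    (1.0, 0.28),
                    (1.0, 0.5, 0.28),
                    (1.0, 0.5, 0.22),
                )
            else:
                self.block_loading_scales = tuple(
                    (1.0,) * len(active) for active in self.block_active_factors
                )
        lengths = {
            len(self.block_features),
            len(self.block_names),
            len(self.block_active_factors),
            len(self.block_loading_scales),
        }
        if len(lengths) != 1:
            raise ValueError("block_* tuples must have equal lengths")
        for active, scales in zip(self.block_active_factors, self.block_loading_scales):
            if len(active) != len(scales):
                raise ValueError("block_loading_scales must match active factors")
        if len(self.beta) != self.k_true:
            raise ValueError("beta must have k_true entries")


def simulate_cohort(config: SimulationConfig | None = None) -> SyntheticCohort:
    """Bundle factors, omics, priors, networks, survival and clinical tables.

    All components share one sample universe; the returned ``truth`` dict
    holds the latent scores, network patterns and hazard coefficients needed
    to score recovery.
    """
    cfg = config or SimulationConfig()
    # derive independent per-component seeds from the master seed
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(8)]

    factors = simulate_latent_factors(cfg.n_samples, cfg.k_true, seeds[0])
    omics = [
        simulate_omics_block(
            factors,
            name,
            n_feat,
            list(active),
            loading_scale=scales,
            noise_sd=cfg.noise_sd,
            inject_constant_fraction=cfg.inject_constant_fraction,
            seed=seeds[1] + i,
        )
        for i, (name, n_feat, active, scales) in enumerate(
            zip(
                cfg.block_names,
                cfg.block_features,
                cfg.block_active_factors,
                cfg.block_loading_scales,
            )
        )
    ]
    struct = np.random.SeedSequence(
        cfg.seed if cfg.structure_seed is None else cfg.structure_seed
    )
    prior_seed, pattern_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in struct.spawn(2)
    )
    motif, ppi = simulate_priors(
        cfg.n_tfs, cfg.n_genes, cfg.motif_density, cfg.ppi_density, prior_seed
    )
    networks, net_expr = simulate_factor_dependent_networks(
        factors,
        motif,
        edge_effect=cfg.edge_effect,
        noise_sd=cfg.network_noise_sd,
        baseline=cfg.network_baseline,
        coupling_factor=cfg.coupling_factor,
        seed=seeds[3],
        pattern_seed=pattern_seed,
    )
    survival = simulate_survival(
        factors, np.asarray(cfg.beta), cfg.baseline_rate, cfg.censor_rate, seeds[4]
    )
    clinical = simulate_clinical(factors, seed=seeds[5])

    return SyntheticCohort(
        omics=omics,
        motif_prior=motif,
        ppi_prior=ppi,
        networks=networks,
        survival=survival,
        clinical=clinical,
        truth={
            "factors": factors,
            "network_expression": net_expr,
            "beta": np.asarray(cfg.beta),
            "config": cfg,
        },
    )
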