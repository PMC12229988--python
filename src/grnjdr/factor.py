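"""Joint factorization of PCA-filtered omics blocks.

The default backend ("mfa_svd") is a deterministic multiple-factor-analysis
style joint SVD: each block's component-score matrix is scaled by its own
first singular value (so no block dominates by sheer variance), the scaled
matrices are concatenated along features, and the top-K left singular
vectors of the concatenation become the shared factor scores. Per-block
weights are the corresponding slices of the right singular vectors times the
singular values, so scores @ weights' reconstructs each scaled block.

Because the backend is linear, factor weights fitted on principal-component
scores can be mapped back to original features exactly by multiplying the
PCA loadings with the factor weights; with all components retained this
equals fitting on the original features directly (up to per-factor sign).
Downstream interpretation relies on the resulting feature rankings rather
than the weight values themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .pca import FilteredBlock

__all__ = [
    "FactorModel",
    "FeatureWeights",
    "fit_jdr",
    "variance_explained",
    "backmap_weights",
    "backmap_model",
    "factor_correlation",
]


@dataclass
class FactorModel:
    """Shared sample-by-factor scores plus per-block weight matrices."""

    factor_scores: pd.DataFrame  # samples x K
    block_weights: dict[str, pd.DataFrame]  # per block: k_m PCs x K
    variance_explained: pd.DataFrame  # blocks x K
    method: str = "mfa_svd"
    seed: int = 13
    block_scale: dict[str, float] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.factor_scores.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.factor_scores.index)


@dataclass
class FeatureWeights:
    """Back-mapped factor weights on a block's original features."""

    block: str
    weights: pd.DataFrame  # features x K


def _scaled_centered_scores(blocks: list[FilteredBlock]) -> tuple[
    list[np.ndarray], list[str], dict[str, float]
]:
    samples = blocks[0].sample_ids
    for blk in blocks[1:]:
        missing = sorted(set(samples) ^ set(blk.sample_ids))
        if missing:
            raise ValueError(
                f"block {blk.name!r} does not share the sample universe; "
                f"mismatched samples: {missing[:10]}"
            )
    mats = []
    scales: dict[str, float] = {}
    for blk in blocks:
        s = blk.scores.loc[samples].to_numpy(dtype=float)
        s = s - s.mean(axis=0, keepdims=True)
        sigma1 = np.linalg.svd(s, compute_uv=False)[0]
        if sigma1 == 0:
            raise ValueError(f"block {blk.name!r} has no variance")
        mats.append(s / sigma1)
        scales[blk.name] = float(sigma1)
    return mats, samples, scales


def fit_jdr(
    blocks: list[FilteredBlock],
    k: int = 5,
    method: str = "mfa_svd",
    seed: int = 13,
    backend: Callable[..., FactorModel] | None = None,
) -> FactorModel:
    """Fit a K-factor linear joint decomposition across filtered blocks.

    ``backend`` allows plugging an external factorization with the same
    call signature and return type; the shipped deterministic backend is
    used otherwise. ``seed`` is recorded for provenance (and forwarded to
    stochastic backends) but does not affect the default backend.
    """
    if backend is not None:
        return backend(blocks, k=k, seed=seed)
    if method != "mfa_svd":
        raise ValueError(f"unknown JDR backend {method!r}")
    if k < 1:
        raise ValueError("k must be at least 1")
    if not blocks:
        raise ValueError("need at least one block")

    mats, samples, scales = _scaled_centered_scores(blocks)
    concat = np.hstack(mats)
    u, s, vt = np.linalg.svd(concat, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds available rank {rank}")

    z = u[:, :k]
    a = (vt.T * s)[:, :k]  # total PCs x K

    # per-factor sign: largest-|weight| entry of the concatenated weights positive
    flip = np.sign(a[np.abs(a).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    z = z * flip[None, :]
    a = a * flip[None, :]

    factors = [f"F{j + 1}" for j in range(k)]
    z_df = pd.DataFrame(z, index=samples, columns=factors)
    weights: dict[str, pd.DataFrame] = {}
    offset = 0
    for blk, mat in zip(blocks, mats):
        k_m = mat.shape[1]
        weights[blk.name] = pd.DataFrame(
            a[offset : offset + k_m], index=blk.scores.columns, columns=factors
        )
        offset += k_m

    model = FactorModel(
        factor_scores=z_df,
        block_weights=weights,
        variance_explained=pd.DataFrame(),
        method=method,
        seed=seed,
        block_scale=scales,
    )
    model.variance_explained = variance_explained(model, blocks)
    return model


def variance_explained(model: FactorModel, blocks: list[FilteredBlock]) -> pd.DataFrame:
    """Per-block, per-factor fraction of variance explained.

    R2[m, k] = 1 - ||S_m - z_k a_{m,k}'||_F^2 / ||S_m||_F^2 on the centered,
    block-scaled score matrices the fit consumed.
    """
    mats, samples, _ = _scaled_centered_scores(blocks)
    if list(model.factor_scores.index) != samples:
        raise ValueError("model was not fitted on these blocks (sample mismatch)")
    z = model.factor_scores.to_numpy(dtype=float)
    out = np.zeros((len(blocks), model.k))
    for m, (blk, s_m) in enumerate(zip(blocks, mats)):
        a_m = model.block_weights[blk.name].to_numpy(dtype=float)
        if a_m.shape != (s_m.shape[1], model.k):
            raise ValueError(f"weight shape mismatch for block {blk.name!r}")
        total = (s_m**2).sum()
        for j in range(model.k):
            resid = s_m - np.outer(z[:, j], a_m[:, j])
            out[m, j] = 1.0 - (resid**2).sum() / total
    return pd.DataFrame(
        out, index=[b.name for b in blocks], columns=list(model.factor_scores.columns)
    )


def backmap_weights(
    pca_loadings: pd.DataFrame, block_weights: pd.DataFrame, block: str = ""
) -> FeatureWeights:
    """Map factor weights from PC space to original features: W = L @ A.

    No normalization is applied; the downstream contract is the ranking of
    features by absolute weight, which is robust to the truncation error
    introduced by discarding low-variance components.
    """
    if pca_loadings.shape[1] != block_weights.shape[0]:
        raise ValueError(
            f"inner dimensions disagree: loadings {pca_loadings.shape} vs "
            f"weights {block_weights.shape}"
        )
    w = pca_loadings.to_numpy(dtype=float) @ block_weights.to_numpy(dtype=float)
    return FeatureWeights(
        block=block,
        weights=pd.DataFrame(
            w, index=pca_loadings.index, columns=block_weights.columns
        ),
    )


def backmap_model(
    model: FactorModel, blocks: list[FilteredBlock]
) -> dict[str, FeatureWeights]:
    """Back-map every block of a fitted model to original-feature weights."""
    out = {}
    for blk in blocks:
        out[blk.name] = backmap_weights(
            blk.pca.loadings, model.block_weights[blk.name], block=blk.name
        )
    return out


def factor_correlation(model_a: FactorModel, model_b: FactorModel) -> pd.DataFrame:
    """Absolute Pearson correlation between two models' factor scores.

    Computed on the shared samples; at least 3 are required.
    """
    shared = [s for s in model_a.sample_ids if s in set(model_b.sample_ids)]
    if len(shared) < 3:
        raise ValueError("factor correlation needs at least 3 shared samples")
    za = model_a.factor_scores.loc[shared].to_numpy(dtype=float)
    zb = model_b.factor_scores.loc[shared].to_numpy(dtype=float)
    ka, kb = za.shape[1], zb.shape[1]
    corr = np.corrcoef(za.T, zb.T)[:ka, ka:]
    return pd.DataFrame(
        np.abs(corr),
        index=list(model_a.factor_scores.columns),
        columns=list(model_b.factor_scores.columns),
    )
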