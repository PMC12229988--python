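"""Per-omic dimensionality filtering.

Each omic block is reduced to the smallest number of principal components
whose cumulative explained variance reaches a threshold (default 0.85), with
a floor on the component count (default 20, capped at the block's rank) so
that blocks of very different widths enter the joint factorization with
dimensionalities within an order of magnitude of each other.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import OmicsBlock

__all__ = [
    "PcaModel",
    "FilteredBlock",
    "drop_zero_variance",
    "fit_pca",
    "select_num_pcs",
    "filter_block",
]

log = logging.getLogger(__name__)


@dataclass
class PcaModel:
    """SVD-based PCA of one block, features treated as variables.

    ``scores`` is samples x k (principal component scores, U*S), ``loadings``
    is features x k with orthonormal columns, and ``variance_ratios`` the
    per-component share of total variance, non-increasing. ``center`` and
    ``scale`` record the per-feature shift and divisor applied before the
    decomposition.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_ratios: np.ndarray
    center: pd.Series
    scale: pd.Series

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    def truncate(self, k: int) -> "PcaModel":
        return PcaModel(
            scores=self.scores.iloc[:, :k],
            loadings=self.loadings.iloc[:, :k],
            variance_ratios=self.variance_ratios[:k],
            center=self.center,
            scale=self.scale,
        )


@dataclass
class FilteredBlock:
    """A block reduced to its selected principal components."""

    name: str
    pca: PcaModel
    k_selected: int
    retained_variance: float

    @property
    def scores(self) -> pd.DataFrame:
        """Samples x k_selected component scores, the JDR input."""
        return self.pca.scores

    @property
    def sample_ids(self) -> list[str]:
        return list(self.pca.scores.index)


def drop_zero_variance(block: OmicsBlock) -> OmicsBlock:
    """Remove features whose sample standard deviation is exactly zero.

    Constancy is detected as max == min, which is exact where a computed
    standard deviation of a constant feature can pick up rounding noise.
    """
    x = block.values.to_numpy(dtype=float)
    keep = x.max(axis=1) > x.min(axis=1)
    n_drop = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError(f"block {block.name!r}: all features are constant")
    if n_drop == 0:
        return block
    log.info("block %s: dropped %d zero-variance features", block.name, n_drop)
    return OmicsBlock(block.name, block.values.loc[keep])


def fit_pca(block: OmicsBlock, center: bool = True, scale: bool = True) -> PcaModel:
    """Full singular value decomposition of the (centered/scaled) block.

    The matrix handed to the SVD is samples x features; scores are U*S and
    loadings the right singular vectors. Component signs are fixed so the
    loading entry of largest magnitude is positive, making the decomposition
    reproducible despite SVD sign ambiguity.
    """
    if block.n_samples < 2 or block.n_features < 2:
        raise ValueError("PCA needs at least 2 samples and 2 features")
    x = block.values.to_numpy(dtype=float).T  # samples x features
    mu = x.mean(axis=0) if center else np.zeros(x.shape[1])
    x = x - mu
    if scale:
        sd = x.std(axis=0, ddof=1)
        flat = x.max(axis=0) == x.min(axis=0)
        if flat.any():
            bad = [f for f, z in zip(block.feature_ids, flat) if z]
            raise ValueError(f"cannot scale zero-variance features: {bad[:10]}")
    else:
        sd = np.ones(x.shape[1])
    x = x / sd

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]

    total = (s**2).sum()
    ratios = s**2 / total if total > 0 else np.zeros_like(s)
    pcs = [f"PC{j + 1}" for j in range(len(s))]
    return PcaModel(
        scores=pd.DataFrame(u * s, index=block.sample_ids, columns=pcs),
        loadings=pd.DataFrame(vt.T, index=block.feature_ids, columns=pcs),
        variance_ratios=ratios,
        center=pd.Series(mu, index=block.feature_ids),
        scale=pd.Series(sd, index=block.feature_ids),
    )


def select_num_pcs(
    variance_ratios: np.ndarray, threshold: float = 0.85, floor: int = 20
) -> int:
    """Smallest component count reaching the cumulative variance threshold,
    raised to ``floor`` and capped at the number of available components."""
    r = np.asarray(variance_ratios, dtype=float)
    if r.size == 0:
        raise ValueError("empty variance ratio vector")
    if (r < -1e-12).any():
        raise ValueError("variance ratios must be non-negative")
    cum = np.cumsum(r)
    reaches = np.nonzero(cum >= threshold - 1e-12)[0]
    k_needed = int(reaches[0]) + 1 if reaches.size else r.size
    return int(min(max(floor, k_needed), r.size))


def filter_block(
    block: OmicsBlock,
    threshold: float = 0.85,
    floor: int = 20,
    center: bool = True,
    scale: bool = True,
) -> FilteredBlock:
    """Zero-variance filter, PCA fit, and component selection for one block."""
    block = drop_zero_variance(block)
    pca = fit_pca(block, center=center, scale=scale)
    if floor > pca.k:
        warnings.warn(
            f"block {block.name!r}: floor {floor} exceeds available rank "
            f"{pca.k}; capping",
            stacklevel=2,
        )
    k = select_num_pcs(pca.variance_ratios, threshold=threshold, floor=floor)
    retained = float(np.cumsum(pca.variance_ratios)[k - 1])
    log.info(
        "block %s: selected %d/%d PCs (retained variance %.3f)",
        block.name,
        k,
        pca.k,
        retained,
    )
    return FilteredBlock(
        name=block.name, pca=pca.truncate(k), k_selected=k, retained_variance=retained
    )
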