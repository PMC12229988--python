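"""Bipartite gene regulatory network inference and degree summaries.

The aggregate network is estimated by message passing between three inputs —
a TF-by-gene motif prior, a TF-by-TF interaction prior, and gene
co-expression — seeking agreement between them: TFs that interact should
share targets, and co-expressed genes should share regulators. Single-sample
networks are then obtained by linear interpolation: each sample's network is
the aggregate plus N times the shift observed when that sample is removed.

Edge weights live on a z-score-like scale and may be negative; the sign
scores interaction likelihood, not activation versus repression, and degree
summaries deliberately sum the signed weights as-is.
"""

from __future__ import annotations

from typing import Callable, Iterator

import numpy as np
import pandas as pd

from .datatypes import (
    AggregateGRN,
    CoexpressionMatrix,
    DegreeMatrix,
    MotifPrior,
    OmicsBlock,
    PpiPrior,
    SampleNetworkSet,
)

__all__ = [
    "compute_coexpression",
    "panda_aggregate",
    "lioness_networks",
    "lioness_iter",
    "indegree",
    "outdegree",
    "make_panda_network_fn",
    "make_masked_coexpression_fn",
    "make_mean_contribution_fn",
]

NetworkFn = Callable[[OmicsBlock], pd.DataFrame]


def compute_coexpression(expr: OmicsBlock) -> CoexpressionMatrix:
    """Pairwise Pearson correlation of gene rows across samples.

    Zero-variance genes are a hard error (they must be filtered upstream)
    and are reported by name.
    """
    if expr.n_samples < 3:
        raise ValueError("co-expression needs at least 3 samples")
    x = expr.values.to_numpy(dtype=float)
    sd = x.std(axis=1)
    dead = [g for g, s in zip(expr.feature_ids, sd) if s == 0]
    if dead:
        raise ValueError(f"zero-variance genes in expression: {dead[:10]}")
    c = np.corrcoef(x)
    np.fill_diagonal(c, 1.0)
    return CoexpressionMatrix(
        pd.DataFrame(c, index=expr.feature_ids, columns=expr.feature_ids)
    )


def _zscore_network(w: np.ndarray) -> np.ndarray:
    """Combined row/column z-score, (z_rows + z_cols) / sqrt(2).

    Rows or columns with zero spread fall back to the overall z-score so a
    flat prior still normalizes to something finite.
    """
    mu_r = w.mean(axis=1, keepdims=True)
    sd_r = w.std(axis=1, keepdims=True)
    mu_c = w.mean(axis=0, keepdims=True)
    sd_c = w.std(axis=0, keepdims=True)
    mu_all = w.mean()
    sd_all = w.std()
    if sd_all == 0:
        sd_all = 1.0
    z_all = (w - mu_all) / sd_all
    with np.errstate(divide="ignore", invalid="ignore"):
        z_r = (w - mu_r) / sd_r
        z_c = (w - mu_c) / sd_c
    z_r = np.where(np.isfinite(z_r), z_r, z_all)
    z_c = np.where(np.isfinite(z_c), z_c, z_all)
    return (z_r + z_c) / np.sqrt(2.0)


def _damped_self_similarity(
    sim: np.ndarray, num: int, alpha: float, step: int
) -> np.ndarray:
    """Replace the diagonal of a self-similarity matrix with an inflated
    value (off-diagonal spread scaled by matrix size and step count).

    The raw diagonal equals each profile's norm, which feeds back into the
    next round's similarities and makes the iteration diverge; the inflated
    diagonal instead grows the denominator of subsequent similarities and
    damps the updates, as in the reference message-passing implementations.
    """
    s = sim.copy()
    np.fill_diagonal(s, np.nan)
    spread = np.nanstd(s, axis=1, ddof=1)
    np.fill_diagonal(s, spread * num * np.exp(2 * alpha * step))
    return s


def _tanimoto(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Continuous Tanimoto similarity between the rows of ``a`` and columns
    of ``b``: T(x, y) = <x,y> / sqrt(|x|^2 + |y|^2 - |<x,y>|)."""
    dot = a @ b
    na = (a * a).sum(axis=1)
    nb = (b * b).sum(axis=0)
    denom = np.sqrt(na[:, None] + nb[None, :] - np.abs(dot))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = dot / denom
    return np.where(np.isfinite(t), t, 0.0)


def panda_aggregate(
    motif: MotifPrior,
    ppi: PpiPrior,
    coexpr: CoexpressionMatrix,
    alpha: float = 0.1,
    tol: float = 1e-3,
    max_iter: int = 200,
) -> AggregateGRN:
    """Message-passing agreement between motif, interaction and co-expression.

    All three inputs are z-score normalized. Each iteration computes a
    responsibility R (agreement between the TF interaction profile and each
    gene's regulator profile) and an availability A (agreement between each
    TF's target profile and the gene co-expression profile) via continuous
    Tanimoto similarity, then moves the edge matrix a step alpha towards
    their mean; the interaction and co-expression matrices are updated the
    same way from the current edge matrix's row/column similarities.

    Convergence is declared when the mean absolute edge change drops below
    ``tol``. With alpha = 0 the update is the identity and the normalized
    motif prior is returned, converged after one iteration.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if list(ppi.tf_ids) != list(motif.tf_ids):
        raise ValueError("PPI prior TFs disagree with motif prior TFs")
    if list(coexpr.gene_ids) != list(motif.gene_ids):
        raise ValueError("co-expression genes disagree with motif prior genes")
    for nm, arr in [
        ("motif", motif.weights),
        ("ppi", ppi.weights),
        ("coexpression", coexpr.values),
    ]:
        if not np.all(np.isfinite(arr.to_numpy(dtype=float))):
            raise ValueError(f"non-finite values in {nm} input")

    w = _zscore_network(motif.weights.to_numpy(dtype=float))
    p = _zscore_network(ppi.weights.to_numpy(dtype=float))
    c = _zscore_network(coexpr.values.to_numpy(dtype=float))

    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        r = _tanimoto(p, w)  # TF x gene: interaction rows vs edge columns
        a = _tanimoto(w, c)  # TF x gene: edge rows vs co-expression columns
        w_new = (1 - alpha) * w + alpha * 0.5 * (r + a)
        delta = float(np.abs(w_new - w).mean())
        w = w_new
        if delta < tol:
            converged = True
            break
        # co-smoothing of the helper networks from the updated edges,
        # with the diagonal damped to keep the iteration stable
        p = (1 - alpha) * p + alpha * _damped_self_similarity(
            _tanimoto(w, w.T), w.shape[0], alpha, n_iter - 1
        )
        c = (1 - alpha) * c + alpha * _damped_self_similarity(
            _tanimoto(w.T, w), w.shape[1], alpha, n_iter - 1
        )
    return AggregateGRN(
        weights=pd.DataFrame(w, index=motif.tf_ids, columns=motif.gene_ids),
        converged=converged,
        n_iterations=n_iter if max_iter > 0 else 0,
    )


def lioness_iter(
    samples: OmicsBlock, network_fn: NetworkFn
) -> Iterator[tuple[str, pd.DataFrame]]:
    """Yield (sample_id, single-sample network) one sample at a time.

    The single-sample network is e(q) = N * (e(all) - e(-q)) + e(-q), where
    e(all) is ``network_fn`` on the full block and e(-q) on all samples but
    q. Streaming keeps only two networks in memory at once, so the full
    samples-by-edges array never needs to exist.
    """
    n = samples.n_samples
    if n < 2:
        raise ValueError("leave-one-out networks need at least 2 samples")
    template = network_fn(samples)
    e_all = template.to_numpy(dtype=float)
    for q, sid in enumerate(samples.sample_ids):
        rest = [s for s in samples.sample_ids if s != sid]
        e_minus = network_fn(samples.subset_samples(rest)).to_numpy(dtype=float)
        e_q = n * (e_all - e_minus) + e_minus
        yield sid, pd.DataFrame(e_q, index=template.index, columns=template.columns)


def lioness_networks(samples: OmicsBlock, network_fn: NetworkFn) -> SampleNetworkSet:
    """Materialize all single-sample networks from :func:`lioness_iter`."""
    mats = []
    sids = []
    tf_ids: list[str] = []
    gene_ids: list[str] = []
    for sid, net in lioness_iter(samples, network_fn):
        sids.append(sid)
        if not tf_ids:
            tf_ids = list(net.index)
            gene_ids = list(net.columns)
        mats.append(net.to_numpy(dtype=float))
    return SampleNetworkSet(
        weights=np.stack(mats, axis=0),
        sample_ids=sids,
        tf_ids=tf_ids,
        gene_ids=gene_ids,
    )


def indegree(networks: SampleNetworkSet) -> DegreeMatrix:
    """Per sample and gene, the summed weight of incoming edges from all TFs."""
    vals = networks.weights.sum(axis=1)  # samples x genes
    return DegreeMatrix(
        pd.DataFrame(vals, index=networks.sample_ids, columns=networks.gene_ids),
        node_kind="gene",
    )


def outdegree(networks: SampleNetworkSet) -> DegreeMatrix:
    """Per sample and TF, the summed weight of outgoing edges to all genes."""
    vals = networks.weights.sum(axis=2)  # samples x TFs
    return DegreeMatrix(
        pd.DataFrame(vals, index=networks.sample_ids, columns=networks.tf_ids),
        node_kind="tf",
    )


# ---------------------------------------------------------------------------
# shipped network_fn factories for lioness_networks


def make_panda_network_fn(
    motif: MotifPrior,
    ppi: PpiPrior,
    alpha: float = 0.1,
    tol: float = 1e-3,
    max_iter: int = 200,
) -> NetworkFn:
    """Aggregate-network estimator that runs the full message-passing fit."""

    def fn(expr: OmicsBlock) -> pd.DataFrame:
        sub = OmicsBlock(expr.name, expr.values.loc[motif.gene_ids])
        coexpr = compute_coexpression(sub)
        return panda_aggregate(motif, ppi, coexpr, alpha, tol, max_iter).weights

    return fn


def make_masked_coexpression_fn(motif: MotifPrior) -> NetworkFn:
    """Motif-masked TF-gene Pearson correlation network.

    Requires the expression block to carry rows for both the prior's TFs and
    its genes; the edge weight is corr(TF expression, gene expression) on
    prior-supported pairs, zero elsewhere.
    """

    def fn(expr: OmicsBlock) -> pd.DataFrame:
        missing = [g for g in motif.tf_ids + motif.gene_ids if g not in expr.values.index]
        if missing:
            raise KeyError(f"expression lacks rows for: {missing[:10]}")
        tf_x = expr.values.loc[motif.tf_ids].to_numpy(dtype=float)
        g_x = expr.values.loc[motif.gene_ids].to_numpy(dtype=float)
        tf_c = tf_x - tf_x.mean(axis=1, keepdims=True)
        g_c = g_x - g_x.mean(axis=1, keepdims=True)
        denom = np.outer(
            np.sqrt((tf_c**2).sum(axis=1)), np.sqrt((g_c**2).sum(axis=1))
        )
        if (denom == 0).any():
            raise ValueError("zero-variance rows in masked co-expression input")
        corr = (tf_c @ g_c.T) / denom
        return pd.DataFrame(
            corr * motif.weights.to_numpy(dtype=float),
            index=motif.tf_ids,
            columns=motif.gene_ids,
        )

    return fn


def make_mean_contribution_fn(
    per_sample_fn: Callable[[pd.Series], pd.DataFrame]
) -> NetworkFn:
    """Estimator defined as the mean of per-sample contribution matrices.

    For any such estimator the interpolation identity recovers each
    contribution exactly: e(q) = N*e(all) - (N-1)*e(-q) = f(q). Used as the
    exact test oracle for the single-sample reconstruction.
    """

    def fn(expr: OmicsBlock) -> pd.DataFrame:
        mats = [per_sample_fn(expr.values[s]) for s in expr.sample_ids]
        out = mats[0].copy()
        out.loc[:, :] = np.mean([m.to_numpy(dtype=float) for m in mats], axis=0)
        return out

    return fn
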