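"""Core containers shared across the pipeline.

Conventions: omics matrices are features x samples (rows are molecular
features); factor score and degree matrices are samples x columns. All
containers carry explicit string identifiers so that sample alignment is
checked, never assumed positional.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} identifiers")


@dataclass
class OmicsBlock:
    """One omic layer: a named feature-by-sample numeric matrix."""

    name: str
    values: pd.DataFrame  # features x samples

    def __post_init__(self) -> None:
        _check_unique(list(self.values.index), "feature")
        _check_unique(list(self.values.columns), "sample")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError(f"block {self.name!r} contains non-finite values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, samples: Sequence[str]) -> "OmicsBlock":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise KeyError(f"block {self.name!r} missing samples: {missing}")
        return OmicsBlock(self.name, self.values.loc[:, list(samples)])


@dataclass
class LatentFactors:
    """Ground-truth latent structure: column-centered samples x K scores."""

    scores: pd.DataFrame  # samples x K_true

    def __post_init__(self) -> None:
        _check_unique(list(self.scores.index), "sample")
        if self.scores.shape[1] < 1:
            raise ValueError("need at least one latent factor")
        if self.scores.isna().any().any():
            raise ValueError("latent scores contain missing values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def k(self) -> int:
        return self.scores.shape[1]


@dataclass
class MotifPrior:
    """TF-by-gene sequence-based prior (typically 0/1 before normalization)."""

    weights: pd.DataFrame  # TFs x genes

    def __post_init__(self) -> None:
        _check_unique(list(self.weights.index), "TF")
        _check_unique(list(self.weights.columns), "gene")
        if self.weights.isna().any().any():
            raise ValueError("motif prior contains missing entries")

    @property
    def tf_ids(self) -> list[str]:
        return list(self.weights.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.weights.columns)


@dataclass
class PpiPrior:
    """Symmetric TF-by-TF interaction prior with unit diagonal."""

    weights: pd.DataFrame

    def __post_init__(self) -> None:
        w = self.weights.to_numpy(dtype=float)
        if w.shape[0] != w.shape[1]:
            raise ValueError("PPI prior must be square")
        if not np.allclose(w, w.T):
            raise ValueError("PPI prior must be symmetric")
        if not np.allclose(np.diag(w), 1.0):
            raise ValueError("PPI prior must have unit diagonal")

    @property
    def tf_ids(self) -> list[str]:
        return list(self.weights.index)


@dataclass
class CoexpressionMatrix:
    """Gene-by-gene Pearson correlation across samples."""

    values: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class AggregateGRN:
    """Population-level complete bipartite TF-by-gene network.

    Edge weights are on a z-score-like scale and may be negative; the sign
    scores interaction likelihood, not activation versus repression.
    """

    weights: pd.DataFrame  # TFs x genes
    converged: bool = True
    n_iterations: int = 0

    @property
    def tf_ids(self) -> list[str]:
        return list(self.weights.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.weights.columns)


@dataclass
class SampleNetworkSet:
    """Per-sample edge weights over a shared complete bipartite edge universe."""

    weights: np.ndarray  # n_samples x n_tfs x n_genes
    sample_ids: list[str]
    tf_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        n, t, g = self.weights.shape
        if n < 1:
            raise ValueError("need at least one sample network")
        if (n, t, g) != (len(self.sample_ids), len(self.tf_ids), len(self.gene_ids)):
            raise ValueError("network array shape disagrees with identifier lists")

    @property
    def n_samples(self) -> int:
        return self.weights.shape[0]


@dataclass
class DegreeMatrix:
    """Per-sample node degrees: gene indegrees or TF outdegrees."""

    values: pd.DataFrame  # samples x nodes
    node_kind: str  # "gene" (indegree) or "tf" (outdegree)

    def __post_init__(self) -> None:
        if self.node_kind not in ("gene", "tf"):
            raise ValueError("node_kind must be 'gene' or 'tf'")

    def as_block(self, name: str) -> OmicsBlock:
        """View the degree matrix as an omics block (features x samples)."""
        return OmicsBlock(name, self.values.T.copy())


@dataclass
class SurvivalTable:
    """Right-censored survival outcomes, one row per sample."""

    data: pd.DataFrame  # index: sample_id; columns: time, event

    def __post_init__(self) -> None:
        if not {"time", "event"} <= set(self.data.columns):
            raise ValueError("survival table needs 'time' and 'event' columns")
        ok = self.data.dropna()
        if (ok["time"] <= 0).any():
            raise ValueError("survival times must be positive")
        if not set(ok["event"].unique()) <= {0, 1}:
            raise ValueError("event indicator must be 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class SyntheticCohort:
    """A complete simulated study: omics, priors, networks, outcomes, truth."""

    omics: list[OmicsBlock]
    motif_prior: MotifPrior
    ppi_prior: PpiPrior
    networks: SampleNetworkSet
    survival: SurvivalTable
    clinical: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        universe = set(self.omics[0].sample_ids)
        for blk in self.omics:
            if set(blk.sample_ids) != universe:
                raise ValueError(f"block {blk.name!r} breaks the shared sample universe")
        for other, label in [
            (set(self.networks.sample_ids), "networks"),
            (set(self.survival.sample_ids), "survival"),
            (set(self.clinical.index), "clinical"),
        ]:
            if other != universe:
                raise ValueError(f"{label} sample ids differ from the omics blocks")

    @property
    def sample_ids(self) -> list[str]:
        return self.omics[0].sample_ids
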