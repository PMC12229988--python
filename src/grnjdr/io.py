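"""TSV/YAML serialization for cohorts, networks, and model artifacts.

Everything is plain text: omics blocks as feature-by-sample TSV with the
feature identifier in the first column, survival and clinical tables as
sample-indexed TSV, priors as dense TSV matrices, per-sample networks as
long-format edge tables, and a YAML manifest indexing the files of a run.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    MotifPrior,
    OmicsBlock,
    PpiPrior,
    SampleNetworkSet,
    SurvivalTable,
    SyntheticCohort,
)

__all__ = [
    "write_block",
    "read_block",
    "write_matrix",
    "read_matrix",
    "write_survival",
    "read_survival",
    "write_networks_edges",
    "write_cohort",
    "read_cohort",
]


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_block(block: OmicsBlock, path: str | Path) -> None:
    write_matrix(block.values, path, index_label="feature")


def read_block(path: str | Path, name: str | None = None) -> OmicsBlock:
    path = Path(path)
    return OmicsBlock(name or path.stem, read_matrix(path))


def write_survival(survival: SurvivalTable, path: str | Path) -> None:
    survival.data.to_csv(path, sep="\t", index_label="sample", float_format="%.10g")


def read_survival(path: str | Path) -> SurvivalTable:
    return SurvivalTable(pd.read_csv(path, sep="\t", index_col=0))


def write_networks_edges(networks: SampleNetworkSet, path: str | Path) -> None:
    """Long-format edge table: sample, tf, gene, weight."""
    n, t, g = networks.weights.shape
    df = pd.DataFrame(
        {
            "sample": np.repeat(networks.sample_ids, t * g),
            "tf": np.tile(np.repeat(networks.tf_ids, g), n),
            "gene": np.tile(networks.gene_ids, n * t),
            "weight": networks.weights.reshape(-1),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_cohort(cohort: SyntheticCohort, outdir: str | Path,
                 include_networks: bool = False) -> Path:
    """Write all cohort components under ``outdir`` and return the manifest path.

    The dense per-sample network array is large; by default only priors,
    omics, outcomes and the truth tables are written, with the networks
    opt-in as a long-format edge table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"omics": {}, "seed": getattr(
        cohort.truth.get("config"), "seed", None)}
    for blk in cohort.omics:
        p = outdir / f"omics_{blk.name}.tsv"
        write_block(blk, p)
        manifest["omics"][blk.name] = p.name
    write_matrix(cohort.motif_prior.weights, outdir / "motif_prior.tsv", "tf")
    write_matrix(cohort.ppi_prior.weights, outdir / "ppi_prior.tsv", "tf")
    write_survival(cohort.survival, outdir / "survival.tsv")
    cohort.clinical.to_csv(outdir / "clinical.tsv", sep="\t", index_label="sample")
    manifest.update(
        motif_prior="motif_prior.tsv",
        ppi_prior="ppi_prior.tsv",
        survival="survival.tsv",
        clinical="clinical.tsv",
    )
    truth_factors = cohort.truth.get("factors")
    if truth_factors is not None:
        write_matrix(truth_factors.scores, outdir / "truth_factors.tsv", "sample")
        manifest["truth_factors"] = "truth_factors.tsv"
    if include_networks:
        write_networks_edges(cohort.networks, outdir / "networks_edges.tsv")
        manifest["networks"] = "networks_edges.tsv"
    manifest_path = outdir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path


def read_cohort(manifest_path: str | Path) -> dict:
    """Read the components listed in a cohort manifest into a dict.

    Returns keys: omics (list of OmicsBlock), motif_prior, ppi_prior,
    survival, clinical, and truth_factors when present. Per-sample networks
    are not materialized here.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    out: dict = {
        "omics": [
            read_block(base / fname, name)
            for name, fname in manifest["omics"].items()
        ],
        "motif_prior": MotifPrior(read_matrix(base / manifest["motif_prior"])),
        "ppi_prior": PpiPrior(read_matrix(base / manifest["ppi_prior"])),
        "survival": read_survival(base / manifest["survival"]),
        "clinical": pd.read_csv(base / manifest["clinical"], sep="\t", index_col=0),
        "seed": manifest.get("seed"),
    }
    if "truth_factors" in manifest:
        out["truth_factors"] = read_matrix(base / manifest["truth_factors"])
    return out
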