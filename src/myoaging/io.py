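"""Readers and writers for the plain-text formats used throughout the package.

Count matrices travel as MatrixMarket ``matrix.mtx`` plus ``barcodes.tsv`` /
``features.tsv`` (10x convention, uncompressed), with per-cell metadata in
``obs.tsv``.  Gene sets use GMT, everything else tab-separated tables.
Floats are written with 9 significant digits so that repeated runs with the
same seed produce byte-identical files.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

FLOAT_FORMAT = "%.9g"


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a table with stable column order and fixed float formatting."""
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_counts(adata: ad.AnnData, outdir: str | Path) -> None:
    """Write an AnnData as MTX + barcodes/features + obs metadata TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = sp.csr_matrix(adata.X)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), X.T.tocoo(), field="integer")
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    pd.Series(adata.var_names).to_csv(
        outdir / "features.tsv", sep="\t", index=False, header=False
    )
    obs = adata.obs.reset_index(names="cell_id")
    write_tsv(obs, outdir / "obs.tsv")


def read_counts(indir: str | Path) -> ad.AnnData:
    """Read a directory written by :func:`write_counts`."""
    indir = Path(indir)
    X = scipy.io.mmread(str(indir / "matrix.mtx")).T.tocsr()
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    features = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0].astype(str)
    adata = ad.AnnData(X=X)
    adata.obs_names = list(barcodes)
    adata.var_names = list(features)
    obs_path = indir / "obs.tsv"
    if obs_path.exists():
        obs = pd.read_csv(obs_path, sep="\t")
        obs = obs.set_index("cell_id")
        obs.index = obs.index.astype(str)
        adata.obs = obs.loc[adata.obs_names]
    return adata


def write_gmt(gene_sets: dict[str, list[str]], path: str | Path) -> None:
    """Write gene sets in GMT format (name, description, members)."""
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, "synthetic"] + list(genes)) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    gene_sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            gene_sets[parts[0]] = [g for g in parts[2:] if g]
    return gene_sets


def read_lr_table(path: str | Path) -> pd.DataFrame:
    """Read a ligand-receptor pair table, deduplicating repeated pairs.

    Columns: interaction_id, ligand, receptor_subunits (semicolon separated).
    """
    df = pd.read_csv(path, sep="\t")
    return dedup_lr_table(df)


def dedup_lr_table(df: pd.DataFrame) -> pd.DataFrame:
    key = df["ligand"].astype(str) + "|" + df["receptor_subunits"].astype(str)
    if key.duplicated().any():
        n_dup = int(key.duplicated().sum())
        warnings.warn(f"dropping {n_dup} duplicated ligand-receptor pair(s)")
        df = df.loc[~key.duplicated()].reset_index(drop=True)
    return df


def write_lr_table(df: pd.DataFrame, path: str | Path) -> None:
    write_tsv(df, path)


def substream_seed(global_seed: int, stage: str) -> int:
    """Derive a deterministic per-stage seed below 2**31 from a global seed.

    Named substreams mean toggling one pipeline stage never perturbs the
    randomness of another.
    """
    import zlib

    return int(
        np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])
        .generate_state(1, np.uint32)[0]
        % (2**31)
    )
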