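"""Cell and nucleus quality control.

Droplet data from muscle dissociation carry empty droplets, doublets and
damaged cells; this module applies the atlas filtering rules: a doublet
score cutoff (score > 0.4 removed), inclusive per-modality gene- and
UMI-count windows, and a strict mitochondrial-fraction cap (more than 10%
for cells, more than 5% for nuclei).  Rules are attributed sequentially —
doublet, gene range, count range, mito — so the per-rule removal counts add
up to the input size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["QCParams", "FilterReport", "compute_qc_metrics", "filter_cells"]

RULE_ORDER = ("doublet", "gene_range", "count_range", "mito")


@dataclass
class QCParams:
    """Per-modality QC thresholds.

    Defaults follow the atlas convention: cells 500-5,000 genes and
    700-50,000 counts with mito <= 10%; nuclei 400-5,000 genes and
    500-40,000 counts with mito <= 5%.  The nuclei upper count bound is
    configurable (see the module documentation) and both count/gene windows
    are inclusive, while the mito and doublet rules are strict
    ("more than").
    """

    modality: str = "cell"
    min_genes: int = 500
    max_genes: int = 5000
    min_counts: int = 700
    max_counts: int = 50000
    max_mito_fraction: float = 0.10
    max_doublet_score: float = 0.4

    def __post_init__(self) -> None:
        if self.min_genes > self.max_genes or self.min_counts > self.max_counts:
            raise ValueError("min thresholds must not exceed max thresholds")
        if not 0 <= self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must be in [0, 1]")

    @classmethod
    def for_modality(cls, modality: str, **overrides) -> "QCParams":
        if modality == "cell":
            base = dict(
                modality="cell",
                min_genes=500,
                max_genes=5000,
                min_counts=700,
                max_counts=50000,
                max_mito_fraction=0.10,
            )
        elif modality == "nucleus":
            base = dict(
                modality="nucleus",
                min_genes=400,
                max_genes=5000,
                min_counts=500,
                max_counts=40000,
                max_mito_fraction=0.05,
            )
        else:
            raise ValueError(f"unknown modality {modality!r}")
        base.update(overrides)
        return cls(**base)


@dataclass
class FilterReport:
    n_input: int
    n_kept: int
    removals: dict[str, int]
    kept_index: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "removals": dict(self.removals),
        }


def compute_qc_metrics(
    adata: ad.AnnData, mito_genes: list[str] | set[str]
) -> pd.DataFrame:
    """Per-cell n_genes, n_counts and mito_fraction.

    ``mito_fraction`` is mito counts over total counts with 0/0 defined as
    0 (an all-zero cell has no evidence of mitochondrial content).
    """
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("empty count matrix")
    mito_genes = set(mito_genes)
    present = [g for g in adata.var_names if g in mito_genes]
    missing = mito_genes - set(present)
    if missing:
        warnings.warn(
            f"{len(missing)} mito gene(s) not in the matrix: {sorted(missing)[:5]}"
        )
    X = sp.csr_matrix(adata.X)
    n_counts = np.asarray(X.sum(axis=1)).ravel()
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    if present:
        mito_counts = np.asarray(
            X[:, [adata.var_names.get_loc(g) for g in present]].sum(axis=1)
        ).ravel()
    else:
        mito_counts = np.zeros(adata.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fraction = np.where(n_counts > 0, mito_counts / np.maximum(n_counts, 1), 0.0)
    return pd.DataFrame(
        {
            "n_genes": n_genes.astype(int),
            "n_counts": n_counts.astype(int),
            "mito_fraction": mito_fraction,
        },
        index=adata.obs_names,
    )


def filter_cells(
    adata: ad.AnnData, metrics: pd.DataFrame, params: QCParams
) -> tuple[ad.AnnData, FilterReport]:
    """Apply the QC rules, attributing each removed cell to the first
    failed rule in the order doublet -> gene range -> count range -> mito.
    """
    if "modality" in adata.obs.columns:
        modalities = set(adata.obs["modality"].astype(str).unique())
        if modalities and modalities != {params.modality}:
            raise ValueError(
                f"params are for modality {params.modality!r} but matrix contains "
                f"{sorted(modalities)}"
            )
    if not metrics.index.equals(adata.obs_names):
        metrics = metrics.reindex(adata.obs_names)
        if metrics.isna().any().any():
            raise ValueError("metrics are not aligned with the matrix cells")

    doublet = (
        adata.obs["doublet_score"].to_numpy(float)
        if "doublet_score" in adata.obs.columns
        else np.zeros(adata.n_obs)
    )
    n_genes = metrics["n_genes"].to_numpy()
    n_counts = metrics["n_counts"].to_numpy()
    mito = metrics["mito_fraction"].to_numpy(float)

    fail = {
        "doublet": doublet > params.max_doublet_score,
        "gene_range": (n_genes < params.min_genes) | (n_genes > params.max_genes),
        "count_range": (n_counts < params.min_counts) | (n_counts > params.max_counts),
        "mito": mito > params.max_mito_fraction,
    }
    removed_by = np.full(adata.n_obs, "", dtype=object)
    for rule in RULE_ORDER:
        mask = fail[rule] & (removed_by == "")
        removed_by[mask] = rule
    keep = removed_by == ""
    report = FilterReport(
        n_input=int(adata.n_obs),
        n_kept=int(keep.sum()),
        removals={rule: int((removed_by == rule).sum()) for rule in RULE_ORDER},
        kept_index=list(adata.obs_names[keep]),
    )
    return adata[keep].copy(), report
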