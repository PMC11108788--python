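"""Ligand-receptor relevance filtering.

An interaction between an emitter and a receiver cluster is considered
relevant only when the ligand is expressed (count > 0) in more than 5% of
the emitter's cells AND every receptor subunit is expressed in more than
5% of the receiver's cells (the min-over-subunits rule for multi-subunit
receptors).  The proportions are computed on raw counts; the threshold is
a strict inequality.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["LRPair", "InteractionCall", "expression_proportion", "filter_interactions"]

DEFAULT_THRESHOLD = 0.05


@dataclass(frozen=True)
class LRPair:
    interaction_id: str
    ligand: str
    receptor_subunits: tuple[str, ...]

    def __post_init__(self):
        if not self.ligand or not self.receptor_subunits:
            raise ValueError("ligand and receptor subunits must be non-empty")

    @classmethod
    def from_row(cls, row: pd.Series) -> "LRPair":
        subunits = tuple(
            s for s in str(row["receptor_subunits"]).split(";") if s
        )
        return cls(str(row["interaction_id"]), str(row["ligand"]), subunits)


@dataclass
class InteractionCall:
    emitter: str
    receiver: str
    pair: LRPair
    ligand_proportion: float
    receptor_proportion: float  # min over subunits
    retained: bool


def expression_proportion(
    adata: ad.AnnData, cluster_key: str = "cluster"
) -> pd.DataFrame:
    """Fraction of cells with count > 0 per (cluster, gene)."""
    labels = adata.obs[cluster_key].astype(str)
    if labels.isna().any():
        raise ValueError("every cell must carry a cluster label")
    X = sp.csr_matrix(adata.X)
    nz = (X > 0).astype(np.int64)
    rows = {}
    for cl in sorted(labels.unique()):
        mask = (labels == cl).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"empty cluster {cl!r}")
        rows[cl] = np.asarray(nz[mask].mean(axis=0)).ravel()
    return pd.DataFrame.from_dict(rows, orient="index", columns=adata.var_names)


def filter_interactions(
    pairs: list[LRPair],
    proportions: pd.DataFrame,
    emitters: list[str],
    receivers: list[str],
    threshold: float = DEFAULT_THRESHOLD,
) -> list[InteractionCall]:
    """Evaluate the relevance rule for every (emitter, receiver, pair).

    Genes missing from the proportion table count as proportion 0.
    """

    def prop(cluster: str, gene: str) -> float:
        if gene in proportions.columns:
            return float(proportions.at[cluster, gene])
        return 0.0

    calls = []
    for em in emitters:
        for rec in receivers:
            for pair in pairs:
                lig_p = prop(em, pair.ligand)
                rec_p = min(prop(rec, s) for s in pair.receptor_subunits)
                calls.append(
                    InteractionCall(
                        emitter=em,
                        receiver=rec,
                        pair=pair,
                        ligand_proportion=lig_p,
                        receptor_proportion=rec_p,
                        retained=(lig_p > threshold) and (rec_p > threshold),
                    )
                )
    return calls


def calls_table(calls: list[InteractionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "interaction_id": [c.pair.interaction_id for c in calls],
            "emitter": [c.emitter for c in calls],
            "receiver": [c.receiver for c in calls],
            "ligand": [c.pair.ligand for c in calls],
            "receptor_subunits": [";".join(c.pair.receptor_subunits) for c in calls],
            "ligand_proportion": [c.ligand_proportion for c in calls],
            "receptor_proportion": [c.receptor_proportion for c in calls],
            "retained": [c.retained for c in calls],
        }
    )
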