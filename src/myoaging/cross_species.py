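"""Cross-species comparison of aging DEG sets.

Human and mouse per-cell-type aging DEG sets are compared after homolog
mapping: consistency is the Jaccard index of mapped sets per (cell type,
direction); pathway-level agreement uses a one-sided hypergeometric
over-representation test with Benjamini-Hochberg adjustment, and the
co-enrichment score counts the cell types in which a pathway is enriched
in BOTH species in the same direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEGSet",
    "EnrichmentRecord",
    "map_homologs",
    "jaccard",
    "ora_hypergeometric",
    "adjust_bh",
    "coenrichment_score",
]


@dataclass
class DEGSet:
    species: str
    cell_type: str
    direction: str  # "up" | "down"
    genes: frozenset[str]


@dataclass
class EnrichmentRecord:
    pathway: str
    cell_type: str
    direction: str
    p_value: float
    p_adjusted: float
    overlap: int
    set_size: int
    universe_size: int


def map_homologs(
    genes: set[str] | frozenset[str],
    homolog_table: pd.DataFrame,
    direction: str = "human_to_mouse",
) -> tuple[frozenset[str], list[str]]:
    """Map a gene set across species via a two-column homolog table.

    Genes without a homolog are dropped (returned in the drop report);
    one-to-many rows expand to every homolog, then deduplicate.
    """
    for col in ("human_gene", "mouse_gene"):
        if col not in homolog_table.columns:
            raise ValueError(f"homolog table missing column {col!r}")
        if homolog_table[col].isna().any() or (homolog_table[col] == "").any():
            raise ValueError("homolog table has empty fields")
    if direction == "human_to_mouse":
        src, dst = "human_gene", "mouse_gene"
    elif direction == "mouse_to_human":
        src, dst = "mouse_gene", "human_gene"
    else:
        raise ValueError(f"unknown direction {direction!r}")
    lookup: dict[str, set[str]] = {}
    for s, d in zip(homolog_table[src], homolog_table[dst]):
        lookup.setdefault(str(s), set()).add(str(d))
    mapped: set[str] = set()
    dropped: list[str] = []
    for g in genes:
        if g in lookup:
            mapped |= lookup[g]
        else:
            dropped.append(g)
    return frozenset(mapped), sorted(dropped)


def jaccard(a: set[str] | frozenset[str], b: set[str] | frozenset[str]) -> tuple[float, bool]:
    """Jaccard index |A n B| / |A u B|; both-empty defined as 0 with a flag."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0, True
    return len(a & b) / len(union), False


def ora_hypergeometric(
    hits: set[str],
    pathway: set[str],
    universe: set[str],
    pathway_id: str = "",
    cell_type: str = "",
    direction: str = "",
) -> EnrichmentRecord:
    """One-sided hypergeometric upper-tail over-representation test.

    p = P(overlap >= observed) drawing |hits| genes from the universe with
    |pathway n universe| marked.  Hits/pathway genes outside the universe
    are dropped with a warning.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    h_in = set(hits) & universe
    p_in = set(pathway) & universe
    if len(h_in) < len(set(hits)) or len(p_in) < len(set(pathway)):
        warnings.warn("genes outside the universe dropped from the ORA")
    overlap = len(h_in & p_in)
    M, n, N = len(universe), len(p_in), len(h_in)
    p = float(scipy.stats.hypergeom.sf(overlap - 1, M, n, N)) if overlap > 0 else 1.0
    p = min(p, 1.0)
    return EnrichmentRecord(
        pathway=pathway_id,
        cell_type=cell_type,
        direction=direction,
        p_value=p,
        p_adjusted=np.nan,
        overlap=overlap,
        set_size=len(p_in),
        universe_size=M,
    )


def adjust_bh(records: list[EnrichmentRecord]) -> list[EnrichmentRecord]:
    """Benjamini-Hochberg adjustment within each (cell type, direction)."""
    df = pd.DataFrame(
        {
            "i": range(len(records)),
            "cell_type": [r.cell_type for r in records],
            "direction": [r.direction for r in records],
            "p": [r.p_value for r in records],
        }
    )
    for _, grp in df.groupby(["cell_type", "direction"]):
        adj = multipletests(grp["p"].to_numpy(), method="fdr_bh")[1]
        for i, a in zip(grp["i"], adj):
            records[i].p_adjusted = float(a)
    return records


def coenrichment_score(
    human_records: list[EnrichmentRecord],
    mouse_records: list[EnrichmentRecord],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Count cell types where a pathway is enriched in BOTH species in the
    same direction (adjusted p < alpha).  Up counts are reported positive,
    down counts negative, plus a signed total for plotting order."""

    def sig_celltypes(records):
        out: dict[tuple[str, str], set[str]] = {}
        for r in records:
            if np.isfinite(r.p_adjusted) and r.p_adjusted < alpha:
                out.setdefault((r.pathway, r.direction), set()).add(r.cell_type)
        return out

    hum = sig_celltypes(human_records)
    mou = sig_celltypes(mouse_records)
    pathways = sorted(
        {p for p, _ in hum} | {p for p, _ in mou}
    )
    rows = []
    for p in pathways:
        up = len(hum.get((p, "up"), set()) & mou.get((p, "up"), set()))
        down = len(hum.get((p, "down"), set()) & mou.get((p, "down"), set()))
        rows.append(
            {"pathway": p, "n_up": up, "n_down": -down, "signed_total": up - down}
        )
    df = pd.DataFrame(rows, columns=["pathway", "n_up", "n_down", "signed_total"])
    return df.sort_values("signed_total", ascending=False).reset_index(drop=True)
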