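"""MYH-based myonuclei typing and donor-level proportion tests.

Myofiber type is encoded by the myosin heavy chain isoform a nucleus
transcribes: MYH7 (slow, type I), MYH2 (fast, type IIA) and MYH1 (fast,
type IIX).  A nucleus is called as expressing a gene when its normalized,
log-transformed expression strictly exceeds 0.5; the combination of
expressed genes yields one of seven classes (three pure, four hybrid).
Nuclei with all three genes at or below the threshold — or flagged as
fragment/hybrid snRNA subtypes — are "unclassified".  Donors in which
unclassified nuclei exceed 75% are excluded from proportion comparisons,
which use an unpaired two-tailed t-test or exact Mann-Whitney test on the
donor-level class proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "MyonucleusCall",
    "DonorProportions",
    "CLASS_NAMES",
    "classify_myonuclei",
    "donor_proportions",
    "compare_age_groups",
]

GENES = ("MYH1", "MYH2", "MYH7")

# class name for each membership subset, pure types first
CLASS_NAMES = (
    "MYH7+",
    "MYH2+",
    "MYH1+",
    "MYH2+MYH1+",
    "MYH7+MYH1+",
    "MYH7+MYH2+",
    "MYH7+MYH2+MYH1+",
    "unclassified",
)

UNCLASSIFIED_DONOR_CUTOFF = 0.75


@dataclass
class MyonucleusCall:
    nucleus_id: str
    expr: tuple[float, float, float]  # (MYH1, MYH2, MYH7), normalized
    cls: str
    excluded_by_flag: bool = False


@dataclass
class DonorProportions:
    donor: str
    age_group: str
    proportions: dict[str, float] = field(default_factory=dict)
    unclassified_fraction: float = 0.0
    excluded: bool = False


def _class_from_membership(m1: bool, m2: bool, m7: bool) -> str:
    parts = [name for flag, name in ((m7, "MYH7+"), (m2, "MYH2+"), (m1, "MYH1+")) if flag]
    return "".join(parts) if parts else "unclassified"


def classify_myonuclei(
    expr: pd.DataFrame,
    threshold: float = 0.5,
    exclusion_flags: pd.Series | None = None,
) -> list[MyonucleusCall]:
    """Classify nuclei from normalized (MYH1, MYH2, MYH7) expression.

    ``expr`` is indexed by nucleus id with columns MYH1, MYH2, MYH7
    holding log1p-normalized values (hence >= 0).  A gene is expressed
    when its value strictly exceeds ``threshold``; a flagged nucleus
    (fragment or rare hybrid subtype) is unclassified regardless of
    expression.
    """
    missing = [g for g in GENES if g not in expr.columns]
    if missing:
        raise ValueError(f"missing marker columns: {missing}")
    vals = expr[list(GENES)].to_numpy(float)
    if np.any(vals < 0):
        raise ValueError("normalized expression must be non-negative")
    flags = (
        exclusion_flags.reindex(expr.index).fillna(False).to_numpy(bool)
        if exclusion_flags is not None
        else np.zeros(len(expr), bool)
    )
    calls = []
    for i, nid in enumerate(expr.index):
        m1, m2, m7 = (vals[i] > threshold).tolist()
        if flags[i]:
            cls = "unclassified"
        else:
            cls = _class_from_membership(m1, m2, m7)
        calls.append(
            MyonucleusCall(
                nucleus_id=str(nid),
                expr=(float(vals[i, 0]), float(vals[i, 1]), float(vals[i, 2])),
                cls=cls,
                excluded_by_flag=bool(flags[i]),
            )
        )
    return calls


def donor_proportions(
    calls: list[MyonucleusCall], donor_map: pd.DataFrame
) -> list[DonorProportions]:
    """Per-donor class proportions over classified + unclassified nuclei.

    ``donor_map`` is indexed by nucleus id with columns donor and
    age_group.  Donors whose unclassified fraction strictly exceeds 0.75
    are marked excluded.
    """
    by_nucleus = {c.nucleus_id: c.cls for c in calls}
    missing = [nid for nid in by_nucleus if nid not in donor_map.index]
    if missing:
        raise ValueError(f"nuclei without donor mapping: {missing[:5]}")
    df = pd.DataFrame(
        {
            "cls": pd.Series(by_nucleus),
            "donor": donor_map.loc[list(by_nucleus), "donor"].to_numpy(str),
            "age_group": donor_map.loc[list(by_nucleus), "age_group"].to_numpy(str),
        }
    )
    out = []
    for (donor, age_group), grp in df.groupby(["donor", "age_group"], sort=True):
        n = len(grp)
        if n == 0:
            raise ValueError(f"donor {donor!r} has no nuclei")
        props = {cls: float((grp["cls"] == cls).mean()) for cls in CLASS_NAMES}
        unc = props["unclassified"]
        out.append(
            DonorProportions(
                donor=str(donor),
                age_group=str(age_group),
                proportions=props,
                unclassified_fraction=unc,
                excluded=unc > UNCLASSIFIED_DONOR_CUTOFF,
            )
        )
    return out


def proportions_table(props: list[DonorProportions]) -> pd.DataFrame:
    rows = []
    for p in props:
        row = {"donor": p.donor, "age_group": p.age_group, "excluded": p.excluded}
        row.update(p.proportions)
        rows.append(row)
    return pd.DataFrame(rows)


def compare_age_groups(
    young: np.ndarray, aged: np.ndarray, test: str = "t"
) -> tuple[float, float, bool]:
    """Unpaired two-tailed test on donor-level values.

    Returns (statistic, p, degenerate).  The t-test is Student
    (equal-variance) by default with ``test='welch'`` available; zero
    variance in both groups yields p = 1 with the degenerate flag.  The
    Mann-Whitney test is exact for group sizes <= 8 and uses the normal
    approximation with tie correction otherwise.
    """
    young = np.asarray(young, float)
    aged = np.asarray(aged, float)
    if test in ("t", "welch"):
        if young.size < 2 or aged.size < 2:
            raise ValueError("t-test needs >= 2 donors per group")
        if young.var() == 0 and aged.var() == 0:
            if young.mean() == aged.mean():
                return 0.0, 1.0, True
            return np.inf, 0.0, True
        res = scipy.stats.ttest_ind(young, aged, equal_var=(test == "t"))
        return float(res.statistic), float(res.pvalue), False
    if test == "mannwhitney":
        method = "exact" if max(young.size, aged.size) <= 8 else "asymptotic"
        res = scipy.stats.mannwhitneyu(
            young, aged, alternative="two-sided", method=method
        )
        return float(res.statistic), float(res.pvalue), False
    raise ValueError(f"unknown test {test!r}")
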