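"""Hierarchical Poisson mixed-model analysis of cell-type composition.

The abundance of each cell type in each 10x library is modeled as a
Poisson count whose log-rate combines a fixed intercept and standardized
age term with Gaussian random effects::

    N_cs ~ Age + (1|Celltype) + (1|Sample) + (1|10x) + (1|batch)
         + (Age-1|Celltype) + (1|10x::Celltype) + (1|batch::Celltype)
         + (1|Sample::Celltype)

where ``Sample`` is the 10x library, ``10x`` the chemistry version and
``batch`` the modality (cells vs nuclei).  All covariates enter as random
terms, which keeps the model estimable despite collinearity between
library, chemistry and modality.  The per-cell-type age effect is the
shared fixed age slope plus the cell-type-specific random age slope,
reported relative to the grand mean over cell types so that 0 means no
effect, with significance summarized by the local true sign rate (LTSR):
the posterior probability that the sign of the effect is estimated
correctly, thresholded at 0.9.

This module also implements the neighborhood post-labeling rules used by
graph-based differential abundance: a neighborhood is labeled by its
majority cell type when that type contributes at least 70% of its cells,
labeled "mixed" and dropped otherwise, and labeled "Donor-specific" and
dropped when more than 90% of its cells come from a single donor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm

from ._glmm import GLMMFit, REGroup, fit_glmm, indicator_matrix, interaction_labels
from .simulate import standardize_age

__all__ = [
    "ModelSpec",
    "CompositionFit",
    "make_composition_table",
    "fit_composition_glmm",
    "compute_ltsr",
    "celltype_age_effects",
    "label_neighborhoods",
    "LTSR_CUTOFF",
]

LTSR_CUTOFF = 0.9

DEFAULT_TERMS = (
    "celltype",
    "sample",
    "chemistry",
    "modality",
    "age_celltype",
    "chemistry_celltype",
    "modality_celltype",
    "sample_celltype",
)

# optional donor-level grouping terms; the default model treats the 10x
# library as the replicate unit, but a donor hierarchy can be added when
# technical replicates would otherwise overstate precision
OPTIONAL_TERMS = ("donor", "donor_celltype")


@dataclass
class ModelSpec:
    """Random-effect structure of the composition model.

    ``terms`` are drawn from the eight default grouping terms; ``pinned``
    lists terms whose standard deviation is constrained to zero (the term
    then drops out — used for the GLM-limit oracle check).
    """

    terms: tuple[str, ...] = DEFAULT_TERMS
    pinned: tuple[str, ...] = ()
    init_sd: float = 0.1
    gtol: float = 1e-8

    def __post_init__(self) -> None:
        unknown = set(self.terms) | set(self.pinned)
        unknown -= set(DEFAULT_TERMS) | set(OPTIONAL_TERMS)
        if unknown:
            raise ValueError(f"unknown model terms: {sorted(unknown)}")


@dataclass
class CompositionFit:
    glmm: GLMMFit
    cell_types: list[str]
    spec: ModelSpec
    age_mean: float
    age_sd: float

    @property
    def converged(self) -> bool:
        return self.glmm.converged

    @property
    def variance_components(self) -> dict[str, float]:
        return dict(self.glmm.sd)


def make_composition_table(
    counts: pd.DataFrame, meta: pd.DataFrame
) -> pd.DataFrame:
    """Join counts with library covariates, materializing zero pairs.

    ``counts`` needs columns cell_type, sample, count; ``meta`` one row per
    sample with donor, age_years, modality, chemistry (sex optional).
    """
    if (counts["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    if counts.duplicated(["cell_type", "sample"]).any():
        raise ValueError("duplicated (cell_type, sample) pairs")
    cts = sorted(counts["cell_type"].unique())
    samples = list(meta["sample"])
    full = pd.MultiIndex.from_product(
        [cts, samples], names=["cell_type", "sample"]
    ).to_frame(index=False)
    table = full.merge(counts, on=["cell_type", "sample"], how="left")
    table["count"] = table["count"].fillna(0).astype(int)
    table = table.merge(meta, on="sample", how="left")
    if table["age_years"].isna().any():
        raise ValueError("some samples in the count table are missing metadata")
    return table


def fit_composition_glmm(
    table: pd.DataFrame, spec: ModelSpec | None = None
) -> CompositionFit:
    """Fit the Poisson mixed model to a long-form composition table."""
    spec = spec or ModelSpec()
    cts = sorted(table["cell_type"].unique())
    samples = table["sample"].unique()
    if len(cts) < 2:
        raise ValueError("need at least 2 cell types")
    if len(samples) < 4:
        raise ValueError("need at least 4 libraries")
    zero_types = [
        ct for ct, tot in table.groupby("cell_type")["count"].sum().items() if tot == 0
    ]
    if zero_types:
        import warnings

        warnings.warn(
            f"cell type(s) with all-zero counts kept (shrinkage handles them): "
            f"{zero_types}"
        )

    # standardized age at the library level, the convention the generator shares
    lib_ages = table.drop_duplicates("sample")["age_years"].to_numpy(float)
    age_mean, age_sd = float(lib_ages.mean()), float(lib_ages.std())
    if age_sd == 0:
        raise ValueError("age has zero variance across libraries")
    z_age = (table["age_years"].to_numpy(float) - age_mean) / age_sd

    y = table["count"].to_numpy(float)
    X = np.column_stack([np.ones(len(table)), z_age])

    ct = table["cell_type"].to_numpy(str)
    sample = table["sample"].to_numpy(str)
    chem = table["chemistry"].to_numpy(str)
    mod = table["modality"].to_numpy(str)

    donor = (
        table["donor"].to_numpy(str) if "donor" in table.columns else sample
    )
    builders = {
        "donor": lambda: indicator_matrix(donor),
        "donor_celltype": lambda: indicator_matrix(interaction_labels(donor, ct)),
        "celltype": lambda: indicator_matrix(ct),
        "sample": lambda: indicator_matrix(sample),
        "chemistry": lambda: indicator_matrix(chem),
        "modality": lambda: indicator_matrix(mod),
        "age_celltype": lambda: indicator_matrix(ct, values=z_age),
        "chemistry_celltype": lambda: indicator_matrix(interaction_labels(chem, ct)),
        "modality_celltype": lambda: indicator_matrix(interaction_labels(mod, ct)),
        "sample_celltype": lambda: indicator_matrix(interaction_labels(sample, ct)),
    }
    groups = []
    for term in spec.terms:
        if term in spec.pinned:
            continue
        Z, levels = builders[term]()
        groups.append(REGroup(term, Z, levels))

    glmm = fit_glmm(
        y, X, groups, family="poisson", init_sd=spec.init_sd, gtol=spec.gtol
    )
    return CompositionFit(
        glmm=glmm, cell_types=cts, spec=spec, age_mean=age_mean, age_sd=age_sd
    )


def compute_ltsr(mean: float, sd: float) -> float:
    """Local true sign rate of a Gaussian posterior summary.

    LTSR = max(P(b > 0), P(b < 0)) = Phi(|mean| / sd), in [0.5, 1].
    """
    if sd <= 0:
        raise ValueError("sd must be > 0")
    return float(norm.cdf(abs(mean) / sd))


def celltype_age_effects(fit: CompositionFit) -> pd.DataFrame:
    """Per-cell-type age effect (natural log per SD of age), sd and LTSR.

    The effect is the shared fixed age slope plus the cell-type random
    slope, centered so the grand mean over cell types equals the shared
    term; ``significant`` applies the LTSR > 0.9 cutoff.
    """
    glmm = fit.glmm
    cts = fit.cell_types
    dim = glmm.n_fixed + glmm.u.size
    age_ix = 1  # columns: intercept, z_age
    rows = []
    has_slopes = "age_celltype" in glmm.group_slices
    for ctype in cts:
        a = np.zeros(dim)
        a[age_ix] = 1.0
        if has_slopes:
            a[glmm.coef_index("age_celltype", ctype)] += 1.0
            for other in glmm.group_levels["age_celltype"]:
                a[glmm.coef_index("age_celltype", other)] -= 1.0 / len(
                    glmm.group_levels["age_celltype"]
                )
        mean, sd = glmm.contrast(a)
        ltsr = compute_ltsr(mean, sd) if sd > 0 else 0.5
        rows.append(
            {
                "cell_type": ctype,
                "covariate": "age",
                "logfc": mean,
                "log2fc": mean / np.log(2.0),
                "sd": sd,
                "ltsr": ltsr,
                "significant": ltsr > LTSR_CUTOFF,
            }
        )
    return pd.DataFrame(rows)


def label_neighborhoods(
    nbhd_by_celltype: pd.DataFrame,
    nbhd_by_donor: pd.DataFrame,
    celltype_min_share: float = 0.70,
    donor_max_share: float = 0.90,
) -> pd.DataFrame:
    """Label KNN neighborhoods by majority cell type with the drop rules.

    A neighborhood keeps its majority cell-type label only when that type
    contributes at least ``celltype_min_share`` of its cells ("mixed"
    otherwise) and no single donor contributes more than
    ``donor_max_share`` ("Donor-specific" otherwise).  The mixed rule is
    checked first.
    """
    if not nbhd_by_celltype.index.equals(nbhd_by_donor.index):
        raise ValueError("neighborhood rows are misaligned between the two matrices")
    ct_tot = nbhd_by_celltype.sum(axis=1)
    don_tot = nbhd_by_donor.sum(axis=1)
    if (ct_tot <= 0).any() or (don_tot <= 0).any():
        raise ValueError("neighborhoods must have positive cell counts")
    ct_share = nbhd_by_celltype.div(ct_tot, axis=0)
    don_share = nbhd_by_donor.div(don_tot, axis=0)
    majority = ct_share.idxmax(axis=1)
    maj_share = ct_share.max(axis=1)
    max_donor = don_share.max(axis=1)

    labels = []
    keep = []
    for nb in nbhd_by_celltype.index:
        if maj_share[nb] < celltype_min_share:
            labels.append("mixed")
            keep.append(False)
        elif max_donor[nb] > donor_max_share:
            labels.append("Donor-specific")
            keep.append(False)
        else:
            labels.append(str(majority[nb]))
            keep.append(True)
    return pd.DataFrame(
        {
            "label": labels,
            "keep": keep,
            "majority_share": maj_share.to_numpy(),
            "max_donor_share": max_donor.to_numpy(),
        },
        index=nbhd_by_celltype.index,
    )
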