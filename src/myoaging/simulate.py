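"""Ground-truth synthetic data for the muscle aging analysis stages.

Two generators mirror the statistical models that are fitted downstream:

* :func:`simulate_composition` draws per-(cell type x library) Poisson
  counts whose log-rate is baseline + age effect x standardized age +
  Gaussian random effects for library, chemistry, modality and their
  cell-type interactions — the generative inverse of the hierarchical
  Poisson mixed model.
* :func:`simulate_expression` draws a negative-binomial cell-by-gene count
  matrix with a lognormal per-cell library-size factor, donor random
  intercepts, planted aging DEGs (mean multiplied by ``2**log2fc`` in aged
  cells) and per-cluster MYH1/MYH2/MYH7 marker programs, emitting mito
  fraction and doublet-score columns for QC fixtures.

Ground truth always travels with the data (returned tables / truth files),
so every downstream stage can be tested against known effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "CompositionTruth",
    "ExpressionTruth",
    "simulate_composition",
    "simulate_expression",
    "make_fixture_tables",
    "standardize_age",
    "MYH_GENES",
]

MYH_GENES = ("MYH1", "MYH2", "MYH7")

_RE_KEYS = {
    "sample",
    "chemistry",
    "modality",
    "celltype",
    "sample_celltype",
    "chemistry_celltype",
    "modality_celltype",
}


@dataclass
class CompositionTruth:
    """Generative parameters for a composition table.

    ``age_logfc`` is the natural-log abundance effect per 1 SD of
    (library-level) standardized age.  ``re_sd`` maps random-effect group
    names (sample, chemistry, modality, celltype and their ``*_celltype``
    interactions) to standard deviations on the log scale.
    """

    cell_types: list[str]
    n_donors: int
    ages: list[float]  # years, one per donor
    baseline_log_abundance: dict[str, float]
    age_logfc: dict[str, float]
    re_sd: dict[str, float] = field(default_factory=dict)
    libraries_per_donor: int = 2  # technical replicates per donor
    modalities: tuple[str, ...] = ("cell", "nucleus")
    chemistries: tuple[str, ...] = ("v2", "v3")

    def validate(self) -> None:
        if self.n_donors != len(self.ages):
            raise ValueError("ages must have one entry per donor")
        for ct in self.cell_types:
            if ct not in self.baseline_log_abundance:
                raise ValueError(f"missing baseline for cell type {ct!r}")
            if not np.isfinite(self.baseline_log_abundance[ct]):
                raise ValueError(f"non-finite baseline for cell type {ct!r}")
        for ct, v in self.age_logfc.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite age_logfc for {ct!r}")
        for k, sd in self.re_sd.items():
            if k not in _RE_KEYS:
                raise ValueError(f"unknown random-effect group {k!r}")
            if sd < 0:
                raise ValueError(f"re_sd[{k!r}] must be >= 0")


@dataclass
class ExpressionTruth:
    """Generative parameters for a cell-by-gene NB count matrix."""

    n_genes: int = 200
    n_cells_per_sample: int = 250
    deg_indices: tuple[int, ...] = ()
    deg_log2fc: dict[int, float] = field(default_factory=dict)
    dispersion: float | np.ndarray = 2.0  # var = mu + mu^2/dispersion
    donor_re_sd: float = 0.1
    libsize_log_sd: float = 0.3  # lognormal(0, 0.3^2) depth factor
    base_mean_log_mu: float = np.log(0.2)
    base_mean_log_sd: float = 1.0
    n_clusters: int = 4
    myh_profile: dict[int, tuple[float, float, float]] = field(default_factory=dict)
    mito_fraction_range: tuple[float, float] = (0.0, 0.08)

    def validate(self) -> None:
        disp = np.asarray(self.dispersion, float)
        if np.any(disp <= 0):
            raise ValueError("dispersion must be > 0")
        for i in self.deg_indices:
            if not 0 <= i < self.n_genes:
                raise ValueError(f"deg index {i} outside gene universe")
        for i in self.deg_log2fc:
            if i not in self.deg_indices:
                raise ValueError(f"deg_log2fc given for gene {i} not in deg_indices")
        lo, hi = self.mito_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("mito_fraction_range must be within [0, 1]")


def standardize_age(ages: np.ndarray) -> np.ndarray:
    """Scale and center ages (ddof=0); the convention shared with the fits."""
    ages = np.asarray(ages, float)
    sd = ages.std()
    if sd == 0:
        return np.zeros_like(ages)
    return (ages - ages.mean()) / sd


def _library_design(truth: CompositionTruth) -> pd.DataFrame:
    rows = []
    for d in range(truth.n_donors):
        donor = f"D{d:02d}"
        for r in range(truth.libraries_per_donor):
            rows.append(
                {
                    "sample": f"{donor}_L{r}",
                    "donor": donor,
                    "age_years": float(truth.ages[d]),
                    "modality": truth.modalities[r % len(truth.modalities)],
                    "chemistry": truth.chemistries[d % len(truth.chemistries)],
                    "sex": "F" if d % 2 else "M",
                }
            )
    meta = pd.DataFrame(rows)
    meta["age_group"] = np.where(
        meta["age_years"] >= meta["age_years"].mean(), "aged", "young"
    )
    return meta


def simulate_composition(
    truth: CompositionTruth, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a composition table (long form) and its library metadata.

    Returns ``(table, meta)`` where ``table`` has one row per
    (cell type x library) with a Poisson count, and ``meta`` one row per
    library with donor, age, modality and chemistry.
    """
    truth.validate()
    rng = np.random.default_rng(seed)
    meta = _library_design(truth)
    z_age = standardize_age(meta["age_years"].to_numpy())
    cts = list(truth.cell_types)

    def draw(levels, key):
        sd = truth.re_sd.get(key, 0.0)
        return dict(zip(levels, rng.normal(0.0, sd, size=len(levels))))

    samples = meta["sample"].tolist()
    chems = sorted(meta["chemistry"].unique())
    mods = sorted(meta["modality"].unique())
    re_sample = draw(samples, "sample")
    re_chem = draw(chems, "chemistry")
    re_mod = draw(mods, "modality")
    re_ct = draw(cts, "celltype")
    re_sample_ct = draw(
        [f"{s}::{c}" for s in samples for c in cts], "sample_celltype"
    )
    re_chem_ct = draw([f"{x}::{c}" for x in chems for c in cts], "chemistry_celltype")
    re_mod_ct = draw([f"{m}::{c}" for m in mods for c in cts], "modality_celltype")

    rows = []
    for i, lib in meta.iterrows():
        s = lib["sample"]
        for c in cts:
            log_rate = (
                truth.baseline_log_abundance[c]
                + truth.age_logfc.get(c, 0.0) * z_age[i]
                + re_sample[s]
                + re_chem[lib["chemistry"]]
                + re_mod[lib["modality"]]
                + re_ct[c]
                + re_sample_ct[f"{s}::{c}"]
                + re_chem_ct[f"{lib['chemistry']}::{c}"]
                + re_mod_ct[f"{lib['modality']}::{c}"]
            )
            if not np.isfinite(log_rate):
                raise ValueError(
                    f"non-finite log-rate for cell type {c!r} in library {s!r}; "
                    "check baselines and effect sizes"
                )
            rows.append(
                {"cell_type": c, "sample": s, "count": int(rng.poisson(np.exp(log_rate)))}
            )
    table = pd.DataFrame(rows)
    return table, meta


def _gene_names(n_genes: int) -> list[str]:
    names = [f"G{i:04d}" for i in range(n_genes)]
    # last three genes carry the myosin heavy chain marker program
    if n_genes >= 3:
        names[-3:] = list(MYH_GENES)
    return names


def simulate_expression(
    truth: ExpressionTruth, design: pd.DataFrame, seed: int
) -> ad.AnnData:
    """Draw an NB cell-by-gene count matrix for the libraries in ``design``.

    ``design`` must carry at least sample, donor, age_years and age_group
    with >= 2 age groups and >= 2 donors per group (the minimum for the
    downstream mixed model to be identifiable).
    """
    truth.validate()
    groups = design.groupby("age_group")["donor"].nunique()
    if len(groups) < 2 or (groups < 2).any():
        raise ValueError("design needs >= 2 age groups with >= 2 donors each")
    rng = np.random.default_rng(seed)

    n_genes = truth.n_genes
    genes = _gene_names(n_genes)
    disp = np.broadcast_to(np.asarray(truth.dispersion, float), (n_genes,)).copy()

    base_mean = rng.lognormal(truth.base_mean_log_mu, truth.base_mean_log_sd, n_genes)
    donors = sorted(design["donor"].unique())
    donor_re = {
        d: rng.normal(0.0, truth.donor_re_sd, n_genes) for d in donors
    }

    lfc = np.zeros(n_genes)
    for i in truth.deg_indices:
        lfc[i] = truth.deg_log2fc.get(i, 0.0) * np.log(2.0)

    myh_idx = {g: genes.index(g) for g in MYH_GENES if g in genes}

    obs_rows = []
    counts = []
    cell_counter = 0
    n_cells = truth.n_cells_per_sample
    for _, lib in design.iterrows():
        aged = lib["age_group"] == "aged"
        libfac = rng.lognormal(0.0, truth.libsize_log_sd, n_cells)
        clusters = np.arange(n_cells) % truth.n_clusters
        mu = base_mean[None, :] * np.exp(donor_re[lib["donor"]])[None, :]
        mu = np.repeat(mu, n_cells, axis=0)
        if aged:
            mu = mu * np.exp(lfc)[None, :]
        for cl, (g, j) in (
            (cl, item) for cl in range(truth.n_clusters) for item in myh_idx.items()
        ):
            if cl in truth.myh_profile:
                triple = dict(zip(MYH_GENES, truth.myh_profile[cl]))
                mu[clusters == cl, j] = triple[g]
        mu = mu * libfac[:, None]
        block = _rnegbin(rng, mu, disp[None, :])
        counts.append(block)
        mito = rng.uniform(*truth.mito_fraction_range, n_cells)
        dbl = rng.beta(2.0, 20.0, n_cells)
        for k in range(n_cells):
            obs_rows.append(
                {
                    "cell_id": f"cell{cell_counter + k:06d}",
                    "sample": lib["sample"],
                    "donor": lib["donor"],
                    "age_years": lib["age_years"],
                    "age_group": lib["age_group"],
                    "modality": lib.get("modality", "cell"),
                    "chemistry": lib.get("chemistry", "v3"),
                    "cluster": f"C{clusters[k]}",
                    "mito_fraction": mito[k],
                    "doublet_score": dbl[k],
                }
            )
        cell_counter += n_cells

    X = np.vstack(counts)
    obs = pd.DataFrame(obs_rows).set_index("cell_id")
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    var["is_deg"] = np.isin(np.arange(n_genes), np.asarray(truth.deg_indices, int))
    var["true_log2fc"] = lfc / np.log(2.0)
    import scipy.sparse as sp

    adata = ad.AnnData(X=sp.csr_matrix(X), obs=obs, var=var)
    return adata


def _rnegbin(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mean mu, dispersion alpha) draws; Poisson for very large alpha."""
    mu = np.asarray(mu, float)
    alpha = np.broadcast_to(np.asarray(alpha, float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    big = alpha > 1e8
    if np.any(big):
        out[big] = rng.poisson(mu[big])
    small = ~big
    if np.any(small):
        p = alpha[small] / (alpha[small] + mu[small])
        out[small] = rng.negative_binomial(alpha[small], p)
    return out


def make_fixture_tables(
    seed: int, n_genes: int = 200
) -> tuple[pd.DataFrame, dict[str, list[str]], pd.DataFrame]:
    """Small internally consistent homolog / GMT / ligand-receptor fixtures.

    Returns ``(homolog_table, gene_sets, lr_table)`` drawn from the same
    synthetic gene universe produced by :func:`simulate_expression`, with
    both 1:1 and 1:many homolog rows and at least one multi-subunit
    receptor.
    """
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    mouse = [g.capitalize() if not g.startswith("MT-") else g for g in genes]

    rows = [{"human_gene": h, "mouse_gene": m} for h, m in zip(genes, mouse)]
    # a few 1:2 expansions
    for h in rng.choice(genes, size=5, replace=False):
        rows.append({"human_gene": str(h), "mouse_gene": str(h).capitalize() + "b"})
    homologs = pd.DataFrame(rows).drop_duplicates().reset_index(drop=True)

    gene_sets: dict[str, list[str]] = {}
    max_size = min(50, max(5, n_genes - 1))
    for i in range(6):
        size = int(rng.integers(5, max_size + 1))
        members = rng.choice(genes, size=size, replace=False)
        gene_sets[f"SET{i:02d}"] = sorted(str(g) for g in members)

    lr_rows = []
    for i in range(12):
        lig, r1, r2 = rng.choice(genes, size=3, replace=False)
        subunits = str(r1) if i % 3 else f"{r1};{r2}"
        lr_rows.append(
            {
                "interaction_id": f"LR{i:03d}",
                "ligand": str(lig),
                "receptor_subunits": subunits,
            }
        )
    lr = pd.DataFrame(lr_rows)
    from .io import dedup_lr_table

    lr = dedup_lr_table(lr)
    return homologs, gene_sets, lr


def validate_fixture_tables(
    homologs: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    lr: pd.DataFrame,
    universe: list[str],
) -> None:
    """Referential-integrity check: every referenced gene exists."""
    uni = set(universe)
    missing = set(homologs["human_gene"]) - uni
    if missing:
        raise ValueError(f"homolog table references unknown genes: {sorted(missing)[:5]}")
    for name, members in gene_sets.items():
        extra = set(members) - uni
        if extra:
            raise ValueError(f"gene set {name!r} references unknown genes")
    for _, row in lr.iterrows():
        refs = [row["ligand"], *str(row["receptor_subunits"]).split(";")]
        if any(g not in uni for g in refs):
            raise ValueError(f"LR pair {row['interaction_id']} references unknown genes")
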