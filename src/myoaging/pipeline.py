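"""End-to-end orchestration: simulate -> qc -> composition -> deg ->
fibertype -> cross-species -> interactions.

One :class:`RunConfig` drives the whole run.  All randomness derives from
the global seed through named per-stage substreams, so toggling one stage
never perturbs another's draws, and two runs with the same config produce
byte-identical output tables.  Every stage appends an entry (row counts,
parameters, wall time) to the machine-readable :class:`RunReport`.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, composition, cross_species, deg, interactions, io
from . import myonuclei as myo
from . import qc as qcmod
from . import simulate as sim

logger = logging.getLogger("myoaging")

STAGES = (
    "simulate",
    "qc",
    "composition",
    "deg",
    "fibertype",
    "cross_species",
    "interactions",
)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "runs/out"
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    # composition fixture: two age groups of donors, two libraries each
    n_donors_young: int = 10
    n_donors_aged: int = 10
    libraries_per_donor: int = 2
    cell_types: int = 10
    planted_celltype_logfc: float = 1.0
    composition_re_sd: dict[str, float] = field(
        default_factory=lambda: {
            "sample": 0.1,
            "chemistry": 0.1,
            "modality": 0.3,
            "sample_celltype": 0.1,
            "chemistry_celltype": 0.1,
            "modality_celltype": 0.1,
        }
    )
    # expression fixture: the standard 200-gene panel
    n_genes: int = 200
    n_spiked: int = 10
    spike_log2fc: float = 1.5
    n_cells_per_sample: int = 250
    expression_donors_per_group: int = 4
    dispersion: float = 2.0
    donor_re_sd: float = 0.1
    # QC thresholds for the synthetic panel (full-transcriptome defaults in
    # qc.QCParams are not meaningful on a 200-gene universe)
    qc_min_genes: int = 5
    qc_max_genes: int = 200
    qc_min_counts: int = 10
    qc_max_counts: int = 100000
    qc_max_mito_fraction: float = 0.10  # cells; the "more than 10%" rule
    qc_max_mito_fraction_nucleus: float = 0.05  # nuclei; "more than 5%"
    qc_max_doublet_score: float = 0.4
    myh_threshold: float = 0.5
    lr_threshold: float = 0.05
    ora_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for k, v in raw.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown config key {k!r}")
            if k == "stages":
                unknown = set(v) - set(STAGES)
                if unknown:
                    raise ValueError(f"unknown stage(s): {sorted(unknown)}")
                cfg.stages.update(v)
            elif isinstance(getattr(cfg, k), dict) and isinstance(v, dict):
                getattr(cfg, k).update(v)
            else:
                setattr(cfg, k, v)
        return cfg

    def validate(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if self.expression_donors_per_group < 2:
            raise ValueError("need >= 2 donors per age group")


@dataclass
class RunReport:
    seed: int
    version: str
    stages: dict[str, dict] = field(default_factory=dict)

    def add(self, stage: str, **info) -> None:
        self.stages[stage] = info

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "version": self.version, "stages": self.stages}, fh, indent=2)

    @classmethod
    def load(cls, path: str | Path) -> "RunReport":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(seed=raw["seed"], version=raw["version"], stages=raw["stages"])


def _composition_truth(cfg: RunConfig, rng: np.random.Generator) -> sim.CompositionTruth:
    cts = [f"CT{i:02d}" for i in range(cfg.cell_types)]
    ages = list(rng.uniform(20, 40, cfg.n_donors_young)) + list(
        rng.uniform(60, 75, cfg.n_donors_aged)
    )
    return sim.CompositionTruth(
        cell_types=cts,
        n_donors=cfg.n_donors_young + cfg.n_donors_aged,
        ages=[float(a) for a in ages],
        baseline_log_abundance={ct: np.log(200.0) for ct in cts},
        age_logfc={cts[0]: cfg.planted_celltype_logfc},
        re_sd=dict(cfg.composition_re_sd),
        libraries_per_donor=cfg.libraries_per_donor,
    )


def _expression_truth(cfg: RunConfig) -> sim.ExpressionTruth:
    spiked = tuple(range(cfg.n_spiked))
    return sim.ExpressionTruth(
        n_genes=cfg.n_genes,
        n_cells_per_sample=cfg.n_cells_per_sample,
        deg_indices=spiked,
        deg_log2fc={i: cfg.spike_log2fc for i in spiked},
        dispersion=cfg.dispersion,
        donor_re_sd=cfg.donor_re_sd,
        myh_profile={0: (0.0, 0.0, 5.0), 1: (0.0, 5.0, 0.0), 2: (5.0, 0.0, 0.0)},
    )


def _expression_design(cfg: RunConfig, rng: np.random.Generator) -> pd.DataFrame:
    k = cfg.expression_donors_per_group
    ages = list(rng.uniform(20, 40, k)) + list(rng.uniform(60, 75, k))
    truth = sim.CompositionTruth(
        cell_types=["x", "y"],
        n_donors=2 * k,
        ages=[float(a) for a in ages],
        baseline_log_abundance={"x": 0.0, "y": 0.0},
        age_logfc={},
        libraries_per_donor=cfg.libraries_per_donor,
    )
    return sim._library_design(truth)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the enabled stages in dependency order."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed, version=__version__)
    artifacts: dict[str, object] = {}

    for stage in STAGES:
        if not config.stages.get(stage, False):
            continue
        t0 = time.perf_counter()
        logger.info("running stage %s", stage)
        try:
            info = _STAGE_FUNCS[stage](config, outdir, artifacts)
        except Exception as exc:  # halt with a partial report
            report.add(stage, status="failed", error=str(exc))
            report.save(outdir / "run_report.json")
            raise StageError(stage, exc) from exc
        info["seconds"] = round(time.perf_counter() - t0, 3)
        info["status"] = "ok"
        report.add(stage, **info)
    report.save(outdir / "run_report.json")
    return report


# ---------------------------------------------------------------------------
# stage implementations


def _stage_simulate(cfg: RunConfig, outdir: Path, art: dict) -> dict:
    seed = io.substream_seed(cfg.seed, "simulate")
    rng = np.random.default_rng(io.substream_seed(cfg.seed, "simulate.design"))
    ctruth = _composition_truth(cfg, rng)
    table, meta = sim.simulate_composition(ctruth, seed)
    etruth = _expression_truth(cfg)
    design = _expression_design(cfg, rng)
    adata = sim.simulate_expression(etruth, design, io.substream_seed(cfg.seed, "simulate.expr"))
    homologs, gene_sets, lr = sim.make_fixture_tables(
        io.substream_seed(cfg.seed, "simulate.fixtures"), n_genes=cfg.n_genes
    )

    d = outdir / "simulate"
    d.mkdir(exist_ok=True)
    io.write_tsv(table, d / "composition.tsv")
    io.write_tsv(meta, d / "composition_meta.tsv")
    io.write_counts(adata, d / "expression")
    io.write_tsv(homologs, d / "homologs.tsv")
    io.write_gmt(gene_sets, d / "gene_sets.gmt")
    io.write_lr_table(lr, d / "lr_pairs.tsv")
    truth_out = pd.DataFrame(
        {
            "gene": adata.var_names,
            "is_deg": adata.var["is_deg"].to_numpy(),
            "true_log2fc": adata.var["true_log2fc"].to_numpy(),
        }
    )
    io.write_tsv(truth_out, d / "expression_truth.tsv")
    io.write_tsv(
        pd.DataFrame(
            {
                "cell_type": ctruth.cell_types,
                "baseline": [ctruth.baseline_log_abundance[c] for c in ctruth.cell_types],
                "age_logfc": [ctruth.age_logfc.get(c, 0.0) for c in ctruth.cell_types],
            }
        ),
        d / "composition_truth.tsv",
    )
    art.update(
        composition_table=table, composition_meta=meta, adata=adata,
        homologs=homologs, gene_sets=gene_sets, lr=lr, ctruth=ctruth,
    )
    return {"n_libraries": len(meta), "n_cells": adata.n_obs, "n_genes": adata.n_vars}


def _stage_qc(cfg: RunConfig, outdir: Path, art: dict) -> dict:
    adata = art["adata"]
    mito_genes = [g for g in adata.var_names if g.startswith("MT-")]
    metrics = qcmod.compute_qc_metrics(adata, mito_genes)
    keep_ids: list[str] = []
    reports = {}
    for modality in sorted(adata.obs["modality"].astype(str).unique()):
        sub = adata[adata.obs["modality"].astype(str) == modality]
        params = qcmod.QCParams(
            modality=modality,
            min_genes=cfg.qc_min_genes,
            max_genes=cfg.qc_max_genes,
            min_counts=cfg.qc_min_counts,
            max_counts=cfg.qc_max_counts,
            max_mito_fraction=(
                cfg.qc_max_mito_fraction
                if modality == "cell"
                else cfg.qc_max_mito_fraction_nucleus
            ),
            max_doublet_score=cfg.qc_max_doublet_score,
        )
        _, rep = qcmod.filter_cells(sub, metrics.loc[sub.obs_names], params)
        keep_ids.extend(rep.kept_index)
        reports[modality] = rep.to_dict()
    keep_set = set(keep_ids)
    filtered = adata[[cid in keep_set for cid in adata.obs_names]].copy()
    d = outdir / "qc"
    d.mkdir(exist_ok=True)
    io.write_counts(filtered, d / "filtered")
    with open(d / "report.json", "w") as fh:
        json.dump(reports, fh, indent=2)
    art["adata_qc"] = filtered
    return {"n_input": int(adata.n_obs), "n_kept": int(filtered.n_obs)}


def _stage_composition(cfg: RunConfig, outdir: Path, art: dict) -> dict:
    table = composition.make_composition_table(
        art["composition_table"], art["composition_meta"]
    )
    fit = composition.fit_composition_glmm(table)
    effects = composition.celltype_age_effects(fit)
    d = outdir / "composition"
    d.mkdir(exist_ok=True)
    io.write_tsv(effects, d / "age_effects.tsv")
    io.write_tsv(
        pd.DataFrame(
            {"group": list(fit.variance_components), "sd": list(fit.variance_components.values())}
        ),
        d / "variance_components.tsv",
    )
    art["composition_effects"] = effects
    return {
        "n_rows": len(table),
        "converged": bool(fit.converged),
        "n_significant": int(effects["significant"].sum()),
    }


def _stage_deg(cfg: RunConfig, outdir: Path, art: dict) -> dict:
    adata = art.get("adata_qc", art.get("adata"))
    fits, props = deg.fit_all_genes(adata)
    results = deg.call_aging_degs(fits, props)
    table = deg.deg_table(results)
    d = outdir / "deg"
    d.mkdir(exist_ok=True)
    io.write_tsv(table, d / "aging_degs.tsv")
    art["deg_table"] = table
    return {"n_genes": len(table), "n_significant": int(table["significant"].sum())}


def _stage_fibertype(cfg: RunConfig, outdir: Path, art: dict) -> dict:
    adata = art.get("adata_qc", art.get("adata"))
    norm = deg.normalize_log(adata)
    expr = pd.DataFrame(
        np.asarray(norm[:, list(myo.GENES)].X.todense()),
        index=norm.obs_names,
        columns=list(myo.GENES),
    )
    calls = myo.classify_myonuclei(expr, threshold=cfg.myh_threshold)
    donor_map = adata.obs[["donor", "age_group"]].copy()
    props = myo.donor_proportions(calls, donor_map)
    table = myo.proportions_table(props)
    tests = []
    kept = table.loc[~table["excluded"]]
    for cls in myo.CLASS_NAMES:
        young = kept.loc[kept["age_group"] == "young", cls].to_numpy()
        aged = kept.loc[kept["age_group"] == "aged", cls].to_numpy()
        if len(young) >= 2 and len(aged) >= 2:
            stat, p, degen = myo.compare_age_groups(young, aged, test="t")
            tests.append({"class": cls, "t": stat, "p": p, "degenerate": degen})
    d = outdir / "fibertype"
    d.mkdir(exist_ok=True)
    io.write_tsv(
        pd.DataFrame(
            {
                "nucleus_id": [c.nucleus_id for c in calls],
                "class": [c.cls for c in calls],
            }
        ),
        d / "calls.tsv",
    )
    io.write_tsv(table, d / "donor_proportions.tsv")
    io.write_tsv(pd.DataFrame(tests), d / "age_tests.tsv")
    return {"n_nuclei": len(calls), "n_donors": len(table), "n_excluded": int(table["excluded"].sum())}


def _stage_cross_species(cfg: RunConfig, outdir: Path, art: dict) -> dict:
    degs = art["deg_table"]
    homologs = art["homologs"]
    gene_sets = art["gene_sets"]
    universe_h = set(degs["gene"])
    records_h, records_m = [], []
    jac_rows = []
    for direction in ("up", "down"):
        sig = set(
            degs.loc[degs["significant"] & (degs["direction"] == direction), "gene"]
        )
        mapped, _ = cross_species.map_homologs(sig, homologs)
        # deterministic stand-in mouse set: two thirds of the mapped genes
        mouse_set = frozenset(sorted(mapped)[: (2 * len(mapped)) // 3])
        jac, empty = cross_species.jaccard(mapped, mouse_set)
        jac_rows.append(
            {"direction": direction, "jaccard": jac, "both_empty": empty}
        )
        universe_m, _ = cross_species.map_homologs(universe_h, homologs)
        for name, members in gene_sets.items():
            records_h.append(
                cross_species.ora_hypergeometric(
                    sig, set(members), universe_h, pathway_id=name,
                    cell_type="all", direction=direction,
                )
            )
            members_m, _ = cross_species.map_homologs(set(members), homologs)
            records_m.append(
                cross_species.ora_hypergeometric(
                    set(mouse_set), set(members_m), set(universe_m),
                    pathway_id=name, cell_type="all", direction=direction,
                )
            )
    cross_species.adjust_bh(records_h)
    cross_species.adjust_bh(records_m)
    score = cross_species.coenrichment_score(records_h, records_m, alpha=cfg.ora_alpha)
    d = outdir / "cross_species"
    d.mkdir(exist_ok=True)
    io.write_tsv(pd.DataFrame(jac_rows), d / "jaccard.tsv")
    io.write_tsv(
        pd.DataFrame([vars(r) for r in records_h]), d / "ora_human.tsv"
    )
    io.write_tsv(score, d / "coenrichment.tsv")
    return {"n_pathways": len(gene_sets), "n_coenriched": int((score[["n_up", "n_down"]].abs().sum(axis=1) > 0).sum()) if len(score) else 0}


def _stage_interactions(cfg: RunConfig, outdir: Path, art: dict) -> dict:
    adata = art.get("adata_qc", art.get("adata"))
    lr = art["lr"]
    props = interactions.expression_proportion(adata)
    pairs = [interactions.LRPair.from_row(row) for _, row in lr.iterrows()]
    clusters = list(props.index)
    calls = interactions.filter_interactions(
        pairs, props, clusters, clusters, threshold=cfg.lr_threshold
    )
    d = outdir / "interactions"
    d.mkdir(exist_ok=True)
    io.write_tsv(interactions.calls_table(calls), d / "calls.tsv")
    return {"n_calls": len(calls), "n_retained": sum(c.retained for c in calls)}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "composition": _stage_composition,
    "deg": _stage_deg,
    "fibertype": _stage_fibertype,
    "cross_species": _stage_cross_species,
    "interactions": _stage_interactions,
}
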