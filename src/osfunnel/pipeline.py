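"""End-to-end orchestration: simulate -> screen -> integrate -> enrich.

One config drives every stage; all randomness flows from a single top-level
seed through named substreams, so the same (config, seed) reproduces the
report byte for byte.  Stage outputs land on disk as the TSV formats of the
I/O module, sufficient to re-run any downstream stage in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as fio
from .datatypes import associations_to_frame
from .enrichment import enrich_by_chromosome
from .integration import (
    apply_funnel,
    correlate_ge_cnv,
    fold_change_vs_normal,
    overlap_fdr,
    replicated_overlap,
    risk_prevalence,
    triple_signature,
)
from .segmentation import SegmentationParams
from .survival import genewise_screen
from .synthetic import Study, SyntheticConfig, default_config, generate_study

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_pipeline_config"]

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    Exactly one of ``synthetic`` (a SyntheticConfig) or ``input_paths``
    (clinical / expression / cnv TSVs plus annotation BED) must be
    supplied.  ``alpha`` applies to every screen; the adjustment set
    defaults to race + metastasis; ``flags`` optionally points to the
    curated per-gene criteria TSV for the final funnel.
    """

    synthetic: Optional[SyntheticConfig] = None
    input_paths: Optional[dict] = None
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    alpha: float = 0.05
    adjust: Sequence[str] = ("race", "metastasis")
    prevalence_threshold: float = 0.9
    flags_path: Optional[str] = None
    out_dir: str = "osfunnel_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.input_paths is None):
            raise ValueError("supply exactly one of synthetic config or input paths")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def load_pipeline_config(path, seed: Optional[int] = None, out_dir: Optional[str] = None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file.

    A ``synthetic`` section maps onto SyntheticConfig (with ``planted_genes``
    as a list of mappings); an ``inputs`` section supplies file paths.  The
    CLI's --seed/--out override the file.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    syn = None
    if "synthetic" in raw:
        body = dict(raw["synthetic"] or {})
        planted = body.pop("planted_genes", None)
        if planted is not None:
            from .synthetic import PlantedGene

            body["planted_genes"] = tuple(PlantedGene(**p) for p in planted)
        syn = SyntheticConfig(**body)
    seg = SegmentationParams(**raw.get("segmentation", {}))
    cfg = PipelineConfig(
        synthetic=syn,
        input_paths=raw.get("inputs"),
        segmentation=seg,
        alpha=raw.get("alpha", 0.05),
        adjust=tuple(raw.get("adjust", ("race", "metastasis"))),
        prevalence_threshold=raw.get("prevalence_threshold", 0.9),
        flags_path=raw.get("flags"),
        out_dir=out_dir or raw.get("out_dir", "osfunnel_out"),
        seed=raw.get("seed", 0) if seed is None else seed,
    )
    if seed is not None and cfg.synthetic is not None:
        cfg.synthetic = dataclasses.replace(cfg.synthetic, seed=seed)
    return cfg


def _load_study_from_paths(paths: dict) -> Study:
    from .datatypes import ClinicalRecord  # noqa: F401  (type context)

    clin = fio.read_clinical(paths["clinical"])
    expr = fio.read_matrix(paths["expression"], "expression")
    cn_cont = fio.read_matrix(paths["cnv_continuous"], "copy_number_continuous")
    cn_cat = (
        fio.read_matrix(paths["cnv_categorical"], "copy_number_categorical")
        if "cnv_categorical" in paths
        else None
    )
    anns = fio.read_annotation_bed(paths["annotation"])
    repl_clin = fio.read_clinical(paths["replication_clinical"])
    repl_expr = fio.read_matrix(paths["replication_expression"], "expression")
    normal = fio.read_matrix(paths["normal_expression"], "expression")
    from .synthetic import Cohort

    discovery = Cohort(clin, expr, cn_cont, cn_cat, truth={})
    replication = Cohort(repl_clin, repl_expr, None, None, truth={})
    return Study(discovery, replication, normal, anns, config=None)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order and return the report.

    Stages: cohort acquisition (synthetic or from disk), the three per-gene
    screens, cross-cohort replication overlap with chance FDR, triple
    signature, fold change vs the normal panel, risk prevalence,
    four-criterion funnel, and per-chromosome enrichment.  Stage TSVs are
    written under ``out_dir``; the report is JSON-serializable and free of
    timestamps.  Any stage error aborts with the stage name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION, "alpha": config.alpha}

    if config.synthetic is not None:
        syncfg = dataclasses.replace(config.synthetic, seed=config.seed)
        study = _stage("simulate")(generate_study)(syncfg)
        report["planted_genes"] = [p["symbol"] for p in study.discovery.truth["planted"]]
        _write_study(study, out)
    else:
        study = _stage("load")(_load_study_from_paths)(config.input_paths)
        report["planted_genes"] = None

    disc, repl = study.discovery, study.replication
    if disc.cn_categorical is None or disc.cn_continuous is None:
        raise RuntimeError("pipeline stage 'screen' needs discovery copy-number data")

    screen = _stage("screen")(genewise_screen)
    ge_surv, ge_sig = screen(disc.expression, disc.clinical, kind="GE~survival",
                             adjust=config.adjust, alpha=config.alpha)
    # replication cohorts typically lack clinical covariates; adjust only
    # with what the cohort actually records
    repl_frame_has = {
        "race": any(r.race is not None for r in repl.clinical),
        "metastasis": any(r.metastasis_at_diagnosis is not None for r in repl.clinical),
        "gender": any(r.gender is not None for r in repl.clinical),
        "age": any(r.age_years is not None for r in repl.clinical),
    }
    repl_adjust = tuple(a for a in config.adjust if repl_frame_has.get(a, False))
    ge_surv_b, ge_sig_b = screen(repl.expression, repl.clinical, kind="GE~survival",
                                 adjust=repl_adjust, alpha=config.alpha)
    cnv_surv, cnv_sig = screen(disc.cn_categorical, disc.clinical, kind="CNV~survival",
                               adjust=config.adjust, alpha=config.alpha)
    ge_cnv = _stage("correlate")(correlate_ge_cnv)(disc.expression, disc.cn_continuous)
    ge_cnv_sig = [r.gene for r in ge_cnv if r.estimable and r.p_value < config.alpha]

    for name, recs in (
        ("ge_survival", ge_surv),
        ("ge_survival_replication", ge_surv_b),
        ("cnv_survival", cnv_surv),
        ("ge_cnv", ge_cnv),
    ):
        associations_to_frame(recs).to_csv(out / f"{name}.tsv", sep="\t")

    overlap = _stage("overlap")(replicated_overlap)(ge_surv, ge_surv_b, config.alpha)
    n_common = len(
        {r.gene for r in ge_surv if r.estimable}
        & {r.gene for r in ge_surv_b if r.estimable}
    )
    fdr = overlap_fdr(n_common, config.alpha, config.alpha, 2, len(overlap)) if overlap else None

    # the triple signature is taken within the replicated gene list,
    # mirroring the funnel order: replicate first, then integrate CNV
    overlap_set = set(overlap)
    ge_surv_repl = [r for r in ge_surv if r.gene in overlap_set]
    signature = _stage("integrate")(triple_signature)(
        ge_surv_repl, cnv_surv, ge_cnv, config.alpha
    )
    signature.table.to_csv(out / "signature.tsv", sep="\t")

    fold = _stage("fold_change")(fold_change_vs_normal)(disc.expression, study.normal)
    fold.to_csv(out / "fold_change.tsv", sep="\t")

    prevalence = {}
    for gene in signature.table.index:
        risk_class = signature.table.loc[gene, "risk_class"]
        prevalence[gene] = risk_prevalence(
            disc.cn_categorical, gene,
            risk_category=1 if risk_class == "gain" else -1,
            include_normal=risk_class == "gain",
        )
    prevalence = pd.Series(prevalence, dtype=float)

    if config.flags_path:
        flags = pd.read_csv(config.flags_path, sep="\t", index_col=0).astype(bool)
    else:
        # without a curated criteria table, every signature gene is taken
        # as targetable/druggable/modeled so the prevalence criterion alone rules
        flags = pd.DataFrame(
            True,
            index=signature.table.index,
            columns=["targetable_network", "inhibitor_available", "model_available"],
        )
    funnel = _stage("funnel")(apply_funnel)(
        signature, flags, prevalence, config.prevalence_threshold
    )
    funnel.to_csv(out / "funnel.tsv", sep="\t")

    chrom_of = {a.symbol: a.chromosome for a in study.annotations}
    cat = disc.cn_categorical.values
    sig_set = set(cnv_sig)
    gene_table = pd.DataFrame(
        {
            "symbol": list(cat.index),
            "chromosome": [chrom_of.get(g, "unplaced") for g in cat.index],
            "significant": [g in sig_set for g in cat.index],
            "gain": (cat == 1).any(axis=1).to_numpy(),
            "loss": (cat == -1).any(axis=1).to_numpy(),
        }
    )
    enrichment = _stage("enrich")(enrich_by_chromosome)(gene_table)
    enrichment.to_csv(out / "enrichment.tsv", sep="\t")

    report.update(
        {
            "n_patients": len(disc.clinical),
            "n_replication": len(repl.clinical),
            "n_genes": len(disc.expression.gene_ids),
            "screen_counts": {
                "ge_survival": len(ge_sig),
                "ge_survival_replication": len(ge_sig_b),
                "cnv_survival": len(cnv_sig),
                "ge_cnv": len(ge_cnv_sig),
            },
            "replicated_overlap": overlap,
            "overlap_fdr": fdr,
            "signature_genes": list(signature.table.index),
            "signature_incoherent": signature.incoherent,
            "signature_fdr": signature.fdr,
            "funnel_candidates": list(funnel.index),
            "prevalence": {g: float(v) for g, v in prevalence.items()},
            "enrichment": {
                chrom: {
                    "total_genes": int(row.total_genes),
                    "significant_genes": int(row.significant_genes),
                    "odds_ratio": (
                        None if not np.isfinite(row.odds_ratio)
                        else round(float(row.odds_ratio), 6)
                    ),
                    "neg_ln_p": round(float(row.neg_ln_p), 6),
                }
                for chrom, row in enrichment.iterrows()
            },
        }
    )
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _write_study(study: Study, out: Path) -> None:
    fio.write_clinical(study.discovery.clinical, out / "clinical.tsv")
    fio.write_matrix(study.discovery.expression, out / "expression.tsv")
    fio.write_matrix(study.discovery.cn_continuous, out / "cnv_continuous.tsv")
    fio.write_matrix(study.discovery.cn_categorical, out / "cnv_categorical.tsv")
    fio.write_clinical(study.replication.clinical, out / "replication_clinical.tsv")
    fio.write_matrix(study.replication.expression, out / "replication_expression.tsv")
    fio.write_matrix(study.normal, out / "normal_expression.tsv")
    fio.write_annotation_bed(study.annotations, out / "annotations.bed")
    truth = {
        "planted": study.discovery.truth["planted"],
        "baseline_hazard": study.discovery.truth["baseline_hazard"],
        "metastasis_log_hazard": study.discovery.truth["metastasis_log_hazard"],
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
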