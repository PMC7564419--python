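"""Integration stages of the prognostic funnel.

Per-gene expression~copy-number regression, direction-consistent
cross-cohort overlap with an empirical chance-overlap FDR, the
triple-significance signature (expression~survival, CNV~survival,
expression~CNV all significant with mutually coherent directions),
fold change against a normal-tissue panel with Wilcoxon rank-sum tests and
Benjamini-Hochberg adjustment, risk-category prevalence, and the final
four-criterion prioritization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    AssociationRecord,
    CopyNumberMatrix,
    ExpressionMatrix,
    associations_to_frame,
)

logger = logging.getLogger(__name__)

__all__ = [
    "correlate_ge_cnv",
    "replicated_overlap",
    "overlap_fdr",
    "triple_signature",
    "fold_change_vs_normal",
    "risk_prevalence",
    "apply_funnel",
    "SignatureTable",
]

_TINY_P = np.finfo(float).tiny


def correlate_ge_cnv(
    expression: ExpressionMatrix, cn_continuous: CopyNumberMatrix
) -> list[AssociationRecord]:
    """Per-gene simple linear regression of expression on copy number.

    Returns one GE~CNV association per shared gene: slope, its standard
    error, and the two-sided p from the t test on the slope.  Genes with
    zero copy-number variance (or fewer than 3 complete pairs) are flagged
    inestimable.
    """
    shared_samples = [s for s in expression.sample_ids if s in cn_continuous.values.columns]
    if len(shared_samples) < 3:
        raise ValueError("need at least 3 shared samples")
    shared_genes = [g for g in expression.gene_ids if g in cn_continuous.values.index]
    e = expression.values.loc[shared_genes, shared_samples].to_numpy()
    c = cn_continuous.values.loc[shared_genes, shared_samples].to_numpy()

    records = []
    for gi, gene in enumerate(shared_genes):
        x, y = c[gi], e[gi]
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        n = len(x)
        if n < 3 or np.ptp(x) == 0:
            records.append(
                AssociationRecord(
                    gene=gene, kind="GE~CNV", beta=np.nan, se=np.nan,
                    p_value=np.nan, direction=0, n_used=n, estimable=False,
                )
            )
            continue
        res = stats.linregress(x, y)
        p = max(float(res.pvalue), _TINY_P)
        records.append(
            AssociationRecord(
                gene=gene, kind="GE~CNV", beta=float(res.slope),
                se=float(res.stderr), p_value=p,
                direction=int(np.sign(res.slope)), n_used=n,
            )
        )
    n_bad = sum(not r.estimable for r in records)
    if n_bad:
        logger.info("correlate_ge_cnv: %d/%d genes inestimable", n_bad, len(records))
    return records


def _significant(records: Sequence[AssociationRecord], alpha: float) -> dict[str, int]:
    """Map gene -> direction for estimable records with p < alpha."""
    return {
        r.gene: r.direction
        for r in records
        if r.estimable and r.p_value < alpha
    }


def replicated_overlap(
    table_a: Sequence[AssociationRecord],
    table_b: Sequence[AssociationRecord],
    alpha: float = 0.05,
) -> list[str]:
    """Genes significant (p < alpha) in both cohorts with the same
    direction of association.  Empty result is allowed."""
    sig_a = _significant(table_a, alpha)
    sig_b = _significant(table_b, alpha)
    return sorted(g for g, d in sig_a.items() if sig_b.get(g) == d)


def overlap_fdr(
    n_common: int,
    alpha_a: float,
    alpha_b: float,
    direction_levels: int,
    observed_overlap: int,
) -> float:
    """Chance-overlap false discovery rate of a replicated gene list.

    Under independent null screens, the expected number of genes passing
    both thresholds with concordant direction is
    n_common x alpha_a x alpha_b / direction_levels; the FDR estimate is
    that expectation over the observed overlap, capped at 1.
    """
    if observed_overlap < 1:
        raise ValueError("observed_overlap must be >= 1")
    expected = n_common * alpha_a * alpha_b / direction_levels
    return min(1.0, expected / observed_overlap)


def triple_overlap_fdr(n_common: int, alpha: float, observed_overlap: int) -> float:
    """Chance FDR for the triple intersection with direction coherence.

    Three independent screens at level alpha, with 2 coherent direction
    patterns out of the 2^3 sign combinations, give expected chance count
    n_common x alpha^3 / 4.
    """
    if observed_overlap < 1:
        raise ValueError("observed_overlap must be >= 1")
    expected = n_common * alpha**3 * 2 / 8
    return min(1.0, expected / observed_overlap)


@dataclass
class SignatureTable:
    """The triple-signature table plus bookkeeping.

    ``table`` has one row per gene in the triple intersection with
    coherent directions (risk classes: gain/up with HR > 1, or
    deletion/down with HR < 1); ``incoherent`` lists genes that met all
    three significance thresholds but mixed their direction pattern
    (reported, not admitted).  ``fdr`` is the chance-overlap estimate for
    the triple intersection.
    """

    table: pd.DataFrame
    incoherent: list[str]
    fdr: Optional[float]


def triple_signature(
    ge_surv: Sequence[AssociationRecord],
    cnv_surv: Sequence[AssociationRecord],
    ge_cnv: Sequence[AssociationRecord],
    alpha: float = 0.05,
) -> SignatureTable:
    """Intersect the three per-gene screens into the prognostic signature.

    A gene enters the signature when all three p-values are < alpha and the
    directions are mutually coherent: expression must rise with copy number
    (positive GE~CNV slope), and the two survival effects must share a
    sign — gain + higher expression + HR > 1 (risk by gain) or deletion +
    lower expression + HR < 1 (risk by deletion).
    """
    sig_ge = _significant(ge_surv, alpha)
    sig_cnv = _significant(cnv_surv, alpha)
    sig_gc = _significant(ge_cnv, alpha)
    common = sorted(set(sig_ge) & set(sig_cnv) & set(sig_gc))

    frames = {
        "ge_survival": associations_to_frame(ge_surv),
        "cnv_survival": associations_to_frame(cnv_surv),
        "ge_cnv": associations_to_frame(ge_cnv),
    }
    rows, incoherent = [], []
    for gene in common:
        d_ge, d_cnv, d_gc = sig_ge[gene], sig_cnv[gene], sig_gc[gene]
        coherent = d_gc > 0 and d_ge == d_cnv
        if not coherent:
            incoherent.append(gene)
            continue
        rows.append(
            {
                "gene": gene,
                "risk_class": "gain" if d_ge > 0 else "deletion",
                "ge_survival_hr": frames["ge_survival"].loc[gene, "hazard_ratio"],
                "ge_survival_p": frames["ge_survival"].loc[gene, "p_value"],
                "cnv_survival_hr": frames["cnv_survival"].loc[gene, "hazard_ratio"],
                "cnv_survival_p": frames["cnv_survival"].loc[gene, "p_value"],
                "ge_cnv_slope": frames["ge_cnv"].loc[gene, "beta"],
                "ge_cnv_p": frames["ge_cnv"].loc[gene, "p_value"],
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene", "risk_class", "ge_survival_hr", "ge_survival_p",
            "cnv_survival_hr", "cnv_survival_p", "ge_cnv_slope", "ge_cnv_p",
        ],
    ).set_index("gene")
    universe = set(frames["ge_survival"].index) & set(frames["cnv_survival"].index) \
        & set(frames["ge_cnv"].index)
    fdr = triple_overlap_fdr(len(universe), alpha, len(table)) if len(table) else None
    return SignatureTable(table=table, incoherent=incoherent, fdr=fdr)


def fold_change_vs_normal(
    tumor: ExpressionMatrix, normal: ExpressionMatrix
) -> pd.DataFrame:
    """Per-gene fold change of tumor over normal plus Wilcoxon rank-sum p.

    Input expression is log-scale; the fold change is the linear-scale
    ratio of geometric means, exp(mean_log_tumor - mean_log_normal).  The
    Wilcoxon rank-sum (Mann-Whitney) test is exact for small groups and
    normal-approximated otherwise (scipy's default switch); BH adjustment
    runs across all shared genes.
    """
    if tumor.shape[1] < 2 or normal.shape[1] < 2:
        raise ValueError("need at least 2 samples per group")
    shared = [g for g in tumor.gene_ids if g in normal.values.index]
    t = tumor.values.loc[shared].to_numpy()
    n = normal.values.loc[shared].to_numpy()
    fold = np.exp(t.mean(axis=1) - n.mean(axis=1))
    pvals = np.array(
        [
            stats.mannwhitneyu(t[i], n[i], alternative="two-sided").pvalue
            for i in range(len(shared))
        ]
    )
    adjusted = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {"fold_change": fold, "wilcoxon_p": pvals, "bh_adjusted_p": adjusted},
        index=pd.Index(shared, name="gene"),
    )


def risk_prevalence(
    categorical: CopyNumberMatrix,
    gene: str,
    risk_category: int = 1,
    include_normal: bool = False,
) -> float:
    """Fraction of patients carrying the gene's risk CNV category.

    ``risk_category`` is +1 (gain) or -1 (deletion).  With
    ``include_normal`` and a gain risk class, the gain-or-normal reading
    (category >= 0) is counted instead.
    """
    if not categorical.categorical:
        raise ValueError("risk_prevalence needs the categorical matrix")
    if gene not in categorical.values.index:
        raise KeyError(f"gene {gene!r} absent from copy-number matrix")
    row = categorical.values.loc[gene]
    if include_normal:
        if risk_category != 1:
            raise ValueError("gain-or-normal reading applies to the gain class only")
        hits = row >= 0
    else:
        hits = row == risk_category
    return float(hits.sum()) / float(len(row))


def apply_funnel(
    signature: SignatureTable,
    flags: pd.DataFrame,
    prevalence: pd.Series,
    prevalence_threshold: float = 0.9,
) -> pd.DataFrame:
    """Four-criterion prioritization over the signature table.

    ``flags`` carries the curated per-gene booleans (targetable_network,
    inhibitor_available, model_available) — supplied knowledge, not
    computed; ``prevalence`` is the risk-category patient fraction.
    Candidates must reach prevalence >= threshold AND all three flags;
    they are ranked by CNV~survival p ascending.
    """
    need = ["targetable_network", "inhibitor_available", "model_available"]
    missing = [c for c in need if c not in flags.columns]
    if missing:
        raise ValueError(f"flags table missing column(s): {missing}")
    rows = []
    for gene in signature.table.index:
        if gene not in flags.index:
            continue
        prev = float(prevalence.get(gene, np.nan))
        ok_flags = bool(flags.loc[gene, need].all())
        if np.isnan(prev) or prev < prevalence_threshold or not ok_flags:
            continue
        rows.append(
            {
                "gene": gene,
                "prevalence": prev,
                "cnv_survival_p": signature.table.loc[gene, "cnv_survival_p"],
                "risk_class": signature.table.loc[gene, "risk_class"],
            }
        )
    out = pd.DataFrame(
        rows, columns=["gene", "prevalence", "cnv_survival_p", "risk_class"]
    ).set_index("gene")
    return out.sort_values("cnv_survival_p")
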