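"""Per-chromosome enrichment of survival-associated CNV genes.

For each chromosome the 2x2 table (significant / not, this chromosome /
all others) yields an enrichment odds ratio OR = (a/b) / (c/d) and a
one-sided chi-square p-value in the direction OR > 1: the signed square
root of the chi-square statistic is treated as a standard normal deviate,
z = sign(ln OR) x sqrt(chi2), p = P(Z > z), with no continuity correction.
A depleted chromosome therefore reports p near 1.  Grand totals always
come from the input table.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["enrich_by_chromosome", "load_published_gene_table"]

#: column order mirrors the published per-chromosome summary layout
COLUMNS = [
    "chromosome",
    "total_genes",
    "significant_genes",
    "significant_pct",
    "cnv_gain_count",
    "cnv_loss_count",
    "p_one_sided",
    "odds_ratio",
    "neg_ln_p",
]


def enrich_by_chromosome(gene_table: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome enrichment rows from a per-gene table.

    ``gene_table`` needs columns (symbol, chromosome, significant) and
    optionally boolean gain / loss flags; each gene belongs to exactly one
    chromosome.  Returns one row per chromosome with counts, percentage,
    gain/loss tallies among significant genes, odds ratio, one-sided p and
    -ln p.  Edge cases: a chromosome with no significant genes reports
    OR = 0; b = 0 or d = 0 leaves the OR undefined (NaN, flagged).
    """
    need = {"symbol", "chromosome", "significant"}
    if not need.issubset(gene_table.columns):
        raise ValueError(f"gene table must have columns {sorted(need)}")
    if gene_table["symbol"].duplicated().any():
        dupes = gene_table["symbol"][gene_table["symbol"].duplicated()].tolist()
        raise ValueError(f"gene(s) assigned more than once: {sorted(set(dupes))[:5]}")

    grand_total = len(gene_table)
    grand_sig = int(gene_table["significant"].sum())

    rows = []
    for chrom, grp in gene_table.groupby("chromosome", sort=False):
        total = len(grp)
        a = int(grp["significant"].sum())
        b = total - a
        c = grand_sig - a
        d = (grand_total - total) - c

        if b == 0 or d == 0:
            odds_ratio = np.nan
        elif a == 0:
            odds_ratio = 0.0
        elif c == 0:
            odds_ratio = np.inf  # every significant gene sits on this chromosome
        else:
            odds_ratio = (a / b) / (c / d)

        chi2 = 0.0
        if 0 < a + b < grand_total and 0 < grand_sig < grand_total:
            obs = np.array([[a, b], [c, d]], dtype=float)
            colsum, rowsum = obs.sum(axis=0), obs.sum(axis=1)
            exp = np.outer(rowsum, colsum) / grand_total
            chi2 = float(((obs - exp) ** 2 / exp).sum())
        direction = 1.0 if (np.isnan(odds_ratio) or odds_ratio >= 1.0) else -1.0
        if odds_ratio == 0.0:
            direction = -1.0
        z = direction * np.sqrt(chi2)
        # survival function on the log scale keeps -ln p exact in far tails
        log_p = stats.norm.logsf(z)
        p = float(np.exp(log_p))

        sig = grp[grp["significant"].astype(bool)]
        gains = int(sig["gain"].sum()) if "gain" in grp.columns else 0
        losses = int(sig["loss"].sum()) if "loss" in grp.columns else 0

        rows.append(
            {
                "chromosome": str(chrom),
                "total_genes": total,
                "significant_genes": a,
                "significant_pct": 100.0 * a / total,
                "cnv_gain_count": gains,
                "cnv_loss_count": losses,
                "p_one_sided": min(p, 1.0) if p > 0 else p,
                "odds_ratio": odds_ratio,
                "neg_ln_p": float(-log_p),
            }
        )
    return pd.DataFrame(rows, columns=COLUMNS).set_index("chromosome")


def load_published_gene_table() -> pd.DataFrame:
    """Expand the packaged published per-chromosome counts to a gene table.

    The packaged TSV holds, for each of the 24 chromosomes, the printed
    total / significant / gain / loss gene counts from the osteosarcoma
    CNV-survival screen.  Symbols are synthetic placeholders — only the
    counts matter to the enrichment arithmetic.  Gain/loss flags are
    assigned to the first significant genes of each chromosome (the
    printed tallies are not mutually exclusive, so both flags may be set).
    """
    counts = load_published_counts()
    rows = []
    for rec in counts.itertuples():
        for i in range(rec.total_genes):
            sig = i < rec.significant_genes
            rows.append(
                {
                    "symbol": f"{rec.Index}_g{i + 1}",
                    "chromosome": rec.Index,
                    "significant": sig,
                    "gain": sig and i < rec.cnv_gain_count,
                    "loss": sig and i < rec.cnv_loss_count,
                }
            )
    return pd.DataFrame(rows)


def load_published_counts() -> pd.DataFrame:
    """The packaged published per-chromosome count table, indexed by chromosome."""
    ref = resources.files("osfunnel").joinpath("data/chromosome_cnv_counts.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    return df.set_index("chromosome")
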