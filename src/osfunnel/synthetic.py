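"""Synthetic cohorts with planted CNV-expression-survival structure.

The generator emulates the statistical skeleton of an integrative
osteosarcoma study: per-gene copy number with planted gain prevalences,
expression linearly coupled to copy number for the planted genes,
right-censored exponential survival under proportional hazards with a
metastasis covariate, a second expression-only replication cohort, a
normal-tissue expression panel, marker-level tracks for the segmenter, and
Hill-curve checkerboard dose-response data with a controllable Bliss-scale
interaction term.  Every output is a pure function of (config, seed); the
truth ledger records all planted parameters so downstream recovery is
checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datatypes import (
    ClinicalRecord,
    CopyNumberMatrix,
    DoseResponseMatrix,
    ExpressionMatrix,
    GeneAnnotation,
    MarkerTrack,
)
from .segmentation import SegmentationParams, categorize_copy_number

__all__ = [
    "PlantedGene",
    "SyntheticConfig",
    "Cohort",
    "Study",
    "default_config",
    "generate_cohort",
    "generate_study",
    "generate_marker_track",
    "generate_normal_panel",
    "generate_dose_matrix",
    "make_annotations",
]

RACES = ("white", "black", "asian", "other")
RACE_PROBS = (0.70, 0.15, 0.08, 0.07)
GAIN_COPIES = (3.0, 4.0)  # planted gains are discrete 3 or 4 copies


@dataclass(frozen=True)
class PlantedGene:
    """Ground truth for one gene with planted structure.

    ``cnv_gain_prevalence`` is the fraction of patients carrying the gain;
    ``ge_cnv_slope`` couples expression to copy number (log-expression
    units per copy); ``log_hazard_per_unit_expression`` drives survival.
    Genes sharing an ``amplicon`` label are co-gained: one carrier draw and
    one gain amplitude per patient covers the whole group, emulating a
    multi-gene amplicon (the gain prevalence is then read from the first
    gene of the group).  ``amplicon=None`` gives the gene its own
    independent gain events.
    """

    symbol: str
    cnv_gain_prevalence: float = 0.5
    ge_cnv_slope: float = 1.3
    log_hazard_per_unit_expression: float = 0.35
    amplicon: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.cnv_gain_prevalence <= 1.0:
            raise ValueError(f"{self.symbol}: prevalence outside [0, 1]")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic generators.

    Defaults mirror the emulated study: discovery cohort of 85 patients,
    replication cohort of 34, ~20% metastatic at diagnosis with log-hazard
    ln(1/0.21), five risk genes planted on chromosome 8.  The gene universe
    is 300 symbols spread over chromosomes 1-22 (a scaled-down genome; the
    generator makes no attempt to match a real platform's gene count).
    """

    n_patients: int = 85
    n_replication: int = 34
    n_normal: int = 10
    n_genes: int = 300
    planted_genes: tuple[PlantedGene, ...] = ()
    baseline_hazard: float = 0.12  # per year
    censoring_rate: float = 0.30
    metastasis_prevalence: float = 0.20
    metastasis_log_hazard: float = 1.56  # ln(1/0.21)
    baseline_expression: float = 5.0
    expression_noise_sd: float = 0.4
    marker_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must be in [0, 1)")
        if not 0.0 <= self.metastasis_prevalence <= 1.0:
            raise ValueError("metastasis_prevalence must be in [0, 1]")
        if self.expression_noise_sd <= 0 or self.marker_noise_sd <= 0:
            raise ValueError("noise standard deviations must be > 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        universe = set(self.gene_ids())
        missing = [g.symbol for g in self.planted_genes if g.symbol not in universe]
        if missing:
            raise ValueError(f"planted symbols outside gene universe: {missing}")

    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]


def make_annotations(config: SyntheticConfig) -> list[GeneAnnotation]:
    """Lay the gene universe out over chromosomes 1-22, round-robin.

    Gene i sits on chr(1 + i mod 22), in 10 kb steps of 5 kb genes
    (0-based half-open).  Deterministic in the config alone.
    """
    anns = []
    rank: dict[str, int] = {}
    for i, symbol in enumerate(config.gene_ids()):
        chrom = f"chr{(i % 22) + 1}"
        k = rank.get(chrom, 0)
        rank[chrom] = k + 1
        start = k * 10_000
        anns.append(GeneAnnotation(symbol=symbol, chromosome=chrom, start=start, end=start + 5_000))
    return anns


def default_config(seed: int = 0) -> SyntheticConfig:
    """The default study conditions: a five-gene co-amplified risk
    signature planted on chromosome 8 (one shared amplicon, mirroring the
    co-gained multi-gene signatures the pipeline is built to find)."""
    base = SyntheticConfig(seed=seed)
    chr8 = [a.symbol for a in make_annotations(base) if a.chromosome == "chr8"]
    planted = tuple(PlantedGene(symbol=s, amplicon="amp8q") for s in chr8[:5])
    return replace(base, planted_genes=planted)


def _uniform_censor_horizon(rates: np.ndarray, target: float) -> float:
    """Administrative horizon T for Uniform(0, T) censoring.

    Chooses T so the expected censored fraction over the cohort's subject-
    specific exponential rates equals ``target``:
    P(censored | rate r) = (1 - exp(-rT)) / (rT), decreasing in T.
    """

    def censored_fraction(T: float) -> float:
        x = rates * T
        return float(np.mean(np.expm1(-x) / -x))

    lo, hi = 1e-9, 1e9
    return brentq(lambda T: censored_fraction(T) - target, lo, hi, xtol=1e-10, rtol=1e-12)


@dataclass
class Cohort:
    """One synthetic patient set plus its ground-truth ledger."""

    clinical: list[ClinicalRecord]
    expression: ExpressionMatrix
    cn_continuous: Optional[CopyNumberMatrix]
    cn_categorical: Optional[CopyNumberMatrix]
    truth: dict = field(repr=False)


def generate_cohort(
    config: SyntheticConfig,
    with_cnv: bool = True,
    n_patients: Optional[int] = None,
    sample_prefix: str = "P",
    subseed: int = 0,
    record_covariates: bool = True,
) -> Cohort:
    """Generate one cohort under the configured study conditions.

    Planted genes: per-patient copy number is a gain of 3 or 4 copies with
    the stated prevalence, else diploid (2); measurement noise with SD
    ``marker_noise_sd`` is added to the continuous gene-level values before
    three-state calling.  Expression is baseline + slope x (copies - 2) +
    Gaussian noise.  Survival is exponential with hazard
    baseline_hazard x exp(sum of per-gene log-hazard x centered expression
    + metastasis term), censored by an independent Uniform(0, T) time with
    T solved to hit the target censoring fraction.  Identical (config,
    subseed) -> identical output.
    """
    rng = np.random.default_rng((config.seed, subseed))
    n = config.n_patients if n_patients is None else n_patients
    genes = config.gene_ids()
    gindex = {g: i for i, g in enumerate(genes)}

    # true integer copies: diploid everywhere, planted gains where drawn;
    # genes of one amplicon share carrier status and gain amplitude
    copies = np.full((config.n_genes, n), 2.0)
    gain_mask = np.zeros((config.n_genes, n), dtype=bool)
    groups: dict[str, list] = {}
    for pg in config.planted_genes:
        key = pg.amplicon if pg.amplicon is not None else f"__solo__{pg.symbol}"
        groups.setdefault(key, []).append(pg)
    for members in groups.values():
        carrier = rng.random(n) < members[0].cnv_gain_prevalence
        amplitude = rng.choice(GAIN_COPIES, size=int(carrier.sum()))
        for pg in members:
            gi = gindex[pg.symbol]
            copies[gi, carrier] = amplitude
            gain_mask[gi] = carrier

    # expression: baseline + slope * (copies - 2) + noise
    expr = np.full((config.n_genes, n), config.baseline_expression)
    for pg in config.planted_genes:
        gi = gindex[pg.symbol]
        expr[gi] += pg.ge_cnv_slope * (copies[gi] - 2.0)
    expr += rng.normal(0.0, config.expression_noise_sd, size=expr.shape)

    # survival: exponential PH on centered expression of planted genes
    metastasis = (rng.random(n) < config.metastasis_prevalence).astype(int)
    lp = config.metastasis_log_hazard * metastasis.astype(float)
    for pg in config.planted_genes:
        gi = gindex[pg.symbol]
        lp += pg.log_hazard_per_unit_expression * (expr[gi] - config.baseline_expression)
    rates = config.baseline_hazard * np.exp(lp)
    death = rng.exponential(1.0 / rates)
    if config.censoring_rate > 0:
        horizon = _uniform_censor_horizon(rates, config.censoring_rate)
        censor = rng.uniform(0.0, horizon, size=n)
        times = np.minimum(death, censor)
        events = (death <= censor).astype(int)
    else:
        horizon = np.inf
        times, events = death, np.ones(n, dtype=int)

    races = rng.choice(RACES, size=n, p=RACE_PROBS)
    genders = rng.choice(("female", "male"), size=n)
    ages = rng.uniform(8.0, 25.0, size=n)

    ids = [f"{sample_prefix}{i + 1:03d}" for i in range(n)]
    # an unannotated cohort still *has* the metastasis biology in its
    # hazard; record_covariates=False just leaves the fields unrecorded
    clinical = [
        ClinicalRecord(
            patient_id=ids[i],
            survival_years=float(times[i]),
            event=int(events[i]),
            metastasis_at_diagnosis=int(metastasis[i]) if record_covariates else None,
            race=str(races[i]) if record_covariates else None,
            gender=str(genders[i]) if record_covariates else None,
            age_years=float(ages[i]) if record_covariates else None,
        )
        for i in range(n)
    ]

    expr_frame = pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=ids)
    expression = ExpressionMatrix(expr_frame)

    cn_cont = cn_cat = None
    if with_cnv:
        measured = copies + rng.normal(0.0, config.marker_noise_sd, size=copies.shape)
        measured = np.clip(measured, 1e-3, None)  # copy number stays positive
        cn_frame = pd.DataFrame(measured, index=pd.Index(genes, name="gene"), columns=ids)
        cn_cont = CopyNumberMatrix(cn_frame, categorical=False)
        cn_cat = categorize_copy_number(cn_cont, SegmentationParams())

    truth = {
        "planted": [
            {
                "symbol": pg.symbol,
                "cnv_gain_prevalence": pg.cnv_gain_prevalence,
                "ge_cnv_slope": pg.ge_cnv_slope,
                "log_hazard_per_unit_expression": pg.log_hazard_per_unit_expression,
                "amplicon": pg.amplicon,
                "realized_gain_fraction": float(gain_mask[gindex[pg.symbol]].mean()),
            }
            for pg in config.planted_genes
        ],
        "baseline_hazard": config.baseline_hazard,
        "censoring_horizon": horizon,
        "metastasis_log_hazard": config.metastasis_log_hazard,
        "true_copies": pd.DataFrame(
            copies, index=pd.Index(genes, name="gene"), columns=ids
        ),
    }
    return Cohort(clinical, expression, cn_cont, cn_cat, truth)


@dataclass
class Study:
    """Discovery cohort (with CNV), expression-only replication cohort,
    normal-tissue panel and gene annotations."""

    discovery: Cohort
    replication: Cohort
    normal: ExpressionMatrix
    annotations: list[GeneAnnotation]
    config: SyntheticConfig


def generate_study(config: SyntheticConfig) -> Study:
    """Generate the full synthetic study from one config and seed.

    The replication cohort shares the planted genes (gains drawn afresh)
    but exposes only clinical + expression data, mirroring an expression-
    only public cohort; the normal panel holds baseline expression with
    the same noise model.
    """
    discovery = generate_cohort(config, with_cnv=True, subseed=1)
    # the replication cohort mirrors an expression-only public dataset:
    # no CNV data and no recorded clinical covariates
    replication = generate_cohort(
        config,
        with_cnv=False,
        n_patients=config.n_replication,
        sample_prefix="R",
        subseed=2,
        record_covariates=False,
    )
    means = pd.Series(config.baseline_expression, index=config.gene_ids())
    normal = generate_normal_panel(
        config.n_normal, means, config.expression_noise_sd, seed=(config.seed, 3)
    )
    return Study(discovery, replication, normal, make_annotations(config), config)


def generate_marker_track(
    segments_spec: Sequence[tuple[str, int, float]],
    marker_noise_sd: float,
    seed,
    sample_id: str = "S1",
) -> tuple[MarkerTrack, list[tuple[str, int]]]:
    """Piecewise-constant marker track plus its true breakpoints.

    ``segments_spec`` lists (chromosome, n_markers, true copy number)
    blocks; consecutive blocks on one chromosome get consecutive 1-based
    positions.  The returned breakpoints are (chromosome, position of the
    first marker after the break); one fewer than blocks per chromosome.
    ``marker_noise_sd`` may be 0 for noiseless fixtures.
    """
    if marker_noise_sd < 0:
        raise ValueError("marker_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows, breakpoints = [], []
    next_pos: dict[str, int] = {}
    for chrom, n_markers, cn in segments_spec:
        if n_markers < 1:
            raise ValueError("each block needs at least one marker")
        if cn <= 0:
            raise ValueError("true copy number must be positive")
        start = next_pos.get(chrom, 1)
        if start > 1:
            breakpoints.append((chrom, start))
        vals = np.full(n_markers, float(cn))
        if marker_noise_sd:
            vals = vals + rng.normal(0.0, marker_noise_sd, n_markers)
        vals = np.clip(vals, 1e-3, None)
        for k in range(n_markers):
            rows.append((chrom, start + k, float(vals[k])))
        next_pos[chrom] = start + n_markers
    frame = pd.DataFrame(rows, columns=["chromosome", "position", "copy_number"])
    return MarkerTrack(sample_id=sample_id, markers=frame), breakpoints


def generate_normal_panel(
    n_samples: int, gene_means: pd.Series, noise_sd: float, seed
) -> ExpressionMatrix:
    """Normal-tissue expression panel: per-gene means plus Gaussian noise."""
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    rng = np.random.default_rng(seed)
    means = gene_means.to_numpy(dtype=float)[:, None]
    vals = means + rng.normal(0.0, noise_sd, size=(len(gene_means), n_samples))
    frame = pd.DataFrame(
        vals,
        index=pd.Index(gene_means.index.astype(str), name="gene"),
        columns=[f"N{i + 1:03d}" for i in range(n_samples)],
    )
    return ExpressionMatrix(frame)


def hill_fraction_affected(dose, dm: float, m: float):
    """Median-effect (Hill) curve fa(D) = 1 / (1 + (Dm/D)^m); fa(0) = 0."""
    dose = np.asarray(dose, dtype=float)
    out = np.zeros_like(dose)
    nz = dose > 0
    out[nz] = 1.0 / (1.0 + (dm / dose[nz]) ** m)
    return out if out.ndim else float(out)


def generate_dose_matrix(
    hill_a: tuple[float, float],
    hill_b: tuple[float, float],
    doses_a: Sequence[float],
    doses_b: Sequence[float],
    interaction_delta: float = 0.0,
    n_replicates: int = 1,
    noise_sd: float = 0.0,
    seed=0,
    drug_a_name: str = "drug_a",
    drug_b_name: str = "drug_b",
) -> tuple[DoseResponseMatrix, dict]:
    """Checkerboard dose-response data from Hill curves plus a Bliss-scale
    interaction.

    Single-agent margins (dose 0 of the partner, prepended to each grid)
    follow fa(D) = 1/(1 + (Dm/D)^m); each combination cell is the Bliss
    expectation A + B - A x B plus ``interaction_delta``, clipped to
    [0, 1], plus optional Gaussian noise (re-clipped).  The truth ledger
    records the realized (pre-noise, post-clip) delta per interior cell and
    which cells were clipped.
    """
    dm_a, m_a = hill_a
    dm_b, m_b = hill_b
    if min(dm_a, m_a, dm_b, m_b) <= 0:
        raise ValueError("Hill parameters Dm and m must be positive")
    doses_a = np.concatenate([[0.0], np.asarray(doses_a, dtype=float)])
    doses_b = np.concatenate([[0.0], np.asarray(doses_b, dtype=float)])
    fa_a = hill_fraction_affected(doses_a, dm_a, m_a)
    fa_b = hill_fraction_affected(doses_b, dm_b, m_b)

    bliss = fa_a[:, None] + fa_b[None, :] - fa_a[:, None] * fa_b[None, :]
    raw = bliss + interaction_delta
    raw[0, :] = fa_b  # margins carry no interaction
    raw[:, 0] = fa_a
    clean = np.clip(raw, 0.0, 1.0)
    clipped = raw != clean

    rng = np.random.default_rng(seed)
    stack = np.repeat(clean[None, :, :], n_replicates, axis=0)
    if noise_sd > 0:
        stack = np.clip(stack + rng.normal(0.0, noise_sd, stack.shape), 0.0, 1.0)
    matrix = DoseResponseMatrix(
        drug_a_name=drug_a_name,
        drug_b_name=drug_b_name,
        doses_a=doses_a,
        doses_b=doses_b,
        effects=stack,
    )
    truth = {
        "hill_a": {"Dm": dm_a, "m": m_a},
        "hill_b": {"Dm": dm_b, "m": m_b},
        "interaction_delta": interaction_delta,
        "delta": clean - bliss,  # realized Bliss-scale delta per cell
        "clipped": clipped,
    }
    return matrix, truth
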