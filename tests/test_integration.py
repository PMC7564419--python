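"""Integration funnel: GE~CNV regression, overlap, FDR, signature, funnel."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from osfunnel.datatypes import AssociationRecord, CopyNumberMatrix, ExpressionMatrix
from osfunnel.integration import (
    SignatureTable,
    apply_funnel,
    correlate_ge_cnv,
    fold_change_vs_normal,
    overlap_fdr,
    replicated_overlap,
    risk_prevalence,
    triple_signature,
)


def _assoc(gene, p, direction, kind="GE~survival", beta=None):
    beta = beta if beta is not None else 0.5 * direction
    hr = float(np.exp(beta)) if kind != "GE~CNV" else None
    return AssociationRecord(gene=gene, kind=kind, beta=beta, se=0.1,
                             p_value=p, hazard_ratio=hr,
                             direction=int(np.sign(beta)))


def _matrices(x, y):
    """One-gene expression/copy-number pair over shared samples."""
    samples = [f"s{i}" for i in range(len(x))]
    e = ExpressionMatrix(pd.DataFrame([y], index=["g"], columns=samples))
    c = CopyNumberMatrix(pd.DataFrame([x], index=["g"], columns=samples))
    return e, c


class TestCorrelateGeCnv:
    def test_exact_linear_relation_recovered(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        e, c = _matrices(x, 2.0 * x + 1.0)
        rec = correlate_ge_cnv(e, c)[0]
        assert rec.beta == pytest.approx(2.0)
        assert rec.p_value < 1e-12
        assert rec.direction == 1

    def test_matches_closed_form_ols_on_five_points(self):
        x = np.array([1.8, 2.0, 2.4, 3.1, 3.9])
        y = np.array([5.0, 5.3, 5.1, 6.2, 6.8])
        e, c = _matrices(x, y)
        rec = correlate_ge_cnv(e, c)[0]
        # closed-form least squares and the slope t test, by hand
        xm, ym = x.mean(), y.mean()
        slope = ((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum()
        resid = y - (ym + slope * (x - xm))
        se = np.sqrt(resid @ resid / 3 / ((x - xm) ** 2).sum())
        p = 2 * stats.t.sf(abs(slope / se), 3)
        assert rec.beta == pytest.approx(slope, rel=1e-12)
        assert rec.se == pytest.approx(se, rel=1e-12)
        assert rec.p_value == pytest.approx(p, rel=1e-9)

    def test_independent_pairs_slope_within_three_se(self, rng):
        x = rng.uniform(1.5, 4.0, 200)
        y = rng.normal(5.0, 1.0, 200)
        e, c = _matrices(x, y)
        rec = correlate_ge_cnv(e, c)[0]
        assert abs(rec.beta) < 3 * rec.se

    def test_zero_variance_copy_number_flagged(self):
        e, c = _matrices(np.full(5, 2.0), np.arange(5.0))
        rec = correlate_ge_cnv(e, c)[0]
        assert not rec.estimable

    def test_too_few_shared_samples_rejected(self):
        e, c = _matrices(np.array([2.0, 3.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="3"):
            correlate_ge_cnv(e, c)


class TestReplicatedOverlap:
    def test_disjoint_universes_empty(self):
        a = [_assoc("g1", 0.01, 1)]
        b = [_assoc("g2", 0.01, 1)]
        assert replicated_overlap(a, b) == []

    def test_direction_mismatch_excluded(self):
        a = [_assoc("g1", 0.01, 1)]
        b = [_assoc("g1", 0.01, -1)]
        assert replicated_overlap(a, b) == []

    def test_enumerated_qualifying_genes(self):
        a = [_assoc("g1", 0.01, 1), _assoc("g2", 0.2, 1),
             _assoc("g3", 0.04, -1), _assoc("g4", 0.03, 1),
             _assoc("g5", 0.001, 1)]
        b = [_assoc("g1", 0.02, 1), _assoc("g2", 0.01, 1),
             _assoc("g3", 0.01, -1), _assoc("g4", 0.9, 1),
             _assoc("g5", 0.04, 1)]
        # significant in both with matching direction: g1, g3, g5
        assert replicated_overlap(a, b, alpha=0.05) == ["g1", "g3", "g5"]

    def test_monotone_in_alpha(self):
        a = [_assoc(f"g{i}", p, 1) for i, p in enumerate([0.001, 0.02, 0.04, 0.3])]
        b = [_assoc(f"g{i}", p, 1) for i, p in enumerate([0.03, 0.01, 0.06, 0.01])]
        small = set(replicated_overlap(a, b, alpha=0.02))
        large = set(replicated_overlap(a, b, alpha=0.10))
        assert small <= large


class TestOverlapFdr:
    def test_zero_alpha_gives_zero_fdr(self):
        assert overlap_fdr(1000, 0.0, 0.05, 2, 5) == 0.0

    def test_capped_at_one_when_expected_exceeds_observed(self):
        assert overlap_fdr(10000, 0.5, 0.5, 1, 1) == 1.0

    def test_reproduces_published_scale_replication_fdr(self):
        # 9,650 shared genes screened at 0.05 in two cohorts with matched
        # direction (2 levels), 71 replicated genes -> FDR about 17%
        fdr = overlap_fdr(9650, 0.05, 0.05, 2, 71)
        assert fdr == pytest.approx(0.17, abs=0.005)

    def test_zero_observed_rejected(self):
        with pytest.raises(ValueError):
            overlap_fdr(100, 0.05, 0.05, 2, 0)


class TestTripleSignature:
    @staticmethod
    def _tables(genes_spec):
        """genes_spec: gene -> (p_ge, d_ge, p_cnv, d_cnv, p_gc, d_gc)."""
        ge, cnv, gc = [], [], []
        for g, (p1, d1, p2, d2, p3, d3) in genes_spec.items():
            ge.append(_assoc(g, p1, d1))
            cnv.append(_assoc(g, p2, d2, kind="CNV~survival"))
            gc.append(_assoc(g, p3, d3, kind="GE~CNV"))
        return ge, cnv, gc

    def test_coherent_risk_genes_admitted_incoherent_reported(self):
        spec = {
            "gain_risk": (0.01, 1, 0.01, 1, 0.01, 1),
            "del_risk": (0.01, -1, 0.01, -1, 0.01, 1),
            "mixed": (0.01, 1, 0.01, -1, 0.01, 1),       # survival signs differ
            "anticorr": (0.01, 1, 0.01, 1, 0.01, -1),     # expression falls with CN
            "not_sig": (0.50, 1, 0.01, 1, 0.01, 1),
        }
        sig = triple_signature(*self._tables(spec), alpha=0.05)
        assert list(sig.table.index) == ["del_risk", "gain_risk"]
        assert sig.table.loc["gain_risk", "risk_class"] == "gain"
        assert sig.table.loc["del_risk", "risk_class"] == "deletion"
        assert sorted(sig.incoherent) == ["anticorr", "mixed"]

    def test_empty_when_any_input_empty(self):
        ge, cnv, gc = self._tables({"g": (0.01, 1, 0.01, 1, 0.01, 1)})
        sig = triple_signature(ge, cnv, [], alpha=0.05)
        assert sig.table.empty and sig.fdr is None

    def test_monotone_in_alpha(self):
        spec = {f"g{i}": (p, 1, p, 1, p, 1)
                for i, p in enumerate([0.001, 0.01, 0.04, 0.2])}
        tabs = self._tables(spec)
        small = set(triple_signature(*tabs, alpha=0.02).table.index)
        large = set(triple_signature(*tabs, alpha=0.05).table.index)
        assert small <= large

    def test_planted_gene_without_hazard_effect_excluded(self):
        # gain drives expression (GE~CNV significant) but survival arms are
        # null: the gene must not enter the signature
        from osfunnel.survival import genewise_screen
        from osfunnel.synthetic import (PlantedGene, SyntheticConfig,
                                        generate_cohort, make_annotations)

        cfg = SyntheticConfig(n_genes=44, n_patients=200, seed=6)
        gene = [a.symbol for a in make_annotations(cfg) if a.chromosome == "chr8"][0]
        cfg = SyntheticConfig(
            n_genes=44, n_patients=200, seed=6,
            planted_genes=(PlantedGene(gene, cnv_gain_prevalence=0.5,
                                       ge_cnv_slope=1.5,
                                       log_hazard_per_unit_expression=0.0),),
        )
        c = generate_cohort(cfg, subseed=1)
        ge, _ = genewise_screen(c.expression, c.clinical)
        cnv, _ = genewise_screen(c.cn_categorical, c.clinical, kind="CNV~survival")
        gc = correlate_ge_cnv(c.expression, c.cn_continuous)
        sig = triple_signature(ge, cnv, gc, alpha=0.05)
        assert gene not in sig.table.index
        rec = {r.gene: r for r in gc}[gene]
        assert rec.p_value < 1e-10  # the GE~CNV arm alone is highly significant

    def test_default_study_recovers_all_planted_genes(self):
        from osfunnel.survival import genewise_screen
        from osfunnel.synthetic import default_config, generate_study

        cfg = default_config(seed=17)
        study = generate_study(cfg)
        d = study.discovery
        ge, _ = genewise_screen(d.expression, d.clinical)
        cnv, _ = genewise_screen(d.cn_categorical, d.clinical, kind="CNV~survival")
        gc = correlate_ge_cnv(d.expression, d.cn_continuous)
        sig = triple_signature(ge, cnv, gc, alpha=0.05)
        planted = {p.symbol for p in cfg.planted_genes}
        assert planted <= set(sig.table.index)
        # chance entries stay near the chance-overlap expectation
        false_entries = set(sig.table.index) - planted
        assert len(false_entries) <= 3


class TestFoldChange:
    @staticmethod
    def _panels(tumor_vals, normal_vals, n_genes=1):
        genes = [f"g{i}" for i in range(n_genes)]
        t = ExpressionMatrix(pd.DataFrame(
            np.tile(tumor_vals, (n_genes, 1)), index=genes,
            columns=[f"t{i}" for i in range(len(tumor_vals))]))
        n = ExpressionMatrix(pd.DataFrame(
            np.tile(normal_vals, (n_genes, 1)), index=genes,
            columns=[f"n{i}" for i in range(len(normal_vals))]))
        return t, n

    def test_noiseless_fourfold_ratio(self):
        # log-scale shift of ln(4) is a 4-fold linear-scale change
        normal = np.array([5.0, 5.0, 5.0])
        tumor = normal + np.log(4.0)
        t, n = self._panels(tumor, normal)
        out = fold_change_vs_normal(t, n)
        assert out.loc["g0", "fold_change"] == pytest.approx(4.0)

    def test_identical_distributions_fold_one_p_uniform(self, rng):
        genes = 300
        t = ExpressionMatrix(pd.DataFrame(rng.normal(5, 1, (genes, 20)),
                                          index=[f"g{i}" for i in range(genes)],
                                          columns=[f"t{i}" for i in range(20)]))
        n = ExpressionMatrix(pd.DataFrame(rng.normal(5, 1, (genes, 20)),
                                          index=[f"g{i}" for i in range(genes)],
                                          columns=[f"n{i}" for i in range(20)]))
        out = fold_change_vs_normal(t, n)
        assert np.median(out["fold_change"]) == pytest.approx(1.0, abs=0.1)
        d = stats.kstest(out["wilcoxon_p"], "uniform").statistic
        assert d < 0.1

    def test_wilcoxon_p_matches_exhaustive_permutation_oracle(self):
        x = np.array([5.1, 6.3, 4.8, 7.0])
        y = np.array([4.2, 4.9, 5.5, 4.4])
        t, n = self._panels(x, y)
        p_impl = fold_change_vs_normal(t, n).loc["g0", "wilcoxon_p"]
        # enumerate all C(8,4) group assignments of the pooled sample and
        # build the exact null distribution of the rank sum
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        observed = ranks[:4].sum()
        stats_null = [ranks[list(idx)].sum() for idx in combinations(range(8), 4)]
        stats_null = np.array(stats_null)
        # two-sided: as or more extreme on either side of the mean rank sum
        mean = stats_null.mean()
        p_exact = np.mean(np.abs(stats_null - mean) >= abs(observed - mean) - 1e-12)
        assert p_impl == pytest.approx(p_exact, rel=1e-9)

    def test_bh_adjustment_monotone_and_not_below_raw(self, rng):
        genes = 50
        t = ExpressionMatrix(pd.DataFrame(rng.normal(5, 1, (genes, 8)),
                                          index=[f"g{i}" for i in range(genes)],
                                          columns=[f"t{i}" for i in range(8)]))
        n = ExpressionMatrix(pd.DataFrame(rng.normal(5.5, 1, (genes, 8)),
                                          index=[f"g{i}" for i in range(genes)],
                                          columns=[f"n{i}" for i in range(8)]))
        out = fold_change_vs_normal(t, n).sort_values("wilcoxon_p")
        assert (out["bh_adjusted_p"] >= out["wilcoxon_p"] - 1e-15).all()
        assert (np.diff(out["bh_adjusted_p"]) >= -1e-15).all()

    def test_single_sample_group_rejected(self):
        t, n = self._panels(np.array([5.0, 6.0]), np.array([4.0]))
        with pytest.raises(ValueError, match="2 samples"):
            fold_change_vs_normal(t, n)


class TestPrevalenceAndFunnel:
    @staticmethod
    def _cat(values):
        df = pd.DataFrame([values], index=["MYC"],
                          columns=[f"p{i}" for i in range(len(values))], dtype=float)
        return CopyNumberMatrix(df, categorical=True)

    def test_prevalence_counting(self):
        assert risk_prevalence(self._cat([1] * 10), "MYC") == 1.0
        assert risk_prevalence(self._cat([1] * 9 + [0]), "MYC") == 0.9
        assert risk_prevalence(self._cat([1, 0, -1, 0]), "MYC",
                               include_normal=True) == 0.75

    def test_prevalence_invariant_under_sample_permutation(self, rng):
        vals = rng.choice([-1, 0, 1], 30)
        p1 = risk_prevalence(self._cat(vals), "MYC")
        p2 = risk_prevalence(self._cat(vals[rng.permutation(30)]), "MYC")
        assert p1 == p2

    def test_absent_gene_rejected(self):
        with pytest.raises(KeyError):
            risk_prevalence(self._cat([1]), "TP53")

    @staticmethod
    def _signature(rows):
        table = pd.DataFrame(rows).set_index("gene")
        return SignatureTable(table=table, incoherent=[], fdr=0.01)

    def test_funnel_flags_and_threshold_and_ranking(self):
        sig = self._signature([
            {"gene": "A", "risk_class": "gain", "cnv_survival_p": 0.01},
            {"gene": "B", "risk_class": "gain", "cnv_survival_p": 0.001},
            {"gene": "C", "risk_class": "gain", "cnv_survival_p": 0.02},
            {"gene": "D", "risk_class": "gain", "cnv_survival_p": 0.03},
        ])
        flags = pd.DataFrame(
            {"targetable_network": [True, True, False, True],
             "inhibitor_available": [True, True, True, True],
             "model_available": [True, True, True, True]},
            index=["A", "B", "C", "D"])
        prevalence = pd.Series({"A": 0.95, "B": 0.92, "C": 0.99, "D": 0.89})
        out = apply_funnel(sig, flags, prevalence, prevalence_threshold=0.9)
        # C fails a flag; D fails the strict prevalence threshold (0.89 < 0.9)
        assert list(out.index) == ["B", "A"]  # ranked by CNV~survival p

    def test_funnel_requires_flag_columns(self):
        sig = self._signature([
            {"gene": "A", "risk_class": "gain", "cnv_survival_p": 0.01}])
        with pytest.raises(ValueError, match="missing"):
            apply_funnel(sig, pd.DataFrame(index=["A"]), pd.Series({"A": 1.0}))
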