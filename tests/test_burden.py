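"""Burden table construction and the covariate-adjusted logistic
enrichment model."""

import numpy as np
import pandas as pd
import pytest

import cnvgsa as c
from cnvgsa.cnv import CNVRecord, GeneIndex
from cnvgsa.simulate import GeneRecord


def _subjects(n_case, n_control, chips=("chipA",), studies=("study0",)):
    n = n_case + n_control
    return pd.DataFrame({
        "subject_id": [f"S{i}" for i in range(n)],
        "phenotype": [1] * n_case + [0] * n_control,
        "chip": [chips[i % len(chips)] for i in range(n)],
        "study": [studies[i % len(studies)] for i in range(n)],
    })


def _annotated(subject, length_kb, genes, chrom="chr1",
               cnv_type=c.DELETION):
    rec = CNVRecord(subject_id=subject, chrom=chrom, start=1,
                    end=length_kb * 1000, cnv_type=cnv_type, n_probes=20)
    return c.AnnotatedCNV(rec, frozenset(genes))


class TestBuildBurdenTable:
    def test_kb_sum_and_distinct_hits(self):
        subj = _subjects(1, 1)
        ann = [_annotated("S0", 150, {"G1", "G2"}),
               _annotated("S0", 250, {"G2", "G3"})]
        t = c.build_burden_table(subj, ann, {"G2"})
        row = t.set_index("subject_id").loc["S0"]
        assert row["total_cnv_kb"] == pytest.approx(400, rel=1e-3)
        assert row["set_hits"] == 1          # G2 counted once
        assert row["total_genes_hit"] == 3   # distinct union

    def test_cnv_free_subjects_zero_filled(self):
        t = c.build_burden_table(_subjects(2, 2), [], {"G1"})
        assert len(t) == 4
        assert (t[["set_hits", "total_cnv_kb", "total_genes_hit"]]
                == 0).all().all()

    def test_unknown_subject_strict_raises(self):
        ann = [_annotated("GHOST", 150, {"G1"})]
        with pytest.raises(KeyError, match="GHOST"):
            c.build_burden_table(_subjects(1, 1), ann, {"G1"})
        t = c.build_burden_table(_subjects(1, 1), ann, {"G1"}, strict=False)
        assert (t["set_hits"] == 0).all()

    def test_mean_genes_per_cnv_mode(self):
        subj = _subjects(1, 1)
        ann = [_annotated("S0", 150, {"G1", "G2"}),
               _annotated("S0", 250, {"G3"})]
        t = c.build_burden_table(subj, ann, set(),
                                 genes_per_cnv_mode="mean")
        assert t.set_index("subject_id").loc["S0", "mean_genes_per_cnv"] \
            == pytest.approx(1.5)

    def test_strata_count_columns_sum_to_all(self, annotated_planted):
        subjects, annotated, planted = annotated_planted
        t_all = c.build_burden_table(subjects, annotated, planted, "all")
        t_del = c.build_burden_table(subjects, annotated, planted,
                                     c.DELETION)
        t_dup = c.build_burden_table(subjects, annotated, planted,
                                     c.DUPLICATION)
        for col in ["total_cnv_kb"]:
            np.testing.assert_allclose(
                t_del[col] + t_dup[col], t_all[col], rtol=1e-9)


class TestBurdenModel:
    def test_matches_2x2_log_odds_ratio(self):
        # no covariate structure, binary exposure: the logistic slope is
        # the 2x2 log odds ratio (analytic oracle)
        a, b_, c_, d = 30, 70, 15, 85  # exposed cases/ctrl-noncases layout
        subj = _subjects(100, 100)
        ann = []
        k = 0
        for i in range(100):      # cases S0..S99
            if i < a:
                ann.append(_annotated(f"S{i}", 150, {"GSET"}))
        for i in range(100, 200):  # controls
            if i < 100 + c_:
                ann.append(_annotated(f"S{i}", 150, {"GSET"}))
        t = c.build_burden_table(subj, ann, {"GSET"})
        res = c.BurdenModel(t, covariates=()).fit()
        expected = np.log((a / b_) / (c_ / d))
        assert res.beta == pytest.approx(expected, abs=1e-6)
        assert np.sign(res.z) == np.sign(res.beta)
        assert res.p == pytest.approx(
            2 * __import__("scipy.stats", fromlist=["norm"]).norm.sf(
                abs(res.z)))

    def test_wald_close_to_lr_at_moderate_n(self):
        subj = _subjects(150, 150)
        ann = [_annotated(f"S{i}", 150, {"GSET"}) for i in range(40)]
        ann += [_annotated(f"S{i}", 150, {"GSET"})
                for i in range(150, 178)]
        t = c.build_burden_table(subj, ann, {"GSET"})
        wald = c.BurdenModel(t, covariates=()).fit(test="wald")
        lr = c.BurdenModel(t, covariates=()).fit(test="lr")
        assert lr.p == pytest.approx(wald.p, rel=0.10)

    def test_constant_exposure_flagged(self):
        t = c.build_burden_table(_subjects(5, 5), [], {"G1"})
        res = c.BurdenModel(t).fit()
        assert not res.estimable
        assert "set_hits" in res.flag
        assert np.isnan(res.p)

    def test_separation_flagged_not_nan_silent(self):
        # exposure perfectly predicts phenotype
        subj = _subjects(20, 20)
        ann = [_annotated(f"S{i}", 150, {"GSET"}) for i in range(20)]
        t = c.build_burden_table(subj, ann, {"GSET"})
        res = c.BurdenModel(t, covariates=()).fit()
        assert (not res.estimable) or res.flag  # flagged, never silent

    def test_single_level_covariates_dropped(self):
        subj = _subjects(50, 50)  # one chip, one study
        ann = [_annotated(f"S{i}", 150, {"GSET"}) for i in range(15)]
        ann += [_annotated(f"S{i}", 150, {"GSET"})
                for i in range(50, 58)]
        table = c.build_burden_table(subj, ann, {"GSET"})
        model = c.BurdenModel(table, covariates=("chip", "study"))
        assert not any(n.startswith(("chip[", "study["))
                       for n in model.exog_names)
        assert model.exog_names == ["const", "set_hits"]
        assert model.fit().estimable

    def test_summary_contains_estimates(self, annotated_planted):
        subjects, annotated, planted = annotated_planted
        model = c.BurdenModel.from_components(subjects, annotated, planted,
                                              stratum="all")
        res = model.fit()
        s = res.summary()
        assert "set_hits" in s and "two-tailed" in s
        assert f"{model.n_case} cases" in s

    def test_planted_effect_recovered(self, annotated_planted):
        subjects, annotated, planted = annotated_planted
        res = c.BurdenModel.from_components(subjects, annotated,
                                            planted).fit()
        # log(2) planted; single cohort, so allow generous sampling slack
        assert res.beta == pytest.approx(np.log(2), abs=3 * res.se)
        assert res.z > 0


class TestBonferroni:
    @pytest.mark.parametrize("p, m, expected", [
        (0.01, 3, 0.03), (0.5, 3, 1.0), (0.2, 1, 0.2)])
    def test_values(self, p, m, expected):
        assert c.bonferroni(p, m) == pytest.approx(expected)

    def test_invalid_family(self):
        with pytest.raises(ValueError):
            c.bonferroni(0.05, 0)

    def test_applied_through_result(self):
        t = c.build_burden_table(
            _subjects(100, 100),
            [_annotated(f"S{i}", 150, {"G"}) for i in range(30)]
            + [_annotated(f"S{i}", 150, {"G"}) for i in range(100, 110)],
            {"G"})
        r = c.BurdenModel(t, covariates=()).fit().as_result(m=3)
        assert r.p_corrected == pytest.approx(min(1.0, 3 * r.p))


class TestPerGeneEnrichment:
    def test_case_only_gene_positive_direction(self):
        subj = _subjects(100, 100)
        ann = [_annotated(f"S{i}", 150, {"GA"}) for i in range(8)]
        gs = c.GeneSet("t", 0.05, frozenset({"GA", "GB"}))
        df = c.per_gene_enrichment(subj, ann, gs, covariates=())
        row = df.set_index("gene").loc["GA"]
        # 8 case carriers, 0 control carriers: enrichment must be positive,
        # agreeing in direction with the 2x2 odds ratio (infinite here,
        # so the fit is either positive or flagged as separated)
        assert (row["estimable"] and row["beta"] > 0) or row["flag"]
        assert row["n_carriers"] == 8

    def test_unhit_gene_non_estimable(self):
        subj = _subjects(10, 10)
        gs = c.GeneSet("t", 0.05, frozenset({"GNOBODY"}))
        df = c.per_gene_enrichment(subj, [], gs, covariates=())
        assert not df.iloc[0]["estimable"]

    def test_direction_matches_contingency_table(self):
        rng = np.random.default_rng(9)
        subj = _subjects(120, 120)
        carriers_case = [f"S{i}" for i in range(30)]
        carriers_ctrl = [f"S{i}" for i in range(120, 132)]
        ann = [_annotated(s, 150, {"GA"})
               for s in carriers_case + carriers_ctrl]
        gs = c.GeneSet("t", 0.05, frozenset({"GA"}))
        df = c.per_gene_enrichment(subj, ann, gs, covariates=())
        beta = df.iloc[0]["beta"]
        oracle = np.log((30 / 90) / (12 / 108))
        assert beta == pytest.approx(oracle, abs=1e-6)
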