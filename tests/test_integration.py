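"""Cross-platform correlation, timing delay, driver calling, clone checks."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import t as tdist, pearsonr

from omicspatterns import (
    OmicsMatrix,
    SimConfig,
    call_epigenetic_drivers,
    clone_validation,
    classify_patterns,
    generate_clone_panel,
    generate_time_course,
    pattern_correlation,
    pattern_markers,
    select_promoter_probes,
    timing_delay,
    fit,
    uncertainty_for,
)
from omicspatterns.pattern_analysis import PatternLabel


class TestPatternCorrelation:
    def test_identical_and_reflected_rows(self):
        cols = [f"s{i}" for i in range(6)]
        row = np.array([0.1, 0.4, 0.2, 0.9, 0.5, 0.3])
        Pe = pd.DataFrame([row], index=["E1"], columns=cols)
        Pm = pd.DataFrame([row, 2 * row.mean() - row], index=["M1", "M2"], columns=cols)
        C = pattern_correlation(Pe, Pm)
        assert C.loc["E1", "M1"] == pytest.approx(1.0)
        assert C.loc["E1", "M2"] == pytest.approx(-1.0)

    def test_constant_row_reported_missing(self):
        cols = [f"s{i}" for i in range(5)]
        Pe = pd.DataFrame([[1, 1, 1, 1, 1]], index=["E1"], columns=cols, dtype=float)
        Pm = pd.DataFrame([[0.1, 0.5, 0.3, 0.7, 0.2]], index=["M1"], columns=cols)
        assert np.isnan(pattern_correlation(Pe, Pm).loc["E1", "M1"])

    def test_too_few_shared_samples(self):
        cols = ["a", "b"]
        P = pd.DataFrame([[1.0, 2.0]], columns=cols)
        with pytest.raises(ValueError):
            pattern_correlation(P, P)

    def test_resistance_patterns_anticorrelated_with_demethylation(self):
        """Planted expression resistance vs methylation patterns, 10 seeds."""
        for seed in range(10):
            _, _, _, truth = generate_time_course(SimConfig(n_genes=60, seed=seed))
            C = pattern_correlation(truth.P_true["expression"], truth.P_true["methylation"])
            labels_e = truth.pattern_labels["expression"]
            labels_m = truth.pattern_labels["methylation"]
            res = f"EP{labels_e.index('resistance') + 1}"
            dem = f"MP{labels_m.index('demethylation') + 1}"
            hyp = f"MP{labels_m.index('hypermethylation') + 1}"
            assert C.loc[res, hyp] > 0.8
            assert C.loc[res, dem] < -0.8

    def test_symmetric_under_platform_swap(self):
        rng = np.random.default_rng(0)
        cols = [f"s{i}" for i in range(8)]
        Pe = pd.DataFrame(rng.uniform(0, 1, (2, 8)), index=["E1", "E2"], columns=cols)
        Pm = pd.DataFrame(rng.uniform(0, 1, (3, 8)), index=["M1", "M2", "M3"], columns=cols)
        C = pattern_correlation(Pe, Pm)
        Ct = pattern_correlation(Pm, Pe)
        pd.testing.assert_frame_equal(C, Ct.T)


class TestTimingDelay:
    def test_delay_arithmetic(self):
        le = [PatternLabel("E1", "immediate", 1, 1)]
        lm = [PatternLabel("M1", "resistance", 4, 1)]
        tab = timing_delay(le, lm)
        assert tab.loc[0, "delay"] == 3 and tab.loc[0, "delay_min"] == 3

    def test_generator_defaults_delay(self):
        _, _, _, truth = generate_time_course(SimConfig(n_genes=50, seed=0))
        expr, meth = truth.P_true["expression"], truth.P_true["methylation"]
        meta = expr.columns  # samples shared
        cfg = SimConfig(n_genes=50, seed=0)
        e, m, _, _ = generate_time_course(cfg)
        le = classify_patterns(expr, e.samples)
        lm = classify_patterns(meth, m.samples)
        tab = timing_delay(le, lm)
        sub = tab[tab["expr_pattern"] == "EP1"]  # immediate, separation 1
        assert set(sub["delay"]) == {4}
        sub2 = tab[tab["expr_pattern"] == "EP2"]  # resistance, separation 4
        assert set(sub2["delay"]) == {1}

    def test_no_separating_meth_pattern_missing(self):
        le = [PatternLabel("E1", "immediate", 1, 1)]
        lm = [PatternLabel("M1", "control-drift", None, 0)]
        tab = timing_delay(le, lm)
        assert tab.empty


def _make_omics(values, meta, platform):
    return OmicsMatrix(values=values, samples=meta, platform=platform)


class TestDriverCalling:
    @pytest.fixture(scope="class")
    def pipeline_run(self):
        cfg = SimConfig(n_genes=800, seed=3)
        e, m, ann, truth = generate_time_course(cfg)
        meth_g = select_promoter_probes(m, ann)
        Fm = fit(meth_g, uncertainty_for(meth_g), 3, n_restarts=2, seed=3)
        lm = classify_patterns(Fm, meth_g.samples)
        res_pats = [l.pattern for l in lm if l.label in ("resistance", "repression")]
        markers = pattern_markers(Fm.A)
        return e, meth_g, markers, res_pats, truth

    def test_positive_correlation_never_called(self, pipeline_run):
        e, meth_g, markers, res_pats, truth = pipeline_run
        tab = call_epigenetic_drivers(e, meth_g, markers, res_pats)
        assert not (tab.loc[tab["r"] > 0, "called"]).any()

    def test_planted_drivers_recovered(self, pipeline_run):
        e, meth_g, markers, res_pats, truth = pipeline_run
        tab = call_epigenetic_drivers(e, meth_g, markers, res_pats)
        called = set(tab.index[tab["called"]])
        planted = set(truth.driver_genes)
        assert len(called & planted) / len(planted) >= 0.9
        assert len(called - planted) / max(len(called), 1) <= 0.1

    def test_label_shuffle_collapses_recall(self, pipeline_run):
        e, meth_g, markers, res_pats, truth = pipeline_run
        rng = np.random.default_rng(0)
        shuffled = e.values.copy()
        shuffled.columns = list(rng.permutation(list(e.values.columns)))
        e_shuf = _make_omics(shuffled[list(e.values.columns)], e.samples, "expression")
        tab = call_epigenetic_drivers(e_shuf, meth_g, markers, res_pats)
        called = set(tab.index[tab["called"]])
        assert len(called & set(truth.driver_genes)) <= 1

    def test_affine_rescaling_of_expression_leaves_r_unchanged(self, pipeline_run):
        e, meth_g, markers, res_pats, _ = pipeline_run
        tab = call_epigenetic_drivers(e, meth_g, markers, res_pats)
        e2 = _make_omics(e.values * 3.0 + 1.0, e.samples, "expression")
        tab2 = call_epigenetic_drivers(e2, meth_g, markers, res_pats)
        pd.testing.assert_series_equal(tab["r"], tab2["r"], atol=1e-12, rtol=0)

    def test_correlation_p_matches_t_distribution_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=22)
        y = -0.7 * x + rng.normal(size=22) * 0.8
        res = pearsonr(x, y)
        r = res.statistic
        t = r * np.sqrt(20) / np.sqrt(1 - r * r)
        p_oracle = 2 * tdist.sf(abs(t), df=20)
        assert res.pvalue == pytest.approx(p_oracle, rel=1e-10)


class TestCloneValidation:
    @pytest.fixture(scope="class")
    def panel(self):
        cfg = SimConfig(n_genes=300, seed=5)
        ce, cm, ptruth = generate_clone_panel(cfg, n_clones=6)
        drivers = pd.DataFrame(
            {"meth_pattern": "MP2", "r": -0.9, "p": 1e-6, "q": 1e-5, "called": True},
            index=pd.Index(ptruth["driver_genes"], name="gene"),
        )
        return drivers, ce, cm, ptruth

    def test_planted_drivers_all_validated(self, panel):
        drivers, ce, cm, ptruth = panel
        out = clone_validation(drivers, ce, cm, "parental")
        assert out["clone_validated"].all()

    def test_demethylated_but_not_overexpressed_fails(self, panel):
        drivers, ce, cm, ptruth = panel
        gene = ptruth["driver_genes"][0]
        ce2 = ce.values.copy()
        ce2.loc[gene, ptruth["designated_clone"]] = ce2.loc[gene, "parental"]
        out = clone_validation(drivers, _make_omics(ce2, ce.samples, "expression"),
                               cm, "parental")
        assert not out.loc[gene, "clone_validated"]

    def test_parental_unmethylated_gene_not_validated(self, panel):
        drivers, ce, cm, ptruth = panel
        gene = ptruth["driver_genes"][0]
        cm2 = cm.values.copy()
        cm2.loc[gene, "parental"] = 0.05
        out = clone_validation(drivers, ce, _make_omics(cm2, cm.samples, "methylation"),
                               "parental")
        assert not out.loc[gene, "clone_validated"]

    def test_inverted_thresholds_rejected(self, panel):
        drivers, ce, cm, _ = panel
        with pytest.raises(ValueError):
            clone_validation(drivers, ce, cm, "parental", unmeth_thr=0.5, meth_thr=0.3)
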