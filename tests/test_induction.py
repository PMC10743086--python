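"""Induction statistics: grouping, Dunnett-vs-control, the 20%-increase rule."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mdr_hcs as m
from mdr_hcs.induction import PercentGroups


def groups_of(control, **treated):
    return PercentGroups(control=control, treated={float(k[1:]): v for k, v in treated.items()})


def call_for(control_mean, treated_mean, p, threshold=0.2, alpha=0.05):
    """Run induction_call on a synthetic one-concentration series with a
    forced adjusted p (variance-free group construction is impossible, so the
    Dunnett result is assembled directly)."""
    g = PercentGroups(control=[control_mean] * 4, treated={1e-6: [treated_mean] * 4})
    dn = m.induction.DunnettResult([1e-6], np.array([0.0]), np.array([p]), df=6)
    cfg = m.AnalysisConfig(induction_threshold=threshold, alpha=alpha)
    return m.induction_call(g, dn, cfg).call


class TestGroupPercentages:
    def test_sem_hand_arithmetic(self):
        g = groups_of([10.0, 12.0, 8.0, 10.0])
        assert g.mean() == pytest.approx(10.0)
        assert g.sem() == pytest.approx(np.std([10, 12, 8, 10], ddof=1) / 2, abs=1e-9)
        assert g.sem() == pytest.approx(0.816, abs=0.001)

    def test_identical_controls_zero_sem(self):
        g = groups_of([10.0] * 4)
        assert g.mean() == 10.0
        assert g.sem() == 0.0

    def test_grouping_from_layout(self, tmp_path):
        from conftest import make_layout_csv

        layout = m.parse_layout(make_layout_csv(tmp_path / "l.csv", n_replicates=4))
        summaries = {}
        rng = np.random.default_rng(0)
        for w in layout.wells:
            pos = int(rng.integers(5, 15))
            summaries[w.well_id] = m.WellSummary(w.well_id, 100, pos, 60 - pos, 5, 35)
        g = m.group_percentages(summaries, layout, "co", "etoposide", "cancer")
        assert len(g.control) == 4
        assert list(g.treated) == sorted(g.treated)
        assert all(len(v) == 4 for v in g.treated.values())

    def test_absent_population_excluded_with_warning(self, tmp_path):
        from conftest import make_layout_csv

        layout = m.parse_layout(make_layout_csv(tmp_path / "l.csv"))
        summaries = {}
        for i, w in enumerate(layout.wells):
            if i == 0:  # control well with no stromal cells at all
                summaries[w.well_id] = m.WellSummary(w.well_id, 50, 20, 30, 0, 0)
            else:
                summaries[w.well_id] = m.WellSummary(w.well_id, 50, 20, 20, 5, 5)
        with pytest.warns(UserWarning, match="no stromal"):
            g = m.group_percentages(summaries, layout, "co", "etoposide", "stromal")
        assert len(g.control) == 3


class TestDunnett:
    def test_k1_equals_pooled_t(self):
        """Single comparison: adjusted p is the ordinary pooled-t p-value."""
        a, b = [14.0, 15.0, 13.0, 12.0], [10.0, 12.0, 8.0, 10.0]
        d = m.dunnett_vs_control(groups_of(b, c1=a))
        _, p = stats.ttest_ind(a, b, equal_var=True)
        assert d.pvalues[0] == pytest.approx(p, abs=1e-6)

    def test_identical_means_p_near_one(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, 4)
        g = groups_of(list(base), c1=list(base), c2=list(base))
        d = m.dunnett_vs_control(g, rng=0)
        assert np.all(d.pvalues > 0.99)

    def test_reproducible_to_3_decimals_at_fixed_seed(self):
        rng = np.random.default_rng(2)
        g = groups_of(list(rng.normal(10, 2, 4)),
                      **{f"c{i}": list(rng.normal(10, 2, 4)) for i in range(1, 6)})
        p1 = m.dunnett_vs_control(g, rng=7).pvalues
        p2 = m.dunnett_vs_control(g, rng=7).pvalues
        assert np.allclose(p1, p2, atol=5e-4)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            m.dunnett_vs_control(groups_of([10.0], c1=[11.0, 12.0]))

    def test_zero_variance_degenerate(self):
        d = m.dunnett_vs_control(groups_of([10.0] * 4, c1=[12.0] * 4, c2=[10.0] * 4))
        assert d.degenerate is True
        assert d.pvalues[0] == 0.0 and d.pvalues[1] == 1.0

    def test_multiplicity_never_decreases_p(self):
        """Adding treated groups never lowers an existing comparison's p."""
        rng = np.random.default_rng(3)
        ctrl = list(rng.normal(10, 2, 4))
        t1 = list(rng.normal(13, 2, 4))
        extra = {f"c{i}": list(rng.normal(10, 2, 4)) for i in range(2, 6)}
        p_alone = m.dunnett_vs_control(groups_of(ctrl, c1=t1), rng=0).pvalues[0]
        p_family = m.dunnett_vs_control(groups_of(ctrl, c1=t1, **extra), rng=0).pvalues[0]
        assert p_family >= p_alone - 5e-3  # QMC jitter allowance


class TestInductionCall:
    def test_significant_and_relevant_is_increase(self):
        assert call_for(10.0, 13.0, p=0.01) == "increase"

    def test_not_significant_is_no_change(self):
        assert call_for(10.0, 13.0, p=0.20) == "no change"

    def test_below_relevance_threshold_is_no_change(self):
        assert call_for(10.0, 11.5, p=0.001) == "no change"

    def test_decrease_never_increase(self):
        assert call_for(10.0, 5.0, p=0.0001) == "no change"

    def test_huge_threshold_always_no_change(self):
        assert call_for(10.0, 15.0, p=0.0001, threshold=0.999) == "no change"

    def test_tiny_threshold_reduces_to_significance(self):
        assert call_for(10.0, 10.5, p=0.001, threshold=1e-9) == "increase"
        assert call_for(10.0, 10.5, p=0.50, threshold=1e-9) == "no change"

    def test_relative_metric_zero_control_errors(self):
        g = PercentGroups(control=[0.0] * 4, treated={1e-6: [5.0] * 4})
        dn = m.induction.DunnettResult([1e-6], np.array([0.0]), np.array([0.01]), df=6)
        with pytest.raises(ValueError, match="absolute_points"):
            m.induction_call(g, dn, m.AnalysisConfig())

    def test_absolute_points_metric(self):
        g = PercentGroups(control=[10.0, 11, 9, 10], treated={1e-6: [40.0, 41, 39, 40]})
        dn = m.induction.DunnettResult([1e-6], np.array([0.0]), np.array([0.001]), df=6)
        cfg = m.AnalysisConfig(induction_threshold=0.20, induction_metric="absolute_points")
        res = m.induction_call(g, dn, cfg)  # +30 points >= 20 points
        assert res.call == "increase"

    def test_concentration_order_invariance(self):
        rng = np.random.default_rng(4)
        vals = {c: list(rng.normal(10, 1, 4)) for c in (1e-6, 5e-6, 2e-6)}
        ctrl = list(rng.normal(10, 1, 4))
        g1 = PercentGroups(control=ctrl, treated=vals)
        g2 = PercentGroups(control=ctrl, treated=dict(reversed(list(vals.items()))))
        d1 = m.dunnett_vs_control(g1, rng=0)
        d2 = m.dunnett_vs_control(g2, rng=0)
        cfg = m.AnalysisConfig()
        r1 = m.induction_call(g1, d1, cfg)
        r2 = m.induction_call(g2, d2, cfg)
        assert r1.call == r2.call
        assert list(r1.table["concentration"]) == list(r2.table["concentration"])


class TestCallMatrix:
    @staticmethod
    def result(marker="ABCB1", culture="co", pop="cancer", drug="x", call="no change"):
        return m.InductionResult(
            marker=marker, culture=culture, population=pop, drug=drug,
            table=pd.DataFrame({"concentration": [1e-6], "n": [4], "mean_pct": [10.0],
                                "sem": [0.5], "p_adj": [0.5], "increase": [0.0],
                                "significant": [False], "relevant": [False]}),
            call=call, control_mean=10.0, control_sem=0.5, n_control=4,
        )

    def test_empty_input_empty_table(self):
        assert m.call_matrix([]).empty

    def test_matrix_shape_and_values(self):
        results = [self.result(drug=d, call=c)
                   for d, c in [("cisplatin", "increase"), ("etoposide", "no change")]]
        wide = m.call_matrix(results)
        assert wide.loc[("ABCB1", "co", "cancer"), "cisplatin"] == "increase"
        assert wide.loc[("ABCB1", "co", "cancer"), "etoposide"] == "no change"

    def test_duplicate_cell_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            m.call_matrix([self.result(), self.result()])


class TestTwowayAnova:
    def test_diagnostic_table(self, tmp_path):
        from conftest import make_layout_csv

        layout = m.parse_layout(make_layout_csv(tmp_path / "l.csv", n_replicates=4))
        rng = np.random.default_rng(5)
        summaries = {}
        for w in layout.wells:
            pos = int(rng.integers(5, 15))
            summaries[w.well_id] = m.WellSummary(w.well_id, 100, pos, 60 - pos, 5, 35)
        tab = m.twoway_anova(summaries, layout, "co", "etoposide")
        assert "C(population)" in tab.index
        assert "C(population):C(concentration)" in tab.index
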