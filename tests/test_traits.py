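"""Asat ANOVA, monthly contrasts, trait LRT, weighted means, percent change."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from herbphys.lmm import loglik_at, marginal_covariance
from herbphys.simulate import TraitScenario, simulate_asat_table, simulate_trait_table
from herbphys.traits import (
    TRAIT_PANEL,
    asat_anova,
    headline_percentages,
    inverse_variance_mean,
    monthly_contrasts,
    percent_change,
    table2_report,
    trait_lrt,
    weighted_group_mean,
)


class TestWeightedGroupMean:
    def test_hand_arithmetic(self):
        m, _ = weighted_group_mean([10.0, 20.0], [1.0, 4.0])
        assert m == pytest.approx(12.0)  # (10/1 + 20/4) / (1 + 1/4)

    def test_equal_ses_give_arithmetic_mean(self, rng):
        v = rng.normal(5, 2, size=12)
        m, _ = weighted_group_mean(v, np.full(12, 0.7))
        assert m == pytest.approx(float(np.mean(v)))

    def test_single_value_returns_itself(self):
        assert weighted_group_mean([3.2], [0.4]) == (3.2, 0.4)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            weighted_group_mean([1.0, 2.0], [0.5, 0.0])

    def test_inverse_variance_alternative_differs(self):
        m1, _ = weighted_group_mean([10.0, 20.0], [1.0, 4.0])
        m2, _ = inverse_variance_mean([10.0, 20.0], [1.0, 4.0])
        assert m2 == pytest.approx((10 + 20 / 16) / (1 + 1 / 16))
        assert m1 != pytest.approx(m2)


class TestPercentChange:
    @pytest.mark.parametrize("new, base, expected", [
        (9.40, 6.26, 50), (350, 674, -48), (674, 350, 93),
        (6.66, 4.70, 42), (211, 314, -33), (4.99, 6.78, -26),
        (643.9, 393.3, 64), (15.63, 52.03, -70), (5.0, 5.0, 0),
    ])
    def test_reported_percentages_from_group_means(self, new, base, expected):
        assert percent_change(new, base).rounded == expected

    def test_half_away_from_zero_rounding(self):
        assert percent_change(100.5, 100.0).rounded == 1  # 0.5 -> 1
        assert percent_change(99.5, 100.0).rounded == -1  # -0.5 -> -1

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_change(1.0, 0.0)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0.1, 1e4), st.floats(0.1, 1e4))
    def test_forward_backward_reciprocity(self, a, b):
        p1 = percent_change(a, b).value
        p2 = percent_change(b, a).value
        assert (1 + p1 / 100) * (1 + p2 / 100) == pytest.approx(1.0, rel=1e-9)

    def test_headline_list_covers_all_reported_values(self):
        percents = [h["percent"] for h in headline_percentages()]
        assert percents == [50, -48, 93, 42, -33, -26, 64, -70]


class TestAsatAnova:
    def test_residual_df_accounting(self):
        # cell-means parameterization: df_resid = n - (#treatments x #months)
        cells = {(m, t): 5.0 for m in range(4, 9) for t in ("fenced", "unfenced")}
        df = simulate_asat_table(cells, n_per_cell=24, seed=0)
        res = asat_anova(df, log_transform="never")
        assert res.df_resid == len(df) - 10

    def test_single_month_reduces_to_two_sample(self):
        cells = {(6, "fenced"): 4.0, (6, "unfenced"): 6.0}
        df = simulate_asat_table(cells, n_per_cell=15, seed=1)
        with pytest.warns(UserWarning, match="single month"):
            res = asat_anova(df, log_transform="never")
        cons = monthly_contrasts(res)
        assert len(cons) == 1
        assert cons[0].p_value < 0.01

    def test_log_transform_triggered_by_heteroscedasticity(self, rng):
        rows = []
        for m, scale in ((5, 1.0), (6, 8.0)):
            for t in ("fenced", "unfenced"):
                for i in range(30):
                    rows.append({"treatment": t, "month": m,
                                 "a_net": float(scale * rng.lognormal(1.0, 0.6))})
        res = asat_anova(pd.DataFrame(rows), log_transform="auto")
        assert res.log_transformed


class TestMonthlyContrasts:
    def test_identical_groups_give_zero_t(self):
        rows = []
        for t in ("fenced", "unfenced"):
            for v in (4.0, 5.0, 6.0, 7.0):
                rows.append({"treatment": t, "month": 6, "a_net": v})
            for v in (3.0, 5.0, 8.0):
                rows.append({"treatment": t, "month": 7, "a_net": v})
        res = asat_anova(pd.DataFrame(rows), log_transform="never")
        cons = monthly_contrasts(res)
        assert all(c.t_statistic == pytest.approx(0.0, abs=1e-12) for c in cons)

    def test_missing_treatment_flagged_without_test(self):
        rows = ([{"treatment": "fenced", "month": 5, "a_net": v} for v in (4, 5, 6)]
                + [{"treatment": t, "month": 6, "a_net": v}
                   for t in ("fenced", "unfenced") for v in (4.0, 5.5, 6.0)])
        res = asat_anova(pd.DataFrame(rows), log_transform="never")
        cons = {c.label: c for c in monthly_contrasts(res)}
        assert "treatment_missing" in cons["5"].flags
        assert not cons["6"].flags

    def test_effect_in_june_only_detected_there(self):
        cells = {(m, t): 5.0 for m in (4, 5, 6, 7) for t in ("fenced", "unfenced")}
        cells[(6, "unfenced")] = 8.0  # injected June effect
        df = simulate_asat_table(cells, n_per_cell=20, sd_residual=1.0, seed=3)
        res = asat_anova(df, log_transform="never")
        cons = {c.label: c for c in monthly_contrasts(res)}
        assert cons["6"].p_value < 0.001
        assert cons["6"].estimate > 0
        others = [cons[str(m)].p_value for m in (4, 5, 7)]
        assert min(others) > 0.01

    def test_bonferroni_inflates_p(self):
        cells = {(m, t): 5.0 for m in (5, 6) for t in ("fenced", "unfenced")}
        df = simulate_asat_table(cells, n_per_cell=10, seed=4)
        res = asat_anova(df, log_transform="never")
        raw = monthly_contrasts(res)
        adj = monthly_contrasts(res, adjust="bonferroni")
        for r, a in zip(raw, adj):
            assert a.p_value == pytest.approx(min(1.0, 2 * r.p_value))


@pytest.fixture(scope="module")
def sla_data():
    return simulate_trait_table(TraitScenario(seed=77)).frame


class TestTraitLrt:
    def test_strong_effect_detected(self, sla_data):
        comp = trait_lrt(sla_data, trait="sla", species="Alliaria")
        assert comp.chi_sq > 10
        assert comp.p_value < 0.001
        assert comp.fenced_mean > comp.unfenced_mean

    def test_chi_sq_equals_twice_delta_loglik_by_direct_evaluation(self, sla_data):
        """Independent likelihood evaluation at both optima reproduces chi^2."""
        comp = trait_lrt(sla_data)
        df = sla_data.reset_index(drop=True)
        y = df["value"].to_numpy(float)
        groups = {"plant_id": df["plant_id"].to_numpy(),
                  "date_id": df["date_id"].to_numpy()}
        fenced = (df["treatment"] == "fenced").to_numpy(float)
        lls = []
        for fit, X in ((comp.full_fit, np.column_stack([np.ones(len(df)), fenced])),
                       (comp.reduced_fit, np.ones((len(df), 1)))):
            V = marginal_covariance(fit, groups)
            lls.append(loglik_at(y, X, V, fit.beta))
        assert comp.chi_sq == pytest.approx(2 * (lls[0] - lls[1]), abs=1e-6)
        assert lls[0] == pytest.approx(comp.full_fit.loglik, abs=1e-6)

    def test_constant_weights_match_unweighted_path(self, sla_data):
        unweighted = trait_lrt(sla_data)
        weighted = trait_lrt(sla_data.assign(se=2.5), weights_col="se")
        assert weighted.weighting == "inverse_se"
        assert weighted.chi_sq == pytest.approx(unweighted.chi_sq, abs=1e-4)

    def test_single_treatment_rejected(self, sla_data):
        with pytest.raises(ValueError):
            trait_lrt(sla_data[sla_data.treatment == "fenced"])


class TestTable2Report:
    def _panel_data(self, seed=0):
        data = {}
        for i, trait in enumerate(TRAIT_PANEL):
            frame = simulate_trait_table(
                TraitScenario(seed=seed + i,
                              trait_mean={"unfenced": 10.0, "fenced": 14.0},
                              sd_individual=1.0, sd_date=0.5, sd_residual=1.0,
                              n_individuals={"unfenced": 12, "fenced": 12},
                              leaves_per_individual=1)).frame
            data[trait] = frame
        return data

    def test_full_panel_has_nine_rows(self):
        report = table2_report(self._panel_data(), species="Alliaria")
        assert len(report) == len(TRAIT_PANEL) == 9
        assert report["chi_sq"].notna().all()

    def test_missing_panel_rendered_na(self):
        data = self._panel_data()
        data["leaf_area"] = None
        sub = data["v_cmax"]
        data["v_cmax"] = sub[sub.treatment == "fenced"]  # one-treatment A/Ci
        report = table2_report(data, species="Trillium").set_index("trait")
        assert report.loc["leaf_area", "signif"] == "NA"
        assert np.isnan(report.loc["v_cmax", "chi_sq"])
        assert not np.isnan(report.loc["v_cmax", "fenced_mean"])
        assert np.isnan(report.loc["v_cmax", "unfenced_mean"])

    def test_report_is_deterministic_in_its_inputs(self):
        data = self._panel_data()
        r1 = table2_report(data, species="Alliaria").to_csv(index=False)
        r2 = table2_report(data, species="Alliaria").to_csv(index=False)
        assert r1 == r2
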