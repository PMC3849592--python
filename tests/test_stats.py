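"""Statistics tests: contrasts, trends, partial correlation, demographics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fiberox import stats as fx


def make_summaries(rng, n_control=12, n_pad=16, effect=0.0):
    rows = []
    for i in range(n_control + n_pad):
        group = "control" if i < n_control else "pad"
        rows.append({
            "patient_id": f"S{i:02d}", "group": group,
            "fontaine_stage": int(rng.integers(2, 5)) if group == "pad" else None,
            "abi": float(rng.uniform(0.1, 0.8)) if group == "pad"
            else float(rng.uniform(0.95, 1.3)),
            "cad": int(rng.random() < 0.5), "htn": int(rng.random() < 0.5),
            "n_fibers": 500,
            "mean_carbonyl_gsu": float(rng.normal(500 + effect * (group == "pad"),
                                                  50)),
            "mean_hne_gsu": float(rng.normal(300, 40)),
            "mean_csa_um2": float(rng.normal(5000, 400)),
        })
    return pd.DataFrame(rows)


class TestPercentDifference:
    @pytest.mark.parametrize("control,pad,convention,expected", [
        (486.0, 695.0, "vs_larger", 30.07),
        (261.0, 436.0, "vs_larger", 40.14),
        (5324.0, 3760.0, "vs_control", -29.38),
        (5324.0, 3760.0, "vs_larger", -29.38),
        (100.0, 150.0, "vs_control", 50.0),
    ])
    def test_reference_values(self, control, pad, convention, expected):
        assert fx.percent_difference(control, pad, convention) \
            == pytest.approx(expected, abs=0.005)

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            fx.percent_difference(0.0, 5.0, "vs_control")


class TestGroupComparison:
    def test_identical_groups_null(self, rng):
        summ = make_summaries(rng, 10, 10)
        summ.loc[summ.group == "pad", ["mean_carbonyl_gsu"]] = \
            summ.loc[summ.group == "control", "mean_carbonyl_gsu"].to_numpy()
        res = fx.adjusted_group_comparison(summ, "carbonyl", covariates=())
        assert res.F_stat == pytest.approx(0.0, abs=1e-12)
        assert res.percent_difference == pytest.approx(0.0, abs=1e-9)

    def test_group_f_equals_t_squared(self, rng):
        """No covariates, balanced design: F of the group term is t²."""
        summ = make_summaries(rng, 14, 14, effect=80.0)
        res = fx.adjusted_group_comparison(summ, "carbonyl", covariates=())
        a = summ.loc[summ.group == "control", "mean_carbonyl_gsu"]
        b = summ.loc[summ.group == "pad", "mean_carbonyl_gsu"]
        t, p = sps.ttest_ind(b, a)
        assert res.F_stat == pytest.approx(t**2, rel=1e-9)
        assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_orthogonal_covariates_leave_estimate_unchanged(self, rng):
        """Covariates balanced identically in both groups do not move the contrast."""
        summ = make_summaries(rng, 12, 12, effect=60.0)
        summ["cad"] = [0, 1] * 12
        summ["htn"] = [0, 0, 1, 1] * 6
        with_cov = fx.adjusted_group_comparison(summ, "carbonyl")
        without = fx.adjusted_group_comparison(summ, "carbonyl", covariates=())
        d_with = with_cov.adjusted_mean_pad - with_cov.adjusted_mean_control
        d_without = without.adjusted_mean_pad - without.adjusted_mean_control
        assert d_with == pytest.approx(d_without, rel=1e-9)

    def test_constant_covariate_dropped_with_warning(self, rng):
        summ = make_summaries(rng)
        summ["htn"] = 1
        with pytest.warns(UserWarning, match="htn"):
            res = fx.adjusted_group_comparison(summ, "carbonyl")
        assert res.covariates == ["cad"]

    def test_df_accounting(self, rng):
        summ = make_summaries(rng, 21, 34)
        res = fx.adjusted_group_comparison(summ, "carbonyl")
        assert res.df_model == 3
        assert res.df_resid == 55 - 4


class TestStageTrend:
    def test_perfect_linear_fit(self):
        summ = pd.DataFrame({
            "patient_id": list("abcdef"), "group": "pad",
            "fontaine_stage": [2, 2, 3, 3, 4, 4],
            "abi": 0.4, "cad": 0, "htn": 0,
            "mean_carbonyl_gsu": [400.0, 400.0, 500.0, 500.0, 600.0, 600.0],
            "mean_hne_gsu": 300.0, "mean_csa_um2": 4000.0,
        })
        res = fx.stage_trend(summ, "carbonyl", covariates=())
        assert res.slope == pytest.approx(100.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_single_stage_errors(self):
        summ = pd.DataFrame({
            "patient_id": ["a", "b"], "group": "pad", "fontaine_stage": [2, 2],
            "abi": 0.4, "cad": 0, "htn": 0, "mean_carbonyl_gsu": [1.0, 2.0],
            "mean_hne_gsu": 1.0, "mean_csa_um2": 1.0})
        with pytest.raises(ValueError, match="distinct"):
            fx.stage_trend(summ, "carbonyl")


class TestPartialCorrelation:
    def _pad(self, rng, n=30):
        df = make_summaries(rng, 0, n)
        return df[df.group == "pad"].reset_index(drop=True)

    def test_no_covariates_reduces_to_pearson(self, rng):
        pad = self._pad(rng)
        res = fx.abi_partial_correlation(pad, "carbonyl", covariates=())
        r, p = sps.pearsonr(pad["mean_carbonyl_gsu"], pad["abi"])
        assert res.r == pytest.approx(r, abs=1e-12)

    def test_perfect_anticorrelation(self, rng):
        pad = self._pad(rng)
        pad["mean_carbonyl_gsu"] = -pad["abi"]
        res = fx.abi_partial_correlation(pad, "carbonyl", covariates=())
        assert res.r == pytest.approx(-1.0, abs=1e-9)

    def test_against_normal_equations_oracle(self):
        """6-row fixture vs residual correlation solved by hand via normal equations."""
        pad = pd.DataFrame({
            "patient_id": list("uvwxyz"), "group": "pad",
            "fontaine_stage": [2, 3, 4, 2, 3, 4],
            "abi": [0.70, 0.45, 0.15, 0.62, 0.38, 0.22],
            "cad": [1, 0, 1, 0, 1, 0], "htn": [0, 1, 1, 0, 0, 1],
            "mean_carbonyl_gsu": [520.0, 640.0, 880.0, 555.0, 700.0, 810.0],
            "mean_hne_gsu": 300.0, "mean_csa_um2": 4000.0,
        })
        y = pad["mean_carbonyl_gsu"].to_numpy()
        x = pad["abi"].to_numpy()
        Z = np.column_stack([np.ones(6), pad["cad"], pad["htn"]])
        ry = y - Z @ np.linalg.solve(Z.T @ Z, Z.T @ y)
        rx = x - Z @ np.linalg.solve(Z.T @ Z, Z.T @ x)
        expected = np.corrcoef(ry, rx)[0, 1]
        res = fx.abi_partial_correlation(pad, "carbonyl")
        assert res.r == pytest.approx(expected, abs=1e-10)
        assert res.ci_low <= res.r <= res.ci_high
        assert 0.0 <= res.p_value <= 1.0

    def test_against_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        pad = self._pad(rng, n=25)
        res = fx.abi_partial_correlation(pad, "carbonyl")
        ref = pingouin.partial_corr(pad, x="abi", y="mean_carbonyl_gsu",
                                    covar=["cad", "htn"])
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.p_value == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)

    def test_insufficient_n(self, rng):
        pad = self._pad(rng, n=5)
        pad["cad"] = [0, 1, 0, 1, 0]
        pad["htn"] = [1, 0, 0, 1, 1]
        with pytest.raises(ValueError, match="n > covariates"):
            fx.abi_partial_correlation(pad, "carbonyl")


class TestQuartileRepeatedMeasures:
    def _qtable(self, values_by_patient):
        rows = []
        for pid, vals in values_by_patient.items():
            for cls, v in zip(("Q1", "Q2", "Q3", "Q4"), vals):
                rows.append({"patient_id": pid, "marker": "carbonyl", "cls": cls,
                             "n_fibers": 100,
                             "mean_csa_um2": v})
        return pd.DataFrame(rows)

    def test_no_class_effect_gives_p_one(self):
        qt = self._qtable({"a": [4000] * 4, "b": [5000] * 4, "c": [4500] * 4})
        res = fx.quartile_repeated_measures(qt, "carbonyl")
        assert res.overall_p == pytest.approx(1.0)
        assert res.contrasts == []

    def test_strong_q4_deficit_detected_with_contrasts(self, rng):
        base = {f"p{i}": [4000 + rng.normal(0, 30) for _ in range(3)] + [3400]
                for i in range(8)}
        res = fx.quartile_repeated_measures(self._qtable(base), "carbonyl")
        assert res.overall_p < 0.05
        pairs = {c["pair"]: c for c in res.contrasts}
        assert set(pairs) == {"Q4-Q1", "Q4-Q2", "Q4-Q3"}
        assert all(c["estimate"] < 0 for c in res.contrasts)
        assert all(c["p"] < 0.05 for c in res.contrasts)

    def test_missing_classes_dropped(self, rng):
        qt = self._qtable({"a": [4000, 4100, 3900, 3000],
                           "b": [5000, np.nan, 4900, 4200]})
        res = fx.quartile_repeated_measures(qt, "carbonyl")
        assert res.n_patients == 2

    def test_too_few_patients_errors(self):
        qt = self._qtable({"a": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError, match=">= 2 patients"):
            fx.quartile_repeated_measures(qt, "carbonyl")


class TestMarkerAgreementAndDemographics:
    def test_exact_linear_markers(self, rng):
        summ = make_summaries(rng, 0, 10)
        summ["mean_hne_gsu"] = 0.6 * summ["mean_carbonyl_gsu"]
        r, p = fx.marker_agreement(summ)
        assert r == pytest.approx(1.0)

    def test_too_few_specimens(self, rng):
        with pytest.raises(ValueError):
            fx.marker_agreement(make_summaries(rng, 0, 2))

    def test_cad_chi_square_matches_reference(self):
        """2×2 CAD table (5/21 vs 21/34) gives chi-square 7.50."""
        chi2, p = fx.chi_square_from_counts(5, 21, 21, 34)
        assert chi2 == pytest.approx(7.50, abs=0.01)
        assert p == pytest.approx(0.006, abs=0.001)

    def test_chi_square_textbook_formula_oracle(self):
        a, b, c, d = 8, 12, 15, 5  # yes/no per group
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        chi2, _ = fx.chi_square_from_counts(a, a + b, c, c + d)
        assert chi2 == pytest.approx(expected, rel=1e-12)

    def test_identical_proportions_give_zero(self):
        chi2, p = fx.chi_square_from_counts(10, 20, 15, 30)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_demographics_table(self, rng):
        summ = make_summaries(rng, 15, 20)
        out = fx.demographics_table(summ).set_index("variable")
        assert set(out.index) == {"cad", "htn", "abi"}
        assert out.loc["abi", "p_value"] < 0.01  # ABI separates groups by design
        assert ((out["p_value"].dropna() >= 0) & (out["p_value"].dropna() <= 1)).all()

    def test_degenerate_table_not_computable(self, rng):
        summ = make_summaries(rng, 8, 8)
        summ["cad"] = 0
        out = fx.demographics_table(summ).set_index("variable")
        assert np.isnan(out.loc["cad", "statistic"])
        assert "not computable" in out.loc["cad", "note"]
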