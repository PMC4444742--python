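"""Population tabulation and statistical tests, against hand-evaluated oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as ss

from kinencode.encoding_analysis import EncodingResult, VariableResult
from kinencode.population_stats import (chi_square_2x2, class_rate_anova,
                                        lag_asymmetry_test,
                                        lateralization_test, stim_anova,
                                        tabulate)
from kinencode.session_io import UnitRecording
from kinencode.synthetic_data import (assign_cohort_specs,
                                      planted_class_table,
                                      sample_stim_summary_table)


def _res(unit_id, variable, sign, lag_s=0.0, r=0.5):
    if variable == "uncorrelated":
        return EncodingResult(unit_id, {}, "uncorrelated", "none",
                              float("nan"), float("nan"), float("nan"))
    r = abs(r) if sign == "positive" else -abs(r)
    per = {variable: VariableResult(variable, lag_s, int(round(lag_s / 0.03)),
                                    r, 0.001, 1000)}
    return EncodingResult(unit_id, per, variable, sign, r, 0.001, lag_s)


def _unit(unit_id, hemisphere="left", mean_rate=5.0):
    return UnitRecording(unit_id, np.array([1.0]), hemisphere=hemisphere,
                         mean_rate=mean_rate, spike_width_fwhm=1.0)


class TestTabulate:
    def test_direct_count(self):
        results = [_res("a", "vel_up", "positive"),
                   _res("b", "vel_left", "negative"),
                   _res("c", "uncorrelated", "none")]
        units = [_unit("a"), _unit("b"), _unit("c")]
        t = tabulate(results, units)
        assert t.counts.loc["velocity", "up"] == 1
        assert t.counts.loc["velocity", "left"] == 1
        assert t.counts.loc["acceleration"].sum() == 0
        assert t.n_uncorrelated == 1
        assert t.n_positive == 1 and t.n_negative == 1
        assert t.n_positive + t.n_negative == t.n_classified

    def test_empty_results_all_zero(self):
        t = tabulate([], [])
        assert t.n_classified == 0 and t.n_uncorrelated == 0

    def test_pure_function_determinism(self):
        results = [_res("a", "acc_down", "positive")]
        units = [_unit("a")]
        t1, t2 = tabulate(results, units), tabulate(results, units)
        assert t1.counts.equals(t2.counts)
        assert t1.to_dict() == t2.to_dict()

    def test_planted_cohort_composition_recovered(self, cohort, cohort_analysis):
        """When recovery is near-perfect the tabulated composition matches the
        planted mix for every correctly recovered unit."""
        bundle, _session, specs = cohort
        results, _, _ = cohort_analysis
        coupled = [s for s in specs if s.target not in (None, "x", "y")]
        coupled_ids = {s.unit_id for s in coupled}
        sub = [r for r in results if r.unit_id in coupled_ids]
        table = tabulate(sub, bundle.units)
        planted = planted_class_table(coupled)
        by_id = {r.unit_id: r for r in sub}
        n_mis = sum(by_id[s.unit_id].class_variable != s.target for s in coupled)
        # each misclassification moves at most one count between two cells
        diff = (table.counts - planted.counts).abs().to_numpy().sum()
        assert diff <= 2 * n_mis
        assert n_mis <= 0.1 * len(coupled)  # near-perfect recovery regime


class TestChiSquare:
    def test_perfectly_crossed_table(self):
        res = chi_square_2x2([[10, 0], [0, 10]])
        assert res.chi2 == pytest.approx(20.0, abs=1e-12)

    def test_symmetric_table_zero(self):
        res = chi_square_2x2([[5, 5], [5, 5]])
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_hand_evaluated_value(self):
        res = chi_square_2x2([[20, 10], [10, 20]])
        assert res.chi2 == pytest.approx(20.0 / 3.0, abs=1e-12)

    def test_zero_marginal_errors(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_2x2([[0, 0], [5, 5]])

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.integers(1, 50), st.integers(1, 50),
           st.integers(1, 50), st.integers(1, 50))
    def test_matches_closed_form(self, a, b, c, d):
        """Pearson chi-square equals n(ad-bc)^2 / product of marginals."""
        res = chi_square_2x2([[a, b], [c, d]])
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert res.chi2 == pytest.approx(closed, rel=1e-12)

    def test_yates_flag_applies_correction(self):
        plain = chi_square_2x2([[12, 5], [6, 14]])
        corr = chi_square_2x2([[12, 5], [6, 14]], yates=True)
        assert corr.chi2 < plain.chi2


class TestLateralization:
    @staticmethod
    def _results_units(cells):
        """cells: dict (hemisphere, direction) -> count, all velocity class."""
        results, units = [], []
        k = 0
        for (hemi, direction), count in cells.items():
            for _ in range(count):
                uid = f"u{k}"
                k += 1
                results.append(_res(uid, f"vel_{direction}", "positive"))
                units.append(_unit(uid, hemisphere=hemi))
        return results, units

    def test_perfectly_crossed_counts(self):
        results, units = self._results_units({
            ("left", "right"): 10, ("right", "left"): 10})
        res = lateralization_test(tabulate(results, units))["velocity"]
        assert res.chi2 == pytest.approx(20.0, abs=1e-12)

    def test_symmetric_counts_zero(self):
        results, units = self._results_units({
            ("left", "right"): 5, ("left", "left"): 5,
            ("right", "right"): 5, ("right", "left"): 5})
        res = lateralization_test(tabulate(results, units))["velocity"]
        assert res.chi2 == 0.0

    def test_empty_contingency_flagged(self):
        results, units = self._results_units({("left", "right"): 5})
        out = lateralization_test(tabulate(results, units))
        assert out["velocity"].insufficient
        assert out["acceleration"].insufficient

    def test_power_under_contralateral_bias(self):
        """bias 0.75 with 60 horizontal units rejects independence at alpha
        0.05 in >= 80% of 200 seeded cohorts."""
        rng = np.random.default_rng(123)
        mix = {"vel_left": 30, "vel_right": 30}
        hits = 0
        for _ in range(200):
            specs = assign_cohort_specs(60, mix=mix, contralateral_bias=0.75,
                                        rng=rng)
            res = lateralization_test(planted_class_table(specs))["velocity"]
            hits += (not res.insufficient) and res.p < 0.05
        assert hits >= 160


class TestClassRateAnova:
    @staticmethod
    def _cohort(groups):
        """groups: dict direction -> list of rates."""
        results, units = [], []
        k = 0
        for direction, rates in groups.items():
            for rate in rates:
                uid = f"u{k}"
                k += 1
                results.append(_res(uid, f"vel_{direction}", "positive"))
                units.append(_unit(uid, mean_rate=rate))
        return results, units

    def test_identical_groups_f_zero(self):
        results, units = self._cohort({"up": [5, 5, 5], "down": [5, 5, 5]})
        res = class_rate_anova(results, units)
        assert res.F == 0.0 and res.p == 1.0

    def test_matches_sum_of_squares_oracle(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        results, units = self._cohort({"up": a, "down": b})
        res = class_rate_anova(results, units)
        # direct sums of squares
        grand = np.mean(a + b)
        ss_between = 3 * ((np.mean(a) - grand) ** 2 + (np.mean(b) - grand) ** 2)
        ss_within = sum((x - np.mean(a)) ** 2 for x in a) + \
            sum((x - np.mean(b)) ** 2 for x in b)
        F = (ss_between / 1) / (ss_within / 4)
        assert res.F == pytest.approx(F, abs=1e-12)
        assert (res.df_between, res.df_within) == (1, 4)
        assert res.p == pytest.approx(ss.f.sf(F, 1, 4), abs=1e-12)

    def test_null_p_values_uniform(self):
        """Groups from one distribution: p ~ U(0,1) over 1000 replicates."""
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(1000):
            groups = {d: list(rng.normal(5, 1, 8))
                      for d in ("up", "down", "left", "right")}
            results, units = self._cohort(groups)
            ps.append(class_rate_anova(results, units).p)
        assert ss.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_groups_error(self):
        results, units = self._cohort({"up": [5.0]})
        with pytest.raises(ValueError, match="2 groups"):
            class_rate_anova(results, units)


class TestLagAsymmetry:
    def test_hand_welch_oracle(self):
        results = [_res(f"p{i}", "vel_up", "positive", lag_s=v)
                   for i, v in enumerate([0.010, 0.020, 0.030])]
        results += [_res(f"n{i}", "vel_up", "negative", lag_s=v)
                    for i, v in enumerate([0.100, 0.150, 0.200])]
        res = lag_asymmetry_test(results)
        a = np.array([0.010, 0.020, 0.030])
        b = np.array([0.100, 0.150, 0.200])
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / 2 + vb ** 2 / 2)
        assert res.t == pytest.approx(t, abs=1e-12)
        assert res.p == pytest.approx(2 * ss.t.sf(abs(t), df), abs=1e-12)
        assert res.mean_pos_s == pytest.approx(0.020)
        assert res.sem_pos_s == pytest.approx(a.std(ddof=1) / np.sqrt(3))

    def test_all_zero_lags_flagged(self):
        results = [_res(f"p{i}", "vel_up", "positive", lag_s=0.0)
                   for i in range(3)]
        results += [_res(f"n{i}", "vel_up", "negative", lag_s=0.0)
                    for i in range(3)]
        res = lag_asymmetry_test(results)
        assert res.flagged
        assert res.mean_pos_s == 0.0 and res.mean_neg_s == 0.0

    def test_planted_lag_asymmetry_recovered(self, cohort, cohort_analysis):
        """Negative (pause) units planted with longer leads than positive
        (burst) units show a larger mean |lag| after recovery."""
        results, _, _ = cohort_analysis
        res = lag_asymmetry_test(results)
        assert not res.flagged
        assert res.mean_neg_s > res.mean_pos_s
        assert res.p < 0.01


class TestStimAnova:
    def test_identical_responses_f_zero(self):
        rows = []
        for g in ("chr2", "control"):
            for s in range(4):
                for f in (11.0, 15.0):
                    rows.append({"genotype": g, "frequency": f,
                                 "peak_speed": 7.0, "distance": 3.0})
        res = stim_anova(pd.DataFrame(rows))
        assert res["peak_speed"].F_genotype == pytest.approx(0.0, abs=1e-9)
        assert res["peak_speed"].F_frequency == pytest.approx(0.0, abs=1e-9)

    def test_single_level_factor_errors(self):
        df = pd.DataFrame({"genotype": ["chr2"] * 4,
                           "frequency": [11, 11, 15, 15],
                           "peak_speed": [1, 2, 3, 4],
                           "distance": [1, 2, 3, 4]})
        with pytest.raises(ValueError, match="2 levels"):
            stim_anova(df)

    def test_balanced_design_matches_sum_of_squares_oracle(self):
        """Hand two-way ANOVA decomposition on a balanced design."""
        rng = np.random.default_rng(3)
        levels_g, levels_f, reps = 2, 3, 5
        data = rng.normal(10, 2, (levels_g, levels_f, reps))
        rows = []
        for i, g in enumerate(("chr2", "control")):
            for j, f in enumerate((11.0, 15.0, 25.0)):
                for k in range(reps):
                    rows.append({"genotype": g, "frequency": f,
                                 "peak_speed": data[i, j, k],
                                 "distance": data[i, j, k]})
        res = stim_anova(pd.DataFrame(rows))["peak_speed"]
        grand = data.mean()
        ss_g = levels_f * reps * ((data.mean(axis=(1, 2)) - grand) ** 2).sum()
        ss_f = levels_g * reps * ((data.mean(axis=(0, 2)) - grand) ** 2).sum()
        cell = data.mean(axis=2)
        ss_int = reps * ((cell - data.mean(axis=(1, 2))[:, None]
                          - data.mean(axis=(0, 2))[None, :] + grand) ** 2).sum()
        ss_err = ((data - cell[:, :, None]) ** 2).sum()
        df_err = levels_g * levels_f * (reps - 1)
        assert res.F_genotype == pytest.approx((ss_g / 1) / (ss_err / df_err),
                                               rel=1e-9)
        assert res.F_frequency == pytest.approx((ss_f / 2) / (ss_err / df_err),
                                                rel=1e-9)
        assert res.F_interaction == pytest.approx((ss_int / 2) / (ss_err / df_err),
                                                  rel=1e-9)
        assert res.df_resid == df_err

    def test_planted_genotype_effect_power(self):
        """+2 mm/s ChR2 offset, 20 sessions: detected in >= 80% of 200 runs."""
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(200):
            df = sample_stim_summary_table(10, (11.0, 15.0, 25.0), 2.0, rng)
            hits += stim_anova(df)["peak_speed"].p_genotype < 0.05
        assert hits >= 160
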