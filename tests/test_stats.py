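"""Paired t-tests, logistic IRLS, and model-comparison statistics."""

import math
import random

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

from bdforum.stats import (
    DegenerateTestError,
    RankDeficientError,
    SeparationError,
    cohens_d_av,
    fit_logistic,
    gender_balanced_rerun,
    information_criteria,
    interpret_d,
    likelihood_ratio,
    mean_profile,
    paired_comparison,
    pseudo_r2,
    relative_probability,
)
from bdforum.synth import simulate_logistic_sample


class TestPairedComparison:
    def test_identical_vectors_null_result(self):
        res = paired_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p_bonf == 1.0 and res.d_z == 0.0

    def test_textbook_hand_computation(self):
        # differences (1, 2, 3): t = 2/(1/sqrt(3)) = 3.4641, d_z = 2.0
        res = paired_comparison([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert res.t == pytest.approx(2.0 / (1.0 / math.sqrt(3.0)), abs=1e-4)
        assert res.d_z == pytest.approx(2.0)
        assert res.df == 2

    def test_constant_nonzero_difference_is_degenerate(self):
        with pytest.raises(DegenerateTestError):
            paired_comparison([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])

    def test_n_below_two_is_error(self):
        with pytest.raises(DegenerateTestError):
            paired_comparison([1.0], [0.0])

    def test_sign_convention_is_mh_minus_nonmh(self):
        res = paired_comparison([1.0, 2.0, 4.0], [2.0, 3.0, 6.0])
        assert res.t < 0 and res.d_z < 0 and res.d_av < 0

    def test_planted_anxiety_effect_detected(self):
        # MH-context anxiety emission double the non-MH rate, 500 users
        rng = np.random.default_rng(500)
        n_tok = 400  # tokens per user per context
        mh = 100.0 * rng.binomial(n_tok, 0.008, size=500) / n_tok
        nonmh = 100.0 * rng.binomial(n_tok, 0.004, size=500) / n_tok
        res = paired_comparison(mh, nonmh)
        assert res.d_z > 0 and res.p_bonf < 0.001

    @given(hst.floats(min_value=0.0, max_value=1.0))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_bonferroni_bounds_and_monotonicity(self, p):
        p_bonf = min(1.0, 5 * p)
        assert p <= p_bonf <= 1.0

    def test_d_av_from_summary_statistics(self):
        assert cohens_d_av(0.67 - 0.37, 0.42, 0.22) == pytest.approx(0.8948, abs=1e-4)

    def test_interpretation_labels(self):
        assert interpret_d(-0.20) == "Small"
        assert interpret_d(0.97) == "Large"
        assert interpret_d(-0.07) == "Very small"
        assert interpret_d(1.63) == "Very large"


class TestFitLogistic:
    def test_two_by_two_closed_form(self):
        # exposed: 10 events/10 non; unexposed: 5 events/20 non -> slope ln 4
        x = [1.0] * 20 + [0.0] * 25
        y = [1.0] * 10 + [0.0] * 10 + [1.0] * 5 + [0.0] * 20
        est, fit = fit_logistic(pd.DataFrame({"exposed": x}), np.array(y))
        by_name = {e.name: e for e in est}
        assert by_name["exposed"].beta == pytest.approx(math.log(4.0), abs=1e-6)
        assert by_name["intercept"].beta == pytest.approx(math.log(5.0 / 20.0), abs=1e-6)

    def test_intercept_only_fifty_fifty(self):
        X = pd.DataFrame(index=range(40))
        y = np.array([1.0] * 20 + [0.0] * 20)
        est, fit = fit_logistic(X, y)
        assert est[0].beta == pytest.approx(0.0, abs=1e-10)
        assert fit.ll == pytest.approx(fit.ll_null)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        X, y = simulate_logistic_sample(800, {"intercept": 0.3, "gender": -0.8, "anxiety": 0.6}, 21)
        est, fit = fit_logistic(X, y)
        sm_fit = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        ours = np.array([e.beta for e in est])
        theirs = sm_fit.params.to_numpy()
        assert ours == pytest.approx(theirs, abs=1e-6)
        ses = np.array([e.se for e in est])
        assert ses == pytest.approx(sm_fit.bse.to_numpy(), rel=1e-4)
        assert fit.ll == pytest.approx(sm_fit.llf, abs=1e-6)

    def test_score_equation_at_optimum(self):
        X, y = simulate_logistic_sample(500, {"gender": -0.5}, 33)
        est, _ = fit_logistic(X, y)
        M = np.hstack([np.ones((len(y), 1)), X.to_numpy()])
        beta = np.array([e.beta for e in est])
        p = 1.0 / (1.0 + np.exp(-(M @ beta)))
        assert np.max(np.abs(M.T @ (y - p))) < 1e-6

    def test_perfect_separation_raises(self):
        x = np.array([0.0] * 20 + [1.0] * 20)
        y = x.copy()
        with pytest.raises(SeparationError):
            fit_logistic(pd.DataFrame({"x": x}), y)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=60)
        X = pd.DataFrame({"a": a, "b": 2.0 * a})
        y = (rng.random(60) < 0.5).astype(float)
        with pytest.raises(RankDeficientError, match="b"):
            fit_logistic(X, y)

    def test_single_outcome_class_is_error(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        with pytest.raises(ValueError):
            fit_logistic(X, np.ones(10))

    def test_random_two_by_two_tables_match_closed_form(self):
        rng = random.Random(99)
        for _ in range(50):
            a, b, c, d = (rng.randint(3, 30) for _ in range(4))  # all cells nonzero
            x = [1.0] * (a + b) + [0.0] * (c + d)
            y = [1.0] * a + [0.0] * b + [1.0] * c + [0.0] * d
            est, _ = fit_logistic(pd.DataFrame({"x": x}), np.array(y))
            slope = next(e for e in est if e.name == "x").beta
            assert slope == pytest.approx(math.log(a * d / (b * c)), abs=1e-6)

    def test_coefficient_accessors_consistent(self):
        X, y = simulate_logistic_sample(300, {"gender": -0.8}, 5)
        est, _ = fit_logistic(X, y)
        for e in est:
            lo, hi = e.ci
            assert lo < e.beta < hi
            assert e.odds_ratio > 0
            assert e.z * e.se == pytest.approx(e.beta)


class TestModelComparison:
    def test_information_criteria_printed_row(self):
        aic, bic = information_criteria(-5227.0, 5, 10309)
        assert round(aic) == 10464
        assert round(bic) == 10500

    def test_information_criteria_trivial(self):
        assert information_criteria(0.0, 0, 1) == (0.0, 0.0)

    def test_lrt_identical_fits(self):
        from bdforum.stats import ModelFit

        fit = ModelFit(ll=-100.0, ll_null=-120.0, k=5, n=50)
        full = ModelFit(ll=-100.0, ll_null=-120.0, k=10, n=50)
        res = likelihood_ratio(fit, full)
        assert res.x2 == 0.0 and res.p == pytest.approx(1.0)

    def test_lrt_printed_example(self):
        from bdforum.stats import ModelFit

        nested = ModelFit(ll=-5227.0, ll_null=-5452.8, k=5, n=10158)
        full = ModelFit(ll=-5192.0, ll_null=-5452.8, k=10, n=10158)
        res = likelihood_ratio(nested, full)
        assert res.x2 == pytest.approx(70.0)
        assert res.df == 5
        assert res.p < 0.001

    def test_lrt_rejects_non_nested(self):
        from bdforum.stats import ModelFit

        nested = ModelFit(ll=-90.0, ll_null=-120.0, k=5, n=50)
        full = ModelFit(ll=-100.0, ll_null=-120.0, k=10, n=50)
        with pytest.raises(ValueError):
            likelihood_ratio(nested, full)

    def test_pseudo_r2_identity_case(self):
        assert pseudo_r2(-10.0, -10.0, 20) == pytest.approx((0.0, 0.0, 0.0))

    def test_pseudo_r2_hand_evaluation(self):
        hl, cs, nk = pseudo_r2(-10.0, -5.0, 20)
        assert hl == pytest.approx(0.5)
        assert cs == pytest.approx(1.0 - math.exp(-0.5), abs=1e-10)
        assert nk == pytest.approx((1.0 - math.exp(-0.5)) / (1.0 - math.exp(-1.0)), abs=1e-10)

    def test_pseudo_r2_ordering_invariants(self):
        hl, cs, nk = pseudo_r2(-300.0, -250.0, 400)
        assert 0 <= cs < 1
        assert nk >= cs


class TestRelativeProbability:
    def test_zero_gender_effect(self):
        from bdforum.stats import CoefficientEstimate

        est = [CoefficientEstimate("intercept", 0.4, 0.1),
               CoefficientEstimate("gender", 0.0, 0.1)]
        assert relative_probability(est, {}) == pytest.approx(0.0)

    def test_two_parameter_hand_case(self):
        from bdforum.stats import CoefficientEstimate

        est = [CoefficientEstimate("intercept", 0.0, 0.1),
               CoefficientEstimate("gender", -0.79, 0.1)]
        assert relative_probability(est, {}) == pytest.approx(60.17, abs=0.01)

    def test_planted_negative_gender_effect_positive_change(self):
        for seed in (1, 2, 3):
            X, y = simulate_logistic_sample(2000, {"intercept": 0.5, "gender": -0.8}, seed)
            est, _ = fit_logistic(X, y)
            assert relative_probability(est, mean_profile(X)) > 0


class TestGenderBalancedRerun:
    def test_counts_after_balancing(self):
        rng = np.random.default_rng(0)
        gender = np.array([0.0] * 60 + [1.0] * 40 + [0.0] * 30 + [1.0] * 30)
        y = np.array([1.0] * 100 + [0.0] * 60)
        X = pd.DataFrame({"gender": gender, "x": rng.normal(size=160)})
        Xb, yb, est, fit = gender_balanced_rerun(X, y, rng)
        assert int(np.sum(yb == 1.0)) == 80  # 40 + 40
        g1 = Xb.loc[yb == 1.0, "gender"]
        assert int((g1 == 0).sum()) == int((g1 == 1).sum()) == 40

    def test_already_balanced_is_identity(self):
        rng = np.random.default_rng(0)
        gender = np.array([0.0, 1.0] * 30)
        y = np.array(([1.0] * 30 + [0.0] * 30))
        X = pd.DataFrame({"gender": gender, "x": rng.normal(size=60)})
        Xb, yb, _, _ = gender_balanced_rerun(X, y, rng)
        assert len(Xb) == 60 and Xb.equals(X)

    def test_single_gender_group_is_error(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"gender": np.zeros(40), "x": rng.normal(size=40)})
        y = np.array([1.0] * 20 + [0.0] * 20)
        with pytest.raises(ValueError, match="single gender"):
            gender_balanced_rerun(X, y, rng)

    def test_substantive_estimates_stable_under_balancing(self):
        # balancing gender within outcome groups removes the gender-outcome
        # association by construction; the robustness question is whether the
        # substantive (mood and control) coefficients survive it
        X, y = simulate_logistic_sample(3000, {"intercept": 0.4, "gender": -0.8, "anxiety": 0.6}, 17)
        full_est, _ = fit_logistic(X, y)
        _, _, bal_est, _ = gender_balanced_rerun(X, y, np.random.default_rng(18))
        full = {e.name: e for e in full_est}
        for e in bal_est:
            if e.name in ("gender", "intercept"):
                continue
            assert abs(e.beta - full[e.name].beta) <= 3 * max(e.se, full[e.name].se)
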