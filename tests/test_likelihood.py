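import numpy as np
import pytest

from illnessdeath import (CoefficientSet, LikelihoodSettings,
                          classify_pattern, contribution_A, contribution_B,
                          contribution_C, contribution_D, contribution_EF,
                          derive_gompertz_23, simpson_integrate,
                          total_minus_log_likelihood)
from conftest import chain_likelihood, make_record


class TestPatternClassification:
    def test_all_six_patterns(self, pattern_records):
        for label, rec in pattern_records.items():
            assert classify_pattern(rec) == label

    def test_derived_anchors(self, pattern_records):
        a = pattern_records["A"]
        assert a.last_healthy_age == 62.0
        assert a.first_ill_age == 64.0
        assert a.end_age == 65.3

    def test_recovery_rejected(self):
        with pytest.raises(ValueError, match="recovery"):
            make_record("bad", [(60, 1), (62, 2), (64, 1)], censor=64.0)

    def test_non_monotone_ages_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            make_record("bad", [(60, 1), (60, 1)], censor=60.0)


class TestSimpson:
    def test_exact_on_cubics(self):
        for res in (0.5, 0.1, 0.031):
            assert simpson_integrate(lambda x: x ** 3, 0.0, 1.0, res) == \
                pytest.approx(0.25, rel=1e-14)

    def test_exponential_integrand(self):
        # composite Simpson error bound at panel width 0.05 is
        # (b-a) h^4 max|f''''| / 180 ~ 9.4e-8
        val = simpson_integrate(np.exp, 0.0, 1.0, 0.05)
        assert val == pytest.approx(np.e - 1.0, abs=1e-7)

    def test_degenerate_interval(self):
        assert simpson_integrate(np.exp, 2.0, 2.0, 0.05) == 0.0


class TestContributionsAgainstChainOracle:
    """Constant-hazard toys vs an independent discrete-time chain (dt=1e-3)."""

    L12, L13, L23 = 0.08, 0.05, 0.3

    def check(self, func, rec, const_theta, fine_settings):
        impl = func(rec, const_theta, fine_settings)
        oracle = chain_likelihood(self.L12, self.L13, self.L23,
                                  rec.baseline_age, rec.visits, rec.end_age,
                                  rec.died)
        assert impl == pytest.approx(oracle, rel=1e-3)

    def test_pattern_A(self, pattern_records, const_theta, fine_settings):
        self.check(contribution_A, pattern_records["A"], const_theta,
                   fine_settings)

    def test_pattern_B(self, pattern_records, const_theta, fine_settings):
        self.check(contribution_B, pattern_records["B"], const_theta,
                   fine_settings)

    def test_pattern_C(self, pattern_records, const_theta, fine_settings):
        self.check(contribution_C, pattern_records["C"], const_theta,
                   fine_settings)

    def test_pattern_D(self, pattern_records, const_theta, fine_settings):
        self.check(contribution_D, pattern_records["D"], const_theta,
                   fine_settings)


class TestContributionStructure:
    def test_A_zero_without_illness_hazard(self, pattern_records, fine_settings):
        theta = CoefficientSet((-60.0, 0.0), (np.log(0.05), 0.0),
                               (np.log(0.3), 0.0), 0.0)
        assert contribution_A(pattern_records["A"], theta, fine_settings) == \
            pytest.approx(0.0, abs=1e-12)

    def test_C_reduces_to_direct_death_without_q12(self, pattern_records,
                                                   fine_settings):
        rec = pattern_records["C"]
        theta = CoefficientSet((-60.0, 0.0), (np.log(0.05), 0.0),
                               (np.log(0.3), 0.0), 0.0)
        # only the never-ill branch survives: P11 * q13 with escape rate q13
        expected = np.exp(-0.05 * (rec.end_age - rec.baseline_age)) * 0.05
        assert contribution_C(rec, theta, fine_settings) == \
            pytest.approx(expected, rel=1e-9)

    def test_C_integral_branch_only_without_q13(self, pattern_records,
                                                const_theta, fine_settings):
        rec = pattern_records["C"]
        theta = CoefficientSet((np.log(0.08), 0.0), (-60.0, 0.0),
                               (np.log(0.3), 0.0), 0.0)
        # oracle with a negligible direct death rate
        oracle = chain_likelihood(0.08, 0.0, 0.3, rec.baseline_age,
                                  rec.visits, rec.end_age, True)
        assert contribution_C(rec, theta, fine_settings) == \
            pytest.approx(oracle, rel=1e-3)

    def test_D_survival_only_without_q12(self, pattern_records, fine_settings):
        rec = pattern_records["D"]
        theta = CoefficientSet((-60.0, 0.0), (np.log(0.05), 0.0),
                               (np.log(0.3), 0.0), 0.0)
        expected = np.exp(-0.05 * (rec.end_age - rec.baseline_age))
        assert contribution_D(rec, theta, fine_settings) == \
            pytest.approx(expected, rel=1e-12)

    def test_D_all_rates_zero_is_one(self, pattern_records, fine_settings):
        theta = CoefficientSet((-60.0, 0.0), (-60.0, 0.0), (-60.0, 0.0), 0.0)
        assert contribution_D(pattern_records["D"], theta, fine_settings) == \
            pytest.approx(1.0, abs=1e-9)

    def test_B_equals_A_window_integral_when_no_death_hazard(
            self, pattern_records, fine_settings):
        # with q23 ~ 0 after onset, P22 = 1 and B reduces to the
        # P11*q12 window integral
        rec = pattern_records["B"]
        theta = CoefficientSet((np.log(0.08), 0.0), (np.log(0.05), 0.0),
                               (-60.0, 0.0), 0.0)
        lam1 = 0.13
        lo, hi = rec.last_healthy_age, rec.first_ill_age
        expected = simpson_integrate(
            lambda w: np.exp(-lam1 * (w - rec.baseline_age)) * 0.08,
            lo, hi, 0.001)
        assert contribution_B(rec, theta, fine_settings) == \
            pytest.approx(expected, rel=1e-6)

    def test_B_grows_as_state2_survival_improves(self, pattern_records,
                                                 fine_settings):
        rec = pattern_records["B"]
        vals = []
        for gamma in (0.0, -0.2, -0.5):
            theta = CoefficientSet((np.log(0.08), 0.0), (np.log(0.05), 0.0),
                                   (np.log(0.3), 0.0), gamma)
            vals.append(contribution_B(rec, theta, fine_settings))
        assert vals == sorted(vals)

    def test_A_shrinks_linearly_with_window(self, const_theta, fine_settings):
        widths, vals = [2.0, 1.0, 0.5], []
        for wdt in widths:
            rec = make_record("a", [(60, 1), (64 - wdt, 1), (64, 2)],
                              death=65.3)
            vals.append(contribution_A(rec, const_theta, fine_settings))
        # ratios follow window widths to first order
        assert vals[0] / vals[1] == pytest.approx(2.0, rel=0.1)
        assert vals[1] / vals[2] == pytest.approx(2.0, rel=0.1)


class TestPatternEF:
    def test_gompertz_closed_form(self):
        """P22 over [A_b, A_N] matches the Gompertz survivor at fine h."""
        theta = CoefficientSet((-9, 0.06), (-10, 0.09), (-5.92, 0.052), -0.11)
        rec = make_record("f", [(70, 2), (72, 2)], censor=72.0)
        W = 65.0
        alpha, xi = derive_gompertz_23(theta, W)
        s = LikelihoodSettings(h=0.001, integ_res=0.001)
        t0, t1 = 70.0 - W, 72.0 - W
        closed = np.exp((alpha / xi) * (np.exp(xi * t0) - np.exp(xi * t1)))
        assert contribution_EF(rec, theta, W, s) == pytest.approx(closed,
                                                                  rel=1e-5)

    def test_markov_case_independent_of_onset(self, fine_settings):
        theta = CoefficientSet((-9, 0.06), (-10, 0.09), (-5.92, 0.052), 0.0)
        rec = make_record("f", [(70, 2), (72, 2)], censor=72.0)
        vals = {contribution_EF(rec, theta, W, fine_settings)
                for W in (50.0, 60.0, 69.0)}
        assert max(vals) - min(vals) < 1e-12

    def test_no_death_hazard(self, fine_settings):
        theta = CoefficientSet((-9, 0.06), (-10, 0.09), (-60.0, 0.0), 0.0)
        f = make_record("f", [(70, 2), (72, 2)], censor=72.0)
        e = make_record("e", [(70, 2), (72, 2)], death=73.1)
        assert contribution_EF(f, theta, 65.0, fine_settings) == \
            pytest.approx(1.0, abs=1e-9)
        assert contribution_EF(e, theta, 65.0, fine_settings) == \
            pytest.approx(0.0, abs=1e-12)

    def test_onset_after_baseline_rejected(self, const_theta, fine_settings):
        rec = make_record("f", [(70, 2), (72, 2)], censor=72.0)
        with pytest.raises(ValueError):
            contribution_EF(rec, const_theta, 71.0, fine_settings)


class TestTotalLikelihood:
    def test_empty_dataset(self, const_theta):
        assert total_minus_log_likelihood([], const_theta) == 0.0

    def test_additivity_under_duplication(self, pattern_records, const_theta,
                                          fine_settings):
        from dataclasses import replace
        recs = [pattern_records[p] for p in "ABCD"]
        double = recs + [replace(r, id=r.id + "2") for r in recs]
        single = total_minus_log_likelihood(recs, const_theta,
                                            settings=fine_settings)
        assert total_minus_log_likelihood(double, const_theta,
                                          settings=fine_settings) == \
            pytest.approx(2.0 * single, rel=1e-12)

    def test_permutation_invariance(self, pattern_records, const_theta,
                                    fine_settings):
        recs = [pattern_records[p] for p in "ABCDEF"]
        W = {"e": 65.0, "f": 64.0}
        fwd = total_minus_log_likelihood(recs, const_theta, W, fine_settings)
        rev = total_minus_log_likelihood(recs[::-1], const_theta, W,
                                         fine_settings)
        assert fwd == rev

    def test_missing_onset_age_rejected(self, pattern_records, const_theta):
        with pytest.raises((KeyError, ValueError)):
            total_minus_log_likelihood([pattern_records["E"]], const_theta,
                                       W_map={})


class TestResolutionConvergence:
    @pytest.mark.parametrize("pattern", list("ABCD"))
    def test_contributions_stable_below_default_resolution(
            self, pattern, pattern_records, const_theta):
        func = {"A": contribution_A, "B": contribution_B,
                "C": contribution_C, "D": contribution_D}[pattern]
        rec = pattern_records[pattern]
        coarse = func(rec, const_theta, LikelihoodSettings(integ_res=0.05))
        fine = func(rec, const_theta, LikelihoodSettings(integ_res=0.005))
        assert coarse == pytest.approx(fine, rel=1e-5)

    def test_contribution_bounded_by_unit_stay_envelope(self, pattern_records,
                                                        const_theta,
                                                        fine_settings):
        # replacing every stay probability by 1 bounds the A integral by
        # window * sup q12
        rec = pattern_records["A"]
        width = rec.first_ill_age - rec.last_healthy_age
        val = contribution_A(rec, const_theta, fine_settings)
        assert val <= width * 0.08 * 0.3
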