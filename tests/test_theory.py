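"""First-order estimates, thresholds and the expectation oracle."""

import math
import warnings

import numpy as np
import pytest

from agony import (CandidateSpec, RSBMParams, candidate_estimate,
                   expectation_oracle, optimal_candidate, planted_estimate,
                   planted_zero, s_max, thresholds)


def make_params(p, q, s, R, n=16):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # grids may cross s_max
        return RSBMParams(p=p, q=q, s=s, R=R, n=n)


PARAM_GRID = [
    # (p, q, s, a) spanning both regimes and several sizes
    (0.5, 0.5, 0.01, 3), (0.5, 0.5, 0.001, 5), (0.5, 0.25, 0.02, 4),
    (0.7, 0.3, 0.005, 3), (0.9, 0.1, 0.01, 4), (0.6, 0.6, 0.05, 2),
    (0.5, 0.0, 0.002, 5), (0.5, 0.0, 0.01, 4), (0.8, 0.0, 0.02, 3),
    (0.3, 0.1, 0.003, 5), (0.4, 0.2, 0.008, 4), (0.2, 0.0, 0.004, 3),
    (1.0, 0.5, 0.03, 3),
]


class TestPlantedEstimate:
    @pytest.mark.parametrize("d", [0, 1, 2, 3])
    def test_perfect_at_zero_backward(self, d):
        params = make_params(0.5, 0.3, 0.0, 8)
        assert planted_estimate(params, d).value == 1.0

    def test_zero_crossing_military(self):
        # closed form 6p/(R(R+1)) at d=1, q=0
        params = make_params(0.5, 0.0, 0.001, 32, n=128)
        root = planted_zero(params, 1)
        assert root == pytest.approx(6 * 0.5 / (32 * 33), rel=1e-12)
        assert root == pytest.approx(0.00284, abs=5e-6)
        shifted = make_params(0.5, 0.0, root, 32, n=128)
        assert planted_estimate(shifted, 1).value == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("p,q,s,a", PARAM_GRID[:6])
    def test_matches_oracle(self, p, q, s, a):
        params = make_params(p, q, s, 2 ** a)
        for d in (0, 1, 2):
            est = planted_estimate(params, d).value
            orc = expectation_oracle(params, d, CandidateSpec(0, False)).value
            assert est == pytest.approx(orc, abs=1e-12)


class TestExpectationOracle:
    def test_full_merge_is_trivial(self):
        params = make_params(0.5, 0.5, 0.01, 8)
        assert expectation_oracle(params, 1, CandidateSpec(3, False)).value == 0.0

    def test_exact_convention_close_to_ensemble(self):
        # conventions differ by O(1/n) on the diagonal blocks
        params = make_params(0.5, 0.5, 0.01, 8, n=64)
        cand = CandidateSpec(1, False)
        e1 = expectation_oracle(params, 1, cand, "ensemble").value
        e2 = expectation_oracle(params, 1, cand, "exact").value
        assert e1 != e2
        assert e1 == pytest.approx(e2, abs=0.5 / 64)

    def test_split_nondivisible_size_rejected(self):
        params = make_params(0.5, 0.5, 0.01, 4, n=6)
        with pytest.raises(ValueError):
            expectation_oracle(params, 1, CandidateSpec(4, False))


class TestClosedForms:
    @pytest.mark.parametrize("p,q,s,a", PARAM_GRID)
    @pytest.mark.parametrize("d", [1, 2])
    def test_match_oracle_everywhere(self, p, q, s, a, d):
        """Closed merged/inverted forms equal the oracle for every b."""
        params = make_params(p, q, s, 2 ** a)
        for b in range(0, a + 1):
            for inverted in (False, True):
                cand = CandidateSpec(b, inverted)
                cf = candidate_estimate(params, d, cand).value
                orc = expectation_oracle(params, d, cand).value
                assert cf == pytest.approx(orc, abs=1e-9), (b, inverted)

    def test_b0_equals_planted(self):
        params = make_params(0.5, 0.5, 0.01, 16)
        for d in (1, 2):
            assert candidate_estimate(params, d, CandidateSpec(0, False)).value == \
                pytest.approx(planted_estimate(params, d).value, abs=1e-12)

    def test_rejects_other_exponents(self):
        params = make_params(0.5, 0.5, 0.01, 8)
        with pytest.raises(ValueError, match="expectation_oracle"):
            candidate_estimate(params, 3, CandidateSpec(1, False))

    def test_twitter_inversion_never_wins(self):
        # p >= q > s: every non-trivial inverted estimate is below the
        # planted one (b = a is the trivial one-class ranking, inversion-free)
        for s in (0.001, 0.01, 0.05):
            params = make_params(0.5, 0.5, s, 32)
            planted = planted_estimate(params, 1).value
            for b in range(0, 5):
                inv = candidate_estimate(params, 1, CandidateSpec(b, True)).value
                assert inv < planted

    def test_splitting_never_optimal_d1(self):
        for (p, q, s, a) in PARAM_GRID[:8]:
            params = make_params(p, q, s, 2 ** a, n=16)
            planted = planted_estimate(params, 1).value
            for b in (-1, -2):
                split = expectation_oracle(params, 1, CandidateSpec(b, False)).value
                assert split < planted


class TestThresholds:
    def test_twitter_d1_printed_value(self):
        params = make_params(0.5, 0.5, 0.001, 32, n=128)
        ts = thresholds(params, 1)
        assert ts.regime == "twitter"
        assert ts.values["s_m"] == pytest.approx(0.00151, abs=5e-6)

    def test_military_d1_printed_value(self):
        params = make_params(0.5, 0.0, 0.001, 32, n=128)
        ts = thresholds(params, 1)
        assert ts.regime == "military"
        assert ts.values["s_i"] == pytest.approx(0.00280, abs=5e-6)
        assert ts.values["s_1"] == pytest.approx(0.00284, abs=5e-6)

    def test_military_si_is_exact_crossing(self):
        # at s_i the planted and fully inverted two-class estimates tie
        base = make_params(0.5, 0.0, 0.001, 32, n=128)
        si = thresholds(base, 1).values["s_i"]
        at = make_params(0.5, 0.0, si, 32, n=128)
        a = 5
        planted = planted_estimate(at, 1).value
        inv2 = candidate_estimate(at, 1, CandidateSpec(a - 1, True)).value
        assert planted == pytest.approx(inv2, abs=1e-12)

    def test_d2_military_identity(self):
        params = make_params(0.5, 0.0, 0.001, 32, n=128)
        vals = thresholds(params, 2).values
        assert vals["s_23_i"] == 3 * vals["s_22_i"]  # exact by construction
        assert vals["s_21_0"] < vals["s_22_i"]

    def test_d2_military_s22_is_zero_of_inverted_two_class(self):
        base = make_params(0.5, 0.0, 0.001, 32, n=128)
        s22 = thresholds(base, 2).values["s_22_i"]
        at = make_params(0.5, 0.0, s22, 32, n=128)
        val = candidate_estimate(at, 2, CandidateSpec(4, True)).value
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_d0_statement(self):
        params = make_params(0.5, 0.5, 0.01, 8)
        ts = thresholds(params, 0)
        assert ts.values["R_opt"] == params.N
        assert ts.values["h0_lower_bound"] == 0.5

    def test_regime_mismatch(self):
        params = make_params(0.3, 0.5, 0.01, 8)  # p < q: neither regime
        with pytest.raises(ValueError, match="regime"):
            thresholds(params, 1)
        with pytest.raises(ValueError, match="q = 0"):
            thresholds(make_params(0.5, 0.2, 0.01, 8), 1, regime="military")

    def test_thresholds_lie_below_smax(self):
        params = make_params(0.5, 0.5, 0.001, 32, n=128)
        ts = thresholds(params, 1)
        assert 0 < ts.values["s_m"] < ts.s_max
        mil = make_params(0.5, 0.0, 0.001, 32, n=128)
        tm = thresholds(mil, 1)
        assert 0 < tm.values["s_i"] < tm.values["s_1"] < tm.s_max

    def test_asymptotic_scalings(self):
        # s_m R^2 -> 6p-3q, s_i R^2 -> 6p, s_21_0 R^3 -> 12p as R grows
        p, q = 0.5, 0.25
        for a in (9, 11):
            R = 2 ** a
            tw = thresholds(make_params(p, q, 1e-9, R, n=2), 1)
            assert tw.values["s_m"] * R ** 2 == pytest.approx(6 * p - 3 * q, rel=0.02)
            mil = thresholds(make_params(p, 0.0, 1e-9, R, n=2), 1)
            assert mil.values["s_i"] * R ** 2 == pytest.approx(6 * p, rel=0.02)
            m2 = thresholds(make_params(p, 0.0, 1e-9, R, n=2), 2)
            assert m2.values["s_21_0"] * R ** 3 == pytest.approx(12 * p, rel=0.02)


class TestFeedbackArcBound:
    @pytest.mark.parametrize("p,q,s,a", PARAM_GRID)
    def test_one_node_per_class_estimate_at_least_half(self, p, q, s, a):
        """d=0: splitting down to singletons always reaches estimate >= 1/2."""
        params = make_params(p, q, s, 2 ** a, n=16)
        if s > s_max(params):
            pytest.skip("not a valid hierarchy")
        b_single = -int(math.log2(16))
        est = expectation_oracle(params, 0, CandidateSpec(b_single, False)).value
        assert est >= 0.5


class TestOptimalCandidate:
    def test_twitter_below_threshold_keeps_planted(self):
        base = make_params(0.5, 0.5, 0.001, 32, n=128)
        sm = thresholds(base, 1).values["s_m"]
        params = make_params(0.5, 0.5, 0.5 * sm, 32, n=128)
        cand, est = optimal_candidate(params, 1)
        assert (cand.b, cand.inverted) == (0, False)

    def test_military_above_threshold_inverts_two_classes(self):
        base = make_params(0.5, 0.0, 0.001, 32, n=128)
        si = thresholds(base, 1).values["s_i"]
        params = make_params(0.5, 0.0, 1.1 * si, 32, n=128)
        cand, est = optimal_candidate(params, 1)
        assert cand.inverted
        assert cand.n_classes(32) == 2

    def test_d0_optimum_is_singletons(self):
        params = make_params(0.5, 0.5, 0.01, 8, n=16)
        cand, est = optimal_candidate(params, 0)
        assert cand.n_classes(8) == params.N
        assert est.value >= 0.5

    def test_twitter_optimal_class_count_monotone_in_s(self):
        base = make_params(0.5, 0.5, 0.001, 16, n=16)
        smax = s_max(base)
        counts = []
        for s in np.linspace(1e-4, smax, 12):
            cand, _ = optimal_candidate(make_params(0.5, 0.5, float(s), 16), 1)
            assert not cand.inverted
            counts.append(cand.n_classes(16))
        assert all(a >= b for a, b in zip(counts, counts[1:]))
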