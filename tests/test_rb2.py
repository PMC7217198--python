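import numpy as np
import pytest
from scipy.stats import hypergeom

from helpers import (
    TOY_DESIGN,
    forward_conditional_first_interim,
    total_variation,
)
from seqelim.estimators import naive_analysis
from seqelim.rb2 import (
    is_consistent,
    reverse_fill,
    reverse_start,
    rb2_estimate,
    two_arm_start,
)
from seqelim.trial_engine import simulate_two_arm_trial


class TestReverseFill:
    def test_anchor_at_first_interim_returns_observed(self, two_arm):
        spec = two_arm_start(two_arm, 1, 20, 15)
        s = reverse_fill(spec, 50, 0)
        assert np.all(s[:, 0, 0, 0] == 20)
        assert np.all(s[:, 1, 0, 0] == 15)

    def test_all_successes_backfill_deterministically(self, two_arm):
        spec = two_arm_start(two_arm, 3, 108, 40)
        s = reverse_fill(spec, 200, 1)
        # arm 1 fully successful: every earlier interim is saturated too
        assert np.all(s[:, 0, 0, 0] == 36)
        assert np.all(s[:, 0, 0, 1] == 72)

    def test_marginal_matches_hypergeometric_pmf(self, two_arm):
        # one back-step of 36 from 72 given 59 successes
        spec = two_arm_start(two_arm, 2, 35, 59)
        s = reverse_fill(spec, 40_000, 2)
        draws = s[:, 1, 0, 0]
        support = np.arange(max(0, 59 - 36), min(36, 59) + 1)
        pmf = hypergeom.pmf(support, 72, 59, 36)
        emp = np.array([(draws == k).mean() for k in support])
        assert total_variation(dict(zip(support, pmf)),
                               dict(zip(support, emp))) < 0.02

    def test_paths_internally_monotone(self, table5):
        spec = reverse_start(table5, pair=(1, 3), option=2)
        s = reverse_fill(spec, 300, 3)
        assert np.all(np.diff(s, axis=3) >= 0)
        assert np.all(s >= 0)


class TestConsistency:
    def test_observed_history_is_consistent(self, table5):
        # the real dataset must survive its own deletion rules
        spec = reverse_start(table5, option=1)
        kc = spec.k_check
        s = np.zeros((1, 4, 4, kc), dtype=np.int64)
        for a in range(1, 5):
            arm = table5.arm(a)
            ka = arm.last_interim
            s[0, a - 1, :, :ka] = arm.cum_s
            s[0, a - 1, :, ka:] = arm.cum_s[:, ka - 1][:, None]
        assert is_consistent(s, spec)[0]

    def test_two_arm_boundary_crossing_deleted(self, two_arm):
        spec = two_arm_start(two_arm, 2, 35, 59)
        s = np.zeros((2, 2, 1, 2), dtype=np.int64)
        s[:, 0, 0, 1] = 35
        s[:, 1, 0, 1] = 59
        s[0, 0, 0, 0], s[0, 1, 0, 0] = 0, 36   # Z1 = -18: stopped early
        s[1, 0, 0, 0], s[1, 1, 0, 0] = 17, 29  # Z1 = -6: interior
        mask = is_consistent(s, spec)
        assert not mask[0] and mask[1]

    def test_conditional_distribution_matches_enumeration(self):
        # exhaustive forward oracle on the enumerable toy trial
        oracle_lo = forward_conditional_first_interim((3, 2), p=0.3)
        oracle_hi = forward_conditional_first_interim((3, 2), p=0.7)
        # sufficiency: the conditional law does not depend on p
        for k in oracle_lo:
            assert oracle_lo[k] == pytest.approx(oracle_hi[k], abs=1e-12)
        spec = two_arm_start(TOY_DESIGN, 2, 3, 2, per_arm=2)
        s = reverse_fill(spec, 60_000, 4)
        mask = is_consistent(s, spec)
        kept = s[mask]
        emp = {}
        for s1, s2 in kept[:, :, 0, 0]:
            emp[(int(s1), int(s2))] = emp.get((int(s1), int(s2)), 0) + 1
        emp = {k: v / len(kept) for k, v in emp.items()}
        assert total_variation(oracle_lo, emp) < 0.015


class TestRB2Estimate:
    def test_two_arm_worked_case1(self, two_arm):
        spec = two_arm_start(two_arm, 2, 35, 59)
        est = rb2_estimate(spec, [(1, 2)], 100_000, 5)[(1, 2)]
        assert 100 * est.prop_complete == pytest.approx(99.3, abs=0.3)
        assert est.theta_tilde == pytest.approx(-1.473, abs=0.02)
        assert est.se == pytest.approx(0.383, abs=0.02)
        assert est.reliable

    def test_stop_at_first_interim_reduces_to_naive(self, two_arm):
        h = simulate_two_arm_trial(two_arm, 1.0, 0.0, 0)
        assert h.K == 1
        naive, _ = naive_analysis(h, (1, 2))
        spec = reverse_start(h)
        est = rb2_estimate(spec, [(1, 2)], 500, 1)[(1, 2)]
        assert est.theta_tilde == pytest.approx(naive.theta_hat, abs=1e-12)
        assert est.se == pytest.approx(naive.se, abs=1e-12)
        assert est.prop_complete == 1.0

    def test_reproducible_and_chunk_stable(self, two_arm):
        spec = two_arm_start(two_arm, 2, 35, 59)
        e1 = rb2_estimate(spec, [(1, 2)], 20_000, 7)[(1, 2)]
        e2 = rb2_estimate(spec, [(1, 2)], 20_000, 7)[(1, 2)]
        assert e1.theta_tilde == e2.theta_tilde
        assert e1.n_complete == e2.n_complete
        e3 = rb2_estimate(spec, [(1, 2)], 20_000, 8, chunk_size=3000)[(1, 2)]
        assert e3.prop_complete == pytest.approx(e1.prop_complete, abs=0.01)

    def test_unreliable_flag_below_threshold(self, two_arm):
        spec = two_arm_start(two_arm, 2, 35, 59)
        est = rb2_estimate(spec, [(1, 2)], 300, 2)[(1, 2)]
        assert not est.reliable

    def test_multiarm_option2_start_anchors(self, table5):
        spec = reverse_start(table5, pair=(1, 3), option=2)
        np.testing.assert_array_equal(spec.anchors, [12, 4, 12, 5])
        spec12 = reverse_start(table5, pair=(1, 2), option=2)
        np.testing.assert_array_equal(spec12.anchors, [4, 4, 4, 4])

    def test_stratified_estimate_uses_adjusted_information(self, table5):
        spec = reverse_start(table5, pair=(1, 2), option=2)
        plain = rb2_estimate(spec, [(1, 2)], 5_000, 3,
                             stratified=False)[(1, 2)]
        adj = rb2_estimate(spec, [(1, 2)], 5_000, 3)[(1, 2)]
        # same filter, different information weighting
        assert adj.prop_complete == plain.prop_complete
        assert adj.mean_inv_v1 != plain.mean_inv_v1

    def test_success_probability_estimates_returned(self, two_arm):
        spec = two_arm_start(two_arm, 2, 35, 59)
        est = rb2_estimate(spec, [(1, 2)], 10_000, 6)[(1, 2)]
        assert 0.3 < est.p_hat[1] < 0.7
        assert 0.6 < est.p_hat[2] < 1.0
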