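import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seqelim.design_core import (
    CONTINUE,
    I_BETTER,
    J_BETTER,
    NO_DIFFERENCE,
    PairwiseBoundary,
    adjusted_information,
    boundary_geometry,
    classify_pair,
    get_design,
    implied_sample_increment,
    pair_statistics,
)

FOUR = get_design("four_arm_sepsis").boundary
TWO = get_design("two_arm_tri").boundary


class TestPairStatistics:
    @pytest.mark.parametrize(
        "ci, cj, z, v",
        [
            ([(72, 35)], [(72, 59)], -12.0, 8.160),      # two-arm case 1
            ([(41, 35)], [(39, 25)], 4.25, 3.75),        # worked centre 1
            ([(36, 23)], [(36, 0)], 11.5, 3.913),
        ],
    )
    def test_single_stratum(self, ci, cj, z, v):
        st_ = pair_statistics(ci, cj)
        assert st_.z == pytest.approx(z, abs=5e-3)
        assert st_.v == pytest.approx(v, abs=5e-3)

    def test_stratified_totals_sum_components(self, table5):
        from seqelim.estimators import select_comparison_data

        ci, cj, k = select_comparison_data(table5, (1, 2), option=2)
        st_ = pair_statistics(ci, cj, pair=(1, 2), interim=k)
        assert k == 4
        assert st_.z == pytest.approx(np.sum(st_.z_c))
        assert st_.z == pytest.approx(14.38, abs=5e-3)
        assert st_.v == pytest.approx(16.28, abs=5e-3)

    def test_equal_arms_equal_successes_give_zero_score(self):
        st_ = pair_statistics([(50, 20)], [(50, 20)])
        assert st_.z == 0.0

    def test_empty_stratum_contributes_nothing(self):
        with_empty = pair_statistics([(72, 35), (0, 0)], [(72, 59), (0, 0)])
        plain = pair_statistics([(72, 35)], [(72, 59)])
        assert with_empty.z == plain.z
        assert with_empty.v == plain.v

    @pytest.mark.parametrize("bad_i, bad_j", [
        ([(10, 12)], [(10, 3)]),    # S > n
        ([(10, -1)], [(10, 3)]),    # negative successes
    ])
    def test_invalid_counts_rejected(self, bad_i, bad_j):
        with pytest.raises(ValueError):
            pair_statistics(bad_i, bad_j)

    @given(
        counts=st.lists(
            st.tuples(st.integers(0, 60), st.integers(0, 60),
                      st.integers(0, 60), st.integers(0, 60)),
            min_size=1, max_size=4,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_antisymmetry(self, counts):
        ci = [(n + s, min(s, n + s)) for n, s, _, _ in counts]
        cj = [(m + t, min(t, m + t)) for _, _, m, t in counts]
        if not any(a[0] + b[0] > 0 for a, b in zip(ci, cj)):
            return
        ij = pair_statistics(ci, cj)
        ji = pair_statistics(cj, ci)
        assert ij.z == pytest.approx(-ji.z)
        assert ij.v == pytest.approx(ji.v)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_information_monotone_over_nested_histories(self, seed):
        # accumulate random responses; total V never decreases
        rng = np.random.default_rng(seed)
        n_i = n_j = 0
        s_i = s_j = 0
        last_v = 0.0
        for _ in range(6):
            add = int(rng.integers(1, 40))
            n_i += add
            n_j += add
            s_i += int(rng.binomial(add, 0.55))
            s_j += int(rng.binomial(add, 0.45))
            v = pair_statistics([(n_i, s_i)], [(n_j, s_j)]).v
            assert v >= last_v - 1e-12
            last_v = v


class TestAdjustedInformation:
    def test_worked_value(self):
        # V = 9*9*12*6/18^3 = 1, V' = V * 18/17
        vp_c, vp = adjusted_information([(9, 8)], [(9, 4)])
        v = pair_statistics([(9, 8)], [(9, 4)]).v
        assert v == pytest.approx(1.0)
        assert vp == pytest.approx(18 / 17)

    @given(
        n_i=st.integers(1, 50), k_i=st.integers(0, 50),
        n_j=st.integers(1, 50), k_j=st.integers(0, 50),
    )
    @settings(max_examples=80, deadline=None)
    def test_identity_v_prime_is_v_scaled(self, n_i, k_i, n_j, k_j):
        s_i, s_j = min(k_i, n_i), min(k_j, n_j)
        v = pair_statistics([(n_i, s_i)], [(n_j, s_j)]).v
        _, vp = adjusted_information([(n_i, s_i)], [(n_j, s_j)])
        n = n_i + n_j
        if n > 1:
            assert vp == pytest.approx(v * n / (n - 1))

    def test_degenerate_strata(self):
        _, vp = adjusted_information([(5, 5)], [(5, 5)])
        assert vp == 0.0  # all successes: no information
        _, vp1 = adjusted_information([(1, 1)], [(0, 0)])
        assert vp1 == 0.0  # single patient


class TestClassification:
    @pytest.mark.parametrize(
        "s1, expect",
        [(23, I_BETTER), (22, CONTINUE)],
    )
    def test_first_interim_elimination_threshold(self, s1, expect):
        # minimal evidence to eliminate at the very first analysis
        st_ = pair_statistics([(36, s1)], [(36, 0)])
        assert classify_pair(st_, FOUR) == expect

    @pytest.mark.parametrize(
        "z, v, expect",
        [
            (0.0, 4.44, CONTINUE),       # origin: inside the triangle
            (0.0, 30.0, NO_DIFFERENCE),  # interval nonempty beyond 29.36
            (0.0, 8.8, CONTINUE),        # interval still empty
            (-14.0, 16.28, J_BETTER),
        ],
    )
    def test_symmetric_regions(self, z, v, expect):
        assert classify_pair((z, v), FOUR) == expect

    def test_mirror_symmetry(self):
        for z, v in [(11.5, 3.9), (-3.0, 31.0), (2.0, 10.0), (14.4, 16.3)]:
            d = classify_pair((z, v), FOUR)
            m = classify_pair((-z, v), FOUR)
            mirror = {I_BETTER: J_BETTER, J_BETTER: I_BETTER}
            assert m == mirror.get(d, d)

    def test_zero_information_continues(self):
        assert classify_pair((0.0, 0.0), FOUR) == CONTINUE

    def test_one_sided_upper_precedence_past_apex(self):
        # beyond the apex both inequalities hold together; efficacy wins
        v, z = 120.0, 30.0
        assert z >= TWO.a + TWO.b_outer * v
        assert z <= -TWO.a + TWO.b_inner * v
        assert classify_pair((z, v), TWO) == I_BETTER


class TestGeometry:
    def test_two_arm_apex(self):
        assert boundary_geometry(TWO)["v_meet"] == pytest.approx(88.8380,
                                                                 abs=5e-4)

    def test_no_difference_impossible_through_interim_six(self):
        geom = boundary_geometry(FOUR)
        assert geom["v_nodiff_min"] == pytest.approx(29.356, abs=5e-3)
        assert geom["v_nodiff_min"] > 6 * 4.40337

    def test_apex_linear_in_intercept(self):
        r1 = PairwiseBoundary(5.0, 0.1, 0.4, symmetric=False)
        r2 = PairwiseBoundary(10.0, 0.1, 0.4, symmetric=False)
        assert boundary_geometry(r2)["v_meet"] == pytest.approx(
            2 * boundary_geometry(r1)["v_meet"])

    def test_parallel_boundaries_rejected(self):
        with pytest.raises(ValueError):
            PairwiseBoundary(5.0, 0.3, 0.3)


class TestImpliedIncrement:
    @pytest.mark.parametrize("p1, p2", [(0.40, 0.50), (0.50, 0.60)])
    def test_design_increment(self, p1, p2):
        n = implied_sample_increment(4.40337, p1, p2)
        assert n == pytest.approx(35.58, abs=5e-3)

    def test_linear_in_information(self):
        assert implied_sample_increment(8.0, 0.4, 0.5) == pytest.approx(
            2 * implied_sample_increment(4.0, 0.4, 0.5))

    def test_degenerate_probabilities_rejected(self):
        with pytest.raises(ValueError):
            implied_sample_increment(4.4, 0.0, 0.0)
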