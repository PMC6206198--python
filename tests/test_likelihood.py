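"""Likelihood kernels: hand-derived cells, exhaustive oracle, identities."""

import itertools
import math
from collections import defaultdict

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bandfec as bf
from bandfec.likelihood import DemographicParams

probs = st.floats(0.01, 0.99)


def params_const(S_j=0.5, S_a=0.6, r_j=0.1, r_a=0.05, p_j=0.5, p_a=0.5, c_j=0.5):
    return DemographicParams.constant(S_j, S_a, r_j, r_a, p_j, p_a, c_j)


class TestCellProbs:
    def test_certain_death_certain_reporting(self):
        assert bf.adult_cell_probs(0.0, 1.0, 0, 1).tolist() == [1.0, 0.0]

    def test_adult_hand_product(self):
        cells = bf.adult_cell_probs(0.6, 0.05, 0, 2)
        np.testing.assert_allclose(cells, [0.02, 0.012, 0.968])

    def test_no_reporting_never_one(self):
        cells = bf.adult_cell_probs(0.7, 0.0, 0, 3)
        assert cells[:-1].sum() == 0.0 and cells[-1] == 1.0

    def test_juvenile_hand_product(self):
        cells = bf.juvenile_cell_probs(0.5, 0.1, 0.6, 0.05, 0, 3)
        np.testing.assert_allclose(cells, [0.05, 0.01, 0.006, 0.934])

    def test_certain_first_year_survival_kills_first_cell(self):
        cells = bf.juvenile_cell_probs(1.0, 0.9, 0.6, 0.05, 0, 3)
        assert cells[0] == 0.0

    @given(S=probs, r=probs)
    def test_juvenile_degenerates_to_adult(self, S, r):
        juv = bf.juvenile_cell_probs(S, r, S, r, 0, 4)
        ad = bf.adult_cell_probs(S, r, 0, 4)
        np.testing.assert_allclose(juv, ad, atol=1e-14)

    @given(S_j=probs, S_a=probs, r_j=probs, r_a=probs,
           t=st.integers(0, 3), T=st.integers(4, 8))
    def test_cells_sum_to_one(self, S_j, S_a, r_j, r_a, t, T):
        for cells in (
            bf.adult_cell_probs(S_a, r_a, t, T),
            bf.juvenile_cell_probs(S_j, r_j, S_a, r_a, t, T),
            bf.collapsed_cell_probs(params_const(S_j, S_a, r_j, r_a), "juvenile", T - t),
            bf.collapsed_cell_probs(params_const(S_j, S_a, r_j, r_a), "adult", T - t),
        ):
            assert abs(cells.sum() - 1.0) < 1e-12
            assert (cells >= 0).all()

    def test_collapsed_adult_single_lag(self):
        cells = bf.collapsed_cell_probs(params_const(S_a=0.6, r_a=0.05), "adult", 1)
        np.testing.assert_allclose(cells, [0.02, 0.98])

    def test_collapsed_matches_full_juvenile_cells(self):
        cells = bf.collapsed_cell_probs(params_const(), "juvenile", 3)
        np.testing.assert_allclose(cells, [0.05, 0.01, 0.006, 0.934])

    def test_horizon_before_cohort_errors(self):
        with pytest.raises(ValueError):
            bf.adult_cell_probs(0.5, 0.1, 3, 2)
        with pytest.raises(ValueError):
            bf.collapsed_cell_probs(params_const(), "adult", 0)

    def test_matrix_matches_per_cohort(self):
        rng = np.random.default_rng(0)
        T = 5
        p = DemographicParams(rng.uniform(0.2, 0.8, T), rng.uniform(0.2, 0.8, T),
                              rng.uniform(0.01, 0.3, T), rng.uniform(0.01, 0.3, T),
                              0.5, 0.5, np.array([0.5]))
        for age in ("juvenile", "adult"):
            m = bf.MArray(age, np.arange(T), np.ones(T, int), np.zeros((T, T), int))
            P = bf.cell_prob_matrix(m, p)
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
            for t in range(T):
                if age == "adult":
                    cells = bf.adult_cell_probs(p.S_a, p.r_a, t, T)
                else:
                    cells = bf.juvenile_cell_probs(p.S_j[t], p.r_j[t], p.S_a, p.r_a, t, T)
                np.testing.assert_allclose(P[t, t:T], cells[:-1], atol=1e-13)
                np.testing.assert_allclose(P[t, T], cells[-1], atol=1e-13)


# ---------------------------------------------------------------------------
# exhaustive individual-fate oracle


def _fate_category_probs(age, S_j, r_j, S_a, r_a, t, T):
    """Path-enumeration probabilities: category k = first recovered at occasion
    k (t <= k < T); category 'never' = dead-unreported or survived the study."""
    cat = defaultdict(float)
    for d in range(t, T):  # death year
        alive = 1.0
        for y in range(t, d):
            alive *= S_j if (age == "juvenile" and y == t) else S_a
        s_d = S_j if (age == "juvenile" and d == t) else S_a
        r_d = r_j if (age == "juvenile" and d == t) else r_a
        cat[d] += alive * (1.0 - s_d) * r_d
        cat["never"] += alive * (1.0 - s_d) * (1.0 - r_d)
    alive = 1.0
    for y in range(t, T):
        alive *= S_j if (age == "juvenile" and y == t) else S_a
    cat["never"] += alive
    return cat


def _brute_force_cohort_ll(age, S_j, r_j, S_a, r_a, t, T, row, never):
    cats = list(range(t, T)) + ["never"]
    p = _fate_category_probs(age, S_j, r_j, S_a, r_a, t, T)
    target = {k: row[k] for k in range(t, T)}
    target["never"] = never
    R = sum(target.values())
    total = 0.0
    for assignment in itertools.product(cats, repeat=R):
        counts = defaultdict(int)
        for c in assignment:
            counts[c] += 1
        if all(counts[c] == target[c] for c in cats):
            prob = 1.0
            for c in assignment:
                prob *= p[c]
            total += prob
    return math.log(total) if total > 0 else -math.inf


@st.composite
def small_marray_case(draw):
    T = draw(st.integers(1, 3))
    age = draw(st.sampled_from(["juvenile", "adult"]))
    releases = [draw(st.integers(0, 4)) for _ in range(T)]
    m = np.zeros((T, T), dtype=int)
    for t in range(T):
        left = releases[t]
        for k in range(t, T):
            c = draw(st.integers(0, left))
            m[t, k] = c
            left -= c
    S_j, S_a, r_j, r_a = (draw(probs) for _ in range(4))
    return age, np.array(releases), m, S_j, S_a, r_j, r_a


class TestRecoveryLoglik:
    def test_empty_marray_zero(self):
        m = bf.MArray("adult", [1, 2], [0, 0], np.zeros((2, 2), int))
        assert bf.recovery_loglik(None, m, params_const()) == 0.0

    def test_single_cohort_binomial_by_hand(self):
        # R=2, one recovered in the only occasion: cell prob 0.02
        m = bf.MArray("adult", [1], [2], [[1]])
        ll = bf.recovery_loglik(None, m, params_const(S_a=0.6, r_a=0.05))
        assert ll == pytest.approx(math.log(2 * 0.02 * 0.98))

    def test_zero_prob_cell_with_count_gives_neg_inf(self):
        m = bf.MArray("adult", [1], [2], [[1]])
        assert bf.recovery_loglik(None, m, params_const(r_a=0.0)) == -math.inf

    @settings(max_examples=40)
    @given(case=small_marray_case())
    def test_matches_exhaustive_fate_enumeration(self, case):
        age, releases, m, S_j, S_a, r_j, r_a = case
        T = len(releases)
        arr = bf.MArray(age, np.arange(1, T + 1), releases, m)
        p = params_const(S_j, S_a, r_j, r_a)
        juv = arr if age == "juvenile" else None
        ad = arr if age == "adult" else None
        got = bf.recovery_loglik(juv, ad, p)
        expected = sum(
            _brute_force_cohort_ll(
                age, S_j, r_j, S_a, r_a, t, T, m[t], releases[t] - m[t].sum()
            )
            for t in range(T)
        )
        assert got == pytest.approx(expected, rel=1e-9)

    def test_additive_over_age_classes(self, toy_marray):
        juv = bf.MArray("juvenile", [1, 2, 3], [5, 5, 5], np.eye(3, dtype=int))
        p = params_const()
        assert bf.recovery_loglik(juv, toy_marray, p) == pytest.approx(
            bf.recovery_loglik(juv, None, p) + bf.recovery_loglik(None, toy_marray, p)
        )

    def test_collapsed_equals_full_single_cohort(self):
        # one cohort: collapsing is the identity, so the likelihood functions agree
        m = bf.MArray("juvenile", [1], [20], [[3]])
        c = bf.collapse_marray(m)
        for S_j, r_j in [(0.3, 0.2), (0.5, 0.1), (0.8, 0.4)]:
            p = params_const(S_j=S_j, r_j=r_j)
            assert bf.recovery_loglik(c, None, p) == pytest.approx(
                bf.recovery_loglik(m, None, p)
            )

    def test_collapsed_exact_vs_pooled_horizons(self, toy_marray):
        # with unequal horizons the exact per-cohort form differs from pooled
        c = bf.collapse_marray(toy_marray)
        p = params_const()
        exact = bf.recovery_loglik(None, c, p)
        pooled = bf.recovery_loglik(None, c, p, pooled_collapsed=True)
        assert np.isfinite(exact) and np.isfinite(pooled)
        assert exact != pytest.approx(pooled)


class TestBinomialComponents:
    def test_recapture_zero_counts_zero_prob(self):
        rs = bf.RecaptureSummary.from_counts(10, 0, 5, 0)
        assert bf.recapture_loglik(rs, 0.0, 0.0) == 0.0

    def test_recapture_hand_value(self):
        rs = bf.RecaptureSummary.from_counts(10, 1, 10, 0)
        ll = bf.recapture_loglik(rs, 0.1, 0.0)
        assert ll == pytest.approx(math.log(10 * 0.1 * 0.9**9))

    def test_recapture_mle_at_f2_over_M(self):
        rs = bf.RecaptureSummary.from_counts(50, 7, 40, 4)
        grid = np.linspace(0.01, 0.5, 200)
        lls = [bf.recapture_loglik(rs, p, 4 / 40) for p in grid]
        assert abs(grid[int(np.argmax(lls))] - 7 / 50) < 0.01

    def test_agecomp_hand_value(self):
        assert bf.age_composition_loglik(1, 1, 0.25) == pytest.approx(
            math.log(2 * 0.25 * 0.75)
        )

    def test_agecomp_symmetric_maximizer(self):
        grid = np.linspace(0.05, 0.95, 181)
        lls = [bf.age_composition_loglik(30, 30, c) for c in grid]
        assert abs(grid[int(np.argmax(lls))] - 0.5) < 0.01

    def test_agecomp_impossible_is_neg_inf(self):
        assert bf.age_composition_loglik(3, 1, 0.0) == -math.inf

    def test_agecomp_per_year_sums(self):
        Mj, Ma = [3, 5], [4, 2]
        total = bf.age_composition_loglik(Mj, Ma, [0.4, 0.6])
        parts = bf.age_composition_loglik(3, 4, 0.4) + bf.age_composition_loglik(5, 2, 0.6)
        assert total == pytest.approx(parts)


class TestDerive:
    def test_lambda_one_at_study_truths(self):
        p = params_const(S_j=0.5, S_a=0.6, p_j=0.01, p_a=0.01, c_j=4 / 9)
        d = bf.derive(p)
        # c/(1-c) = 0.8 with V = 1
        assert d.F[0] == pytest.approx(0.8)
        assert d.lam[0] == pytest.approx(1.0)

    def test_no_vulnerability_adjustment(self):
        d = bf.derive(params_const(p_j=0.3, p_a=0.3, c_j=0.6))
        assert d.V == pytest.approx(1.0)
        assert d.F[0] == pytest.approx(0.6 / 0.4)

    def test_arithmetic_example(self):
        d = bf.derive(params_const(p_j=0.4, p_a=0.2, c_j=2 / 3))
        assert d.V == pytest.approx(2.0)
        assert d.F[0] == pytest.approx(1.0)

    @given(S_j=probs, S_a=probs, p_j=probs, p_a=probs, c_j=probs)
    def test_lambda_identity(self, S_j, S_a, p_j, p_a, c_j):
        d = bf.derive(params_const(S_j=S_j, S_a=S_a, p_j=p_j, p_a=p_a, c_j=c_j))
        assert d.lam[0] - S_a - d.F[0] * S_j == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            bf.derive(params_const(p_a=0.0))
        with pytest.raises(ValueError):
            bf.derive(params_const(c_j=1.0))
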