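"""Distances, scores, matrices and the greedy matchers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from admixpair import (
    Cohort,
    CohortTooSmallError,
    DimensionMismatchError,
    Individual,
    MatchConfig,
    build_gd_matrix,
    build_score_matrix,
    generate_base,
    genetic_distance,
    pair_score,
    pam_full,
    pam_simple,
    perturb,
)
from conftest import brute_force_min_gd, random_cohort


def ind(vec, id="x", age=None, gender=None):
    return Individual(id, np.asarray(vec, dtype=float), age=age, gender=gender)


E = np.eye(9)


class TestGeneticDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (E[0], E[0], 0.0),
            (E[0], E[1], 2.0),  # two disjoint unit vectors: two unit deviations
            (
                [0.5, 0.5, 0, 0, 0, 0, 0, 0, 0],
                [0.4, 0.6, 0, 0, 0, 0, 0, 0, 0],
                0.02,  # 0.1^2 + 0.1^2
            ),
        ],
    )
    def test_values(self, a, b, expected):
        d = genetic_distance(ind(a, "a"), ind(b, "b"))
        assert d == pytest.approx(expected, abs=1e-12)
        assert genetic_distance(ind(b, "b"), ind(a, "a")) == pytest.approx(d)

    def test_dimension_mismatch(self):
        with pytest.raises(DimensionMismatchError):
            genetic_distance(ind([0.5, 0.5], "a"), ind([0.5, 0.25, 0.25], "b"))


class TestPairScore:
    def test_ideal_pair_scores_ten(self):
        a = ind(E[0], "a", age=30, gender=1)
        b = ind(E[0], "b", age=33, gender=1)
        assert pair_score(a, b) == 10

    def test_age_outside_window_loses_demographic_point(self):
        a = ind(E[0], "a", age=30, gender=1)
        b = ind(E[0], "b", age=36, gender=1)
        assert pair_score(a, b) == 9

    def test_six_matching_components_scores_seven(self):
        # six equal components; three differ by 0.05 / 0.025 / 0.025 (all > 1%)
        a = ind([0.2, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1], "a", age=30, gender=2)
        b = ind([0.25, 0.075, 0.075, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1], "b", age=30, gender=2)
        assert pair_score(a, b) == 7

    def test_nothing_matches_scores_zero(self):
        a = ind([0.5, 0.3, 0.2, 0, 0, 0, 0, 0, 0], "a", age=30, gender=1)
        b = ind([0.3, 0.5, 0.05, 0.15, 0, 0, 0, 0, 0], "b", age=30, gender=2)
        # zero components agree within 1%... except the five shared zeros
        assert pair_score(a, b) == 5
        c = ind(np.full(9, 1 / 9), "c", age=30, gender=2)
        d = ind([0.13, 0.131, 0.129, 0.13, 0.1, 0.1, 0.1, 0.09, 0.09], "d", age=70, gender=1)
        assert pair_score(c, d) == 0

    def test_missing_age_or_gender_withholds_demographic_point(self):
        a = ind(E[0], "a", age=30, gender=None)
        b = ind(E[0], "b", age=30, gender=1)
        assert pair_score(a, b) == 9
        c = ind(E[0], "c", age=None, gender=1)
        assert pair_score(c, b) == 9

    def test_inclusive_boundaries(self):
        cfg = MatchConfig()
        a = ind([0.5, 0.5, 0, 0, 0, 0, 0, 0, 0], "a", age=30, gender=1)
        b = ind([0.51, 0.49, 0, 0, 0, 0, 0, 0, 0], "b", age=35, gender=1)
        # |delta age| = 5 and |delta comp| = 0.01 both count (<= comparisons)
        assert pair_score(a, b, cfg) == 10


class TestMatrices:
    def test_gd_matrix_properties(self):
        cohort = random_cohort(12, K=5, seed=3)
        gd = build_gd_matrix(cohort)
        assert np.array_equal(gd, gd.T)
        assert np.all(np.diag(gd) == 0)
        assert np.all(gd >= 0) and np.all(gd <= 2)
        assert gd[2, 7] == pytest.approx(genetic_distance(cohort[2], cohort[7]))

    def test_unit_vector_cohort_all_off_diagonal_two(self):
        cohort = Cohort.from_arrays(E[:3])
        gd = build_gd_matrix(cohort)
        off = gd[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 2.0)

    def test_score_matrix_of_clones_is_all_ten(self, dataset1):
        sub = Cohort(dataset1.cohort.individuals[:20])
        score = build_score_matrix(sub)
        assert score.max() == 10
        assert np.all(np.diag(score) == 10)
        true_pairs = score[np.arange(0, 20, 2), np.arange(1, 20, 2)]
        assert np.all(true_pairs == 10)

    def test_score_matrix_symmetric(self):
        cohort = random_cohort(15, seed=4)
        score = build_score_matrix(cohort)
        assert np.array_equal(score, score.T)

    def test_too_small_cohort(self):
        solo = Cohort([ind(E[0], "only", age=30, gender=1)])
        with pytest.raises(CohortTooSmallError):
            build_gd_matrix(solo)
        with pytest.raises(CohortTooSmallError):
            pam_simple(solo)


class TestPamSimple:
    def test_clone_cohort_reaches_optimum(self, dataset1):
        sol = pam_simple(dataset1.cohort)
        assert sol.n_pairs == 500
        assert sol.total_gd <= 1e-9
        assert sol.total_score == 5000
        assert sol.unpaired == []

    def test_odd_cohort_leaves_one_unpaired(self):
        sol = pam_simple(random_cohort(7, seed=5))
        assert sol.n_pairs == 3
        assert len(sol.unpaired) == 1

    def test_threshold_rejects_low_scoring_pair(self):
        # two individuals agreeing on 4 shared-zero components only: score 4
        a = ind([0.4, 0.3, 0.2, 0.1, 0, 0, 0, 0, 0], "a", age=30, gender=1)
        b = ind([0.1, 0.2, 0.4, 0.25, 0.05, 0, 0, 0, 0], "b", age=50, gender=1)
        assert pair_score(a, b) == 4
        sol = pam_simple(Cohort([a, b]), MatchConfig(threshold=7))
        assert sol.pairs == []
        assert sorted(sol.unpaired) == ["a", "b"]

    def test_tie_breaks_to_lowest_column_index(self):
        # row 0 is equidistant (GD 0.02) from rows 1 and 2: must take row 1
        cohort = Cohort(
            [
                ind([0.5, 0.5], "a"),
                ind([0.6, 0.4], "b"),
                ind([0.4, 0.6], "c"),
                ind([0.7, 0.3], "d"),
            ]
        )
        sol = pam_simple(cohort)
        assert {(p.id_a, p.id_b) for p in sol.pairs} == {("a", "b"), ("c", "d")}

    def test_unpaired_count_monotone_in_threshold(self):
        ds = perturb(generate_base(40, seed=6), 0.11)
        counts = [
            len(pam_simple(ds.cohort, MatchConfig(threshold=t)).unpaired)
            for t in range(11)
        ]
        assert counts == sorted(counts)
        assert len(pam_simple(ds.cohort).unpaired) == counts[0] == 0

    def test_total_gd_nondecreasing_in_perturbation(self):
        grid = (0.0, 0.05, 0.11, 0.2)
        means = []
        for x in grid:
            totals = [
                pam_simple(perturb(generate_base(30, seed=s), x).cohort).total_gd
                for s in range(10)
            ]
            means.append(np.mean(totals))
        assert all(a <= b + 1e-12 for a, b in zip(means, means[1:]))


class TestPamFull:
    def test_clone_cohort_reaches_global_floor(self):
        ds = generate_base(25, seed=7)
        sol = pam_full(ds.cohort, MatchConfig(seed=1))
        assert sol.total_gd <= 1e-9
        assert sol.total_score == 250
        assert sol.unpaired == []

    def test_deterministic_under_fixed_seed(self):
        cohort = random_cohort(20, seed=8)
        cfg = MatchConfig(seed=123)
        s1, s2 = pam_full(cohort, cfg), pam_full(cohort, cfg)
        assert s1.pairs == s2.pairs and s1.unpaired == s2.unpaired

    def test_never_worse_than_any_internal_candidate(self):
        cohort = random_cohort(14, seed=9)
        sol, trace = pam_full(cohort, MatchConfig(seed=3), return_trace=True)
        assert sol.total_gd == min(trace)
        assert sol.total_gd <= trace[0]

    def test_usually_at_least_as_good_as_single_sweep(self):
        wins = 0
        for s in range(100):
            cohort = random_cohort(6, seed=1000 + s)
            simple = pam_simple(cohort).total_gd
            full = pam_full(cohort, MatchConfig(seed=s)).total_gd
            wins += full <= simple + 1e-12
        assert wins > 50


class TestOracleBound:
    @pytest.mark.parametrize("n", [4, 6, 8])
    def test_greedy_never_beats_brute_force(self, n):
        for s in range(10):
            cohort = random_cohort(n, K=4, seed=200 + s)
            gd = build_gd_matrix(cohort)
            opt = brute_force_min_gd(gd)
            assert pam_simple(cohort).total_gd >= opt - 1e-12
            assert pam_full(cohort, MatchConfig(seed=s)).total_gd >= opt - 1e-12

    def test_equality_on_clone_cohorts(self):
        ds = generate_base(4, seed=10)
        gd = build_gd_matrix(ds.cohort)
        assert brute_force_min_gd(gd) == pytest.approx(0.0, abs=1e-12)
        assert pam_simple(ds.cohort).total_gd == pytest.approx(0.0, abs=1e-12)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    n=st.integers(2, 12),
    k=st.integers(2, 6),
    seed=st.integers(0, 10_000),
    threshold=st.one_of(st.none(), st.integers(0, 10)),
)
def test_solution_partitions_cohort(n, k, seed, threshold):
    """pairs and unpaired always partition the cohort; threshold is enforced."""
    cohort = random_cohort(n, K=k, seed=seed)
    sol = pam_simple(cohort, MatchConfig(threshold=threshold))
    covered = sorted(sol.ids())
    assert covered == sorted(cohort.ids)
    assert 2 * sol.n_pairs + len(sol.unpaired) == n
    if threshold is not None:
        assert all(p.score >= threshold for p in sol.pairs)
    assert sol.total_gd == pytest.approx(sum(p.gd for p in sol.pairs), abs=1e-9)
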