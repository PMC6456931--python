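"""Calibration statistics: hit-count expectations, waiting-time and
random-walk distributions, and the derived (rho, delta) thresholds."""

import numpy as np
import pytest

from groupseed.stats import (
    ErrorModel,
    GroupCriteria,
    diagonal_shift_distribution,
    diagonal_shift_probability,
    expected_overlap_hits,
    expected_random_hits,
    match_probability,
    recommend_filter_threshold,
    solve_delta,
    solve_rho,
    waiting_time_distribution,
)


class TestMatchProbability:
    @pytest.mark.parametrize(
        "epsilon, k, expected",
        [
            (0.0, 15, 1.0),
            (0.15, 1, 0.85**2 + 0.15**2 / 3),  # 0.73
            (0.15, 15, (0.85**2 + 0.15**2 / 3) ** 15),  # ~8.91e-3
        ],
    )
    def test_values(self, epsilon, k, expected):
        assert match_probability(epsilon, k) == pytest.approx(expected, rel=1e-12)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            match_probability(0.1, 0)
        with pytest.raises(ValueError):
            match_probability(1.0, 5)
        with pytest.raises(ValueError):
            match_probability(-0.1, 5)


class TestExpectedHits:
    @pytest.mark.parametrize(
        "len_a, len_b, k, expected",
        [
            (0, 0, 15, 0.0),
            (1, 1, 1, 0.25),
            (2000, 2000, 15, 4e6 / 4**15),  # ~3.73e-3
        ],
    )
    def test_random(self, len_a, len_b, k, expected):
        assert expected_random_hits(len_a, len_b, k) == pytest.approx(expected)

    def test_overlap_example(self):
        got = expected_overlap_hits(500, 2000, 2000, 0.15, 15)
        want = match_probability(0.15, 15) * 500 + 4e6 / 4**15
        assert got == pytest.approx(want)
        assert got == pytest.approx(4.46, abs=0.01)

    @pytest.mark.parametrize("length", [100, 2000, 9999])
    @pytest.mark.parametrize("epsilon", [0.0, 0.1, 0.3])
    @pytest.mark.parametrize("k", [5, 15])
    def test_zero_overlap_reduces_to_random(self, length, epsilon, k):
        assert expected_overlap_hits(0, length, length, epsilon, k) == pytest.approx(
            expected_random_hits(length, length, k), rel=1e-14
        )

    def test_error_free_overlap_adds_full_signal(self):
        m = 700
        got = expected_overlap_hits(m, 2000, 3000, 0.0, 15)
        assert got == pytest.approx(m + expected_random_hits(2000, 3000, 15))

    def test_rejects_oversized_overlap(self):
        with pytest.raises(ValueError):
            expected_overlap_hits(2001, 2000, 3000, 0.1, 15)


class TestWaitingTime:
    @pytest.mark.parametrize("p, k", [(0.85, 9), (0.5, 3), (0.95, 5)])
    def test_support_and_head(self, p, k):
        dist = waiting_time_distribution(p, k, 400)
        assert np.all(dist.mass[:k] == 0.0)
        assert dist.mass[k] == pytest.approx(p**k)

    def test_deterministic_matches(self):
        dist = waiting_time_distribution(1.0, 9, 50)
        assert dist.mass[9] == 1.0
        assert dist.mass.sum() == 1.0

    @pytest.mark.parametrize("p, k", [(0.7, 5), (0.85, 9), (0.95, 5)])
    def test_cumulative_is_a_cdf(self, p, k):
        mean_wait = (1 - p**k) / ((1 - p) * p**k)
        dist = waiting_time_distribution(p, k, int(40 * mean_wait))
        cdf = dist.cdf()
        assert np.all(np.diff(cdf) >= 0)
        assert np.all(cdf <= 1 + 1e-9)
        assert cdf[-1] >= 1 - 1e-6

    def test_rejects_small_support(self):
        with pytest.raises(ValueError):
            waiting_time_distribution(0.85, 9, 8)

    def test_monte_carlo_agreement(self, rng):
        """Empirical CDF of distances between consecutive 9-runs of heads
        matches the tabulated distribution within 3 standard errors."""
        from conftest import mc_waiting_samples

        p, k, n = 0.85, 9, 100_000
        samples = mc_waiting_samples(p, k, n, rng)
        cdf = waiting_time_distribution(p, k, 2000).cdf()
        for x in (9, 20, 54, 100):
            theo = cdf[x]
            emp = (samples <= x).mean()
            se = np.sqrt(theo * (1 - theo) / n)
            assert abs(emp - theo) <= 3 * se + 1e-12


class TestSolveRho:
    def test_published_default(self):
        assert solve_rho(0.85, 9, 0.05) == 54

    def test_certain_match_collapses_to_k(self):
        assert solve_rho(1.0, 9, 0.05) == 9
        assert solve_rho(1.0, 9, 0.4) == 9

    def test_matches_monte_carlo_quantile(self, rng):
        # geometric waiting time for a single head at p = 0.5
        samples = rng.geometric(0.5, size=1_000_000)
        empirical = int(np.percentile(samples, 95))
        assert solve_rho(0.5, 1, 0.05) == empirical == 5

    def test_monotone_in_p_k_alpha(self):
        rhos_p = [solve_rho(p, 9, 0.05) for p in (0.7, 0.8, 0.9, 0.99)]
        assert rhos_p == sorted(rhos_p, reverse=True)
        rhos_k = [solve_rho(0.85, k, 0.05) for k in (5, 7, 9, 12)]
        assert rhos_k == sorted(rhos_k)
        rhos_a = [solve_rho(0.85, 9, a) for a in (0.01, 0.05, 0.2, 0.5)]
        assert rhos_a == sorted(rhos_a, reverse=True)

    def test_fails_when_level_unreachable(self):
        with pytest.raises(ValueError):
            solve_rho(0.05, 15, 0.05, max_support=2000)


class TestDiagonalShift:
    def test_no_indels_no_drift(self):
        for l in (0, 1, 10):
            dist = diagonal_shift_distribution(0.0, l)
            assert dist.prob(0) == 1.0

    def test_single_step(self):
        dist = diagonal_shift_distribution(0.06, 1)
        assert dist.prob(0) == pytest.approx(0.88)
        assert dist.prob(1) == pytest.approx(0.06)
        assert dist.prob(-1) == pytest.approx(0.06)

    def test_two_steps(self):
        dist = diagonal_shift_distribution(0.06, 2)
        assert dist.prob(0) == pytest.approx(0.88**2 + 2 * 0.06**2)
        assert dist.prob(1) == pytest.approx(2 * 0.88 * 0.06)
        assert dist.prob(2) == pytest.approx(0.06**2)

    @pytest.mark.parametrize("q", [0.01, 0.06, 0.2])
    @pytest.mark.parametrize("l", [0, 1, 5, 25, 54])
    def test_shape_invariants(self, q, l):
        dist = diagonal_shift_distribution(q, l)
        mass = dist.mass
        assert mass.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(mass, mass[::-1])  # symmetric in i
        assert mass[l] == mass.max()  # mode at zero shift

    @pytest.mark.parametrize("q", [0.01, 0.06, 0.2])
    @pytest.mark.parametrize("l", [1, 7, 30, 54])
    def test_closed_form_matches_convolution(self, q, l):
        dist = diagonal_shift_distribution(q, l)
        for i in range(-l, l + 1):
            assert diagonal_shift_probability(q, l, i) == pytest.approx(
                dist.prob(i), abs=1e-12
            )

    def test_rejects_q_half(self):
        with pytest.raises(ValueError):
            diagonal_shift_distribution(0.5, 10)

    def test_monte_carlo_agreement(self, rng):
        from conftest import mc_shift_samples

        q, l, n = 0.06, 54, 100_000
        samples = mc_shift_samples(q, l, n, rng)
        dist = diagonal_shift_distribution(q, l)
        for i in (0, 1, 3, 5):
            theo = dist.prob(i)
            emp = (samples == i).mean()
            se = np.sqrt(theo * (1 - theo) / n)
            assert abs(emp - theo) <= 3 * se + 1e-12


class TestSolveDelta:
    def test_published_default(self):
        assert solve_delta(0.06, 54, 0.05) == 5

    def test_no_indels(self):
        assert solve_delta(0.0, 54, 0.05) == 0
        assert solve_delta(0.0, 7, 0.3) == 0

    def test_matches_cumulative_oracle(self):
        q, l, alpha = 0.06, 20, 0.05
        mass = diagonal_shift_distribution(q, l).mass
        cum, d = mass[l], 0
        while cum < 1 - alpha:
            d += 1
            cum += mass[l + d] + mass[l - d]
        assert solve_delta(q, l, alpha) == d

    def test_monotone_in_q_and_l(self):
        deltas_q = [solve_delta(q, 54, 0.05) for q in (0.01, 0.06, 0.15, 0.3)]
        assert deltas_q == sorted(deltas_q)
        deltas_l = [solve_delta(0.06, l, 0.05) for l in (10, 30, 54, 120)]
        assert deltas_l == sorted(deltas_l)


class TestGroupCriteria:
    def test_calibrate_defaults(self):
        crit = GroupCriteria.calibrate(p=0.85, q=0.06, k=9, alpha=0.05)
        assert (crit.rho, crit.delta) == (54, 5)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            GroupCriteria(k=9, rho=5, delta=2)
        with pytest.raises(ValueError):
            GroupCriteria(k=9, rho=20, delta=-1)


class TestErrorModel:
    def test_defaults_valid(self):
        ErrorModel()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"epsilon": 1.0},
            {"p": 0.0},
            {"q": 0.5},
            {"alpha": 0.0},
            {"alphabet_size": 1},
        ],
    )
    def test_rejects_invalid(self, kwargs):
        with pytest.raises(ValueError):
            ErrorModel(**kwargs)


class TestFilterThreshold:
    def test_long_read_default(self):
        lengths = [2000, 3000, 5000, 8000, 12000]
        assert recommend_filter_threshold(lengths, 15, 0.15) == 2

    def test_short_read_regime(self):
        # metagenome-like profile: mean ~1700, longest ~3200, k = 11
        lengths = list(range(800, 3201, 50))
        assert recommend_filter_threshold(lengths, 11, 0.15) == 3

    def test_floor_is_two(self):
        # error-free reads with a huge overlap: bounded by E[X_o], still >= 2
        assert recommend_filter_threshold([3000], 15, 0.0, overlap_fraction=1.0) == 2

    def test_warns_without_separation(self):
        # a huge length spread: random hits at the longest pair exceed the
        # in-overlap expectation at the shortest read, so no threshold works
        with pytest.warns(UserWarning, match="low confidence"):
            t = recommend_filter_threshold([2000, 60_000], 13, 0.15)
        assert t == 2
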