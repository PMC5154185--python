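"""Agent policies and the Monte Carlo engine against analytic oracles."""

import math

import numpy as np
import pytest

from ramforage.errors import InsufficientDataError, NoDataError, PolicyConfigError
from ramforage.metrics import correct_before_first_revisit, correct_in_first_eight, total_revisits
from ramforage.simulate import (
    AgentPolicy,
    TransitionMatrix,
    chance_policy,
    compare_to_null,
    estimate_transition_matrix,
    memory_policy,
    monte_carlo_null,
    next_choice,
    simulate_bout,
    simulate_metrics_batch,
    stereotyped_policy,
    NullDistribution,
)

from conftest import make_seq

# analytic chance-policy oracles (uniform over 8 flowers, stop at coverage):
# coupon collector, occupancy and duplicate-free-prefix closed forms
H8 = sum(1.0 / k for k in range(1, 9))
CHANCE_MEAN_REVISITS = 8 * H8 - 8
CHANCE_MEAN_FIRST8 = 8 * (1 - (7 / 8) ** 8)
CHANCE_MEAN_PREFIX = sum(
    math.prod((8 - j) / 8 for j in range(k)) for k in range(1, 9)
)


def cycle_matrix(first_on: int = 1) -> TransitionMatrix:
    m = np.zeros((8, 8))
    for i in range(8):
        m[i, (i + 1) % 8] = 1.0
    fc = np.zeros(8)
    fc[first_on - 1] = 1.0
    return TransitionMatrix(matrix=m, first_choice=fc)


class TestPolicies:
    def test_stereotyped_requires_matrix(self):
        with pytest.raises(PolicyConfigError):
            AgentPolicy(kind="stereotyped")

    def test_memory_strength_bounds(self):
        with pytest.raises(PolicyConfigError):
            memory_policy(1.5)

    def test_row_sums_validated(self):
        with pytest.raises(PolicyConfigError):
            TransitionMatrix(matrix=np.full((8, 8), 0.2), first_choice=np.full(8, 0.125))

    def test_chance_choice_uniform(self, rng):
        pol = chance_policy()
        draws = np.array([next_choice(pol, 3, {1, 2, 3}, rng) for _ in range(8000)])
        freqs = np.bincount(draws, minlength=9)[1:] / 8000
        assert np.all(np.abs(freqs - 1 / 8) < 0.03)

    def test_cycle_matrix_is_deterministic(self, rng):
        pol = stereotyped_policy(cycle_matrix())
        assert next_choice(pol, 3, {1, 2, 3}, rng) == 4

    def test_memory_one_picks_the_last_flower(self, rng):
        pol = memory_policy(1.0)
        assert next_choice(pol, 7, set(range(1, 8)), rng) == 8


class TestSimulateBout:
    def test_perfect_memory_is_error_free(self, rng):
        seq = simulate_bout(memory_policy(1.0), rng)
        assert seq.n_visits == 8 and total_revisits(seq) == 0

    def test_deterministic_cycle_visits_in_order(self, rng):
        seq = simulate_bout(stereotyped_policy(cycle_matrix(first_on=1)), rng)
        assert list(seq.choices) == [1, 2, 3, 4, 5, 6, 7, 8]

    def test_chance_bout_is_at_least_eight_visits(self, rng):
        for _ in range(50):
            assert simulate_bout(chance_policy(), rng).n_visits >= 8

    def test_fixed_seed_gives_identical_sequences(self):
        a = simulate_bout(chance_policy(), np.random.default_rng(7))
        b = simulate_bout(chance_policy(), np.random.default_rng(7))
        assert list(a.choices) == list(b.choices)

    def test_visit_cap_flags_incomplete(self, rng):
        # a cycle over flowers 1..7 never reaches flower 8
        m = np.zeros((8, 8))
        for i in range(7):
            m[i, (i + 1) % 7] = 1.0
        m[7, 0] = 1.0
        fc = np.zeros(8)
        fc[0] = 1.0
        seq = simulate_bout(
            stereotyped_policy(TransitionMatrix(matrix=m, first_choice=fc)),
            rng,
            max_visits=50,
        )
        assert seq.n_visits == 50 and not seq.complete


class TestBatchEngine:
    def test_batch_matches_sequence_metrics_exactly_for_cycle(self, rng):
        batch = simulate_metrics_batch(stereotyped_policy(cycle_matrix()), 100, rng)
        assert np.all(batch["total_revisits"] == 0)
        assert np.all(batch["correct_before_first_revisit"] == 8)
        assert np.all(batch["correct_in_first_eight"] == 8)
        assert np.all(batch["n_visits"] == 8)

    def test_batch_agrees_with_sequential_simulation(self):
        """Batch and per-bout paths draw from the same distribution."""
        n = 4000
        batch = simulate_metrics_batch(chance_policy(), n, np.random.default_rng(1))
        rng = np.random.default_rng(2)
        seq_revisits = np.array(
            [total_revisits(simulate_bout(chance_policy(), rng)) for _ in range(n)]
        )
        se = math.sqrt(batch["total_revisits"].var() / n + seq_revisits.var() / n)
        assert abs(batch["total_revisits"].mean() - seq_revisits.mean()) < 4 * se

    def test_memory_strength_reduces_revisits_monotonically(self):
        means = []
        for i, m in enumerate([0.0, 0.25, 0.5, 0.75, 1.0]):
            batch = simulate_metrics_batch(
                memory_policy(m), 10_000, np.random.default_rng(100 + i)
            )
            means.append(batch["total_revisits"].mean())
        assert all(a > b for a, b in zip(means, means[1:]))
        assert means[-1] == 0.0


class TestMonteCarloNull:
    def test_chance_means_match_closed_forms(self):
        nulls = monte_carlo_null(chance_policy(), n_iterations=30_000, seed=5)
        for name, target in [
            ("total_revisits", CHANCE_MEAN_REVISITS),
            ("correct_in_first_eight", CHANCE_MEAN_FIRST8),
            ("correct_before_first_revisit", CHANCE_MEAN_PREFIX),
        ]:
            nd = nulls[name]
            assert abs(nd.mean - target) < 3 * nd.mc_se

    def test_reproducible_for_fixed_seed(self):
        a = monte_carlo_null(chance_policy(), n_iterations=2000, seed=9, keep_values=True)
        b = monte_carlo_null(chance_policy(), n_iterations=2000, seed=9, keep_values=True)
        np.testing.assert_array_equal(
            a["total_revisits"].values, b["total_revisits"].values
        )

    def test_mc_se_definition(self):
        nd = monte_carlo_null(chance_policy(), n_iterations=1000, seed=3)["total_revisits"]
        assert nd.mc_se == pytest.approx(nd.sd / math.sqrt(nd.n_iterations))

    def test_rejects_zero_iterations(self):
        with pytest.raises(InsufficientDataError):
            monte_carlo_null(chance_policy(), n_iterations=0, seed=1)


class TestEstimateTransitionMatrix:
    def test_count_and_normalise(self):
        tm = estimate_transition_matrix(
            [make_seq([1, 2, 3]), make_seq([1, 2, 4])], pseudocount=0.0
        )
        assert tm.matrix[0, 1] == 1.0
        assert tm.matrix[1, 2] == pytest.approx(0.5)
        assert tm.matrix[1, 3] == pytest.approx(0.5)
        np.testing.assert_allclose(tm.first_choice[0], 1.0)

    def test_zero_count_row_falls_back_to_uniform(self):
        tm = estimate_transition_matrix([make_seq([1, 2])], pseudocount=0.0)
        np.testing.assert_allclose(tm.matrix[2], np.full(8, 1 / 8))

    def test_add_one_smoothing(self):
        tm = estimate_transition_matrix([make_seq([1, 2])], pseudocount=1.0)
        expected = np.array([1, 2, 1, 1, 1, 1, 1, 1]) / 9
        np.testing.assert_allclose(tm.matrix[0], expected)

    def test_empty_input_raises(self):
        with pytest.raises(NoDataError):
            estimate_transition_matrix([])

    def test_simulate_then_reestimate_recovers_matrix(self, rng):
        """Markov simulation followed by re-estimation converges to the truth."""
        truth = np.full((8, 8), 0.4 / 7)
        np.fill_diagonal(truth, 0.0)
        for i in range(8):
            truth[i, (i + 1) % 8] += 0.6  # contiguity-biased generating matrix
        fc = np.full(8, 1 / 8)
        n_bouts, length = 30_000, 25
        # vectorised fixed-length Markov chains, independent of the bout engine
        cum = np.cumsum(truth, axis=1)
        cum_fc = np.cumsum(fc)
        states = np.empty((n_bouts, length), dtype=np.int64)
        states[:, 0] = np.searchsorted(cum_fc, rng.random(n_bouts), side="right")
        for t in range(1, length):
            r = rng.random(n_bouts)
            rows = cum[states[:, t - 1]]
            states[:, t] = (rows < r[:, None]).sum(axis=1)
        bouts = [make_seq(states[b] + 1) for b in range(n_bouts)]
        est = estimate_transition_matrix(bouts, pseudocount=0.0)
        assert np.max(np.abs(est.matrix - truth)) < 0.02


class TestCompareToNull:
    def test_derived_t_interval(self):
        null = NullDistribution(
            metric="total_revisits", n_iterations=10**6, mean=CHANCE_MEAN_REVISITS, sd=8.7
        )
        cmp_ = compare_to_null([1, 3, 2, 2, 4, 0, 2, 1, 3, 2], null)
        assert cmp_.observed_mean == pytest.approx(2.0)
        assert cmp_.ci_low == pytest.approx(1.174, abs=5e-3)
        assert cmp_.ci_high == pytest.approx(2.826, abs=5e-3)
        assert not cmp_.null_inside_ci
        assert cmp_.direction == "better"

    def test_null_equal_to_observed_mean_is_inside(self):
        null = NullDistribution(metric="total_revisits", n_iterations=100, mean=2.0, sd=1.0)
        cmp_ = compare_to_null([1.0, 2.0, 3.0], null)
        assert cmp_.null_inside_ci and cmp_.direction == "equal"

    def test_degenerate_observations(self):
        null = NullDistribution(metric="correct_in_first_eight", n_iterations=100, mean=5.0, sd=1.0)
        cmp_ = compare_to_null([0.0, 0.0, 0.0], null)
        assert cmp_.ci_low == cmp_.ci_high == 0.0
        assert not cmp_.null_inside_ci
        assert cmp_.direction == "worse"

    def test_bootstrap_interval_close_to_t(self, rng):
        obs = rng.normal(5.0, 1.0, size=60)
        null = NullDistribution(metric="total_revisits", n_iterations=100, mean=5.0, sd=1.0)
        t_ci = compare_to_null(obs, null, method="t")
        b_ci = compare_to_null(obs, null, method="bootstrap", rng=rng)
        assert abs(t_ci.ci_low - b_ci.ci_low) < 0.15
        assert abs(t_ci.ci_high - b_ci.ci_high) < 0.15

    def test_single_observation_rejected(self):
        null = NullDistribution(metric="total_revisits", n_iterations=10, mean=1.0, sd=1.0)
        with pytest.raises(InsufficientDataError):
            compare_to_null([1.0], null)


def test_uniform_stereotyped_equals_chance_in_distribution():
    """A uniform matrix + uniform first choice reproduces the chance policy."""
    uniform = TransitionMatrix(matrix=np.full((8, 8), 1 / 8), first_choice=np.full(8, 1 / 8))
    n = 50_000
    a = monte_carlo_null(chance_policy(), n_iterations=n, seed=11)
    b = monte_carlo_null(stereotyped_policy(uniform), n_iterations=n, seed=12)
    for metric in a:
        se = math.hypot(a[metric].mc_se, b[metric].mc_se)
        assert abs(a[metric].mean - b[metric].mean) < 3 * se
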