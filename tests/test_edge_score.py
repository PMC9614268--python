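"""Edge-prevalence Score and permutation inference against exact oracles."""

import numpy as np
import pytest

from fcdiff import (
    edge_scores,
    exact_permutation_p,
    generate_binary_cohort,
    permutation_p,
)


def _edge_cohort(present_in_g1, present_in_g2):
    """Single-edge cohort from explicit per-subject indicators."""
    x = np.array(present_in_g1 + present_in_g2, dtype=np.uint8).reshape(-1, 1)
    labels = np.array(["p"] * len(present_in_g1) + ["c"] * len(present_in_g2))
    return x, labels


class TestScore:
    def test_full_presence_vs_full_absence_gives_one(self):
        x, labels = _edge_cohort([1, 1, 1], [0, 0, 0])
        assert edge_scores(x, labels).score.iloc[0] == 1.0

    def test_equal_prevalence_gives_zero(self):
        x = np.zeros((244, 1), dtype=np.uint8)
        x[:71, 0] = 1  # 71/142 in group 1
        x[142 : 142 + 51, 0] = 1  # 51/102 in group 2
        labels = np.array(["p"] * 142 + ["c"] * 102)
        assert edge_scores(x, labels).score.iloc[0] == 0.0

    def test_direct_fraction_arithmetic(self):
        x = np.zeros((244, 1), dtype=np.uint8)
        x[:100, 0] = 1
        x[142 : 142 + 30, 0] = 1
        labels = np.array(["p"] * 142 + ["c"] * 102)
        expected = 100 / 142 - 30 / 102  # independent fraction computation
        assert edge_scores(x, labels).score.iloc[0] == pytest.approx(expected, abs=1e-15)
        assert expected == pytest.approx(0.4101077, abs=1e-7)

    def test_score_bounds_and_label_swap_antisymmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n1, n2 = int(rng.integers(1, 8)), int(rng.integers(1, 8))
            x = (rng.random((n1 + n2, 6)) < 0.5).astype(np.uint8)
            labels = np.array(["p"] * n1 + ["c"] * n2)
            a = edge_scores(x, labels, group_order=("p", "c")).score.to_numpy()
            b = edge_scores(x, labels, group_order=("c", "p")).score.to_numpy()
            assert np.abs(a).max() <= 1.0
            np.testing.assert_allclose(a, -b, atol=1e-15)

    def test_empty_group_rejected(self):
        x = np.ones((3, 2), dtype=np.uint8)
        with pytest.raises(ValueError):
            edge_scores(x, ["p", "p", "p"])


class TestExactOracle:
    def test_identical_subjects_give_p_one(self):
        x = np.ones((6, 3), dtype=np.uint8)
        labels = np.array(["p"] * 3 + ["c"] * 3)
        tab = exact_permutation_p(x, labels)
        np.testing.assert_array_equal(tab.p_value, 1.0)
        np.testing.assert_array_equal(tab.score, 0.0)

    def test_hand_enumeration_two_vs_two(self):
        # edge in both group-1 subjects and neither group-2 subject:
        # of the C(4,2)=6 partitions exactly 1 reattains S=1 -> tail P=1/6
        x, labels = _edge_cohort([1, 1], [0, 0])
        tab = exact_permutation_p(x, labels, tail="directional", estimator="tail")
        assert tab.p_value.iloc[0] == pytest.approx(1 / 6)

    def test_hand_enumeration_three_vs_three(self):
        # one-sided tail 1/C(6,3) = 0.05 for full separation
        x, labels = _edge_cohort([1, 1, 1], [0, 0, 0])
        tab = exact_permutation_p(x, labels, tail="directional", estimator="tail")
        assert tab.p_value.iloc[0] == pytest.approx(1 / 20)

    def test_enumeration_bound_enforced(self):
        x = np.ones((40, 1), dtype=np.uint8)
        labels = np.array(["p"] * 20 + ["c"] * 20)
        with pytest.raises(ValueError, match="partitions"):
            exact_permutation_p(x, labels)


class TestPermutationP:
    def test_observed_zero_score_gives_p_one(self):
        x, labels = _edge_cohort([1, 0], [1, 0])
        tab = permutation_p(x, labels, n_perm=100, seed=0)
        assert tab.score.iloc[0] == 0.0 and tab.p_value.iloc[0] == 1.0

    def test_edge_present_everywhere_gives_p_one(self):
        x, labels = _edge_cohort([1, 1, 1], [1, 1])
        tab = permutation_p(x, labels, n_perm=100, seed=0)
        assert tab.p_value.iloc[0] == 1.0

    def test_monte_carlo_matches_spec_tail_example(self):
        x, labels = _edge_cohort([1, 1, 1], [0, 0, 0])
        tab = permutation_p(x, labels, n_perm=100_000, seed=1, tail="directional", estimator="tail")
        assert tab.p_value.iloc[0] == pytest.approx(0.05, abs=0.005)

    @pytest.mark.parametrize("estimator", ["midp", "tail"])
    def test_monte_carlo_agrees_with_exact_oracle(self, estimator):
        """MC estimate within 3 Monte-Carlo SEs of exact enumeration, 20 cohorts."""
        n_perm = 20_000
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n1, n2 = int(rng.integers(3, 6)), int(rng.integers(3, 6))
            x, labels = generate_binary_cohort(
                n1, n2, 8, rng.uniform(0.2, 0.8, 8), rng.uniform(0.2, 0.8, 8), seed=seed
            )
            ex = exact_permutation_p(x, labels, estimator=estimator).p_value.to_numpy()
            mc = permutation_p(
                x, labels, n_perm=n_perm, seed=seed + 99, estimator=estimator
            ).p_value.to_numpy()
            se = np.sqrt(np.maximum(ex * (1 - ex), 0.25 / n_perm) / n_perm)
            assert np.all(np.abs(mc - ex) <= 3 * se + 2.0 / n_perm)

    def test_label_swap_preserves_p_negates_score(self):
        x, labels = generate_binary_cohort(6, 5, 10, 0.7, 0.3, seed=5)
        a = permutation_p(x, labels, n_perm=5000, seed=2, group_order=("patient", "control"))
        b = permutation_p(x, labels, n_perm=5000, seed=2, group_order=("control", "patient"))
        np.testing.assert_allclose(a.score, -b.score, atol=1e-15)
        np.testing.assert_allclose(a.p_value, b.p_value, atol=1e-12)

    def test_p_values_in_unit_interval(self):
        x, labels = generate_binary_cohort(5, 5, 20, 0.5, 0.5, seed=3)
        for tail in ("two_sided", "directional", "literal"):
            p = permutation_p(x, labels, n_perm=500, seed=4, tail=tail).p_value
            assert ((p > 0) & (p <= 1)).all()

    def test_power_on_strong_prevalence_difference(self):
        """Prevalence 0.9 vs 0.3 at n=40+40 attains P < 0.001 in >= 95% of seeds."""
        hits = 0
        for seed in range(20):
            x, labels = generate_binary_cohort(40, 40, 1, 0.9, 0.3, seed=seed)
            tab = permutation_p(x, labels, n_perm=10_000, seed=seed + 7)
            hits += int(tab.p_value.iloc[0] < 0.001)
        assert hits >= 19

    def test_literal_printed_rule_is_large_for_extreme_positive_scores(self):
        x, labels = _edge_cohort([1, 1, 1, 1], [0, 0, 0, 0])
        lit = permutation_p(x, labels, n_perm=2000, seed=0, tail="literal")
        two = permutation_p(x, labels, n_perm=2000, seed=0, tail="two_sided")
        assert lit.p_value.iloc[0] > 0.9  # evidence-for-null reading
        assert two.p_value.iloc[0] < 0.05

    def test_invalid_inputs_rejected(self):
        x, labels = _edge_cohort([1, 1], [0, 0])
        with pytest.raises(ValueError):
            permutation_p(x, labels, n_perm=0)
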