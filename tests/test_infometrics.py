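import math
from itertools import combinations

import numpy as np
import pytest

from infosimplex import (
    JointDistribution,
    Variable,
    conditional_entropy,
    conditional_mutual_information,
    elementary_energies,
    energy_decomposition,
    entropy,
    information_rate,
    kl_divergence,
    marginalize,
    mutual_information,
    pseudo_volume,
    total_correlation,
)
from infosimplex import synthetic

from _oracles import conditioned_information, state_sum_information


def product_of_marginals(joint):
    probs = None
    for i in joint.indices:
        m = marginalize(joint, {i}).probs
        probs = m if probs is None else np.multiply.outer(probs, m)
    return JointDistribution(joint.variables, probs)


class TestEntropy:
    def test_uniform_binary_one_bit(self):
        j = JointDistribution((Variable(1, 2),), np.array([0.5, 0.5]))
        assert entropy(j) == pytest.approx(1.0)

    def test_point_mass_zero_bits(self):
        j = JointDistribution((Variable(1, 3),), np.array([0.0, 1.0, 0.0]))
        assert entropy(j) == 0.0

    def test_borromean_two_bits(self, borromean):
        assert entropy(borromean) == pytest.approx(2.0)


class TestKL:
    def test_identical_distributions_zero(self, borromean):
        assert kl_divergence(borromean, borromean) == 0.0

    def test_point_mass_vs_uniform_one_bit(self):
        v = (Variable(1, 2),)
        p = JointDistribution(v, np.array([1.0, 0.0]))
        q = JointDistribution(v, np.array([0.5, 0.5]))
        assert kl_divergence(p, q) == pytest.approx(1.0)

    def test_support_violation_infinite(self):
        v = (Variable(1, 2),)
        p = JointDistribution(v, np.array([0.5, 0.5]))
        q = JointDistribution(v, np.array([1.0, 0.0]))
        assert kl_divergence(p, q) == math.inf

    def test_joint_vs_product_equals_total_correlation(self, borromean):
        d = kl_divergence(borromean, product_of_marginals(borromean))
        assert d == pytest.approx(total_correlation(borromean, (1, 2, 3)))
        assert d == pytest.approx(1.0)


class TestMutualInformation:
    def test_independent_pair_zero(self):
        j = synthetic.gen_independent(2)
        assert mutual_information(j, (1, 2)) == pytest.approx(0.0)

    def test_borromean_triple_minus_one_bit(self, borromean):
        assert mutual_information(borromean, (1, 2, 3)) == pytest.approx(-1.0)

    def test_identical_pair_one_bit(self):
        j = synthetic.gen_redundant(2)
        assert mutual_information(j, (1, 2)) == pytest.approx(1.0)

    def test_degree_one_is_entropy(self, borromean):
        assert mutual_information(borromean, (1,)) == pytest.approx(
            entropy(marginalize(borromean, {1}))
        )

    def test_empty_subset_zero(self, borromean):
        assert mutual_information(borromean, ()) == 0.0

    def test_permutation_symmetric(self, dirichlet):
        j = dirichlet(4, seed=11)
        assert mutual_information(j, (1, 2, 3, 4)) == pytest.approx(
            mutual_information(j, (4, 2, 1, 3))
        )

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("n,card", [(2, 3), (3, 2), (4, 2)])
    def test_matches_direct_state_sum(self, n, card, seed, dirichlet):
        """Inclusion-exclusion agrees with the single-sum log-ratio definition."""
        j = dirichlet(n, card, seed=seed)
        subset = tuple(range(1, n + 1))
        assert mutual_information(j, subset) == pytest.approx(
            state_sum_information(j, subset), abs=1e-9
        )


class TestTotalCorrelation:
    def test_independent_zero(self):
        j = synthetic.gen_independent(3)
        assert total_correlation(j, (1, 2, 3)) == pytest.approx(0.0)

    def test_borromean_one_bit(self, borromean):
        assert total_correlation(borromean, (1, 2, 3)) == pytest.approx(1.0)

    def test_fully_redundant_two_bits(self, redundant3):
        assert total_correlation(redundant3, (1, 2, 3)) == pytest.approx(2.0)

    def test_needs_two_variables(self, borromean):
        with pytest.raises(ValueError):
            total_correlation(borromean, (1,))

    def test_equals_alternating_information_sum(self, dirichlet):
        j = dirichlet(4, seed=3)
        subset = (1, 2, 3, 4)
        alternating = 0.0
        for size in range(2, 5):
            for T in combinations(subset, size):
                alternating += (-1) ** size * mutual_information(j, T)
        assert total_correlation(j, subset) == pytest.approx(alternating, abs=1e-9)


class TestConditionals:
    def test_independent_pair_conditioning_changes_nothing(self):
        j = synthetic.gen_independent(2, marginal=(0.3, 0.7))
        assert conditional_entropy(j, (1,), (2,)) == pytest.approx(
            entropy(marginalize(j, {1}))
        )

    def test_identical_pair_conditional_entropy_zero(self):
        j = synthetic.gen_redundant(2)
        assert conditional_entropy(j, (1,), (2,)) == pytest.approx(0.0)

    def test_borromean_determined_by_the_other_two(self, borromean):
        assert conditional_entropy(borromean, (1,), (2, 3)) == pytest.approx(0.0)

    def test_borromean_conditional_pair_information_one_bit(self, borromean):
        assert conditional_mutual_information(
            borromean, (1, 2), (3,)
        ) == pytest.approx(1.0)

    def test_all_independent_conditional_information_zero(self):
        j = synthetic.gen_independent(3)
        assert conditional_mutual_information(j, (1, 2), (3,)) == pytest.approx(0.0)

    def test_overlap_rejected(self, borromean):
        with pytest.raises(IndexError):
            conditional_entropy(borromean, (1, 2), (2,))
        with pytest.raises(IndexError):
            conditional_mutual_information(borromean, (1, 2), (1,))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_conditioning_oracle_and_pair_nonnegative(self, seed, dirichlet):
        """B.I(A) equals the expectation over B of I(A) under conditional laws."""
        j = dirichlet(4, seed=seed)
        for A, B in [((1, 2), (3,)), ((1, 2), (3, 4)), ((1, 2, 3), (4,)), ((2,), (1, 3))]:
            val = conditional_mutual_information(j, A, B)
            assert val == pytest.approx(
                conditioned_information(j, A, B), abs=1e-9
            )
            if len(A) == 2:
                assert val >= -1e-12


class TestChainRulesAndDuality:
    @pytest.mark.parametrize("seed", range(10))
    def test_entropy_chain_rule(self, seed, dirichlet):
        """H(A,B) = H(B) + B.H(A) for random laws up to five variables."""
        n = 3 + seed % 3
        j = dirichlet(n, seed=seed)
        idx = tuple(range(1, n + 1))
        for split in range(1, n):
            A, B = idx[:split], idx[split:]
            lhs = entropy(j.marginal(idx))
            rhs = entropy(j.marginal(B)) + conditional_entropy(j, A, B)
            assert lhs == pytest.approx(rhs, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_information_chain_rule(self, seed, dirichlet):
        """I(k-1) - I(k) = X_k . I(k-1) along growing prefixes."""
        n = 3 + seed % 3
        j = dirichlet(n, seed=100 + seed)
        idx = tuple(range(1, n + 1))
        for k in range(2, n + 1):
            prefix, last = idx[: k - 1], idx[k - 1]
            lhs = mutual_information(j, prefix) - mutual_information(j, idx[:k])
            rhs = conditional_mutual_information(j, prefix, (last,))
            assert lhs == pytest.approx(rhs, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_inclusion_exclusion_duality(self, seed, dirichlet):
        """H_n from the alternating I-sum equals the directly computed H_n."""
        n = 3 + seed % 3
        j = dirichlet(n, seed=200 + seed)
        idx = tuple(range(1, n + 1))
        alternating = 0.0
        for size in range(1, n + 1):
            for T in combinations(idx, size):
                alternating += (-1) ** (size - 1) * mutual_information(j, T)
        assert entropy(j) == pytest.approx(alternating, abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_matsuda_sign_equivalence(self, seed, dirichlet):
        """X_k.I(prefix) is negative exactly when the information sequence rises."""
        j = dirichlet(4, seed=300 + seed)
        idx = (1, 2, 3, 4)
        for k in range(2, 5):
            prefix, last = idx[: k - 1], idx[k - 1]
            cond = conditional_mutual_information(j, prefix, (last,))
            diff = mutual_information(j, prefix) - mutual_information(j, idx[:k])
            if abs(cond) > 1e-12:
                assert (cond > 0) == (diff > 0)


class TestPseudoVolume:
    def test_identical_pair_zero_distance(self):
        j = synthetic.gen_redundant(2)
        assert pseudo_volume(j, (1, 2)) == pytest.approx(0.0)

    def test_independent_pair_sums_entropies(self):
        j = synthetic.gen_independent(2, marginal=(0.3, 0.7))
        h1 = entropy(marginalize(j, {1}))
        assert pseudo_volume(j, (1, 2)) == pytest.approx(2 * h1)

    def test_borromean_three_bits(self, borromean):
        assert pseudo_volume(borromean, (1, 2, 3)) == pytest.approx(3.0)

    def test_degree_one_vanishes(self, borromean):
        assert pseudo_volume(borromean, (2,)) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_pairwise_triangle_inequality(self, seed, dirichlet):
        """V_2 is a pseudo-metric: d(1,3) <= d(1,2) + d(2,3) on random triples."""
        j = dirichlet(3, seed=400 + seed)
        d = lambda a, b: pseudo_volume(j, (a, b))
        for a, b, c in [(1, 2, 3), (2, 1, 3), (1, 3, 2)]:
            assert d(a, c) <= d(a, b) + d(b, c) + 1e-9


class TestEnergies:
    def test_borromean_all_states_three_bits(self, borromean):
        E = elementary_energies(borromean).energies
        assert np.allclose(E, 3.0)

    def test_independent_uniform_pair_two_bits(self):
        j = synthetic.gen_independent(2)
        assert np.allclose(elementary_energies(j).energies, 2.0)

    def test_point_mass_zero_energy(self):
        j = JointDistribution((Variable(1, 2),), np.array([0.0, 1.0]))
        E = elementary_energies(j)
        assert E.energies[1] == 0.0
        assert (0,) in E.flagged  # unreachable state, infinite energy

    def test_borromean_decomposition(self, borromean):
        d = energy_decomposition(borromean)
        assert d.U == pytest.approx(3.0)
        assert d.G == pytest.approx(1.0)
        assert d.H == pytest.approx(2.0)

    def test_independent_free_energy_vanishes(self):
        j = synthetic.gen_independent(4, marginal=(0.2, 0.8))
        d = energy_decomposition(j)
        assert d.G == pytest.approx(0.0, abs=1e-12)
        assert d.H == pytest.approx(d.U)

    @pytest.mark.parametrize("seed", range(6))
    def test_internal_energy_is_expected_elementary_energy(self, seed, dirichlet):
        """U equals the expectation of the per-state extensive energies."""
        j = dirichlet(3, 3, seed=500 + seed)
        E = elementary_energies(j).energies
        d = energy_decomposition(j)
        assert d.U == pytest.approx(float((j.probs * E).sum()), abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_isotherm_identity_and_nonnegative_G(self, seed, dirichlet):
        j = dirichlet(4, seed=600 + seed)
        d = energy_decomposition(j)
        assert d.H == pytest.approx(d.U - d.G, abs=1e-9)
        assert d.G >= -1e-12


class TestInformationRate:
    def test_iid_uniform_binary_rate_one(self):
        j = synthetic.gen_independent(4)
        assert information_rate(entropy(j), 4) == pytest.approx(1.0)

    def test_fully_redundant_rate_shrinks(self):
        j = synthetic.gen_redundant(4)
        assert information_rate(entropy(j), 4) == pytest.approx(0.25)

    def test_borromean_two_thirds(self, borromean):
        assert information_rate(entropy(borromean), 3) == pytest.approx(2 / 3)

    def test_zero_degree_rejected(self):
        with pytest.raises(ValueError):
            information_rate(1.0, 0)


class TestIndependenceCharacterization:
    @pytest.mark.parametrize("marginals", [
        ((0.5, 0.5), (0.5, 0.5), (0.5, 0.5)),
        ((0.25, 0.75), (0.5, 0.5), (0.125, 0.875)),
        ((0.1, 0.9), (0.9, 0.1), (0.5, 0.5)),
    ])
    def test_product_laws_have_vanishing_informations(self, marginals):
        probs = None
        for m in marginals:
            arr = np.asarray(m)
            probs = arr if probs is None else np.multiply.outer(probs, arr)
        j = JointDistribution(tuple(Variable(i + 1, 2) for i in range(3)), probs)
        for size in (2, 3):
            for T in combinations((1, 2, 3), size):
                assert mutual_information(j, T) == pytest.approx(0.0, abs=1e-12)

    def test_vanishing_informations_imply_factorization(self, dirichlet):
        """Zero I at every degree >= 2 forces the joint to be the marginal product."""
        j = synthetic.gen_independent(3, marginal=(0.4, 0.6))
        assert all(
            abs(mutual_information(j, T)) < 1e-12
            for size in (2, 3) for T in combinations((1, 2, 3), size)
        )
        assert np.allclose(j.probs, product_of_marginals(j).probs, atol=1e-12)
        # and a perturbed product law fails both sides
        perturbed = dirichlet(3, seed=7, concentration=5.0)
        assert any(
            abs(mutual_information(perturbed, T)) > 1e-6
            for size in (2, 3) for T in combinations((1, 2, 3), size)
        )
        assert not np.allclose(
            perturbed.probs, product_of_marginals(perturbed).probs, atol=1e-6
        )
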