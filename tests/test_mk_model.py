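"""Unit tests for Mk/GTR transition probabilities, pruning, and fitting."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from glasstree.matrix_io import CharacterMatrix, read_tree
from glasstree.mk_model import (
    GtrModel,
    MkModel,
    discrete_gamma_rates,
    excluded_pattern_probability,
    optimize_model,
    per_character_loglik,
    pruning_loglik,
    transition_probabilities,
)
from glasstree.synthetic_data import simulate_discrete_characters, simulate_tree

from oracle_utils import enum_character_loglik


class TestTransitionProbabilities:
    @pytest.mark.parametrize(
        "model",
        [
            MkModel(k=2, q=0.7),
            MkModel(k=4, q=1.3),
            MkModel(k=2, mode="asymmetric", q01=0.4, q10=1.9),
            GtrModel(exchangeabilities=[1, 2, 1, 1, 4, 1], base_freqs=[0.3, 0.2, 0.2, 0.3]),
        ],
    )
    def test_identity_at_zero_and_rows_sum_to_one(self, model):
        p0 = transition_probabilities(model, 0.0)
        assert np.allclose(p0, np.eye(model.k), atol=1e-12)
        p = transition_probabilities(model, 0.37)
        assert np.allclose(p.sum(axis=1), 1.0)
        assert (p >= 0).all()

    @pytest.mark.parametrize(
        "model",
        [
            MkModel(k=2, q=0.7),
            MkModel(k=3, q=1.1),
            MkModel(k=2, mode="asymmetric", q01=0.4, q10=1.9),
        ],
    )
    def test_equilibrium_limit(self, model):
        p = transition_probabilities(model, 500.0)
        for row in p:
            assert np.allclose(row, model.stationary(), atol=1e-9)

    def test_matches_matrix_exponential(self):
        """Closed forms equal expm of the generator to 1e-10."""
        q = 0.8
        generator = np.array([[-q, q], [q, -q]])
        for t in (0.01, 0.3, 2.5):
            assert np.allclose(
                transition_probabilities(MkModel(k=2, q=q), t),
                expm(generator * t),
                atol=1e-10,
            )
        q01, q10 = 0.4, 1.9
        generator = np.array([[-q01, q01], [q10, -q10]])
        model = MkModel(k=2, mode="asymmetric", q01=q01, q10=q10)
        for t in (0.01, 0.3, 2.5):
            assert np.allclose(
                transition_probabilities(model, t), expm(generator * t), atol=1e-10
            )

    def test_gtr_matches_matrix_exponential(self):
        model = GtrModel(
            exchangeabilities=[1, 2, 1.5, 0.8, 4, 1], base_freqs=[0.3, 0.2, 0.2, 0.3]
        )
        generator = model.rate_matrix()
        for t in (0.05, 0.7):
            assert np.allclose(
                transition_probabilities(model, t), expm(generator * t), atol=1e-10
            )

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            transition_probabilities(MkModel(), -0.1)


class TestDiscreteGamma:
    def test_category_rates_average_to_one(self):
        for shape in (0.2, 0.5, 1.0, 5.0):
            rates = discrete_gamma_rates(shape, 4)
            assert rates.mean() == pytest.approx(1.0, abs=1e-10)
            assert (np.diff(rates) > 0).all()

    def test_large_shape_converges_to_homogeneous(self):
        tree = read_tree("((A:0.3,B:0.7):0.4,(C:0.2,D:0.9):0.1);")
        matrix = CharacterMatrix(
            ["A", "B", "C", "D"], np.array([["0"], ["1"], ["0"], ["1"]])
        )
        flat = pruning_loglik(tree, matrix, MkModel(k=2, q=0.8))
        nearly_flat = pruning_loglik(
            tree, matrix, MkModel(k=2, q=0.8, gamma_shape=1e6)
        )
        assert nearly_flat == pytest.approx(flat, abs=1e-4)


class TestPruning:
    def test_single_leaf_equal_prior(self):
        tree = read_tree("A;")
        matrix = CharacterMatrix(["A"], np.array([["0"]]))
        ll = pruning_loglik(tree, matrix, MkModel(k=2, q=1.0, root_prior="equal"))
        assert ll == pytest.approx(np.log(0.5))

    def test_matches_enumeration_on_random_instances(self, rng):
        from oracle_utils import random_tree

        for _ in range(6):
            labels = [f"t{i}" for i in range(4)]
            tree = random_tree(rng, labels)
            states = rng.integers(0, 2, size=4)
            matrix = CharacterMatrix(labels, states.astype("<U1")[:, None])
            model = MkModel(k=2, q=float(rng.uniform(0.2, 1.5)))
            column = {t: int(s) for t, s in zip(labels, states)}
            assert pruning_loglik(tree, matrix, model) == pytest.approx(
                enum_character_loglik(tree, column, model), abs=1e-10
            )

    def test_missing_leaf_contributes_all_ones(self, rng):
        from oracle_utils import random_tree

        labels = [f"t{i}" for i in range(4)]
        tree = random_tree(rng, labels)
        matrix = CharacterMatrix(labels, np.array([["0"], ["?"], ["1"], ["0"]]))
        model = MkModel(k=2, q=0.6)
        column = {"t0": 0, "t1": None, "t2": 1, "t3": 0}
        assert pruning_loglik(tree, matrix, model) == pytest.approx(
            enum_character_loglik(tree, column, model), abs=1e-10
        )

    def test_invariant_to_root_placement_under_symmetric_mk(self):
        """The same unrooted tree rooted two ways has one likelihood."""
        rooted_one = read_tree("((A:0.3,B:0.7):0.2,(C:0.4,D:0.9):0.3);")
        rooted_two = read_tree("(A:0.3,(B:0.7,((C:0.4,D:0.9):0.5):0.0):0.0);")
        # same unrooted metric tree: internal path C/D clade <-> A/B = 0.5
        matrix = CharacterMatrix(
            ["A", "B", "C", "D"], np.array([["0"], ["1"], ["1"], ["0"]])
        )
        model = MkModel(k=2, q=0.8)
        assert pruning_loglik(rooted_one, matrix, model) == pytest.approx(
            pruning_loglik(rooted_two, matrix, model), abs=1e-10
        )

    def test_loglik_never_positive(self, rng):
        tree = simulate_tree(8, seed=2)
        matrix, _ = simulate_discrete_characters(tree, MkModel(q=0.4), 20, seed=3)
        assert (per_character_loglik(tree, matrix, MkModel(q=0.4)) <= 0).all()

    def test_missing_lengths_need_flag(self):
        tree = read_tree("((A,B),(C,D));")
        matrix = CharacterMatrix(
            ["A", "B", "C", "D"], np.array([["0"], ["1"], ["0"], ["1"]])
        )
        with pytest.raises(ValueError):
            pruning_loglik(tree, matrix, MkModel(k=2, q=0.5))
        assert pruning_loglik(
            tree, matrix, MkModel(k=2, q=0.5), unit_branch_lengths=True
        ) < 0


class TestAscertainment:
    def test_constant_probability_approaches_one_at_zero_rate(self):
        tree = read_tree("((A:1e-8,B:1e-8):1e-8,(C:1e-8,D:1e-8):1e-8);")
        p = excluded_pattern_probability(tree, MkModel(k=2, q=0.5), "variable-only")
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_long_branch_limit_matches_uniform_patterns(self):
        tree = read_tree("((A:50,B:50):50,(C:50,D:50):50);")
        model = MkModel(k=2, q=1.0)
        assert excluded_pattern_probability(tree, model, "variable-only") == pytest.approx(
            2 / 16, abs=1e-6
        )
        assert excluded_pattern_probability(
            tree, model, "informative-only"
        ) == pytest.approx(10 / 16, abs=1e-6)

    def test_correction_increases_variable_pattern_loglik(self):
        tree = read_tree("((A:0.3,B:0.7):0.4,(C:0.2,D:0.9):0.1);")
        matrix = CharacterMatrix(
            ["A", "B", "C", "D"], np.array([["0"], ["1"], ["0"], ["1"]])
        )
        model = MkModel(k=2, q=0.8)
        assert pruning_loglik(tree, matrix, model, "variable-only") > pruning_loglik(
            tree, matrix, model
        )

    def test_mode_none_rejected(self):
        tree = read_tree("((A:1,B:1):1,C:1);")
        with pytest.raises(ValueError):
            excluded_pattern_probability(tree, MkModel(), "none")

    def test_conditional_pattern_probabilities_sum_to_one(self):
        """Retained-pattern probabilities, renormalized, form a distribution."""
        tree = read_tree("((A:0.4,B:0.6):0.3,(C:0.2,D:0.8):0.5);")
        labels = ["A", "B", "C", "D"]
        model = MkModel(k=2, q=0.7)
        pattern_probs = {}
        for pattern in itertools.product("01", repeat=4):
            matrix = CharacterMatrix(labels, np.array(pattern)[:, None])
            pattern_probs[pattern] = np.exp(pruning_loglik(tree, matrix, model))
        assert sum(pattern_probs.values()) == pytest.approx(1.0, abs=1e-10)
        for mode, keep in (
            ("variable-only", lambda p: len(set(p)) > 1),
            ("informative-only", lambda p: min(p.count("0"), p.count("1")) >= 2),
        ):
            excluded = excluded_pattern_probability(tree, model, mode)
            retained = sum(v for p, v in pattern_probs.items() if keep(p))
            assert retained / (1 - excluded) == pytest.approx(1.0, abs=1e-10)


class TestOptimize:
    def test_constant_character_drives_rate_to_lower_bound(self):
        tree = read_tree("((A:1,B:1):1,(C:1,D:1):1);")
        matrix = CharacterMatrix(["A", "B", "C", "D"], np.full((4, 1), "0", dtype="<U1"))
        fit = optimize_model(tree, matrix, MkModel(k=2, q=0.5), ("q",), seed=1)
        assert fit.model.q == pytest.approx(1e-6, rel=10)

    def test_rate_recovery_smoke(self):
        tree = simulate_tree(16, seed=21)
        true = MkModel(k=2, q=0.5)
        matrix, _ = simulate_discrete_characters(tree, true, 300, seed=22)
        fit = optimize_model(tree, matrix, MkModel(k=2, q=1.0), ("q",), seed=2)
        assert fit.converged
        assert fit.model.q == pytest.approx(0.5, rel=0.3)

    def test_deterministic_given_seed(self):
        tree = simulate_tree(8, seed=5)
        matrix, _ = simulate_discrete_characters(tree, MkModel(q=0.4), 50, seed=6)
        one = optimize_model(tree, matrix, MkModel(k=2, q=1.0), ("q",), seed=9)
        two = optimize_model(tree, matrix, MkModel(k=2, q=1.0), ("q",), seed=9)
        assert one.model.q == two.model.q and one.loglik == two.loglik

    def test_no_free_parameters_rejected(self):
        tree = read_tree("((A:1,B:1):1,C:1);")
        matrix = CharacterMatrix(["A", "B", "C"], np.array([["0"], ["1"], ["0"]]))
        with pytest.raises(ValueError):
            optimize_model(tree, matrix, MkModel(), ())
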