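"""Unit tests for parsimony scoring, search, consensus, and tracing."""

import itertools

import numpy as np
import pytest

from glasstree.matrix_io import CharacterMatrix, read_tree
from glasstree.parsimony_engine import (
    ParsimonyResult,
    SearchConfig,
    bootstrap_support,
    character_step_bounds,
    consensus,
    ensemble_indices,
    fitch_length,
    implied_weight_score,
    mp_search,
    mp_trace,
    rooted_clades,
    round_half_up,
    unrooted_splits,
)
from glasstree.synthetic_data import simulate_tree

from oracle_utils import brute_force_steps, random_matrix, random_tree


def clade_indicator_matrix(tree, repeats=1):
    """Homoplasy-free characters: one 0/1 indicator per non-trivial clade."""
    labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
    columns = []
    for node in tree.postorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        members = {l.taxon.label for l in node.leaf_iter()}
        if 2 <= len(members) <= len(labels) - 2:
            columns.extend([[("1" if t in members else "0") for t in labels]] * repeats)
    return CharacterMatrix(labels, np.array(columns, dtype="<U1").T)


class TestStepBounds:
    @pytest.mark.parametrize(
        "states, expected",
        [
            (["0", "0", "1", "1"], (1, 2)),
            (["0", "0", "0", "0"], (0, 0)),
            (["0", "1", "2"], (2, 2)),
            (["0", "?", "1", "1"], (1, 1)),
        ],
    )
    def test_examples(self, states, expected):
        matrix = CharacterMatrix(
            [f"t{i}" for i in range(len(states))], np.array(states)[:, None]
        )
        assert character_step_bounds(matrix, 0) == expected

    def test_all_missing_errors(self):
        matrix = CharacterMatrix(["a", "b"], np.array([["?"], ["?"]]))
        with pytest.raises(ValueError):
            character_step_bounds(matrix, 0)


class TestFitchLength:
    def test_constant_character(self, quartet_tree):
        matrix = CharacterMatrix(
            ["A", "B", "C", "D"], np.full((4, 1), "1", dtype="<U1")
        )
        assert fitch_length(quartet_tree, matrix).total_length == 0

    def test_single_origin(self, quartet_tree):
        matrix = CharacterMatrix(
            ["A", "B", "C", "D"], np.array([["0"], ["0"], ["1"], ["1"]])
        )
        assert fitch_length(quartet_tree, matrix).total_length == 1

    def test_missing_is_universal(self, quartet_tree):
        matrix = CharacterMatrix(
            ["A", "B", "C", "D"], np.array([["0"], ["?"], ["?"], ["1"]])
        )
        assert fitch_length(quartet_tree, matrix).total_length == 1

    def test_leaf_absent_from_matrix(self, quartet_tree):
        matrix = CharacterMatrix(["A", "B", "C"], np.full((3, 1), "0", dtype="<U1"))
        with pytest.raises(KeyError, match="D"):
            fitch_length(quartet_tree, matrix)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(15):
            n = int(rng.integers(4, 7))
            labels = [f"t{i}" for i in range(n)]
            tree = random_tree(rng, labels, with_lengths=False)
            matrix = random_matrix(rng, labels, 4, k=3, missing_prob=0.15)
            result = fitch_length(tree, matrix)
            for c in range(4):
                assert result.steps[c] == brute_force_steps(tree, matrix, c)

    def test_length_invariant_under_rerooting(self, rng):
        labels = [f"t{i}" for i in range(7)]
        tree = random_tree(rng, labels, with_lengths=False)
        matrix = random_matrix(rng, labels, 10)
        baseline = fitch_length(tree, matrix).total_length
        for leaf in list(tree.leaf_node_iter())[:3]:
            rerooted = read_tree(tree.as_string(schema="newick"))
            target = [
                l for l in rerooted.leaf_node_iter() if l.taxon.label == leaf.taxon.label
            ][0]
            rerooted.reroot_at_edge(target.edge)
            assert fitch_length(rerooted, matrix).total_length == baseline


class TestEnsembleIndices:
    def test_clean_split_is_perfect(self, quartet_tree):
        matrix = CharacterMatrix(
            ["A", "B", "C", "D"], np.array([["0"], ["0"], ["1"], ["1"]])
        )
        ci, ri, rc = ensemble_indices(fitch_length(quartet_tree, matrix))
        assert (ci, ri, rc) == (1.0, 1.0, 1.0)

    def test_maximal_homoplasy_has_zero_retention(self):
        tree = read_tree("((A,C),(B,D));")
        matrix = CharacterMatrix(
            ["A", "B", "C", "D"], np.array([["0"], ["0"], ["1"], ["1"]])
        )
        result = fitch_length(tree, matrix)
        assert result.steps[0] == result.max_steps[0]
        _, ri, _ = ensemble_indices(result)
        assert ri == 0.0

    def test_zero_length_errors(self, quartet_tree):
        matrix = CharacterMatrix(["A", "B", "C", "D"], np.full((4, 2), "0", dtype="<U1"))
        with pytest.raises(ValueError):
            ensemble_indices(fitch_length(quartet_tree, matrix))

    def test_indices_invariant_under_character_reordering(self, rng, quartet_tree):
        labels = ["A", "B", "C", "D"]
        matrix = random_matrix(rng, labels, 12)
        perm = rng.permutation(12)
        shuffled = CharacterMatrix(labels, matrix.cells[:, perm])
        assert ensemble_indices(fitch_length(quartet_tree, matrix)) == pytest.approx(
            ensemble_indices(fitch_length(quartet_tree, shuffled))
        )


class TestImpliedWeights:
    def test_no_homoplasy_no_cost(self, quartet_tree):
        matrix = CharacterMatrix(
            ["A", "B", "C", "D"], np.array([["0"], ["0"], ["1"], ["1"]])
        )
        assert implied_weight_score(fitch_length(quartet_tree, matrix), 3.0) == 0.0

    def test_fit_at_three_extra_steps(self):
        result = ParsimonyResult(
            steps=np.array([4]), min_steps=np.array([1]), max_steps=np.array([5])
        )
        assert implied_weight_score(result, 3.0) == pytest.approx(0.5)

    def test_monotone_in_homoplasy(self):
        low = ParsimonyResult(np.array([2]), np.array([1]), np.array([5]))
        high = ParsimonyResult(np.array([3]), np.array([1]), np.array([5]))
        assert implied_weight_score(high, 3.0) > implied_weight_score(low, 3.0)

    def test_large_concavity_ranks_like_equal_weights(self, rng):
        """As K grows, h/(h+K) ~ h/K: tree ranking matches raw length."""
        labels = [f"t{i}" for i in range(6)]
        matrix = random_matrix(rng, labels, 8)
        trees = [random_tree(rng, labels, with_lengths=False) for _ in range(12)]
        results = [fitch_length(t, matrix) for t in trees]
        lengths = [r.total_length for r in results]
        big_k = [implied_weight_score(r, 1e7) for r in results]
        assert np.argsort(lengths, kind="stable").tolist() == np.argsort(
            big_k, kind="stable"
        ).tolist()


class TestSearch:
    def test_recovers_generating_topology_from_clean_characters(self):
        tree = simulate_tree(8, seed=11)
        matrix = clade_indicator_matrix(tree)
        config = SearchConfig(n_random_additions=5, rng_seed=3)
        best = mp_search(matrix, config)
        assert len(best) == 1
        assert unrooted_splits(best[0]) == unrooted_splits(tree)
        result = fitch_length(best[0], matrix)
        assert result.total_length == int(result.min_steps.sum())

    def test_deterministic_given_seed(self, rng):
        labels = [f"t{i}" for i in range(7)]
        matrix = random_matrix(rng, labels, 12)
        config = SearchConfig(n_random_additions=4, rng_seed=9)
        first = [t.as_string(schema="newick") for t in mp_search(matrix, config)]
        second = [t.as_string(schema="newick") for t in mp_search(matrix, config)]
        assert first == second

    def test_small_matrix_rejected(self):
        matrix = CharacterMatrix(["a", "b", "c"], np.full((3, 2), "0", dtype="<U1"))
        with pytest.raises(ValueError):
            mp_search(matrix, SearchConfig())

    @pytest.mark.parametrize("strategy", ["NNI", "SPR", "TBR"])
    def test_swap_strategies_reach_optimum_on_clean_data(self, strategy):
        tree = simulate_tree(6, seed=4)
        matrix = clade_indicator_matrix(tree)
        config = SearchConfig(n_random_additions=4, rng_seed=1, swap_strategy=strategy)
        best = mp_search(matrix, config)
        result = fitch_length(best[0], matrix)
        assert result.total_length == int(result.min_steps.sum())

    def test_implied_weights_search_on_clean_data(self):
        tree = simulate_tree(6, seed=8)
        matrix = clade_indicator_matrix(tree)
        config = SearchConfig(
            n_random_additions=4, rng_seed=2, objective="implied_weights"
        )
        best = mp_search(matrix, config)
        assert unrooted_splits(best[0]) == unrooted_splits(tree)


class TestConsensus:
    def test_identical_trees(self):
        trees = [read_tree("((A,B),(C,D));") for _ in range(3)]
        assert rooted_clades(consensus(trees, "strict")) == rooted_clades(trees[0])

    def test_conflicting_clade_collapses(self):
        trees = [read_tree("((A,(B,C)),D);"), read_tree("(((A,B),C),D);")]
        clades = rooted_clades(consensus(trees, "strict"))
        assert frozenset({"A", "B", "C"}) in clades
        assert frozenset({"B", "C"}) not in clades and frozenset({"A", "B"}) not in clades

    def test_majority_threshold(self):
        trees = [
            read_tree("((A,B),(C,D));"),
            read_tree("((A,B),(C,D));"),
            read_tree("((A,C),(B,D));"),
        ]
        clades = rooted_clades(consensus(trees, "majority", threshold=0.5))
        assert frozenset({"A", "B"}) in clades

    def test_mismatched_leaf_sets_rejected(self):
        with pytest.raises(ValueError):
            consensus([read_tree("((A,B),C);"), read_tree("((A,B),D);")], "strict")

    def test_strict_equals_naive_clade_intersection(self, rng):
        labels = [f"t{i}" for i in range(6)]
        for _ in range(8):
            trees = [random_tree(rng, labels, with_lengths=False) for _ in range(3)]
            expected = set.intersection(*(rooted_clades(t) for t in trees))
            observed = rooted_clades(consensus(trees, "strict"))
            assert observed == expected


class TestBootstrap:
    def test_deterministic(self, rng):
        labels = [f"t{i}" for i in range(6)]
        matrix = random_matrix(rng, labels, 15)
        config = SearchConfig(n_random_additions=2, rng_seed=5)
        one = bootstrap_support(matrix, config, replicates=10, seed=42)
        two = bootstrap_support(matrix, config, replicates=10, seed=42)
        assert one.as_string(schema="newick") == two.as_string(schema="newick")

    def test_decisive_clean_matrix_gets_high_support(self):
        tree = simulate_tree(6, seed=13)
        matrix = clade_indicator_matrix(tree, repeats=8)
        config = SearchConfig(n_random_additions=2, rng_seed=5)
        support = bootstrap_support(
            matrix, config, replicates=30, seed=7, reference_tree=tree
        )
        values = [
            float(n.label)
            for n in support.postorder_node_iter()
            if n.label is not None and not n.is_leaf()
        ]
        assert values and min(values) >= 80.0

    def test_constant_characters_support_nothing(self, rng):
        labels = [f"t{i}" for i in range(6)]
        matrix = CharacterMatrix(labels, np.full((6, 10), "0", dtype="<U1"))
        reference = random_tree(rng, labels, with_lengths=False)
        config = SearchConfig(n_random_additions=1, rng_seed=3)
        support = bootstrap_support(
            matrix, config, replicates=20, seed=11, reference_tree=reference
        )
        values = [
            float(n.label)
            for n in support.postorder_node_iter()
            if n.label is not None and not n.is_leaf()
        ]
        assert values and max(values) < 80.0


class TestTrace:
    def test_constant_character_fixed_everywhere(self, quartet_tree):
        matrix = CharacterMatrix(["A", "B", "C", "D"], np.full((4, 1), "1", dtype="<U1"))
        trace = mp_trace(quartet_tree, matrix, 0)
        fixed = frozenset({trace.symbols.index("1")})
        assert all(states == fixed for states in trace.state_sets.values())
        assert not trace.transition_counts

    def test_all_missing_errors(self, quartet_tree):
        matrix = CharacterMatrix(["A", "B", "C", "D"], np.full((4, 1), "?", dtype="<U1"))
        with pytest.raises(ValueError):
            mp_trace(quartet_tree, matrix, 0)

    def test_mpr_sets_match_exhaustive_enumeration(self, rng):
        for _ in range(10):
            labels = [f"t{i}" for i in range(5)]
            tree = random_tree(rng, labels, with_lengths=False)
            matrix = random_matrix(rng, labels, 1, k=2, missing_prob=0.1)
            if (matrix.cells == "?").all():
                continue
            trace = mp_trace(tree, matrix, 0)
            enc, _ = matrix.encoded()
            rows = {t: i for i, t in enumerate(labels)}
            nodes = list(tree.postorder_node_iter())
            free = [
                n
                for n in nodes
                if not n.is_leaf() or enc[rows[n.taxon.label], 0] < 0
            ]
            best_cost = None
            optimal_states = {n: set() for n in nodes}
            for assign in itertools.product(range(2), repeat=len(free)):
                states = dict(zip(free, assign))
                for n in nodes:
                    if n.is_leaf() and enc[rows[n.taxon.label], 0] >= 0:
                        states[n] = int(enc[rows[n.taxon.label], 0])
                cost = sum(
                    1
                    for n in nodes
                    if n.parent_node is not None and states[n] != states[n.parent_node]
                )
                if best_cost is None or cost < best_cost:
                    best_cost = cost
                    optimal_states = {n: {states[n]} for n in nodes}
                elif cost == best_cost:
                    for n in nodes:
                        optimal_states[n].add(states[n])
            for n in nodes:
                assert trace.state_sets[n] == frozenset(optimal_states[n])

    def test_single_gain_counted(self):
        tree = read_tree("((A,B),(C,D));")
        matrix = CharacterMatrix(
            ["A", "B", "C", "D"], np.array([["0"], ["0"], ["1"], ["1"]])
        )
        trace = mp_trace(tree, matrix, 0)
        assert trace.origins + trace.losses == 1


def test_round_half_up():
    assert round_half_up(0.125, 2) == 0.13
    assert round_half_up(0.124, 2) == 0.12
    assert round_half_up(46.825, 1) == 46.8  # repr-based, not binary-float artifacts
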