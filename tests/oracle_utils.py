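"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: exhaustive enumeration over
internal state assignments or over all unrooted topologies.  These
functions never share code with the package's own algorithms.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from glasstree.matrix_io import CharacterMatrix, read_tree
from glasstree.mk_model import transition_probabilities


def brute_force_steps(tree, matrix: CharacterMatrix, character_index: int) -> int:
    """Minimum number of state changes by exhaustive assignment enumeration."""
    enc, symbols = matrix.encoded()
    k = max(len(symbols), 1)
    rows = {t: i for i, t in enumerate(matrix.taxon_labels)}
    nodes = list(tree.postorder_node_iter())
    free = []  # internal nodes and missing leaves
    fixed = {}
    for node in nodes:
        if node.is_leaf():
            state = enc[rows[node.taxon.label], character_index]
            if state < 0:
                free.append(node)
            else:
                fixed[node] = int(state)
        else:
            free.append(node)
    best = math.inf
    for assign in itertools.product(range(k), repeat=len(free)):
        states = dict(zip(free, assign))
        states.update(fixed)
        cost = 0
        for node in nodes:
            if node.parent_node is None:
                continue
            if states[node] != states[node.parent_node]:
                cost += 1
        best = min(best, cost)
    return int(best)


def enumerate_unrooted_topologies(labels: list[str]) -> list:
    """All unrooted binary topologies on the labels, as dendropy trees.

    Built by recursive leaf insertion on nested-tuple representations;
    3 labels give 1 topology, 6 labels give 105.
    """
    assert len(labels) >= 3

    def edges(subtree, path=()):  # yields paths addressing insertable edges
        if isinstance(subtree, tuple):
            for i, child in enumerate(subtree):
                yield path + (i,)
                yield from edges(child, path + (i,))

    def insert(subtree, path, leaf):
        if len(path) == 1:
            return tuple(
                (child if i != path[0] else (child, leaf)) for i, child in enumerate(subtree)
            )
        return tuple(
            (child if i != path[0] else insert(child, path[1:], leaf))
            for i, child in enumerate(subtree)
        )

    shapes = [tuple(labels[:3])]
    for leaf in labels[3:]:
        grown = []
        for shape in shapes:
            for path in edges(shape):
                grown.append(insert(shape, path, leaf))
        shapes = grown

    def to_newick(subtree) -> str:
        if isinstance(subtree, str):
            return subtree
        return "(" + ",".join(to_newick(c) for c in subtree) + ")"

    return [read_tree(to_newick(s) + ";") for s in shapes]


def enum_character_loglik(tree, column: dict, model) -> float:
    """Log-likelihood of one character by summation over all assignments.

    ``column`` maps leaf label -> state index or None for missing.
    """
    prior = model.root_distribution()
    nodes = list(tree.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    missing_leaves = [n for n in nodes if n.is_leaf() and column[n.taxon.label] is None]
    free = internals + missing_leaves
    k = model.k
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(free)):
        states = dict(zip(free, assign))
        for node in nodes:
            if node.is_leaf() and column[node.taxon.label] is not None:
                states[node] = column[node.taxon.label]
        prob = prior[states[tree.seed_node]]
        for node in nodes:
            if node.parent_node is None:
                continue
            p = transition_probabilities(model, node.edge.length)
            prob *= p[states[node.parent_node], states[node]]
        total += prob
    return math.log(total)


def enum_marginals(tree, column: dict, model) -> dict:
    """Per-node marginal state probabilities by joint enumeration."""
    prior = model.root_distribution()
    nodes = list(tree.postorder_node_iter())
    k = model.k
    free = [n for n in nodes if not n.is_leaf() or column[n.taxon.label] is None]
    marg = {n: np.zeros(k) for n in nodes}
    for assign in itertools.product(range(k), repeat=len(free)):
        states = dict(zip(free, assign))
        for node in nodes:
            if node.is_leaf() and column[node.taxon.label] is not None:
                states[node] = column[node.taxon.label]
        prob = prior[states[tree.seed_node]]
        for node in nodes:
            if node.parent_node is None:
                continue
            p = transition_probabilities(model, node.edge.length)
            prob *= p[states[node.parent_node], states[node]]
        for node in nodes:
            marg[node][states[node]] += prob
    return {n: v / v.sum() for n, v in marg.items()}


def random_matrix(rng, labels, n_chars, k=2, missing_prob=0.0) -> CharacterMatrix:
    cells = rng.integers(0, k, size=(len(labels), n_chars)).astype("<U1")
    if missing_prob:
        mask = rng.random(cells.shape) < missing_prob
        cells[mask] = "?"
    return CharacterMatrix(list(labels), cells)


def random_tree(rng, labels, with_lengths=True):
    """Random binary rooted tree by sequential attachment (newick text)."""
    # grow a nested-tuple rooted binary tree
    shape = (labels[0], labels[1])
    for leaf in labels[2:]:
        # pick a random path to an existing subtree and pair it with the leaf
        def paths(sub, path=()):
            yield path
            if isinstance(sub, tuple):
                for i, child in enumerate(sub):
                    yield from paths(child, path + (i,))

        all_paths = list(paths(shape))
        chosen = all_paths[int(rng.integers(len(all_paths)))]

        def insert(sub, path):
            if not path:
                return (sub, leaf)
            return tuple(
                child if i != path[0] else insert(child, path[1:])
                for i, child in enumerate(sub)
            )

        shape = insert(shape, chosen)

    def to_newick(sub):
        if isinstance(sub, str):
            label = sub
            return f"{label}:{rng.uniform(0.05, 1.0):.4f}" if with_lengths else label
        inner = ",".join(to_newick(c) for c in sub)
        return f"({inner}):{rng.uniform(0.05, 1.0):.4f}" if with_lengths else f"({inner})"

    newick = to_newick(shape)
    if with_lengths:
        newick = newick.rsplit(":", 1)[0]
    return read_tree(newick + ";")
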