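"""Maximum-likelihood marginal ancestral-state reconstruction.

For every node of a rooted tree the proportional likelihood (pl) of
each character state is the normalized marginal likelihood obtained by
combining tipward (pruning) and rootward partials under a fitted Mk
variant — the symmetric one-rate binary model ("Mk1") or the asymmetric
two-rate model ("aMk2", equilibrium root frequencies by default).
Trees without branch lengths adopt the all-unit convention, mirroring
how reconstruction programs treat parsimony trees.

A topology-sensitivity protocol is supported through :func:`regraft`,
which prunes a named clade and re-attaches it as sister to another
clade, so reconstructions can be repeated under alternative placements
of unstable taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import dendropy
import numpy as np
import pandas as pd

from glasstree.matrix_io import CharacterMatrix, normalize_label
from glasstree.mk_model import MkModel, _category_rates, optimize_model, transition_probabilities
from glasstree.parsimony_engine import round_half_up

__all__ = [
    "AsrResult",
    "asr_report",
    "locate_clade",
    "marginal_asr",
    "regraft",
]


@dataclass
class AsrResult:
    """Per-node proportional likelihoods for one character."""

    character_index: int
    model: MkModel
    tree: dendropy.Tree
    node_pl: dict  # dendropy node -> np.ndarray over states, sums to 1
    symbols: list[str]  # state index -> symbol
    decision_threshold: float = 0.95

    def pl(self, node) -> np.ndarray:
        return self.node_pl[node]

    def pl_at_clade(self, leaf_labels) -> np.ndarray:
        return self.node_pl[locate_clade(self.tree, leaf_labels)]

    def ambiguous_nodes(self) -> list:
        """Nodes whose best state falls below the decision threshold."""
        return [n for n, p in self.node_pl.items() if p.max() < self.decision_threshold]


def _has_branch_lengths(tree: dendropy.Tree) -> bool:
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            return False
    return True


def _character_states(matrix: CharacterMatrix, character_index: int, k: int):
    """Map a character column onto model state indices.

    Digit symbols map to their numeric value when that fits the model's
    state count (preserving absence/presence semantics of 0/1 coding);
    otherwise states are indexed by sorted symbol order.
    """
    column = matrix.cells[:, character_index]
    observed = sorted(set(column) - {matrix.missing_symbol})
    if not observed:
        raise ValueError(f"character {character_index} is entirely missing")
    if all(s.isdigit() for s in observed) and max(int(s) for s in observed) < k:
        mapping = {s: int(s) for s in observed}
    else:
        if len(observed) > k:
            raise ValueError(
                f"character {character_index} has {len(observed)} states; model has k={k}"
            )
        mapping = {s: i for i, s in enumerate(observed)}
    symbols = [None] * k
    for sym, idx in mapping.items():
        symbols[idx] = sym
    symbols = [s if s is not None else str(i) for i, s in enumerate(symbols)]
    states = np.array([mapping.get(c, -1) for c in column], dtype=np.int64)
    return states, symbols


def marginal_asr(
    tree: dendropy.Tree,
    matrix: CharacterMatrix,
    character_index: int,
    model: MkModel,
    root_prior=None,
    unit_branch_lengths: bool | None = None,
) -> AsrResult:
    """Marginal ancestral states for one character under a fitted model.

    ``pl(node, state)`` combines the tipward partial (likelihood of the
    subtree below the node) with the rootward partial (likelihood of the
    rest of the tree, root prior included) and normalizes over states.
    Polytomies are treated as hard.  ``unit_branch_lengths=None``
    auto-detects: trees without stored lengths use all-unit branches.
    """
    if root_prior is not None:
        model = replace(model, root_prior=root_prior)
    if unit_branch_lengths is None:
        unit_branch_lengths = not _has_branch_lengths(tree)
    k = model.k
    states, symbols = _character_states(matrix, character_index, k)
    rows = {normalize_label(t): i for i, t in enumerate(matrix.taxon_labels)}

    def edge_len(node) -> float:
        return 1.0 if unit_branch_lengths else float(node.edge.length)

    rates = _category_rates(model)
    prior = model.root_distribution()
    root = tree.seed_node
    joint = {node: np.zeros(k) for node in tree.preorder_node_iter()}
    for rate in rates:
        down: dict = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                label = normalize_label(node.taxon.label)
                if label not in rows:
                    raise KeyError(f"tree leaf {label!r} absent from matrix")
                state = states[rows[label]]
                part = np.ones(k) if state < 0 else np.eye(k)[state]
                down[node] = part
            else:
                part = np.ones(k)
                for child in node.child_nodes():
                    p = transition_probabilities(model, edge_len(child) * rate)
                    part = part * (p @ down[child])
                down[node] = part
        up: dict = {root: prior.copy()}
        for node in tree.preorder_node_iter():
            for child in node.child_nodes():
                p = transition_probabilities(model, edge_len(child) * rate)
                # product over the node's other children (recomputed
                # directly rather than divided out, to stay safe at 0)
                sibling = np.ones(k)
                for other in node.child_nodes():
                    if other is child:
                        continue
                    po = transition_probabilities(model, edge_len(other) * rate)
                    sibling = sibling * (po @ down[other])
                up[child] = (up[node] * sibling) @ p
        for node in tree.preorder_node_iter():
            joint[node] += up[node] * down[node] / len(rates)

    node_pl = {}
    for node, vec in joint.items():
        total = vec.sum()
        if total <= 0:
            raise ValueError("zero marginal likelihood; check data and model")
        node_pl[node] = vec / total
    return AsrResult(character_index, model, tree, node_pl, symbols)


def locate_clade(tree: dendropy.Tree, leaf_labels) -> dendropy.Node:
    """MRCA node of the named leaves (a single leaf returns that leaf)."""
    wanted = {normalize_label(l) for l in leaf_labels}
    if not wanted:
        raise ValueError("empty clade query")
    found = {}
    for leaf in tree.leaf_node_iter():
        label = normalize_label(leaf.taxon.label)
        if label in wanted:
            found[label] = leaf
    missing = wanted - set(found)
    if missing:
        raise KeyError(f"leaves not in tree: {sorted(missing)}")
    if len(found) == 1:
        return next(iter(found.values()))
    nodes = set(found.values())
    # walk up from one leaf; the first ancestor covering all is the MRCA
    node = next(iter(nodes))
    while node is not None:
        covered = {
            leaf for leaf in node.leaf_iter()
        }
        if nodes <= covered:
            return node
        node = node.parent_node
    raise RuntimeError("unreachable: root covers all leaves")


def _clone_tree(tree: dendropy.Tree) -> dendropy.Tree:
    clone = dendropy.Tree(tree)
    clone.is_rooted = True
    return clone


def regraft(tree: dendropy.Tree, clade_labels, attachment_labels) -> dendropy.Tree:
    """Prune a clade and re-attach it as sister to another clade.

    Both arguments are leaf-label collections identifying subtrees by
    their MRCA; they must be disjoint.  The new edges get unit branch
    lengths; the rest of the tree is untouched.  Returns a new tree.
    """
    clade_set = {normalize_label(l) for l in clade_labels}
    attach_set = {normalize_label(l) for l in attachment_labels}
    if clade_set & attach_set:
        raise ValueError("clade and attachment leaf sets overlap")
    work = _clone_tree(tree)
    clade_node = locate_clade(work, clade_set)
    moved_leaves = {normalize_label(l.taxon.label) for l in clade_node.leaf_iter()}
    if attach_set & moved_leaves:
        raise ValueError("attachment point lies inside the moved clade")
    parent = clade_node.parent_node
    if parent is None:
        raise ValueError("cannot move the entire tree")
    parent.remove_child(clade_node)
    # splice out degree-2 remnants
    if parent.num_child_nodes() == 1:
        only = parent.child_nodes()[0]
        grand = parent.parent_node
        if grand is None:
            only.parent_node = None
            work.seed_node = only
        else:
            grand.remove_child(parent)
            grand.add_child(only)
    attach_node = locate_clade(work, attach_set)
    attach_parent = attach_node.parent_node
    joint = dendropy.Node()
    if attach_parent is None:
        # sister to the whole remaining tree: new root
        joint.add_child(attach_node)
        joint.add_child(clade_node)
        work.seed_node = joint
    else:
        attach_parent.remove_child(attach_node)
        attach_parent.add_child(joint)
        joint.add_child(attach_node)
        joint.add_child(clade_node)
    joint.edge.length = 1.0
    clade_node.edge.length = 1.0
    attach_node.edge.length = attach_node.edge.length or 1.0
    work.update_bipartitions(suppress_unifurcations=True)
    work.is_rooted = True
    return work


def asr_report(
    tree: dendropy.Tree,
    matrix: CharacterMatrix,
    characters,
    clade_queries: dict,
    models=("mk1", "amk2"),
    seed: int = 0,
    unit_branch_lengths: bool | None = None,
) -> pd.DataFrame:
    """Tabulate proportional likelihoods per (character, clade, model).

    ``clade_queries`` maps clade names to leaf-label collections.  Rates
    are fitted per character by maximum likelihood.  Proportional
    likelihoods are reported to two decimals (half-up) together with the
    fitted rates; rows are ordered by (character, clade, model).
    """
    records = []
    for ci in sorted(characters):
        single = CharacterMatrix(
            list(matrix.taxon_labels),
            matrix.cells[:, ci : ci + 1],
            matrix.missing_symbol,
        )
        for model_name in sorted(models):
            if model_name == "mk1":
                template = MkModel(k=2, mode="symmetric", q=0.1)
                free = ("q",)
            elif model_name == "amk2":
                template = MkModel(k=2, mode="asymmetric", q01=0.1, q10=0.1)
                free = ("q01", "q10")
            else:
                raise ValueError(f"unknown model {model_name!r}")
            fit = optimize_model(
                tree,
                single,
                template,
                free_parameters=free,
                seed=seed,
                unit_branch_lengths=unit_branch_lengths
                if unit_branch_lengths is not None
                else not _has_branch_lengths(tree),
            )
            result = marginal_asr(
                tree, matrix, ci, fit.model, unit_branch_lengths=unit_branch_lengths
            )
            for clade_name in sorted(clade_queries):
                pl = result.pl_at_clade(clade_queries[clade_name])
                record = {
                    "character": ci,
                    "clade": clade_name,
                    "model": model_name,
                }
                for state, value in enumerate(pl):
                    record[f"pl_{result.symbols[state]}"] = round_half_up(value, 2)
                if model_name == "mk1":
                    record["rate_q"] = fit.model.q
                else:
                    record["rate_q01"] = fit.model.q01
                    record["rate_q10"] = fit.model.q10
                records.append(record)
    frame = pd.DataFrame.from_records(records)
    return frame.sort_values(["character", "clade", "model"]).reset_index(drop=True)
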