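"""Weighted morphology-based placement onto a molecular reference tree.

Genera without sequence data are attached to a molecular backbone
phylogeny using their morphological characters only.  Characters are
first calibrated against the reference tree: each character's weight is
its retention index on that tree, so characters congruent with the
molecular backbone count fully and maximally homoplastic characters are
ignored.  A query taxon is then tried on every edge of the reference
tree and edges are ranked by the weighted parsimony score of the
augmented tree.  This is a deterministic, documented variant of
"morphology-based phylogenetic binning"; bit-for-bit fidelity to any
particular binning program is not claimed.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from glasstree.matrix_io import CharacterMatrix, normalize_label
from glasstree.parsimony_engine import (
    _SN,
    _clone,
    _insert_at_edge,
    _leaf_costs,
    _leaf_row_map,
    _postorder,
    _steps_light,
    fitch_length,
)

__all__ = [
    "PlacementResult",
    "PlacementWeights",
    "calibrate_weights",
    "place_all",
    "place_query",
]


@dataclass
class PlacementWeights:
    """Per-character placement weights (retention index on the reference)."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isfinite(self.weights).all() or (self.weights < 0).any():
            raise ValueError("weights must be finite and non-negative")
        if self.weights.size and not self.weights.any():
            raise ValueError("all-zero weight vector: no character is informative "
                             "about the reference tree")


@dataclass
class PlacementResult:
    """Ranked candidate attachment edges for one query taxon.

    Edges are identified by the postorder index of the edge's child node
    in the reference tree; the ranking is ascending in weighted score
    with ties broken by edge index.
    """

    query: str
    ranked_edges: list  # [(edge_id, score)] ascending
    best_edge: int
    tie: bool


def calibrate_weights(
    reference_tree: dendropy.Tree, morphology: CharacterMatrix
) -> PlacementWeights:
    """Weight each character by its retention index on the reference tree.

    Characters whose RI is undefined on the reference leaf set (constant
    or single-taxon-variant characters, ``g == m``) get weight 0.
    """
    result = fitch_length(reference_tree, morphology)
    ri = result.retention_index_per_character()
    weights = np.where(np.isnan(ri), 0.0, np.clip(ri, 0.0, 1.0))
    return PlacementWeights(weights)


def _reference_light(reference_tree, morphology):
    """Light tree + edge index bookkeeping for repeated re-scoring."""
    mapping = _leaf_row_map(reference_tree, morphology)
    enc, symbols = morphology.encoded()
    k = max(len(symbols), 1)
    order = list(reference_tree.postorder_node_iter())
    index_of = {node: i for i, node in enumerate(order)}
    light_of = {}
    for node in order:
        light = _SN(mapping[node] if node.is_leaf() else None)
        for child in node.child_nodes():
            light.add(light_of[child])
        light_of[node] = light
    root = light_of[order[-1]]
    edges = [
        (index_of[node], light_of[node]) for node in order if node.parent_node is not None
    ]
    edges.sort(key=lambda pair: pair[0])
    return root, edges, enc, k


def place_query(
    reference_tree: dendropy.Tree,
    weights: PlacementWeights,
    morphology: CharacterMatrix,
    query_taxon: str,
) -> PlacementResult:
    """Score the query on every edge of the reference tree.

    The query leaf is attached at each edge in turn and the weighted
    parsimony score ``sum_c w_c * s_c`` of the augmented tree computed;
    lower is better.  Deterministic: ties rank by postorder edge index.
    """
    query_taxon = normalize_label(query_taxon)
    query_row = morphology.taxon_labels.index(query_taxon)
    if (morphology.cells[query_row] == morphology.missing_symbol).all():
        raise ValueError(f"query {query_taxon!r} has no scored characters")
    root, edges, enc, k = _reference_light(reference_tree, morphology)
    leaf_costs = _leaf_costs(enc, k)
    w = weights.weights
    if w.shape[0] != morphology.n_characters:
        raise ValueError("weight vector length does not match character count")
    scored = []
    for edge_id, light_node in edges:
        candidate = _clone(root)
        cmap = dict(zip(_postorder(root), _postorder(candidate)))
        _insert_at_edge(cmap[light_node], _SN(query_row))
        steps = _steps_light(candidate, leaf_costs, morphology.n_characters, k)
        scored.append((edge_id, float((w * steps).sum())))
    scored.sort(key=lambda pair: (pair[1], pair[0]))
    best_edge, best_score = scored[0]
    tie = len(scored) > 1 and abs(scored[1][1] - best_score) <= 1e-9
    return PlacementResult(query_taxon, scored, best_edge, tie)


def place_all(
    reference_tree: dendropy.Tree,
    weights: PlacementWeights,
    morphology: CharacterMatrix,
    queries,
) -> tuple[list[PlacementResult], dendropy.Tree]:
    """Place queries independently and graft each at its best edge.

    Every query is scored against the original reference tree, so
    results are order-independent; the composite tree then grafts each
    query at its best edge (degree-3 joint, unit-length pendant edge).
    """
    queries = [normalize_label(q) for q in queries]
    reference_leaves = {
        normalize_label(l.taxon.label) for l in reference_tree.leaf_node_iter()
    }
    overlap = set(queries) & reference_leaves
    if overlap:
        raise ValueError(f"queries already in reference tree: {sorted(overlap)}")
    results = [place_query(reference_tree, weights, morphology, q) for q in queries]

    composite = dendropy.Tree(reference_tree)
    composite.is_rooted = True
    order = list(composite.postorder_node_iter())
    for result in results:
        target = order[result.best_edge]
        parent = target.parent_node
        joint = dendropy.Node()
        original_length = target.edge.length
        parent.remove_child(target)
        parent.add_child(joint)
        joint.add_child(target)
        leaf = dendropy.Node()
        leaf.taxon = composite.taxon_namespace.require_taxon(label=result.query)
        joint.add_child(leaf)
        leaf.edge.length = 1.0
        if original_length is not None:
            joint.edge.length = original_length / 2.0
            target.edge.length = original_length / 2.0
    return results, composite
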