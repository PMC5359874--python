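"""End-to-end total-evidence workflow orchestration.

The workflow mirrors the study design for reconstructing a complete
genus-level phylogeny from partially sequenced taxa: reduce species to
one exemplar per genus, add rooting outgroups (an artificial all-zero
taxon for morphology-only analyses; a functional cross-subclass
outgroup with zero-coded morphology for the combined analyses), recode
and concatenate molecular + morphological partitions, run parsimony
searches per subclass, place unsequenced taxa on the molecular
backbone, graft the subclass trees into one tree, and reconstruct
ancestral states on it.  Every stage is seeded and the outputs are a
pure function of (inputs, config, seeds); a JSON manifest records
checksums of everything emitted.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone

import dendropy
import numpy as np

from glasstree import matrix_io
from glasstree.matrix_io import (
    Alignment,
    CharacterMatrix,
    MISSING,
    concatenate,
    normalize_label,
    recode_nucleotides,
    summarize_matrix,
    write_character_matrix,
    write_tree,
)
from glasstree.parsimony_engine import (
    SearchConfig,
    bootstrap_support,
    consensus,
    ensemble_indices,
    fitch_length,
    mp_search,
    round_half_up,
)
from glasstree.asr import asr_report
from glasstree.binning_placement import calibrate_weights, place_all
from glasstree.synthetic_data import StudyLikeConfig, SyntheticStudySet, make_study_like_dataset

__all__ = [
    "PipelineError",
    "WorkflowConfig",
    "add_artificial_outgroup",
    "build_total_evidence",
    "graft_subclass_trees",
    "monospecific_percentage",
    "reduce_taxa",
    "run_workflow",
]


class PipelineError(RuntimeError):
    """A workflow stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def monospecific_percentage(n_monospecific: int, n_genera: int) -> float:
    """Percentage of monospecific genera, one decimal, half-up."""
    if n_genera <= 0:
        raise ValueError("need a positive genus count")
    return round_half_up(100.0 * n_monospecific / n_genera, 1)


# ---------------------------------------------------------------------------
# dataset assembly steps


def reduce_taxa(data, retention_map: dict):
    """Reduce a dataset to one exemplar per genus.

    ``retention_map`` maps retained species labels to genus labels
    (injective on the kept species).  Retained rows are relabelled to
    the genus name; all other rows are dropped and listed in the
    returned drop log.
    """
    normalized = {normalize_label(k): normalize_label(v) for k, v in retention_map.items()}
    if len(set(normalized.values())) != len(normalized):
        raise ValueError("retention map is not injective on genus labels")
    labels = data.taxon_labels
    missing = sorted(set(normalized) - set(labels))
    if missing:
        raise KeyError(f"retained species absent from data: {missing}")
    keep = [i for i, t in enumerate(labels) if t in normalized]
    dropped = [t for t in labels if t not in normalized]
    new_labels = [normalized[labels[i]] for i in keep]
    if isinstance(data, Alignment):
        reduced = Alignment(new_labels, [data.sequences[i] for i in keep], dict(data.partitions))
    else:
        reduced = CharacterMatrix(
            new_labels, data.cells[keep], data.missing_symbol,
            dict(data.partitions), data.character_labels,
        )
    return reduced, dropped


def add_artificial_outgroup(
    matrix: CharacterMatrix,
    label: str = "ARTIFICIAL_OUTGROUP",
    morphology_partitions=None,
) -> CharacterMatrix:
    """Append an artificial outgroup row coded 0 for every morphological character.

    The artificial taxon anchors the root in analyses where no real
    outgroup shares comparable characters.  In mixed matrices, only the
    named morphology partitions are zero-coded; molecular partitions
    stay missing.  ``morphology_partitions=None`` treats every
    partition as morphological.
    """
    label = normalize_label(label)
    if label in matrix.taxon_labels:
        raise ValueError(f"label {label!r} already present")
    if morphology_partitions is None:
        morphology_partitions = list(matrix.partitions)
    row = np.full(matrix.n_characters, MISSING, dtype="<U1")
    for name in morphology_partitions:
        start, end = matrix.partitions[name]
        row[start:end] = "0"
    cells = np.vstack([matrix.cells, row[None, :]])
    return CharacterMatrix(
        matrix.taxon_labels + [label], cells, matrix.missing_symbol,
        dict(matrix.partitions), matrix.character_labels,
    )


def build_total_evidence(
    molecular: Alignment,
    morphology: CharacterMatrix,
    retention_map: dict | None = None,
):
    """Assemble the combined (total-evidence) parsimony matrix.

    The molecular alignment is optionally genus-reduced, recoded
    (A/C/G/T -> 0-3, ambiguities and gaps -> missing) and concatenated
    with the morphology under the union policy, so genera without
    sequence data get an all-missing molecular partition.  Returns
    ``(matrix, summary)``; the summary records the overall missing
    fraction of the combined matrix.
    """
    if retention_map is not None:
        molecular, _ = reduce_taxa(molecular, retention_map)
    overlap = set(molecular.taxon_labels) & set(morphology.taxon_labels)
    if not overlap:
        raise ValueError("no taxa shared between molecular and morphological data")
    recoded = recode_nucleotides(molecular)
    combined = concatenate([recoded, morphology], "union-fill-missing")
    return combined, summarize_matrix(combined)


def root_with_outgroup(tree: dendropy.Tree, outgroup_label: str) -> dendropy.Tree:
    """Re-root a tree so the named leaf is sister to everything else."""
    outgroup_label = normalize_label(outgroup_label)
    work = dendropy.Tree(tree)
    target = None
    for leaf in work.leaf_node_iter():
        if normalize_label(leaf.taxon.label) == outgroup_label:
            target = leaf
            break
    if target is None:
        raise KeyError(f"outgroup {outgroup_label!r} not in tree")
    work.reroot_at_edge(target.edge, update_bipartitions=False)
    work.is_rooted = True
    return work


def graft_subclass_trees(
    tree_a: dendropy.Tree,
    tree_b: dendropy.Tree,
    outgroup_a: str | None = None,
    outgroup_b: str | None = None,
) -> dendropy.Tree:
    """Join two subclass trees under a new root after dropping their outgroups.

    Each input must be rooted with its functional outgroup leaf attached
    at the root (auto-detected when not named).  The two ingroup clades
    become the children of a new root, i.e. the combined tree is rooted
    as a bifurcation at the subclass split.
    """
    def ingroup(tree: dendropy.Tree, outgroup: str | None) -> dendropy.Node:
        work = dendropy.Tree(tree)
        root_children = work.seed_node.child_nodes()
        if outgroup is None:
            leaves = [c for c in root_children if c.is_leaf()]
            if len(leaves) != 1:
                raise ValueError(
                    "cannot auto-detect the functional outgroup; pass its label"
                )
            out = leaves[0]
        else:
            out = None
            wanted = normalize_label(outgroup)
            for child in root_children:
                if child.is_leaf() and normalize_label(child.taxon.label) == wanted:
                    out = child
            if out is None:
                raise ValueError(f"outgroup {outgroup!r} is not a child of the root")
        work.seed_node.remove_child(out)
        rest = work.seed_node.child_nodes()
        if len(rest) == 1:
            node = rest[0]
        else:
            node = work.seed_node
        node.parent_node = None
        return node

    node_a = ingroup(tree_a, outgroup_a)
    node_b = ingroup(tree_b, outgroup_b)
    leaves_a = {normalize_label(l.taxon.label) for l in node_a.leaf_iter()}
    leaves_b = {normalize_label(l.taxon.label) for l in node_b.leaf_iter()}
    if leaves_a & leaves_b:
        raise ValueError(f"overlapping leaf names: {sorted(leaves_a & leaves_b)}")
    namespace = dendropy.TaxonNamespace()
    combined = dendropy.Tree(taxon_namespace=namespace)
    combined.seed_node.add_child(node_a)
    combined.seed_node.add_child(node_b)
    combined.is_rooted = True
    # re-bind taxa into the fresh namespace
    for leaf in combined.leaf_node_iter():
        leaf.taxon = namespace.require_taxon(label=leaf.taxon.label)
    return combined


# ---------------------------------------------------------------------------
# the orchestrated workflow


@dataclass
class WorkflowConfig:
    """Declarative settings for :func:`run_workflow`.

    When no input paths are given, a study-like synthetic dataset is
    generated from ``study`` (scaled down by default so a full run
    completes in minutes on one CPU).
    """

    output_dir: str = "glasstree_run"
    seed: int = 0
    # inputs; None -> synthetic
    morphology_path: str | None = None
    alignment_path: str | None = None
    retention_map: dict | None = None
    study: StudyLikeConfig = field(
        default_factory=lambda: StudyLikeConfig(
            n_taxa=20,
            n_subclass_a=6,
            n_morphology=(12, 30),
            molecular_partitions={"18S": 160, "28S": 140, "16S": 60, "COI": 80},
        )
    )
    # stage toggles
    run_mp: bool = True
    run_bootstrap: bool = False
    run_placement: bool = True
    run_asr: bool = True
    # analysis settings
    objective: str = "implied_weights"
    concavity: float = 3.0
    swap_strategy: str = "SPR"
    n_random_additions: int = 2
    bootstrap_replicates: int = 50
    asr_characters: tuple = (0, 1)
    outgroup_label: str = "ARTIFICIAL_OUTGROUP"


def _sha256(path: str) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        digest.update(fh.read())
    return digest.hexdigest()


def _write(path: str, text: str, manifest: dict) -> None:
    with open(path, "w") as fh:
        fh.write(text)
    manifest["artifacts"][os.path.basename(path)] = _sha256(path)


def run_workflow(config: WorkflowConfig, dataset: SyntheticStudySet | None = None) -> dict:
    """Execute the enabled stages in order and emit artifacts + manifest.

    Stage order: assemble inputs -> artificial outgroup -> total
    evidence -> subclass MP searches (+ optional bootstrap) ->
    morphology-based placement -> subclass-tree grafting -> ancestral
    state report.  Any stage failure raises :class:`PipelineError`
    naming the stage; partial outputs are retained.  Re-running with
    identical config and seeds produces byte-identical tree and table
    files.
    """
    os.makedirs(config.output_dir, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items() if k != "study"},
        "study": asdict(config.study),
        "artifacts": {},
        "stages": [],
        "generated_at": datetime.now(timezone.utc).isoformat(),
    }
    out = lambda name: os.path.join(config.output_dir, name)

    # ---------------------------------------------------------------- inputs
    stage = "assemble"
    try:
        if dataset is None and config.morphology_path is None:
            dataset = make_study_like_dataset(config.study, seed=config.seed)
        if dataset is not None:
            morphology = dataset.morphology
            alignment = dataset.alignment
            subclass_a, subclass_b = dataset.subclass_a, dataset.subclass_b
            molecular_taxa = dataset.molecular_taxa
            _write(out("true_tree.nwk"), write_tree(dataset.tree), manifest)
        else:
            morphology = matrix_io.read_character_matrix(config.morphology_path)
            alignment = matrix_io.read_alignment(config.alignment_path)
            if config.retention_map:
                morphology, drop_log = reduce_taxa(morphology, config.retention_map)
                _write(out("dropped_taxa.txt"), "\n".join(drop_log) + "\n", manifest)
            molecular_taxa = [
                t for t in alignment.taxon_labels if t in morphology.taxon_labels
            ]
            half = len(morphology.taxon_labels) // 2
            subclass_a = morphology.taxon_labels[:half]
            subclass_b = morphology.taxon_labels[half:]
        _write(out("morphology.nex"), write_character_matrix(morphology), manifest)
        manifest["stages"].append(stage)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ------------------------------------------------------- total evidence
    stage = "total_evidence"
    try:
        combined, summary = build_total_evidence(alignment, morphology, config.retention_map)
        _write(out("total_evidence.nex"), write_character_matrix(combined), manifest)
        _write(out("total_evidence_summary.tsv"), summary.to_tsv(), manifest)
        manifest["missing_fraction"] = summary.missing_fraction
        manifest["stages"].append(stage)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    search_config = SearchConfig(
        concavity=config.concavity,
        n_random_additions=config.n_random_additions,
        swap_strategy=config.swap_strategy,
        rng_seed=config.seed,
        objective=config.objective,
    )

    subclass_trees = {}
    if config.run_mp:
        stage = "mp_search"
        try:
            for name, members in (("subclass_a", subclass_a), ("subclass_b", subclass_b)):
                other = subclass_b if name == "subclass_a" else subclass_a
                functional_outgroup = sorted(set(other) & set(molecular_taxa))
                functional_outgroup = (
                    functional_outgroup[0] if functional_outgroup else sorted(other)[0]
                )
                taxa = sorted(set(members) & set(combined.taxon_labels))
                sub = combined.subset_taxa(taxa + [functional_outgroup])
                # functional outgroup: morphology coded absent (0)
                row = sub.taxon_labels.index(normalize_label(functional_outgroup))
                for pname, (start, end) in sub.partitions.items():
                    if pname.startswith("morph"):
                        sub.cells[row, start:end] = "0"
                trees = mp_search(sub, search_config)
                best = fitch_length(trees[0], sub)
                cons = consensus(trees, "strict") if len(trees) > 1 else trees[0]
                rooted = root_with_outgroup(cons, functional_outgroup)
                subclass_trees[name] = (rooted, functional_outgroup)
                _write(out(f"{name}_mpts.nwk"), "".join(write_tree(t) for t in trees), manifest)
                _write(out(f"{name}_consensus.nwk"), write_tree(rooted), manifest)
                ci, ri, rc = ensemble_indices(best)
                stats = (
                    f"n_trees\t{len(trees)}\nTL\t{best.total_length}\n"
                    f"CI\t{round_half_up(ci, 2):.2f}\nRI\t{round_half_up(ri, 2):.2f}\n"
                    f"RC\t{round_half_up(rc, 2):.2f}\n"
                )
                _write(out(f"{name}_stats.tsv"), stats, manifest)
                if config.run_bootstrap:
                    support = bootstrap_support(
                        sub, search_config, config.bootstrap_replicates,
                        seed=config.seed + 1, reference_tree=trees[0],
                    )
                    _write(out(f"{name}_bootstrap.nwk"), write_tree(support), manifest)
            manifest["stages"].append(stage)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    if config.run_placement:
        stage = "placement"
        try:
            molecular_set = sorted(set(molecular_taxa) & set(morphology.taxon_labels))
            queries = sorted(set(morphology.taxon_labels) - set(molecular_set))
            recoded = recode_nucleotides(alignment)
            backbone_matrix = recoded.subset_taxa(molecular_set)
            reference = mp_search(backbone_matrix, search_config)[0]
            weights = calibrate_weights(reference, morphology)
            results, composite = place_all(reference, weights, morphology, queries)
            lines = ["query\tbest_edge\ttie\tbest_score"]
            for r in results:
                lines.append(f"{r.query}\t{r.best_edge}\t{int(r.tie)}\t{r.ranked_edges[0][1]:.4f}")
            _write(out("placements.tsv"), "\n".join(lines) + "\n", manifest)
            _write(out("placement_composite.nwk"), write_tree(composite), manifest)
            manifest["stages"].append(stage)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    combined_tree = None
    if config.run_mp and len(subclass_trees) == 2:
        stage = "graft"
        try:
            (tree_a, out_a) = subclass_trees["subclass_a"]
            (tree_b, out_b) = subclass_trees["subclass_b"]
            combined_tree = graft_subclass_trees(tree_a, tree_b, out_a, out_b)
            _write(out("combined_tree.nwk"), write_tree(combined_tree), manifest)
            manifest["stages"].append(stage)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    if config.run_asr and combined_tree is not None:
        stage = "asr"
        try:
            clades = {
                "root": [l.taxon.label for l in combined_tree.leaf_node_iter()],
                "subclass_a": [
                    l.taxon.label
                    for l in combined_tree.leaf_node_iter()
                    if normalize_label(l.taxon.label) in set(subclass_a)
                ],
            }
            clades = {k: v for k, v in clades.items() if v}
            report = asr_report(
                combined_tree,
                morphology,
                list(config.asr_characters),
                clades,
                seed=config.seed,
                unit_branch_lengths=True,
            )
            _write(out("asr_report.tsv"), report.to_csv(sep="\t", index=False), manifest)
            manifest["stages"].append(stage)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    manifest_path = out("manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
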