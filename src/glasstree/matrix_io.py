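"""Reading, writing, recoding, and summarizing character matrices and trees.

The central in-memory currency is :class:`CharacterMatrix`, a taxa x
characters grid of single-character state symbols (binary morphology
``0/1`` or parsimony-recoded nucleotides ``0-3``) with one reserved
missing symbol and named, contiguous character partitions.  NEXUS and
FASTA parsing is delegated to :mod:`dendropy`; this module normalizes
the result into a single downstream representation in which both the
NEXUS gap symbol and the missing symbol map to one internal missing
state (gaps are treated as missing data in all parsimony analyses).

Trees are plain :class:`dendropy.Tree` objects read and written here so
that every other module shares one tree type.
"""

from __future__ import annotations

import io
import os
import re
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Alignment",
    "CharacterMatrix",
    "MatrixSummary",
    "ParseError",
    "concatenate",
    "normalize_label",
    "read_alignment",
    "read_character_matrix",
    "read_tree",
    "recode_nucleotides",
    "summarize_matrix",
    "write_character_matrix",
    "write_tree",
]

MISSING = "?"

#: Nucleotide -> parsimony symbol recoding used when mixing sequence data
#: with morphology in a single parsimony matrix: A->0, C->1, G->2, T->3.
#: Every IUPAC ambiguity code (including N) and the gap symbol become
#: missing data.
NUCLEOTIDE_RECODING = {"A": "0", "C": "1", "G": "2", "T": "3"}

_IUPAC_AMBIGUOUS = set("NRYSWKMBDHV")
_IUPAC_OK = set("ACGT") | _IUPAC_AMBIGUOUS | {"-", "?"}


class ParseError(ValueError):
    """Raised when a character matrix or tree cannot be parsed."""


def normalize_label(label: str) -> str:
    """Normalize a taxon label for cross-block matching.

    NEXUS dialects interchange underscores and spaces; labels are
    matched after collapsing runs of whitespace to single underscores.
    """
    return re.sub(r"\s+", "_", label.strip())


@dataclass
class CharacterMatrix:
    """Taxa x discrete-characters grid of state symbols.

    Parameters
    ----------
    taxon_labels
        Ordered, unique taxon names (whitespace normalized to ``_``).
    cells
        ``(n_taxa, n_characters)`` array of single-character symbols;
        ``missing_symbol`` marks unscored cells.
    missing_symbol
        The single reserved missing symbol (default ``?``); never part
        of the state alphabet.
    partitions
        Named, disjoint, covering half-open character ranges.  If empty,
        a single partition ``all`` spanning the matrix is created.
    character_labels
        Optional per-character names.
    """

    taxon_labels: list[str]
    cells: np.ndarray
    missing_symbol: str = MISSING
    partitions: dict[str, tuple[int, int]] = field(default_factory=dict)
    character_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.taxon_labels = [normalize_label(t) for t in self.taxon_labels]
        self.cells = np.asarray(self.cells, dtype="<U1")
        if self.cells.ndim != 2:
            raise ParseError("cells must be a 2-D taxa x characters grid")
        if len(self.taxon_labels) != self.cells.shape[0]:
            raise ParseError(
                f"{len(self.taxon_labels)} taxon labels for "
                f"{self.cells.shape[0]} rows"
            )
        dupes = {t for t in self.taxon_labels if self.taxon_labels.count(t) > 1}
        if dupes:
            raise ParseError(f"duplicate taxon labels: {sorted(dupes)}")
        if not self.partitions:
            self.partitions = {"all": (0, self.n_characters)}
        self._check_partitions()
        if self.character_labels is not None and len(self.character_labels) != self.n_characters:
            raise ParseError("character_labels length mismatch")

    def _check_partitions(self) -> None:
        covered = np.zeros(self.n_characters, dtype=bool)
        for name, (start, end) in self.partitions.items():
            if not (0 <= start <= end <= self.n_characters):
                raise ParseError(f"partition {name!r} out of range: {(start, end)}")
            if covered[start:end].any():
                raise ParseError(f"partition {name!r} overlaps another partition")
            covered[start:end] = True
        if self.n_characters and not covered.all():
            raise ParseError("partitions do not cover all characters")

    @property
    def n_taxa(self) -> int:
        return self.cells.shape[0]

    @property
    def n_characters(self) -> int:
        return self.cells.shape[1]

    @property
    def state_symbols(self) -> list[str]:
        """Sorted observed state symbols, excluding the missing symbol."""
        return sorted(set(self.cells.ravel()) - {self.missing_symbol})

    def row(self, taxon: str) -> np.ndarray:
        try:
            return self.cells[self.taxon_labels.index(normalize_label(taxon))]
        except ValueError:
            raise KeyError(f"taxon {taxon!r} not in matrix") from None

    def encoded(self) -> tuple[np.ndarray, list[str]]:
        """Integer-encode the matrix for numerical work.

        Returns ``(codes, symbols)`` where ``codes`` is an ``int8``
        array with missing cells as ``-1`` and ``codes[i, j] == s``
        meaning taxon *i* shows ``symbols[s]`` at character *j*.
        """
        symbols = self.state_symbols
        lookup = {sym: i for i, sym in enumerate(symbols)}
        codes = np.full(self.cells.shape, -1, dtype=np.int8)
        for sym, code in lookup.items():
            codes[self.cells == sym] = code
        return codes, symbols

    def subset_taxa(self, labels: list[str]) -> "CharacterMatrix":
        """Row-subset (and reorder) the matrix to the given taxa."""
        idx = [self.taxon_labels.index(normalize_label(t)) for t in labels]
        return CharacterMatrix(
            [self.taxon_labels[i] for i in idx],
            self.cells[idx],
            self.missing_symbol,
            dict(self.partitions),
            self.character_labels,
        )


@dataclass
class Alignment:
    """Equal-length nucleotide sequences over IUPAC codes plus gap."""

    taxon_labels: list[str]
    sequences: list[str]
    partitions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.taxon_labels = [normalize_label(t) for t in self.taxon_labels]
        if len(set(self.taxon_labels)) != len(self.taxon_labels):
            raise ParseError("duplicate taxon labels in alignment")
        if len(self.sequences) != len(self.taxon_labels):
            raise ParseError("sequence count does not match label count")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ParseError(f"unequal sequence lengths: {sorted(lengths)}")
        # normalize at read time: upper case, RNA U -> T
        self.sequences = [s.upper().replace("U", "T") for s in self.sequences]
        if not self.partitions:
            self.partitions = {"all": (0, self.length)}

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_labels)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0


@dataclass
class MatrixSummary:
    """Dimensions, distinct column patterns, and missingness of a matrix."""

    n_taxa: int
    n_characters: int
    distinct_patterns: dict[str, int]
    distinct_patterns_total: int
    missing_fraction: float
    #: For alignments only: missing fraction when IUPAC ambiguity codes
    #: (N, R, Y, ...) are also counted as missing; equals
    #: ``missing_fraction`` for recoded/morphological matrices.
    missing_fraction_with_ambiguity: float = 0.0

    def to_tsv(self) -> str:
        lines = [
            f"n_taxa\t{self.n_taxa}",
            f"n_characters\t{self.n_characters}",
        ]
        for name, count in self.distinct_patterns.items():
            lines.append(f"distinct_patterns[{name}]\t{count}")
        lines.append(f"distinct_patterns_total\t{self.distinct_patterns_total}")
        lines.append(f"missing_fraction\t{self.missing_fraction:.4f}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# reading and writing


def _as_text(source) -> str:
    """Accept a path, file object, or raw text and return text."""
    if hasattr(source, "read"):
        return source.read()
    source = str(source)
    if "\n" not in source and os.path.exists(source):
        with open(source) as fh:
            return fh.read()
    return source


def _partitions_from_charsets(char_matrix, n_characters: int) -> dict[str, tuple[int, int]]:
    """Convert dendropy character subsets into contiguous ranges."""
    partitions: dict[str, tuple[int, int]] = {}
    for name, subset in char_matrix.character_subsets.items():
        indices = sorted(subset.character_indices)
        if not indices:
            continue
        if indices != list(range(indices[0], indices[-1] + 1)):
            raise ParseError(f"charset {name!r} is not a contiguous range")
        partitions[name] = (indices[0], indices[-1] + 1)
    if partitions:
        covered = sum(end - start for start, end in partitions.values())
        if covered != n_characters:
            # charsets covering only part of the matrix are ignored rather
            # than guessed at; the caller can re-partition explicitly
            return {}
    return partitions


def read_character_matrix(source) -> CharacterMatrix:
    """Read a NEXUS CHARACTERS/DATA block into a :class:`CharacterMatrix`.

    Interleaved and non-interleaved dialects are both accepted.  The
    declared gap symbol is mapped to the internal missing symbol, so a
    single missing semantics applies downstream.
    """
    text = _as_text(source)
    try:
        dataset = dendropy.DataSet.get(data=text, schema="nexus", preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise ParseError(f"cannot parse NEXUS character matrix: {exc}") from exc
    if not dataset.char_matrices:
        raise ParseError("no CHARACTERS/DATA block found")
    cm = dataset.char_matrices[0]
    taxa = [t.label for t in cm]
    n_chars = max(len(cm[t]) for t in cm) if taxa else 0
    rows = []
    for taxon in cm:
        vec = cm[taxon]
        if len(vec) != n_chars:
            raise ParseError(
                f"taxon {taxon.label!r} has {len(vec)} characters, expected {n_chars}"
            )
        row = []
        for cell in vec:
            sym = str(cell.symbol) if cell.symbol is not None else MISSING
            row.append(MISSING if sym in ("?", "-") else sym)
        rows.append(row)
    cells = np.array(rows, dtype="<U1") if rows else np.empty((0, 0), dtype="<U1")
    partitions = _partitions_from_charsets(cm, n_chars)
    char_labels = None
    if getattr(cm, "character_subsets", None) is not None:
        labels = [
            getattr(cm.character_types[i], "label", None) if i < len(cm.character_types) else None
            for i in range(n_chars)
        ]
        if any(labels):
            char_labels = [lab or f"char{i + 1}" for i, lab in enumerate(labels)]
    return CharacterMatrix(taxa, cells, MISSING, partitions, char_labels)


def write_character_matrix(matrix: CharacterMatrix, path=None) -> str:
    """Write a matrix as a non-interleaved NEXUS DATA block (plus SETS)."""
    symbols = "".join(matrix.state_symbols) or "01"
    buf = io.StringIO()
    buf.write("#NEXUS\n\nBEGIN DATA;\n")
    buf.write(f"DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};\n")
    buf.write(f'FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;\n')
    buf.write("MATRIX\n")
    width = max((len(t) for t in matrix.taxon_labels), default=0) + 2
    for taxon, row in zip(matrix.taxon_labels, matrix.cells):
        seq = "".join(row).replace(matrix.missing_symbol, "?")
        buf.write(f"{taxon:<{width}}{seq}\n")
    buf.write(";\nEND;\n")
    if list(matrix.partitions) != ["all"]:
        buf.write("\nBEGIN SETS;\n")
        for name, (start, end) in matrix.partitions.items():
            buf.write(f"CHARSET {name} = {start + 1}-{end};\n")
        buf.write("END;\n")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_alignment(source, schema: str = "fasta") -> Alignment:
    """Read a nucleotide alignment (FASTA or NEXUS)."""
    text = _as_text(source)
    if text.lstrip().startswith("#NEXUS"):
        schema = "nexus"
    try:
        cm = dendropy.DnaCharacterMatrix.get(data=text, schema=schema, preserve_underscores=True)
    except Exception as exc:
        raise ParseError(f"cannot parse alignment: {exc}") from exc
    taxa = [t.label for t in cm]
    seqs = [str(cm[t]) for t in cm]
    return Alignment(taxa, seqs)


def read_tree(source) -> dendropy.Tree:
    """Read a single tree from Newick or NEXUS text (or a path).

    Topology, branch lengths, and internal labels are preserved; trees
    written without lengths come back with all ``edge.length`` unset.
    """
    text = _as_text(source)
    schema = "nexus" if text.lstrip().startswith("#NEXUS") else "newick"
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema=schema,
            preserve_underscores=True,
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ParseError(f"cannot parse tree: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {t for t in labels if labels.count(t) > 1}
    if dupes:
        raise ParseError(f"duplicate leaf labels: {sorted(dupes)}")
    for leaf in tree.leaf_node_iter():
        leaf.taxon.label = normalize_label(leaf.taxon.label)
    return tree


def write_tree(tree: dendropy.Tree, path=None, schema: str = "newick") -> str:
    text = tree.as_string(
        schema=schema,
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# recoding, concatenation, summaries


def recode_nucleotides(alignment: Alignment) -> CharacterMatrix:
    """Recode nucleotides as parsimony symbols: A->0, C->1, G->2, T->3.

    Ambiguity codes (N, R, Y, ...) and gaps become missing data, so the
    recoded block can be concatenated with morphology and analyzed with
    unordered parsimony.
    """
    n = alignment.n_taxa
    if n == 0 or alignment.length == 0:
        return CharacterMatrix(list(alignment.taxon_labels), np.empty((n, 0), dtype="<U1"))
    rows = []
    for taxon, seq in zip(alignment.taxon_labels, alignment.sequences):
        row = []
        for pos, base in enumerate(seq):
            if base not in _IUPAC_OK:
                raise ParseError(
                    f"non-IUPAC symbol {base!r} at position {pos + 1} of taxon {taxon!r}"
                )
            row.append(NUCLEOTIDE_RECODING.get(base, MISSING))
        rows.append(row)
    return CharacterMatrix(
        list(alignment.taxon_labels),
        np.array(rows, dtype="<U1"),
        MISSING,
        {name: rng for name, rng in alignment.partitions.items()},
    )


def concatenate(
    blocks: list[CharacterMatrix], taxon_union_policy: str = "union-fill-missing"
) -> CharacterMatrix:
    """Concatenate character blocks column-wise into one supermatrix.

    ``taxon_union_policy`` is ``"union-fill-missing"`` (taxa absent from
    a block get all-missing cells for that block's characters) or
    ``"intersection"`` (only taxa present in every block are kept).
    Partition names follow the source blocks; column order is block
    order.
    """
    if not blocks:
        raise ValueError("need at least one block")
    if taxon_union_policy not in ("union-fill-missing", "intersection"):
        raise ValueError(f"unknown policy {taxon_union_policy!r}")
    if taxon_union_policy == "intersection":
        taxa = [t for t in blocks[0].taxon_labels if all(t in b.taxon_labels for b in blocks)]
        if not taxa:
            raise ValueError("no taxa shared by all blocks")
    else:
        taxa = []
        for block in blocks:
            for t in block.taxon_labels:
                if t not in taxa:
                    taxa.append(t)
    total = sum(b.n_characters for b in blocks)
    cells = np.full((len(taxa), total), MISSING, dtype="<U1")
    partitions: dict[str, tuple[int, int]] = {}
    offset = 0
    for i, block in enumerate(blocks):
        index = {t: j for j, t in enumerate(block.taxon_labels)}
        for r, taxon in enumerate(taxa):
            if taxon in index:
                row = block.cells[index[taxon]]
                row = np.where(row == block.missing_symbol, MISSING, row)
                cells[r, offset : offset + block.n_characters] = row
        for name, (start, end) in block.partitions.items():
            if name == "all":
                name = f"block{i + 1}"
            base = name
            suffix = 2
            while name in partitions:
                name = f"{base}.{suffix}"
                suffix += 1
            partitions[name] = (offset + start, offset + end)
        offset += block.n_characters
    return CharacterMatrix(taxa, cells, MISSING, partitions)


def summarize_matrix(matrix: CharacterMatrix | Alignment) -> MatrixSummary:
    """Count distinct column patterns per partition and overall missingness.

    Pattern identity compares symbols verbatim after case-folding, with
    the missing symbol participating as its own symbol; the total is the
    sum over partitions (matching partitioned-analysis reporting).
    Missing fraction counts only the reserved missing/gap symbols.
    """
    if isinstance(matrix, Alignment):
        cells = np.array([list(s) for s in matrix.sequences], dtype="<U1")
        missing_symbols = {"-", "?"}
        ambiguous_symbols = missing_symbols | _IUPAC_AMBIGUOUS
        partitions = matrix.partitions
    else:
        cells = matrix.cells
        missing_symbols = {matrix.missing_symbol}
        ambiguous_symbols = missing_symbols
        partitions = matrix.partitions
    n_taxa, n_chars = cells.shape if cells.size else (len(matrix.taxon_labels), 0)
    folded = np.char.upper(cells) if cells.size else cells
    per_partition: dict[str, int] = {}
    for name, (start, end) in partitions.items():
        block = folded[:, start:end]
        columns = {tuple(block[:, j]) for j in range(block.shape[1])}
        per_partition[name] = len(columns)
    total_patterns = sum(per_partition.values())
    total_cells = n_taxa * n_chars
    if total_cells:
        missing = np.isin(folded, sorted(missing_symbols)).sum()
        missing_amb = np.isin(folded, sorted(ambiguous_symbols)).sum()
        missing_fraction = float(missing) / total_cells
        missing_fraction_amb = float(missing_amb) / total_cells
    else:
        missing_fraction = missing_fraction_amb = 0.0
    return MatrixSummary(
        n_taxa, n_chars, per_partition, total_patterns, missing_fraction, missing_fraction_amb
    )
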