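"""Domain types and file formats shared by every pipeline stage.

The central objects are :class:`GeneRecord` / :class:`Proteome` (one
predicted protein-coding gene, one strain's ORFome), the boolean
:class:`PresenceAbsenceMatrix` of gene families across genomes, and rooted
or unrooted strain trees (scikit-bio ``TreeNode`` under the hood, exchanged
as Newick).  Readers are strict: every malformed input raises a typed,
position-bearing error rather than silently producing partial data.

Coordinates are 0-based half-open; strand is ``'+'``/``'-'``.  FASTA record
IDs are the token before the first whitespace of the header; the full
header is kept as the description.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from skbio import TreeNode

__all__ = [
    "FormatError",
    "GeneRecord",
    "Proteome",
    "PresenceAbsenceMatrix",
    "AnnotationTable",
    "read_fasta",
    "write_fasta",
    "parse_newick",
    "write_newick",
    "read_annotation_table",
    "write_annotation_table",
    "write_json_report",
]

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")
DNA_ALPHABET = frozenset("ACGTN")


class FormatError(ValueError):
    """A file violated its declared format; carries file/record position."""


@dataclass
class GeneRecord:
    """One predicted protein-coding gene (ORF) of a strain genome."""

    gene_id: str
    genome_id: str
    protein_seq: str
    nucleotide_seq: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None
    functional_label: str | None = None
    partial: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        if self.nucleotide_seq is not None and not self.partial:
            if len(self.nucleotide_seq) != 3 * len(self.protein_seq) + 3:
                raise ValueError(
                    f"gene {self.gene_id}: nucleotide length "
                    f"{len(self.nucleotide_seq)} is not 3*protein+3 "
                    f"({3 * len(self.protein_seq) + 3}); flag partial=True "
                    "for incomplete ORFs"
                )
        if self.start is not None and self.end is not None and self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end must exceed start")
        if self.strand is not None and self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")


@dataclass
class Proteome:
    """All genes of one strain genome, optionally with its assembly."""

    genome_id: str
    genes: list[GeneRecord]
    assembly_seqs: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"proteome {self.genome_id} has no genes")
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError(f"proteome {self.genome_id}: duplicate gene IDs")
        for g in self.genes:
            if g.genome_id != self.genome_id:
                raise ValueError(
                    f"gene {g.gene_id} carries genome_id {g.genome_id!r}, "
                    f"expected {self.genome_id!r}"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


class PresenceAbsenceMatrix:
    """Boolean incidence of gene families across genomes.

    Backed by a pandas ``DataFrame`` (families x genomes) of bools, with an
    optional parallel integer copy-count frame.
    """

    def __init__(self, cells: pd.DataFrame, copy_counts: pd.DataFrame | None = None):
        cells = cells.astype(bool)
        if (cells.sum(axis=1) == 0).any():
            empty = cells.index[cells.sum(axis=1) == 0].tolist()
            raise ValueError(f"families present in no genome: {empty[:5]}")
        if copy_counts is not None:
            copy_counts = copy_counts.reindex(index=cells.index, columns=cells.columns)
            if ((copy_counts > 0) != cells).any().any():
                raise ValueError("copy_counts must be > 0 exactly where present")
        self.cells = cells
        self.copy_counts = copy_counts

    @property
    def family_ids(self) -> list[str]:
        return list(self.cells.index)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.cells.columns)

    @property
    def n_families(self) -> int:
        return self.cells.shape[0]

    @property
    def n_genomes(self) -> int:
        return self.cells.shape[1]

    def genomes_with(self, family_id: str) -> list[str]:
        row = self.cells.loc[family_id]
        return list(row.index[row])

    def families_of(self, genome_id: str) -> set[str]:
        col = self.cells[genome_id]
        return set(col.index[col])

    def core_family_ids(self) -> list[str]:
        mask = self.cells.all(axis=1)
        return list(self.cells.index[mask])

    def unique_family_ids(self) -> list[str]:
        mask = self.cells.sum(axis=1) == 1
        return list(self.cells.index[mask])

    def to_tsv(self, path: str | Path) -> None:
        self.cells.astype(int).to_csv(path, sep="\t", index_label="family_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PresenceAbsenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col="family_id")
        bad = ~df.isin([0, 1]).all()
        if bad.any():
            raise FormatError(f"{path}: non-0/1 cells in columns {list(df.columns[bad])}")
        return cls(df.astype(bool))

    def __eq__(self, other) -> bool:
        return isinstance(other, PresenceAbsenceMatrix) and self.cells.equals(other.cells)


# ---------------------------------------------------------------------------
# FASTA


@dataclass
class FastaRecord:
    id: str
    description: str
    seq: str


def read_fasta(path: str | Path, alphabet: str = "protein") -> list[FastaRecord]:
    """Read a FASTA file, validating residues against *alphabet*.

    Parameters
    ----------
    path:
        FASTA file; plain text, headers begin ``>``.
    alphabet:
        ``"protein"`` (20 standard residues plus X and ``*``) or ``"dna"``
        (A/C/G/T/N).  Sequences are uppercased before validation.

    Returns records in input order with line wrapping removed.  Raises
    :class:`FormatError` on an empty file, a duplicate ID, or an illegal
    residue (naming the record and 1-based position).
    """
    allowed = {"protein": PROTEIN_ALPHABET, "dna": DNA_ALPHABET}.get(alphabet)
    if allowed is None:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    path = Path(path)
    records: list[FastaRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        rid = header.split()[0] if header.split() else ""
        if not rid:
            raise FormatError(f"{path}: empty FASTA header")
        if rid in seen:
            raise FormatError(f"{path}: duplicate record ID {rid!r}")
        seen.add(rid)
        seq = "".join(chunks).upper()
        for i, ch in enumerate(seq):
            if ch not in allowed:
                raise FormatError(
                    f"{path}: record {rid!r} position {i + 1}: "
                    f"illegal {alphabet} residue {ch!r}"
                )
        records.append(FastaRecord(rid, header, seq))

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                chunks = []
            else:
                if header is None:
                    raise FormatError(f"{path}:{lineno}: sequence before first '>' header")
                chunks.append(line.strip())
    flush()
    if not records:
        raise FormatError(f"{path}: empty FASTA file")
    return records


def write_fasta(records: Iterable[FastaRecord | GeneRecord], path: str | Path,
                kind: str = "protein", width: int = 70) -> None:
    """Write records as FASTA; GeneRecords pick protein or nucleotide by *kind*."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, GeneRecord):
                seq = rec.protein_seq if kind == "protein" else rec.nucleotide_seq
                if seq is None:
                    raise ValueError(f"gene {rec.gene_id} has no {kind} sequence")
                header = rec.gene_id if not rec.description else f"{rec.gene_id} {rec.description}"
            else:
                seq = rec.seq
                header = rec.description or rec.id
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Newick


def _check_parens(s: str) -> None:
    depth = 0
    for i, ch in enumerate(s):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise FormatError(f"newick: unbalanced ')' at character {i}")
    if depth != 0:
        raise FormatError(f"newick: {depth} unclosed '(' at end of string")


def parse_newick(s: str) -> TreeNode:
    """Parse a Newick string into a ``TreeNode``; errors carry an offset."""
    _check_parens(s)
    try:
        return TreeNode.read([s], format="newick")
    except Exception as exc:  # skbio raises its own parse errors
        raise FormatError(f"newick parse failed: {exc}") from exc


def write_newick(tree: TreeNode) -> str:
    """Serialize with branch lengths at 10 significant digits."""
    buf = []
    _write_newick_node(tree, buf)
    buf.append(";")
    return "".join(buf)


def _write_newick_node(node: TreeNode, buf: list[str]) -> None:
    if node.children:
        buf.append("(")
        for i, child in enumerate(node.children):
            if i:
                buf.append(",")
            _write_newick_node(child, buf)
        buf.append(")")
    if node.name:
        buf.append(_escape_label(node.name))
    if node.length is not None:
        buf.append(f":{node.length:.10g}")


def _escape_label(name: str) -> str:
    if any(c in name for c in "(),:; \t'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def read_newick_file(path: str | Path) -> TreeNode:
    return parse_newick(Path(path).read_text())


def write_newick_file(tree: TreeNode, path: str | Path) -> None:
    Path(path).write_text(write_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# Annotation tables and reports


class AnnotationTable:
    """gene_id -> functional label mapping; absent genes are "unlabeled"."""

    UNLABELED = "unlabeled"

    def __init__(self, labels: Mapping[str, str]):
        self._labels = dict(labels)

    def __getitem__(self, gene_id: str) -> str:
        return self._labels.get(gene_id, self.UNLABELED)

    def __len__(self) -> int:
        return len(self._labels)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._labels

    def items(self):
        return self._labels.items()


def read_annotation_table(path: str | Path) -> AnnotationTable:
    """Read a TSV with header columns ``gene_id`` and ``label``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "label"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    dup = df["gene_id"].duplicated()
    if dup.any():
        raise FormatError(
            f"{path}: duplicate gene_id rows: {df['gene_id'][dup].tolist()[:5]}"
        )
    return AnnotationTable(dict(zip(df["gene_id"], df["label"])))


def write_annotation_table(labels: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"gene_id": list(labels.keys()), "label": list(labels.values())}
    ).to_csv(path, sep="\t", index=False)


def write_json_report(report: dict, path: str | Path) -> None:
    """Machine-readable stage provenance: parameters, seeds, counts."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
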