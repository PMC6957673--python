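"""Sequence, alignment, annotation and tree I/O.

All downstream analyses operate on an :class:`Alignment` (equal-length gapped
sequences) plus a table of :class:`GeneAnnotation` records whose coordinates
are 1-based inclusive on the *ungapped* reference sequence, following the
GenBank convention.  Trees are handled as :class:`dendropy.Tree` objects with
branch lengths in expected substitutions per site.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SequenceRecord",
    "Alignment",
    "GeneAnnotation",
    "read_fasta",
    "write_fasta",
    "as_alignment",
    "read_annotations",
    "write_annotations",
    "extract_gene",
    "read_newick",
    "write_newick",
    "parse_newick",
    "newick_string",
]

#: Nucleotide alphabet accepted on input: canonical bases, U, N, the IUPAC
#: ambiguity codes, and the gap character '-'.  '.' is deliberately rejected.
VALID_RESIDUES = frozenset("ACGTUNRYSWKMBDHV-")

_COMPLEMENT = str.maketrans(
    "ACGTUNRYSWKMBDHV-",
    "TGCAANYRSWMKVHDB-",
)

FEATURE_TYPES = ("CDS", "rRNA", "tRNA", "D-loop")


class SeqIOError(ValueError):
    """Malformed sequence, annotation, or tree input."""


@dataclass
class SequenceRecord:
    """A named nucleotide sequence, possibly gapped."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("sequence record has an empty id")
        if not self.residues:
            raise SeqIOError(f"sequence {self.id!r} is empty")
        self.residues = self.residues.upper()
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            pos = next(
                i for i, c in enumerate(self.residues, start=1) if c in bad
            )
            raise SeqIOError(
                f"sequence {self.id!r} contains non-IUPAC character "
                f"{self.residues[pos - 1]!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(
            self.id, self.residues.translate(_COMPLEMENT)[::-1], self.description
        )


class Alignment:
    """An ordered collection of equal-length sequence records.

    Invariants: at least two records, unique ids, identical lengths, and no
    all-gap row.
    """

    def __init__(self, records: Sequence[SequenceRecord]):
        records = list(records)
        if len(records) < 2:
            raise SeqIOError("an alignment needs at least 2 sequences")
        ids = [r.id for r in records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise SeqIOError(f"duplicate sequence id(s): {sorted(dupes)}")
        lengths = {len(r) for r in records}
        if len(lengths) > 1:
            detail = ", ".join(f"{r.id}={len(r)}" for r in records)
            raise SeqIOError(f"unequal sequence lengths: {detail}")
        for r in records:
            if set(r.residues) == {"-"}:
                raise SeqIOError(f"sequence {r.id!r} is all gaps")
        self.records = records
        self._index = {r.id: r for r in records}

    @property
    def n_columns(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    def __getitem__(self, seq_id: str) -> SequenceRecord:
        try:
            return self._index[seq_id]
        except KeyError:
            raise KeyError(f"sequence id {seq_id!r} not in alignment") from None

    def columns(self, column_indices: Iterable[int]) -> "Alignment":
        """Sub-alignment of the given 1-based column indices, in order."""
        idx = [c - 1 for c in column_indices]
        n = self.n_columns
        for c in idx:
            if c < 0 or c >= n:
                raise SeqIOError(f"column {c + 1} outside alignment (1..{n})")
        return Alignment(
            [
                SequenceRecord(
                    r.id, "".join(r.residues[c] for c in idx), r.description
                )
                for r in self.records
            ]
        )


@dataclass
class GeneAnnotation:
    """A named mitogenome feature on the ungapped reference.

    ``start``/``end`` are 1-based inclusive.  Only CDS features are
    translated downstream; ``codon_start`` gives the reading-frame offset.
    """

    gene: str
    feature_type: str
    start: int
    end: int
    strand: str = "+"
    codon_start: int = 1

    def __post_init__(self) -> None:
        if self.feature_type not in FEATURE_TYPES:
            raise SeqIOError(
                f"{self.gene}: feature_type {self.feature_type!r} not in "
                f"{FEATURE_TYPES}"
            )
        if self.start < 1:
            raise SeqIOError(f"{self.gene}: coordinates are 1-based, got start={self.start}")
        if self.start > self.end:
            raise SeqIOError(f"{self.gene}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise SeqIOError(f"{self.gene}: strand must be '+' or '-'")
        if self.codon_start not in (1, 2, 3):
            raise SeqIOError(f"{self.gene}: codon_start must be 1, 2 or 3")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into records (residues uppercased, gaps kept)."""
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqIOError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        records.append(SequenceRecord(rec.id, str(rec.seq), desc))
    if not records:
        raise SeqIOError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def as_alignment(records: Sequence[SequenceRecord]) -> Alignment:
    """Validate records as an alignment (equal lengths, >=2 rows)."""
    return Alignment(records)


_ANNOTATION_COLUMNS = ["gene", "feature_type", "start", "end", "strand", "codon_start"]


def read_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read a tab-separated annotation table, sorted by start coordinate.

    Expected header: ``gene  feature_type  start  end  strand  codon_start``.
    Overlapping features are allowed (mitochondrial genes overlap).
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in _ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise SeqIOError(f"annotation table missing column(s): {missing}")
    anns = [
        GeneAnnotation(
            gene=row.gene,
            feature_type=row.feature_type,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            codon_start=int(row.codon_start),
        )
        for row in df.itertuples()
    ]
    return sorted(anns, key=lambda a: (a.start, a.end, a.gene))


def write_annotations(annotations: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_ANNOTATION_COLUMNS) + "\n")
        for a in annotations:
            fh.write(
                f"{a.gene}\t{a.feature_type}\t{a.start}\t{a.end}\t{a.strand}\t{a.codon_start}\n"
            )


def reference_column_map(reference: SequenceRecord) -> list[int]:
    """1-based alignment column of each ungapped reference position."""
    cols = [i + 1 for i, c in enumerate(reference.residues) if c != "-"]
    return cols


def extract_gene(
    alignment: Alignment, reference_id: str, annotation: GeneAnnotation
) -> Alignment:
    """Slice the alignment columns spanned by a feature on the reference.

    The span is mapped through alignment gaps: columns whose ungapped
    reference position lies in ``[start, end]`` are taken, together with any
    interior columns where the reference is gapped (insertions relative to
    the reference inside the gene).  Minus-strand features are
    reverse-complemented, so the result reads in coding orientation.
    """
    if reference_id not in alignment:
        raise SeqIOError(f"reference id {reference_id!r} not in alignment")
    ref = alignment[reference_id]
    cols = reference_column_map(ref)
    if annotation.end > len(cols):
        raise SeqIOError(
            f"{annotation.gene}: span {annotation.start}..{annotation.end} exceeds "
            f"ungapped reference length {len(cols)}"
        )
    first = cols[annotation.start - 1]
    last = cols[annotation.end - 1]
    sub = alignment.columns(range(first, last + 1))
    if annotation.strand == "-":
        sub = Alignment([r.reverse_complement() for r in sub.records])
    return sub


# ---------------------------------------------------------------------------
# Newick trees (dendropy-backed)

def parse_newick(text: str, taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    """Parse a Newick string into a dendropy tree.

    Rootedness is taken from the basal degree: a basal bifurcation is treated
    as rooted, a trifurcation (or higher) as unrooted.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            taxon_namespace=taxon_namespace,
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise SeqIOError(f"malformed Newick: {exc}") from exc
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise SeqIOError("Newick tree has an unlabeled tip")
    tree.is_rooted = len(tree.seed_node.child_nodes()) == 2
    return tree


def read_newick(path: str | Path) -> dendropy.Tree:
    return parse_newick(Path(path).read_text())


def newick_string(tree: dendropy.Tree, precision: int = 10) -> str:
    out = io.StringIO()
    tree.write(
        file=out,
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=f".{precision}g",
    )
    return out.getvalue().strip()


def write_newick(tree: dendropy.Tree, path: str | Path, precision: int = 10) -> None:
    Path(path).write_text(newick_string(tree, precision) + "\n")
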