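"""Vertebrate-mitochondrial translation and amino-acid replacement tables.

Protein-coding mitogenome features are translated under NCBI genetic code
table 2 (vertebrate mitochondrial: AGA/AGG are stop, ATA is Met, TGA is
Trp).  Variable amino-acid positions among a set of taxa are collected into
an :class:`AaReplacementTable`; for exactly three taxa each variable column
is assigned to a branch of the three-taxon tree by parsimony.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "translate_mito",
    "AaReplacementTable",
    "aa_replacement_table",
    "BranchEventCounts",
    "assign_branches",
    "pairwise_aa_differences",
]

_TABLE2 = CodonTable.unambiguous_dna_by_id[2]
_CODON_MAP = dict(_TABLE2.forward_table)
for _stop in _TABLE2.stop_codons:
    _CODON_MAP[_stop] = "*"


def translate_mito(cds_sequence: str, codon_start: int = 1) -> str:
    """Translate DNA under the vertebrate mitochondrial code.

    Codons containing a gap, N or any ambiguity code translate to 'X'; a
    trailing incomplete codon is dropped.  ``codon_start`` (1-3) gives the
    GenBank-style offset of the first complete codon.
    """
    if not cds_sequence:
        raise ValueError("empty CDS sequence")
    if codon_start not in (1, 2, 3):
        raise ValueError("codon_start must be 1, 2 or 3")
    seq = cds_sequence.upper()[codon_start - 1 :]
    aa = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aa.append(_CODON_MAP.get(seq[i : i + 3], "X"))
    return "".join(aa)


@dataclass(frozen=True)
class AaReplacementTable:
    """Variable amino-acid positions across taxa.

    ``proteins[i]``/``positions[i]`` give the protein name and the 1-based
    amino-acid position of column *i*; ``states[taxon][i]`` the residue.
    Positions are strictly increasing within each protein.
    """

    proteins: tuple[str, ...]
    positions: tuple[int, ...]
    states: Mapping[str, str]

    @property
    def n_columns(self) -> int:
        return len(self.positions)

    @property
    def taxa(self) -> list[str]:
        return list(self.states)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (prot, pos) in enumerate(zip(self.proteins, self.positions)):
            row = {"protein": prot, "position": pos}
            for taxon, s in self.states.items():
                row[taxon] = s[i]
            rows.append(row)
        return pd.DataFrame(rows)

    def render(self) -> str:
        """Compact text rendering: vertical-digit positions, dot-compressed
        states (first row literal, later rows '.' where equal to it)."""
        width = max((len(str(p)) for p in self.positions), default=1)
        digit_rows = []
        for d in range(width):
            digit_rows.append("".join(
                str(p).rjust(width, "0")[d] for p in self.positions
            ))
        taxa = self.taxa
        lines = ["protein " + "".join(p[:1] for p in self.proteins)]
        label_w = max(len(t) for t in taxa) + 1
        for row in digit_rows:
            lines.append(" " * label_w + row)
        first = self.states[taxa[0]]
        lines.append(taxa[0].ljust(label_w) + first)
        for t in taxa[1:]:
            s = self.states[t]
            lines.append(t.ljust(label_w) + "".join(
                "." if a == b else a for a, b in zip(s, first)
            ))
        return "\n".join(lines)


def aa_replacement_table(
    aa_alignments: Mapping[str, Mapping[str, str]] | Sequence[tuple[str, Mapping[str, str]]],
    taxa: Sequence[str] | None = None,
) -> AaReplacementTable:
    """Collect variable amino-acid positions across proteins.

    ``aa_alignments`` maps protein name -> {taxon: AA sequence} (equal
    lengths per protein).  A column is variable when at least two distinct
    non-'X' states occur; 'X' (missing) never makes a column variable and is
    retained in the table as missing data.
    """
    items = list(aa_alignments.items()) if isinstance(aa_alignments, Mapping) else list(aa_alignments)
    if taxa is None:
        taxa = list(items[0][1].keys())
    if len(taxa) < 2:
        raise ValueError("need at least two taxa")
    proteins: list[str] = []
    positions: list[int] = []
    cols: dict[str, list[str]] = {t: [] for t in taxa}
    for prot, seqs in items:
        lengths = {len(seqs[t]) for t in taxa}
        if len(lengths) > 1:
            raise ValueError(f"{prot}: unequal amino-acid sequence lengths")
        (length,) = lengths
        for i in range(length):
            residues = [seqs[t][i] for t in taxa]
            observed = {r for r in residues if r != "X"}
            if len(observed) >= 2:
                proteins.append(prot)
                positions.append(i + 1)
                for t, r in zip(taxa, residues):
                    cols[t].append(r)
    return AaReplacementTable(
        tuple(proteins), tuple(positions),
        {t: "".join(cols[t]) for t in taxa},
    )


@dataclass(frozen=True)
class BranchEventCounts:
    """Parsimony assignment of replacement events to three-taxon branches.

    ``tip_a``/``tip_b`` count columns where that tip alone differs,
    ``internal`` columns where the two tips agree against the outgroup, and
    ``ambiguous`` columns where all three states differ.
    """

    tip_a: int
    tip_b: int
    internal: int
    ambiguous: int

    @property
    def total(self) -> int:
        return self.tip_a + self.tip_b + self.internal + self.ambiguous


def assign_branches(table: AaReplacementTable, tip_a: str, tip_b: str,
                    outgroup: str) -> BranchEventCounts:
    """Assign each variable column to a branch by three-taxon parsimony."""
    roles = (tip_a, tip_b, outgroup)
    if sorted(roles) != sorted(table.taxa) or len(set(roles)) != 3:
        raise ValueError(
            f"roles {roles} must name the table's three taxa {table.taxa}"
        )
    a_s, b_s, o_s = (table.states[t] for t in roles)
    ca = cb = ci = camb = 0
    for a, b, o in zip(a_s, b_s, o_s):
        states = {a, b, o}
        if "X" in states or len(states) == 1:
            continue
        if b == o != a:
            ca += 1
        elif a == o != b:
            cb += 1
        elif a == b != o:
            ci += 1
        else:
            camb += 1
    return BranchEventCounts(ca, cb, ci, camb)


def pairwise_aa_differences(table: AaReplacementTable, tip_a: str, tip_b: str) -> int:
    """Columns where the two taxa have distinct non-'X' states."""
    for t in (tip_a, tip_b):
        if t not in table.states:
            raise KeyError(f"taxon {t!r} not in table")
    a_s, b_s = table.states[tip_a], table.states[tip_b]
    return sum(1 for a, b in zip(a_s, b_s) if a != b and "X" not in (a, b))
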