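"""Uncorrected (p-) distances, base-difference counts and indel summaries.

All comparisons use pairwise deletion: an alignment column is *comparable*
for a pair of sequences only when both residues are one of A, C, G, T.
Gaps, N and IUPAC ambiguity codes are excluded, so a column with missing
data in one sequence never contributes to a distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .seqio import Alignment, GeneAnnotation, extract_gene

__all__ = [
    "DistanceResult",
    "IndelEvent",
    "p_distance",
    "count_differences",
    "gene_distance_table",
    "indel_summary",
]

_BASES = frozenset("ACGT")


class UndefinedDistanceError(ValueError):
    """Raised when two sequences share no comparable column.

    Returning 0 here would silently fabricate identity, so the condition is
    an error instead.
    """


@dataclass(frozen=True)
class DistanceResult:
    seq_a: str
    seq_b: str
    p_distance: float
    n_compared: int
    n_diff: int


@dataclass(frozen=True)
class IndelEvent:
    """A maximal gap run present in exactly one sequence of a pair."""

    start_column: int  # 1-based, inclusive
    end_column: int
    length: int
    bearer: str  # id of the sequence carrying the gap
    genes: tuple[str, ...] = ()


def _compare(alignment: Alignment, id_a: str, id_b: str,
             columns: Iterable[int] | None = None) -> tuple[int, int]:
    a = alignment[id_a].residues
    b = alignment[id_b].residues
    if columns is None:
        pairs = zip(a, b)
    else:
        idx = list(columns)
        n = alignment.n_columns
        for c in idx:
            if c < 1 or c > n:
                raise ValueError(f"column {c} outside alignment (1..{n})")
        pairs = ((a[c - 1], b[c - 1]) for c in idx)
    n_comp = n_diff = 0
    for x, y in pairs:
        if x in _BASES and y in _BASES:
            n_comp += 1
            if x != y:
                n_diff += 1
    return n_comp, n_diff


def p_distance(alignment: Alignment, id_a: str, id_b: str,
               columns: Iterable[int] | None = None) -> DistanceResult:
    """Uncorrected proportion of differing sites under pairwise deletion."""
    n_comp, n_diff = _compare(alignment, id_a, id_b, columns)
    if n_comp == 0:
        raise UndefinedDistanceError(
            f"no comparable columns between {id_a!r} and {id_b!r}"
        )
    return DistanceResult(id_a, id_b, n_diff / n_comp, n_comp, n_diff)


def count_differences(alignment: Alignment, id_a: str, id_b: str) -> int:
    """Number of differing comparable columns over the whole alignment."""
    n_comp, n_diff = _compare(alignment, id_a, id_b)
    if n_comp == 0:
        raise UndefinedDistanceError(
            f"no comparable columns between {id_a!r} and {id_b!r}"
        )
    return n_diff


def gene_distance_table(
    alignment: Alignment,
    reference_id: str,
    annotations: Sequence[GeneAnnotation],
    pairs: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Per-gene pairwise p-distances as a tidy table.

    One row per (gene, pair).  Failures (e.g. a pair with no comparable
    column inside a short feature) are recorded in the ``error`` column
    rather than aborting the whole table.
    """
    rows = []
    for ann in annotations:
        try:
            sub = extract_gene(alignment, reference_id, ann)
        except Exception as exc:
            for a, b in pairs:
                rows.append(dict(gene=ann.gene, feature_type=ann.feature_type,
                                 pair_a=a, pair_b=b, p_distance=None,
                                 n_compared=0, n_diff=0, error=str(exc)))
            continue
        for a, b in pairs:
            try:
                res = p_distance(sub, a, b)
                rows.append(dict(gene=ann.gene, feature_type=ann.feature_type,
                                 pair_a=a, pair_b=b, p_distance=res.p_distance,
                                 n_compared=res.n_compared, n_diff=res.n_diff,
                                 error=None))
            except (UndefinedDistanceError, KeyError) as exc:
                rows.append(dict(gene=ann.gene, feature_type=ann.feature_type,
                                 pair_a=a, pair_b=b, p_distance=None,
                                 n_compared=0, n_diff=0, error=str(exc)))
    return pd.DataFrame(rows)


def indel_summary(
    alignment: Alignment,
    id_a: str,
    id_b: str,
    annotations: Sequence[GeneAnnotation] | None = None,
    reference_id: str | None = None,
) -> list[IndelEvent]:
    """Maximal gap runs present in exactly one of the two sequences.

    If ``annotations`` are given (with ``reference_id`` naming the sequence
    carrying the coordinate system, default ``id_b``), each event is tagged
    with the names of the overlapping features.
    """
    a = alignment[id_a].residues
    b = alignment[id_b].residues
    events: list[IndelEvent] = []
    col = 0
    n = alignment.n_columns
    while col < n:
        ga, gb = a[col] == "-", b[col] == "-"
        if ga != gb:
            bearer, partner = (id_a, b) if ga else (id_b, a)
            bearer_seq = a if ga else b
            start = col
            while (col < n and bearer_seq[col] == "-"
                   and (a[col] == "-") != (b[col] == "-")):
                col += 1
            events.append(IndelEvent(start + 1, col, col - start, bearer))
        else:
            col += 1
    if annotations:
        ref_id = reference_id or id_b
        ref = alignment[ref_id]
        # ungapped reference position of each alignment column (0 if gap)
        pos_of_col = []
        p = 0
        for c in ref.residues:
            if c != "-":
                p += 1
            pos_of_col.append(p)
        tagged = []
        for ev in events:
            # reference positions flanking/inside the gap span
            lo = max(pos_of_col[ev.start_column - 1], 1)
            hi = pos_of_col[ev.end_column - 1]
            genes = tuple(dict.fromkeys(
                ann.gene for ann in annotations
                if hi >= ann.start and lo <= ann.end
            ))
            tagged.append(IndelEvent(ev.start_column, ev.end_column,
                                     ev.length, ev.bearer, genes))
        events = tagged
    return events
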