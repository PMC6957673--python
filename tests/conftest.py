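"""Shared fixtures: small alignments, trees and simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest

from mitodate.seqio import Alignment, SequenceRecord, parse_newick


@pytest.fixture
def toy_alignment() -> Alignment:
    return Alignment([
        SequenceRecord("a", "ACGTACGTAC"),
        SequenceRecord("b", "ACGAACGTAC"),
        SequenceRecord("c", "ACGTAC-TNC"),
    ])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20200113)


def jc_pair_alignment(t_total: float, n_sites: int,
                      rng: np.random.Generator) -> Alignment:
    """Two sequences separated by path length ``t_total`` under JC."""
    p_same = 0.25 + 0.75 * np.exp(-4.0 * t_total / 3.0)
    a = rng.integers(0, 4, n_sites)
    b = a.copy()
    mut = rng.random(n_sites) > p_same
    b[mut] = (b[mut] + rng.integers(1, 4, mut.sum())) % 4
    to_str = lambda x: "".join("ACGT"[i] for i in x)  # noqa: E731
    return Alignment([SequenceRecord("a", to_str(a)),
                      SequenceRecord("b", to_str(b))])


@pytest.fixture
def quartet_tree():
    return parse_newick("((a:0.1,b:0.23):0.07,c:0.4,d:0.02);")
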