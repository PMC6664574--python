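"""Pairwise comparison of repeat element copies.

Two copies of the same L1 subfamily are compared at two levels: plain
sequence identity through an affine-gap global alignment, and *motif
identity* — the fraction of motifs whose full span aligns gap-free and
residue-identical to the partner ("completely matched" motifs).  Because a
single substitution or 1-nt indel anywhere inside a motif unmatches it,
motif identity decays much faster with divergence than sequence identity.

Alignment is computed with Bio.Align.PairwiseAligner (global mode, affine
gaps).  A gap of length L costs |gap_open| + |gap_extend| * L.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio import Align

from .scan import MotifSite


@dataclass
class PairAlignment:
    """A global alignment of two sequences as equal-length gapped strings."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("gapped strings must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)

    @property
    def identity(self) -> float:
        """% of alignment columns with identical residues."""
        same = sum(
            1 for x, y in zip(self.aligned_a, self.aligned_b) if x == y and x != "-"
        )
        return 100.0 * same / self.n_columns

    @property
    def gap_fraction(self) -> float:
        """% of alignment columns containing a gap."""
        gaps = sum(
            1 for x, y in zip(self.aligned_a, self.aligned_b) if x == "-" or y == "-"
        )
        return 100.0 * gaps / self.n_columns


def align_global(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -2.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> PairAlignment:
    """Optimal affine-gap global alignment (BLASTN-like default scoring).

    A gap of length L is penalized gap_open + L * gap_extend (both
    negative).  Ties are broken deterministically by taking the aligner's
    first reported optimum.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    # Biopython charges open_gap_score for the first gap position and
    # extend_gap_score for each further one; shift to open+extend*L.
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    return PairAlignment(ga, gb, float(aln.score))


@dataclass
class MotifComparison:
    """Motif correspondence between two elements through an alignment."""

    n_a: int
    n_b: int
    matched_a: int  # motifs of A completely matched in B
    matched_b: int  # motifs of B completely matched in A
    motif_identity_a: float | None  # % of A's motifs matched (None if n_a == 0)
    motif_identity_b: float | None


def _position_to_column(gapped: str) -> list[int]:
    """Map ungapped residue positions to alignment columns."""
    cols = []
    for col, ch in enumerate(gapped):
        if ch != "-":
            cols.append(col)
    return cols


def _matched_count(
    sites: Sequence[MotifSite], own: str, other: str, own_cols: list[int]
) -> int:
    matched = 0
    n_res = len(own_cols)
    for s in sites:
        if s.end > n_res:
            raise ValueError(f"site [{s.start}, {s.end}) outside sequence of {n_res} nt")
        cols = own_cols[s.start : s.end]
        # gap-free in own row <=> columns are consecutive
        if cols[-1] - cols[0] != len(cols) - 1:
            continue
        span_own = own[cols[0] : cols[-1] + 1]
        span_other = other[cols[0] : cols[-1] + 1]
        if "-" in span_other:
            continue
        if span_own == span_other:
            matched += 1
    return matched


def motif_identity(
    sites_a: Sequence[MotifSite],
    sites_b: Sequence[MotifSite],
    alignment: PairAlignment,
) -> MotifComparison:
    """Count completely matched motifs through the alignment.

    A motif of A is completely matched iff its projected alignment columns
    contain no gap in either row and every column is residue-identical.
    Proportions are reported against both denominators; motifs with no
    gap-free identical counterpart count as unmatched.
    """
    cols_a = _position_to_column(alignment.aligned_a)
    cols_b = _position_to_column(alignment.aligned_b)
    matched_a = _matched_count(sites_a, alignment.aligned_a, alignment.aligned_b, cols_a)
    matched_b = _matched_count(sites_b, alignment.aligned_b, alignment.aligned_a, cols_b)
    return MotifComparison(
        n_a=len(sites_a),
        n_b=len(sites_b),
        matched_a=matched_a,
        matched_b=matched_b,
        motif_identity_a=100.0 * matched_a / len(sites_a) if sites_a else None,
        motif_identity_b=100.0 * matched_b / len(sites_b) if sites_b else None,
    )
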