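"""Shared fixtures and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from triplexmotif import (
    MotifCriteria,
    MotifSite,
    NucleotideSequence,
    is_valid_motif,
)


@pytest.fixture
def uc_criteria() -> MotifCriteria:
    return MotifCriteria.uc_hoogsteen()


@pytest.fixture
def ag_criteria() -> MotifCriteria:
    return MotifCriteria.ag_reverse_hoogsteen()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


# ---------------------------------------------------------------------------
# Brute-force scanner oracles (independent of the scanning algorithm: they
# enumerate every substring and apply only the validity predicate)
# ---------------------------------------------------------------------------


def brute_force_windows(
    residues: str, criteria: MotifCriteria, length_range=None
) -> list[tuple[int, int]]:
    """All (start, end) windows that satisfy the validity rules."""
    classset = {criteria.anchor_base, criteria.partner_base}
    n = len(residues)
    minl = criteria.min_length
    if length_range is not None:
        minl = max(minl, length_range[0])
    out = []
    for i in range(n):
        for j in range(i + minl, n + 1):
            if length_range is not None and j - i > length_range[1]:
                break
            sub = residues[i:j]
            if set(sub) - classset:
                break  # extending right cannot remove the foreign base
            if is_valid_motif(sub, criteria):
                out.append((i, j))
    return out


def brute_force_sites(residues: str, criteria: MotifCriteria) -> list[tuple[int, int]]:
    """Valid windows minus those contained in a longer valid window."""
    wins = brute_force_windows(residues, criteria)
    maximal = [
        (i, j)
        for (i, j) in wins
        if not any(
            (i2 <= i and j <= j2) and (i2, j2) != (i, j) for (i2, j2) in wins
        )
    ]
    return sorted(maximal)


def random_sequence(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def make_seq(residues: str, seq_id: str = "s") -> NucleotideSequence:
    return NucleotideSequence(seq_id, residues.upper().replace("U", "T"))


def coords(sites: list[MotifSite]) -> list[tuple[int, int]]:
    return sorted((s.start, s.end) for s in sites)
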