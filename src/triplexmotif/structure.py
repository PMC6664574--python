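"""Secondary-structure loop classification and motif accessibility filtering.

A motif can only present its bases for triplex formation where the RNA is
single-stranded, so each motif is reduced to its *usable length*: the
longest run of consecutive motif positions that are unpaired, lie in an
eligible loop type, and belong to the same loop instance.  Motifs whose
usable length stays above the minimum motif length are retained.

Loop taxonomy is the standard one: a loop closed by one helix is a hairpin;
by two helices an internal loop (a bulge when one side is empty); by three
or more a multibranch loop; unpaired positions enclosed by no pair are
exterior.  Eligible types default to {hairpin, internal, bulge} — the
single-stranded loops counted in the source analysis; multibranch and
exterior can be switched on.  Pseudoknots are rejected, not silently broken.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import UNPAIRED
from .scan import MotifCriteria, MotifSite
from .stats import LengthDistribution, length_distribution

PAIRED = "paired"
HAIRPIN = "hairpin"
INTERNAL = "internal"
BULGE = "bulge"
MULTIBRANCH = "multibranch"
EXTERIOR = "exterior"

DEFAULT_ELIGIBLE_LOOPS = frozenset({HAIRPIN, INTERNAL, BULGE})


@dataclass
class SecondaryStructure:
    """Pairing table plus per-position loop labels and loop-instance ids."""

    seq_id: str
    pairing: np.ndarray
    loop_label: list[str]
    loop_id: np.ndarray  # -1 for paired positions; same id = same loop instance

    def __len__(self) -> int:
        return len(self.pairing)


def _check_pairing(pairing: np.ndarray) -> list[tuple[int, int]]:
    pairs = []
    for i, j in enumerate(pairing):
        if j == UNPAIRED:
            continue
        if j == i:
            raise ValueError(f"position {i} paired to itself")
        if pairing[j] != i:
            raise ValueError(f"pairing is not an involution at positions {i}/{j}")
        if i < j:
            pairs.append((i, int(j)))
    # pseudoknot (crossing pair) detection via nesting stack
    stack: list[tuple[int, int]] = []
    for i, j in sorted(pairs):
        while stack and stack[-1][1] < i:
            stack.pop()
        if stack and not (j < stack[-1][1]):
            raise ValueError(
                f"crossing pairs (pseudoknot): ({stack[-1][0]},{stack[-1][1]}) vs ({i},{j})"
            )
        stack.append((i, j))
    return pairs


def classify_positions(pairing: np.ndarray, seq_id: str = "?") -> SecondaryStructure:
    """Label every position as paired or by the loop type enclosing it."""
    pairing = np.asarray(pairing, dtype=np.int64)
    n = len(pairing)
    pairs = _check_pairing(pairing)
    labels = [PAIRED if pairing[i] != UNPAIRED else None for i in range(n)]
    loop_id = np.full(n, -1, dtype=np.int64)
    next_loop = 0

    # walk each pair's interior: direct children helices + directly enclosed
    # unpaired positions define the pair's loop
    for i, j in pairs:
        unpaired_left: list[int] = []  # between i and first child (5' side)
        members: list[int] = []
        sides = 0  # number of maximal unpaired stretches in the loop
        children = 0
        k = i + 1
        in_gap = False
        while k < j:
            if pairing[k] == UNPAIRED:
                members.append(k)
                if not in_gap:
                    sides += 1
                    in_gap = True
                k += 1
            else:
                children += 1
                in_gap = False
                k = int(pairing[k]) + 1
        if not members:
            continue  # stacked helix or loop with no unpaired bases
        if children == 0:
            kind = HAIRPIN
        elif children == 1:
            kind = INTERNAL if sides == 2 else BULGE
        else:
            kind = MULTIBRANCH
        for m in members:
            labels[m] = kind
            loop_id[m] = next_loop
        next_loop += 1

    # exterior: unpaired positions enclosed by no pair (one loop instance)
    ext = [i for i in range(n) if labels[i] is None]
    for m in ext:
        labels[m] = EXTERIOR
        loop_id[m] = next_loop
    return SecondaryStructure(seq_id, pairing, labels, loop_id)


@dataclass
class UsableMotif:
    """A motif site with its accessible (single-stranded) length."""

    site: MotifSite
    usable_length: int
    retained: bool


def usable_length(
    site: MotifSite,
    structure: SecondaryStructure,
    eligible: frozenset[str] | set[str] = DEFAULT_ELIGIBLE_LOOPS,
    contiguous: bool = True,
) -> int:
    """Accessible length of a motif within the structure.

    With ``contiguous=True`` (default): the longest run of consecutive site
    positions that are unpaired, in an eligible loop type, and in the same
    loop instance.  With ``contiguous=False``: the total count of such
    positions anywhere in the motif.
    """
    if site.start < 0 or site.end > len(structure):
        raise ValueError(f"site [{site.start}, {site.end}) outside structure bounds")
    ok = [
        structure.loop_label[p] in eligible for p in range(site.start, site.end)
    ]
    ids = structure.loop_id[site.start : site.end]
    if not contiguous:
        return int(sum(ok))
    best = cur = 0
    prev_id = None
    for flag, lid in zip(ok, ids):
        if flag and (cur == 0 or lid == prev_id):
            cur += 1
        elif flag:
            cur = 1
        else:
            cur = 0
        prev_id = lid if flag else None
        best = max(best, cur)
    return best


def filter_sites(
    sites: Sequence[MotifSite],
    structure: SecondaryStructure,
    criteria: MotifCriteria,
    eligible: frozenset[str] | set[str] = DEFAULT_ELIGIBLE_LOOPS,
    contiguous: bool = True,
) -> tuple[list[UsableMotif], LengthDistribution, LengthDistribution]:
    """Reduce sites to their usable lengths and split retained/lost.

    Returns (usable motifs, before-distribution of site lengths,
    after-distribution of usable lengths of the retained motifs).
    """
    usable: list[UsableMotif] = []
    for s in sites:
        ul = usable_length(s, structure, eligible, contiguous)
        usable.append(UsableMotif(s, ul, ul >= criteria.min_length))
    before = length_distribution(sites)
    after_counts: dict[int, int] = {}
    for u in usable:
        if u.retained:
            after_counts[u.usable_length] = after_counts.get(u.usable_length, 0) + 1
    return usable, before, LengthDistribution(after_counts)
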