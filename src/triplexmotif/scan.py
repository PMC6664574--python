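"""Redundant UC(TC) / AG motif definition and scanning.

A pyrimidine ("r-UC") motif is a string over {U/T, C}, at least 5 nt long,
with at least 3 nucleotides strictly between the first and the last U/T
(the anchor base), no more than 3 U/Ts in a row and at most 2 Cs in a row —
the composition compatible with Hoogsteen (parallel) triplex formation at
neutral pH.  The purine ("r-AG") motif is its base-complement analogue
(anchor A, partner G); in reverse-Hoogsteen (antiparallel) mode the limit on
consecutive Gs is lifted, because G runs increase reverse-Hoogsteen affinity.

Two counting semantics coexist: a *site* is a maximal valid window (no valid
window of the same class strictly contains it), while *windows* enumerates
every valid substring including nested and overlapping ones (used for the
cumulative short-motif ratios).
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace

from .io import NucleotideSequence

HOOGSTEEN = "hoogsteen"
REVERSE_HOOGSTEEN = "reverse_hoogsteen"

PYRIMIDINE = "UC"  # anchor U/T, partner C
PURINE = "AG"  # anchor A, partner G

_CLASS_BASES = {PYRIMIDINE: ("T", "C"), PURINE: ("A", "G")}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class MotifCriteria:
    """Parameterization of the motif validity rules.

    ``max_partner_run=None`` means unlimited (reverse-Hoogsteen purine
    default).  ``anchor_bounded`` additionally requires the motif to begin
    and end with the anchor base; the published criteria do not ask for it,
    so it is off by default.
    """

    motif_class: str = PYRIMIDINE
    mode: str = HOOGSTEEN
    min_length: int = 5
    min_internal_gap: int = 3
    max_anchor_run: int = 3
    max_partner_run: int | None = 2
    anchor_bounded: bool = False

    def __post_init__(self) -> None:
        if self.motif_class not in _CLASS_BASES:
            raise ValueError(f"motif_class must be 'UC' or 'AG', got {self.motif_class!r}")
        if self.mode not in (HOOGSTEEN, REVERSE_HOOGSTEEN):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.min_length < self.min_internal_gap + 2:
            raise ValueError("min_length must be >= min_internal_gap + 2")
        if self.max_anchor_run < 1 or (
            self.max_partner_run is not None and self.max_partner_run < 1
        ):
            raise ValueError("run limits must be >= 1")

    @property
    def anchor_base(self) -> str:
        return _CLASS_BASES[self.motif_class][0]

    @property
    def partner_base(self) -> str:
        return _CLASS_BASES[self.motif_class][1]

    @classmethod
    def uc_hoogsteen(cls, **kw) -> "MotifCriteria":
        """Pyrimidine criteria: <=3 U/T in a row, <=2 C in a row."""
        return cls(motif_class=PYRIMIDINE, mode=HOOGSTEEN, max_partner_run=2, **kw)

    @classmethod
    def ag_reverse_hoogsteen(cls, **kw) -> "MotifCriteria":
        """Purine criteria with no limit on consecutive Gs."""
        return cls(motif_class=PURINE, mode=REVERSE_HOOGSTEEN, max_partner_run=None, **kw)

    @classmethod
    def ag_hoogsteen(cls, **kw) -> "MotifCriteria":
        """Purine criteria with the Hoogsteen-mode partner-run limit (<=2 Gs)."""
        return cls(motif_class=PURINE, mode=HOOGSTEEN, max_partner_run=2, **kw)

    def complementary(self) -> "MotifCriteria":
        """Criteria for the base-complement class with mirrored run limits."""
        other = PURINE if self.motif_class == PYRIMIDINE else PYRIMIDINE
        return replace(self, motif_class=other)


@dataclass
class MotifSite:
    """One located motif (0-based half-open coordinates on the sequence)."""

    seq_id: str
    start: int
    end: int
    motif_class: str
    sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError("site coordinates do not match its sequence")

    @property
    def length(self) -> int:
        return self.end - self.start


def _normalize_query(s: str) -> str:
    return s.upper().replace("U", "T")


def is_valid_motif(s: str, criteria: MotifCriteria) -> bool:
    """Check the motif validity rules on a residue string.

    N never occurs inside a motif (ambiguity breaks motifs); residues
    outside {A, C, G, T/U, N} raise.
    """
    if not s:
        raise ValueError("empty motif string")
    s = _normalize_query(s)
    bad = set(s) - {"A", "C", "G", "T", "N"}
    if bad:
        raise ValueError(f"illegal residues {sorted(bad)}")
    anchor, partner = criteria.anchor_base, criteria.partner_base
    if set(s) - {anchor, partner}:
        return False  # includes N and the other class's bases
    if len(s) < criteria.min_length:
        return False
    if criteria.anchor_bounded and (s[0] != anchor or s[-1] != anchor):
        return False
    first = s.find(anchor)
    last = s.rfind(anchor)
    if first < 0 or last - first - 1 < criteria.min_internal_gap:
        return False
    # run-length limits
    run_char, run_len = "", 0
    for ch in s:
        run_len = run_len + 1 if ch == run_char else 1
        run_char = ch
        if ch == anchor and run_len > criteria.max_anchor_run:
            return False
        if (
            ch == partner
            and criteria.max_partner_run is not None
            and run_len > criteria.max_partner_run
        ):
            return False
    return True


def _class_runs(s: str, anchor: str, partner: str):
    """Maximal runs [a, b) consisting only of the class's two bases."""
    classset = {anchor, partner}
    i, n = 0, len(s)
    while i < n:
        if s[i] in classset:
            j = i
            while j < n and s[j] in classset:
                j += 1
            yield i, j
            i = j
        else:
            i += 1


def _violation_starts(s: str, a: int, b: int, base: str, max_run: int) -> list[int]:
    """Start positions p in [a, b) where s[p : p + max_run + 1] is all ``base``."""
    k = max_run + 1
    out = []
    run = 0
    for i in range(a, b):
        run = run + 1 if s[i] == base else 0
        if run >= k:
            out.append(i - k + 1)
    return out


def _scan_run(s: str, a: int, b: int, criteria: MotifCriteria, seq_id: str) -> list[MotifSite]:
    anchor, partner = criteria.anchor_base, criteria.partner_base
    ka = criteria.max_anchor_run + 1
    bad_a = _violation_starts(s, a, b, anchor, criteria.max_anchor_run)
    if criteria.max_partner_run is not None:
        kp = criteria.max_partner_run + 1
        bad_p = _violation_starts(s, a, b, partner, criteria.max_partner_run)
    else:
        kp, bad_p = 0, []
    anchors = [i for i in range(a, b) if s[i] == anchor]

    sites: list[MotifSite] = []
    last_end = -1
    for i in range(a, b):
        if criteria.anchor_bounded and s[i] != anchor:
            continue
        # largest j such that [i, j) contains no over-long run
        jmax = b
        idx = bisect_left(bad_a, i)
        if idx < len(bad_a):
            jmax = min(jmax, bad_a[idx] + ka - 1)
        idx = bisect_left(bad_p, i)
        if idx < len(bad_p):
            jmax = min(jmax, bad_p[idx] + kp - 1)
        end = jmax
        if criteria.anchor_bounded:
            # trim to the last anchor before jmax
            idx = bisect_left(anchors, jmax) - 1
            if idx < 0 or anchors[idx] < i:
                continue
            end = anchors[idx] + 1
        if end - i < criteria.min_length:
            continue
        lo = bisect_left(anchors, i)
        hi = bisect_left(anchors, end) - 1
        if lo >= len(anchors) or anchors[lo] >= end or hi < lo:
            continue
        if anchors[hi] - anchors[lo] - 1 < criteria.min_internal_gap:
            continue
        if end > last_end:  # otherwise contained in the previous site
            sites.append(MotifSite(seq_id, i, end, criteria.motif_class, s[i:end]))
            last_end = end
    return sites


def find_motif_sites(seq: NucleotideSequence, criteria: MotifCriteria) -> list[MotifSite]:
    """Locate motif *sites*: maximal valid windows, sorted by start.

    Windows are confined to maximal same-class runs; a run that violates a
    run-length rule is not discarded wholesale — its maximal valid
    sub-windows are reported.
    """
    s = seq.residues
    sites: list[MotifSite] = []
    for a, b in _class_runs(s, criteria.anchor_base, criteria.partner_base):
        sites.extend(_scan_run(s, a, b, criteria, seq.id))
    return sites


def enumerate_motif_windows(
    seq: NucleotideSequence,
    criteria: MotifCriteria,
    length_range: tuple[int, int] | None = None,
) -> list[MotifSite]:
    """Enumerate *every* valid window, including nested/overlapping ones."""
    s = seq.residues
    minl = criteria.min_length
    maxl = None
    if length_range is not None:
        minl = max(minl, length_range[0])
        maxl = length_range[1]
    anchor, partner = criteria.anchor_base, criteria.partner_base
    ka = criteria.max_anchor_run + 1
    windows: list[MotifSite] = []
    for a, b in _class_runs(s, anchor, partner):
        bad_a = _violation_starts(s, a, b, anchor, criteria.max_anchor_run)
        if criteria.max_partner_run is not None:
            kp = criteria.max_partner_run + 1
            bad_p = _violation_starts(s, a, b, partner, criteria.max_partner_run)
        else:
            kp, bad_p = 0, []
        anchors = [i for i in range(a, b) if s[i] == anchor]
        for i in range(a, b):
            if criteria.anchor_bounded and s[i] != anchor:
                continue
            jmax = b
            idx = bisect_left(bad_a, i)
            if idx < len(bad_a):
                jmax = min(jmax, bad_a[idx] + ka - 1)
            idx = bisect_left(bad_p, i)
            if idx < len(bad_p):
                jmax = min(jmax, bad_p[idx] + kp - 1)
            hi_j = jmax if maxl is None else min(jmax, i + maxl)
            lo = bisect_left(anchors, i)
            if lo >= len(anchors):
                continue
            first_anchor = anchors[lo]
            for j in range(i + minl, hi_j + 1):
                if criteria.anchor_bounded and s[j - 1] != anchor:
                    continue
                hi = bisect_right(anchors, j - 1) - 1
                if hi < lo or first_anchor >= j:
                    continue
                if anchors[hi] - first_anchor - 1 < criteria.min_internal_gap:
                    continue
                windows.append(MotifSite(seq.id, i, j, criteria.motif_class, s[i:j]))
    windows.sort(key=lambda w: (w.start, w.end))
    return windows


def complement(seq: NucleotideSequence) -> NucleotideSequence:
    """Base-wise complement (no reversal)."""
    return NucleotideSequence(seq.id, seq.residues.translate(_COMPLEMENT), seq.is_rna)


def reverse_complement(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


def invert_region(seq: NucleotideSequence, start: int, end: int) -> NucleotideSequence:
    """Replace [start, end) by its reverse complement (a genomic inversion).

    Applying the same inversion twice restores the original sequence.  An
    inversion swaps the motif classes of the sites inside it: pyrimidine
    motifs reappear as purine motifs and vice versa.
    """
    if not (0 <= start < end <= len(seq.residues)):
        raise ValueError(f"inversion [{start}, {end}) out of range for length {len(seq)}")
    s = seq.residues
    return NucleotideSequence(
        seq.id, s[:start] + reverse_complement(s[start:end]) + s[end:], seq.is_rna
    )
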