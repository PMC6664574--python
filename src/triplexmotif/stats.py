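"""Summary statistics over motif sites and repeat annotations.

Covers per-sequence motif profiles (site counts, occupancy = fraction of
nucleotides covered by the union of sites, sites per kb, and the UC/AG
occupancy ratio used as a lncRNA fingerprint), empirical motif-length
distributions compared with the Kolmogorov–Smirnov distance, cumulative
overlapping-window ratios, and chromosome x repeat-family proportion tables
with per-length-bin random sampling.

The KS distance here is the plain sup-difference of two discrete empirical
CDFs — a descriptive distance with a conventional similarity threshold of
0.100, not a hypothesis test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import NucleotideSequence, RepeatAnnotation
from .scan import MotifCriteria, MotifSite, find_motif_sites

#: Descriptive similarity threshold for motif-length distributions.
KS_SIMILARITY_THRESHOLD = 0.100


@dataclass
class LengthDistribution:
    """Empirical distribution of motif lengths (in nucleotides)."""

    counts: dict[int, int]

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def cdf(self, x: float) -> float:
        """F(x) = P(length <= x)."""
        if self.n == 0:
            raise ValueError("CDF of an empty distribution")
        return sum(c for length, c in self.counts.items() if length <= x) / self.n

    @property
    def support(self) -> list[int]:
        return sorted(self.counts)


def length_distribution(sites: Sequence[MotifSite]) -> LengthDistribution:
    """Tabulate site lengths (sites should be of a single class)."""
    counts: dict[int, int] = {}
    for s in sites:
        counts[s.length] = counts.get(s.length, 0) + 1
    return LengthDistribution(counts)


def ks_distance(d1: LengthDistribution, d2: LengthDistribution) -> float:
    """max_x |F1(x) - F2(x)| over the union of observed lengths."""
    if d1.n == 0 or d2.n == 0:
        raise ValueError("KS distance requires non-empty distributions")
    xs = sorted(set(d1.counts) | set(d2.counts))
    return float(max(abs(d1.cdf(x) - d2.cdf(x)) for x in xs))


def similar(d1: LengthDistribution, d2: LengthDistribution) -> bool:
    """Whether the two length distributions fall under the 0.100 threshold."""
    return ks_distance(d1, d2) < KS_SIMILARITY_THRESHOLD


# ---------------------------------------------------------------------------
# Per-sequence motif profile
# ---------------------------------------------------------------------------


def union_coverage(sites: Iterable[MotifSite]) -> int:
    """Number of positions covered by the union of the site intervals."""
    ivals = sorted((s.start, s.end) for s in sites)
    covered = 0
    cur_start, cur_end = None, None
    for start, end in ivals:
        if cur_end is None or start > cur_end:
            if cur_end is not None:
                covered += cur_end - cur_start
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_end is not None:
        covered += cur_end - cur_start
    return covered


@dataclass
class MotifProfile:
    """Motif summary of one sequence, per class."""

    seq_id: str
    seq_length: int
    site_count: dict[str, int]
    occupancy: dict[str, float]  # fraction of nucleotides covered (union)
    frequency: dict[str, float]  # sites per kb
    ratio_uc_over_ag: float | None  # None when AG occupancy is zero


def profile_sequence(
    seq: NucleotideSequence,
    criteria_uc: MotifCriteria | None = None,
    criteria_ag: MotifCriteria | None = None,
) -> MotifProfile:
    """Count maximal sites of both classes and derive occupancy statistics.

    The UC/AG ratio is computed from the unrounded occupancies; round only
    for display.  The occupancy denominator is the full sequence length
    (including N runs).
    """
    if len(seq) == 0:
        raise ValueError("cannot profile a zero-length sequence")
    criteria_uc = criteria_uc or MotifCriteria.uc_hoogsteen()
    criteria_ag = criteria_ag or MotifCriteria.ag_reverse_hoogsteen()
    counts, occ, freq = {}, {}, {}
    for label, crit in (("UC", criteria_uc), ("AG", criteria_ag)):
        sites = find_motif_sites(seq, crit)
        counts[label] = len(sites)
        occ[label] = union_coverage(sites) / len(seq)
        freq[label] = len(sites) / (len(seq) / 1000)
    ratio = occ["UC"] / occ["AG"] if occ["AG"] > 0 else None
    return MotifProfile(seq.id, len(seq), counts, occ, freq, ratio)


def cumulative_short_motif_ratio(
    windows: Sequence[MotifSite], length_band: tuple[int, int] = (5, 7)
) -> float:
    """Fraction of overlapping windows whose length falls in the band.

    ``windows`` should come from :func:`~triplexmotif.scan.enumerate_motif_windows`
    (overlaps included); the 5–7-nt band covers the minimum-length motifs
    preferentially used for multi-site binding.
    """
    if not windows:
        raise ValueError("no windows to summarize")
    lo, hi = length_band
    in_band = sum(1 for w in windows if lo <= w.length <= hi)
    return in_band / len(windows)


# ---------------------------------------------------------------------------
# RepeatMasker family statistics
# ---------------------------------------------------------------------------


def family_proportions(
    annotations: Sequence[RepeatAnnotation],
    chrom_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """Per-chromosome proportion of bases annotated to each repeat family.

    proportion = sum of element lengths of the family / chromosome length.
    Overlapping records are summed raw with a warning (RepeatMasker output
    rarely overlaps).
    """
    for a in annotations:
        if a.chrom not in chrom_lengths:
            raise KeyError(f"no length given for chromosome {a.chrom!r}")
        if a.end > chrom_lengths[a.chrom]:
            raise ValueError(
                f"annotation [{a.start}, {a.end}) beyond end of {a.chrom} "
                f"({chrom_lengths[a.chrom]} bp)"
            )
    _warn_if_overlapping(annotations)
    rows: dict[str, dict[str, int]] = {c: {} for c in chrom_lengths}
    for a in annotations:
        rows[a.chrom][a.family] = rows[a.chrom].get(a.family, 0) + a.length
    families = sorted({a.family for a in annotations})
    df = pd.DataFrame(
        [
            [rows[c].get(f, 0) / chrom_lengths[c] for f in families]
            for c in chrom_lengths
        ],
        index=list(chrom_lengths),
        columns=families,
    )
    df.index.name = "chrom"
    return df


def _warn_if_overlapping(annotations: Sequence[RepeatAnnotation]) -> None:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for a in annotations:
        by_chrom.setdefault(a.chrom, []).append((a.start, a.end))
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        for (s1, e1), (s2, _) in zip(ivals, ivals[1:]):
            if s2 < e1:
                warnings.warn(
                    f"overlapping annotations on {chrom}; proportions use raw summed lengths",
                    stacklevel=3,
                )
                return


def make_length_bins(max_bp: int) -> list[tuple[int, int]]:
    """Right-closed element-length bins: every 100 bp up to 1,000 bp, then
    every 1,000 bp (matches labels "<=100", "101–200", ..., "1,001–2,000")."""
    bins = [(lo, lo + 100) for lo in range(0, 1000, 100)]
    lo = 1000
    while lo < max_bp:
        bins.append((lo, lo + 1000))
        lo += 1000
    return bins


def assign_length_bin(length: int, bins: Sequence[tuple[int, int]]) -> int | None:
    """Index of the right-closed bin (lo, hi] containing ``length``."""
    for i, (lo, hi) in enumerate(bins):
        if lo < length <= hi:
            return i
    return None


def family_length_bin_table(
    annotations: Sequence[RepeatAnnotation],
    bins: Sequence[tuple[int, int]],
) -> pd.DataFrame:
    """Count and total bp of elements per family x length bin."""
    records = []
    for a in annotations:
        idx = assign_length_bin(a.length, bins)
        if idx is None:
            continue
        lo, hi = bins[idx]
        records.append({"family": a.family, "bin": f"({lo},{hi}]", "length": a.length})
    if not records:
        return pd.DataFrame(columns=["family", "bin", "count", "total_bp"])
    df = pd.DataFrame(records)
    out = (
        df.groupby(["family", "bin"])
        .agg(count=("length", "size"), total_bp=("length", "sum"))
        .reset_index()
    )
    return out


def sample_by_length_bin(
    annotations: Sequence[RepeatAnnotation],
    bins: Sequence[tuple[int, int]],
    k: int,
    seed: int | np.random.Generator,
) -> list[RepeatAnnotation]:
    """Uniformly sample up to ``k`` elements per length bin, without
    replacement; bins holding fewer than ``k`` elements contribute all of
    their elements (mirrors the sampling of 50 L1s / 30 L2s per bin)."""
    if not bins:
        raise ValueError("empty bin set")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_bin: dict[int, list[RepeatAnnotation]] = {i: [] for i in range(len(bins))}
    for a in annotations:
        idx = assign_length_bin(a.length, bins)
        if idx is not None:
            by_bin[idx].append(a)
    sampled: list[RepeatAnnotation] = []
    for i in range(len(bins)):
        members = by_bin[i]
        if len(members) <= k:
            sampled.extend(members)
        else:
            chosen = rng.choice(len(members), size=k, replace=False)
            sampled.extend(members[j] for j in sorted(chosen))
    return sampled
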