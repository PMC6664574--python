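"""Synthetic inputs with known ground truth.

Every stage of the pipeline can be exercised without downloads: sequences
with planted motifs of known positions and lengths, 5'-truncated L1-like
element families with a RepeatMasker-format annotation fixture, mutated
sequence pairs with a reconstructible edit list, and valid dot-bracket
structure fixtures with forced single-stranded windows.

Planted motifs are flanked by an opposite-class base so a plant is always
exactly one maximal same-class run: scanner recall on plants is exact by
construction.  Accidental motifs arising in the random background are
permitted; callers recover them by scanning and subtracting the plant list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import NucleotideSequence, RepeatAnnotation
from .scan import (
    PURINE,
    PYRIMIDINE,
    MotifCriteria,
    MotifSite,
    is_valid_motif,
)

#: Default motif-length weights: lengths 5-17 nt with geometrically decaying
#: frequency (short motifs dominate real motif-length distributions).
DEFAULT_LENGTH_WEIGHTS = {length: 0.6 ** (length - 5) for length in range(5, 18)}

_CLASS_BASES = {PYRIMIDINE: ("T", "C"), PURINE: ("A", "G")}
_OPPOSITE = {PYRIMIDINE: ("A", "G"), PURINE: ("T", "C")}

_DEFAULT_CRITERIA = {
    PYRIMIDINE: MotifCriteria.uc_hoogsteen(),
    PURINE: MotifCriteria.ag_reverse_hoogsteen(),
}


@dataclass
class SyntheticConfig:
    """Configuration for the motif-planting sequence generator."""

    seq_length: int = 10_000
    target_occupancy: dict[str, float] = field(default_factory=lambda: {"AG": 0.15})
    motif_length_dist: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_WEIGHTS)
    )
    background_composition: dict[str, float] = field(
        default_factory=lambda: {b: 0.25 for b in "ACGT"}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.target_occupancy.values()) >= 1.0:
            raise ValueError("target occupancies must sum to < 1")
        if any(l < 5 for l in self.motif_length_dist):
            raise ValueError("motif lengths must be >= 5")


def _random_motif(
    length: int, motif_class: str, rng: np.random.Generator, max_tries: int = 2000
) -> str:
    """Rejection-sample a residue string satisfying the class criteria."""
    bases = _CLASS_BASES[motif_class]
    criteria = _DEFAULT_CRITERIA[motif_class]
    for _ in range(max_tries):
        s = "".join(rng.choice(bases, size=length))
        if is_valid_motif(s, criteria):
            return s
    raise RuntimeError(f"could not sample a valid {motif_class} motif of length {length}")


def generate_motif_sequence(
    cfg: SyntheticConfig,
) -> tuple[NucleotideSequence, list[MotifSite]]:
    """Generate a random sequence with planted motifs (the ground truth).

    Motif lengths are drawn from ``cfg.motif_length_dist`` until each
    class's planted bases reach ``target_occupancy * seq_length``; plants
    are placed uniformly with >= 2 background positions between plants, and
    the positions immediately flanking each plant are set to an
    opposite-class base, so every plant is one maximal class run and the
    scanner recovers it exactly.  Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.seq_length
    lengths = np.array(sorted(cfg.motif_length_dist))
    weights = np.array([cfg.motif_length_dist[l] for l in lengths], dtype=float)
    weights /= weights.sum()

    plants: list[tuple[str, str]] = []  # (class, motif string)
    total_plant = 0
    for cls, target in cfg.target_occupancy.items():
        if cls not in _CLASS_BASES:
            raise ValueError(f"unknown motif class {cls!r}")
        goal = target * L
        planted = 0
        while planted < goal:
            l = int(rng.choice(lengths, p=weights))
            if planted + l > goal + lengths.min():  # avoid large overshoot
                l = int(lengths.min())
            plants.append((cls, _random_motif(l, cls, rng)))
            planted += l
            total_plant += l
    n = len(plants)
    reserved_gaps = 2 * max(n - 1, 0)
    free = L - total_plant - reserved_gaps
    if free < 0:
        raise ValueError(
            f"infeasible config: {total_plant} planted nt + spacers exceed length {L}"
        )
    order = rng.permutation(n)
    plants = [plants[i] for i in order]
    extra = rng.multinomial(free, np.full(n + 1, 1.0 / (n + 1))) if n else np.array([free])

    bases = sorted(cfg.background_composition)
    probs = np.array([cfg.background_composition[b] for b in bases], dtype=float)
    probs /= probs.sum()
    seq = rng.choice(bases, size=L, p=probs)

    sites: list[MotifSite] = []
    pos = int(extra[0])
    seq_id = f"synthetic_seed{cfg.seed}"
    for i, (cls, motif) in enumerate(plants):
        start, end = pos, pos + len(motif)
        seq[start:end] = list(motif)
        opp = _OPPOSITE[cls]
        if start > 0:
            seq[start - 1] = opp[rng.integers(len(opp))]
        if end < L:
            seq[end] = opp[rng.integers(len(opp))]
        sites.append(MotifSite(seq_id, start, end, cls, motif))
        pos = end + (2 + int(extra[i + 1]) if i < n - 1 else 0)
    sites.sort(key=lambda s: s.start)
    return NucleotideSequence(seq_id, "".join(seq)), sites


# ---------------------------------------------------------------------------
# L1-like families
# ---------------------------------------------------------------------------


@dataclass
class L1Family:
    """A synthetic LINE-1-like family: consensus, 5'-truncated copies and a
    RepeatMasker-style annotation fixture on one synthetic chromosome."""

    consensus: NucleotideSequence
    elements: list[NucleotideSequence]
    annotations: list[RepeatAnnotation]
    chrom: str
    chrom_length: int


def default_truncation_lengths(
    n: int, consensus_length: int, rng: np.random.Generator
) -> np.ndarray:
    """Element lengths emulating pervasive 5' truncation: ~10% full length,
    the rest exponentially distributed (mean = consensus_length / 3)."""
    lengths = np.minimum(
        rng.exponential(scale=consensus_length / 3, size=n).astype(int) + 10,
        consensus_length,
    )
    full = rng.random(n) < 0.10
    lengths[full] = consensus_length
    return lengths


def generate_l1_family(
    consensus_length: int,
    n_elements: int,
    truncation_lengths=None,
    cfg: SyntheticConfig | None = None,
    seed: int = 0,
    chrom: str = "chrXsyn",
) -> L1Family:
    """Generate an L1-like family of 3'-anchored suffixes of one consensus.

    The consensus carries planted AG motifs at ~15% occupancy and UC motifs
    at ~3% (the L1-like regime).  ``truncation_lengths`` may be an explicit
    sequence of element lengths or a callable ``(n, consensus_length, rng)
    -> lengths``; the default emulates pervasive 5' truncation.  Elements
    shorter than 5 nt are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    if cfg is None:
        cfg = SyntheticConfig(
            seq_length=consensus_length,
            target_occupancy={"AG": 0.15, "UC": 0.03},
            seed=int(rng.integers(2**31)),
        )
    consensus, _ = generate_motif_sequence(cfg)
    consensus = NucleotideSequence("L1_syn_consensus", consensus.residues)

    if truncation_lengths is None:
        lengths = default_truncation_lengths(n_elements, consensus_length, rng)
    elif callable(truncation_lengths):
        lengths = np.asarray(truncation_lengths(n_elements, consensus_length, rng))
    else:
        lengths = np.asarray(list(truncation_lengths), dtype=int)
        if len(lengths) != n_elements:
            raise ValueError("truncation_lengths must provide one length per element")
    if (lengths > consensus_length).any():
        raise ValueError("element length exceeds consensus length")

    elements: list[NucleotideSequence] = []
    annotations: list[RepeatAnnotation] = []
    gap = 100
    pos = gap
    for i, l in enumerate(lengths):
        l = int(l)
        if l < 5:
            warnings.warn(f"element {i} truncated to {l} nt (< 5), skipped", stacklevel=2)
            continue
        residues = consensus.residues[-l:]  # 5'-truncated = 3'-anchored suffix
        elements.append(NucleotideSequence(f"L1_syn_e{i}", residues))
        annotations.append(
            RepeatAnnotation(
                chrom=chrom,
                start=pos,
                end=pos + l,
                strand="+",
                repeat_class="LINE",
                family="L1",
                subfamily="L1_syn",
            )
        )
        pos += l + gap
    return L1Family(consensus, elements, annotations, chrom, pos)


# ---------------------------------------------------------------------------
# Mutated pairs
# ---------------------------------------------------------------------------

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass
class MutationModel:
    """Per-site substitution/indel model for diverging sequence pairs."""

    substitution_rate: float = 0.0
    transition_fraction: float = 0.67
    indel_rate: float = 0.0
    indel_length_dist: dict[int, float] = field(
        default_factory=lambda: {1: 0.6, 2: 0.25, 3: 0.15}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "transition_fraction", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def mutate_pair(
    seq: NucleotideSequence, model: MutationModel
) -> tuple[NucleotideSequence, list[tuple]]:
    """Produce a diverged copy plus the ground-truth edit list.

    Edits are tuples ``("sub", pos, ref, alt)``, ``("del", pos, ref)`` and
    ``("ins", pos, inserted)`` with positions on the *original* sequence
    (insertions occur before ``pos``); :func:`apply_edits` reconstructs the
    mutant from them exactly.
    """
    rng = np.random.default_rng(model.seed)
    s = seq.residues
    lengths = np.array(sorted(model.indel_length_dist))
    lw = np.array([model.indel_length_dist[l] for l in lengths], dtype=float)
    lw /= lw.sum()

    out: list[str] = []
    edits: list[tuple] = []
    i = 0
    while i < len(s):
        if model.indel_rate and rng.random() < model.indel_rate:
            l = int(rng.choice(lengths, p=lw))
            if rng.random() < 0.5:  # deletion
                l = min(l, len(s) - i)
                edits.append(("del", i, s[i : i + l]))
                i += l
                continue
            ins = "".join(rng.choice(list("ACGT"), size=l))
            edits.append(("ins", i, ins))
            out.append(ins)
        ch = s[i]
        if ch != "N" and model.substitution_rate and rng.random() < model.substitution_rate:
            if rng.random() < model.transition_fraction:
                alt = _TRANSITION[ch]
            else:
                alt = _TRANSVERSIONS[ch][rng.integers(2)]
            edits.append(("sub", i, ch, alt))
            ch = alt
        out.append(ch)
        i += 1
    return NucleotideSequence(seq.id + "_mut", "".join(out), seq.is_rna), edits


def apply_edits(seq: NucleotideSequence, edits: list[tuple]) -> NucleotideSequence:
    """Reconstruct the mutant from the original and the edit list."""
    by_pos: dict[int, list[tuple]] = {}
    for e in edits:
        by_pos.setdefault(e[1], []).append(e)
    out: list[str] = []
    i = 0
    s = seq.residues
    while i < len(s):
        ops = by_pos.get(i, [])
        skip = 0
        ch = s[i]
        for op in ops:
            if op[0] == "ins":
                out.append(op[2])
            elif op[0] == "del":
                skip = len(op[2])
            elif op[0] == "sub":
                ch = op[3]
        if skip:
            i += skip
            continue
        out.append(ch)
        i += 1
    return NucleotideSequence(seq.id + "_mut", "".join(out), seq.is_rna)


# ---------------------------------------------------------------------------
# Structure fixtures
# ---------------------------------------------------------------------------


def generate_structure_fixture(
    seq_length: int,
    paired_fraction: float,
    loop_spec: list[tuple[int, int]] | None = None,
    seed: int = 0,
) -> str:
    """Build a balanced, pseudoknot-free dot-bracket string.

    ``loop_spec`` windows are forced to stay unpaired; each forced window is
    enclosed in its own helix where flanking space allows, so it forms a
    hairpin loop (eligible for the accessibility filter).  Remaining free
    space is tiled with hairpin modules until roughly ``paired_fraction`` of
    positions are paired.  Raises when the spec cannot be realized.
    """
    if not 0.0 <= paired_fraction <= 1.0:
        raise ValueError("paired_fraction must be in [0, 1]")
    loop_spec = sorted(loop_spec or [])
    db = ["."] * seq_length
    forced = np.zeros(seq_length, dtype=bool)
    for a, b in loop_spec:
        if not (0 <= a < b <= seq_length):
            raise ValueError(f"forced window [{a}, {b}) out of range")
        if forced[a:b].any():
            raise ValueError("forced windows overlap")
        forced[a:b] = True

    target_pairs = round(paired_fraction * seq_length / 2)
    blocked = forced.copy()  # positions unavailable for new helices
    placed = 0

    def free_before(x: int) -> int:
        k = 0
        while x - 1 - k >= 0 and not blocked[x - 1 - k]:
            k += 1
        return k

    def free_after(x: int) -> int:
        k = 0
        while x + k < seq_length and not blocked[x + k]:
            k += 1
        return k

    # enclose each forced window in a helix so it becomes a hairpin loop
    for a, b in loop_spec:
        if placed >= target_pairs:
            break
        k = min(free_before(a), free_after(b), max(target_pairs - placed, 1), 8)
        if k < 1:
            continue  # window stays exterior; documented behavior
        for t in range(1, k + 1):
            db[a - t] = "("
            db[b + t - 1] = ")"
            blocked[a - t] = blocked[b + t - 1] = True
        placed += k

    # tile remaining free runs with hairpin modules (stem + >=3 nt loop)
    i = 0
    while i < seq_length and placed < target_pairs:
        if blocked[i]:
            i += 1
            continue
        j = i
        while j < seq_length and not blocked[j]:
            j += 1
        seg = j - i
        s = min((seg - 3) // 2, target_pairs - placed)
        if s >= 1:
            for t in range(s):
                db[i + t] = "("
                db[j - 1 - t] = ")"
            placed += s
        i = j
    if placed < target_pairs:
        raise ValueError(
            f"infeasible structure spec: only {placed} of {target_pairs} pairs placeable"
        )
    return "".join(db)
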