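"""Readers and writers for the file formats the pipeline touches.

Sequences come in as FASTA, repeat annotations as RepeatMasker ``.out``
tables, and secondary structures as dot-bracket (Vienna) or CT files.
All internal coordinates are 0-based half-open; RepeatMasker's 1-based
inclusive convention is converted on read.  RNA and DNA share a single
internal alphabet: U is normalized to T on input (the motif criteria are
defined over {A, C, G, T}), and a flag records whether the input was RNA
so output can echo the original alphabet.
"""

from __future__ import annotations

import urllib.request
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: IUPAC ambiguity codes collapsed to N (criteria are defined only over the 4 bases).
AMBIGUITY_CODES = set("RYSWKMBDHV")
VALID_BASES = set("ACGTN")

UNPAIRED = -1


@dataclass
class NucleotideSequence:
    """A normalized nucleotide sequence.

    ``residues`` contains only A, C, G, T, N; ``is_rna`` records whether the
    original input used U so that downstream tables can echo the input
    alphabet.
    """

    id: str
    residues: str
    is_rna: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        bad = set(self.residues) - VALID_BASES
        if bad:
            raise ValueError(f"non-normalized residues {sorted(bad)} in '{self.id}'")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class RepeatAnnotation:
    """One RepeatMasker interval (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    strand: str
    repeat_class: str  # e.g. "LINE"
    family: str  # e.g. "L1", "L2", "CR1", "RTE"
    subfamily: str  # e.g. "L1PA5", "L1Md_T"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def normalize_residues(raw: str, seq_id: str = "?") -> tuple[str, bool]:
    """Uppercase, map U->T and IUPAC ambiguity codes -> N (with a warning).

    Returns the normalized string and whether the input used U (RNA).
    """
    up = raw.upper()
    is_rna = "U" in up
    out = []
    n_ambiguous = 0
    for ch in up:
        if ch == "U":
            out.append("T")
        elif ch in VALID_BASES:
            out.append(ch)
        elif ch in AMBIGUITY_CODES:
            out.append("N")
            n_ambiguous += 1
        else:
            raise ValueError(f"illegal residue {ch!r} in sequence '{seq_id}'")
    if n_ambiguous:
        warnings.warn(
            f"{n_ambiguous} IUPAC ambiguity code(s) in '{seq_id}' mapped to N",
            stacklevel=2,
        )
    return "".join(out), is_rna


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a FASTA file into normalized sequences (input order preserved)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues, is_rna = normalize_residues(str(rec.seq), rec.id)
        records.append(NucleotideSequence(rec.id, residues, is_rna))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Sequence[NucleotideSequence], path: str | Path) -> Path:
    """Write sequences as FASTA.  RNA inputs are echoed back with U."""
    if not records:
        raise ValueError("refusing to write an empty FASTA file")
    path = Path(path)
    seqrecs = []
    for r in records:
        residues = r.residues.replace("T", "U") if r.is_rna else r.residues
        seqrecs.append(SeqRecord(Seq(residues), id=r.id, description=""))
    SeqIO.write(seqrecs, str(path), "fasta")
    return path


def fetch_accession(accession: str, timeout: float = 30.0) -> NucleotideSequence:
    """Fetch one nucleotide accession from NCBI efetch (requires network).

    Convenience helper for real-data mode (e.g. the XIST/Xist/Rsx reference
    transcripts NR_001564 / NR_001463 / JQ937282); nothing in the test suite
    depends on it.
    """
    url = (
        "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
        f"?db=nuccore&id={accession}&rettype=fasta&retmode=text"
    )
    with urllib.request.urlopen(url, timeout=timeout) as fh:
        text = fh.read().decode()
    lines = text.strip().splitlines()
    if not lines or not lines[0].startswith(">"):
        raise IOError(f"unexpected efetch response for {accession}")
    residues, is_rna = normalize_residues("".join(lines[1:]), accession)
    return NucleotideSequence(accession, residues, is_rna)


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

_RM_HEADER = """\
   SW  perc perc perc  query     position in query          matching repeat            position in repeat
score  div. del. ins.  sequence  begin    end       (left)  repeat      class/family   begin  end    (left)   ID
"""


def read_repeatmasker_out(path: str | Path) -> list[RepeatAnnotation]:
    """Parse a RepeatMasker ``.out`` table.

    Tolerates the usual 3-line header (or none), whitespace-separated
    columns, strand given as ``+``/``C`` and an optional trailing ``*``.
    1-based inclusive query coordinates are converted to 0-based half-open.
    """
    path = Path(path)
    annotations = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if not fields[0].lstrip("-").isdigit():  # header lines
                continue
            if len(fields) < 11:
                raise ValueError(f"{path}:{lineno}: expected >=11 columns, got {len(fields)}")
            chrom = fields[4]
            try:
                begin, end = int(fields[5]), int(fields[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinates") from exc
            strand = "-" if fields[8] == "C" else fields[8]
            subfamily = fields[9]
            class_family = fields[10]
            repeat_class, _, family = class_family.partition("/")
            annotations.append(
                RepeatAnnotation(
                    chrom=chrom,
                    start=begin - 1,  # 1-based inclusive -> 0-based half-open
                    end=end,
                    strand=strand,
                    repeat_class=repeat_class,
                    family=family or repeat_class,
                    subfamily=subfamily,
                )
            )
    return annotations


def write_repeatmasker_out(
    annotations: Iterable[RepeatAnnotation], path: str | Path
) -> Path:
    """Write annotations in RepeatMasker ``.out`` dialect (fixture writer)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_RM_HEADER + "\n")
        for i, a in enumerate(annotations, 1):
            strand = "C" if a.strand == "-" else "+"
            class_family = (
                f"{a.repeat_class}/{a.family}"
                if a.family != a.repeat_class
                else a.repeat_class
            )
            fh.write(
                f"  100  0.0  0.0  0.0  {a.chrom}  {a.start + 1}  {a.end}  (0)  "
                f"{strand}  {a.subfamily}  {class_family}  1  {a.length}  (0)  {i}\n"
            )
    return path


# ---------------------------------------------------------------------------
# Secondary structures (dot-bracket / CT)
# ---------------------------------------------------------------------------


def _pairing_from_dotbracket(db: str) -> np.ndarray:
    pairing = np.full(len(db), UNPAIRED, dtype=np.int64)
    stack: list[int] = []
    for i, ch in enumerate(db):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pairing[j] = i
            pairing[i] = j
        elif ch != ".":
            raise ValueError(f"unsupported structure symbol {ch!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return pairing


def _pairing_from_ct(lines: list[str]) -> np.ndarray:
    header = lines[0].split()
    n = int(header[0])
    pairing = np.full(n, UNPAIRED, dtype=np.int64)
    rows = [ln for ln in lines[1:] if ln.split()]
    if len(rows) < n:
        raise ValueError(f"CT file declares {n} rows but has {len(rows)}")
    for ln in rows[:n]:
        fields = ln.split()
        idx = int(fields[0]) - 1
        partner = int(fields[4]) - 1
        pairing[idx] = partner if partner >= 0 else UNPAIRED
    # involution check
    for i, j in enumerate(pairing):
        if j != UNPAIRED:
            if j == i:
                raise ValueError(f"position {i} paired to itself")
            if pairing[j] != i:
                raise ValueError(f"CT partner asymmetry at positions {i}/{j}")
    return pairing


def read_structure(path: str | Path, format: str | None = None) -> np.ndarray:
    """Read a secondary structure into a per-position partner table.

    Returns an int array where entry ``i`` is the partner index of position
    ``i`` or ``-1`` (``triplexmotif.io.UNPAIRED``) when unpaired.  The table
    is guaranteed to be a self-inverse partial pairing.  ``format`` is
    inferred from the extension (``.ct`` vs anything else = dot-bracket)
    when not given.
    """
    path = Path(path)
    if format is None:
        format = "ct" if path.suffix.lower() == ".ct" else "dot-bracket"
    lines = path.read_text().splitlines()
    if format == "ct":
        return _pairing_from_ct(lines)
    if format == "dot-bracket":
        for ln in lines:
            ln = ln.strip()
            if ln and set(ln) <= {".", "(", ")"}:
                return _pairing_from_dotbracket(ln)
        raise ValueError(f"no dot-bracket line found in {path}")
    raise ValueError(f"unknown structure format {format!r}")


def pairing_from_dotbracket(db: str) -> np.ndarray:
    """Parse an in-memory dot-bracket string into a partner table."""
    return _pairing_from_dotbracket(db)


# ---------------------------------------------------------------------------
# Site tables
# ---------------------------------------------------------------------------


def write_sites_table(sites, path: str | Path, bed_path: str | Path | None = None) -> Path:
    """Write motif sites as a TSV (and optionally BED6, 0-based half-open)."""
    import pandas as pd

    path = Path(path)
    rows = [
        {
            "seq_id": s.seq_id,
            "start": s.start,
            "end": s.end,
            "length": s.length,
            "class": s.motif_class,
            "motif_sequence": s.sequence,
        }
        for s in sites
    ]
    df = pd.DataFrame(rows, columns=["seq_id", "start", "end", "length", "class", "motif_sequence"])
    df.to_csv(path, sep="\t", index=False)
    if bed_path is not None:
        bed = pd.DataFrame(
            {
                "chrom": df["seq_id"],
                "start": df["start"],
                "end": df["end"],
                "name": df["class"],
                "score": 0 if len(df) else pd.Series(dtype=int),
                "strand": "+" if len(df) else pd.Series(dtype=str),
            }
        )
        bed.to_csv(bed_path, sep="\t", index=False, header=False)
    return path


def read_sites_table(path: str | Path):
    """Read a TSV written by :func:`write_sites_table` back into MotifSites."""
    import pandas as pd

    from .scan import MotifSite

    df = pd.read_csv(path, sep="\t")
    return [
        MotifSite(
            seq_id=str(r.seq_id),
            start=int(r.start),
            end=int(r.end),
            motif_class=str(r["class"]),
            sequence=str(r.motif_sequence),
        )
        for _, r in df.iterrows()
    ]
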