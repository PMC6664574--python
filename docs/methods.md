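# Methods

## Motif model

A motif class is defined by an anchor base (U/T for the pyrimidine class,
A for the purine class) and a partner base (C, G respectively). A residue
string is a valid motif iff it

1. contains only the class's two bases (N or any other base breaks a motif),
2. is at least `min_length` (default 5) nucleotides long,
3. has at least `min_internal_gap` (default 3) nucleotides strictly between
   its first and last anchor base,
4. contains no anchor run longer than `max_anchor_run` (default 3), and
5. contains no partner run longer than `max_partner_run` (default 2 in
   Hoogsteen mode; unlimited in reverse-Hoogsteen purine mode, because long
   G runs increase reverse-Hoogsteen triplex affinity rather than breaking
   it).

The rules say nothing about the boundary bases; an optional
`anchor_bounded` flag additionally requires motifs to begin and end with the
anchor base (off by default, since the published criteria do not ask for it
and the worked examples are consistent with either reading).

**Sites vs windows.** A *site* is a maximal valid window: a valid window not
contained in any longer valid window of the same class. Because rules 2–3
are monotone (a superset window can only satisfy them more easily) and rules
4–5 are antitone (a superset can only violate them), the maximal end for
each start is well-defined, and the scanner finds all maximal sites in one
left-to-right pass over each maximal same-class run; a run that violates a
run-length rule still contributes its maximal valid sub-windows. The
*window* enumeration returns every valid window, nested and overlapping
included; it backs the cumulative short-motif (5–7 nt) ratios. Both are
checked against a brute-force enumerate-all-substrings oracle in the tests.

U and T are interchangeable: input is normalized to a single DNA-letter
alphabet (U→T, lowercase→uppercase, IUPAC ambiguity codes→N with a warning),
and an RNA flag lets writers echo the input alphabet. All internal
coordinates are 0-based half-open; RepeatMasker's 1-based inclusive
coordinates are converted on read, and its `C` strand symbol maps to `-`.

## Occupancy, ratio, KS distance

Occupancy is the fraction of sequence positions covered by the union of a
class's sites; the denominator is the full sequence length including N runs
(the simplest defensible reading of a "proportion"). Frequency is sites per
kb. The UC/AG ratio divides the *unrounded* occupancies and is rounded only
for display — rounding first is visibly inconsistent (e.g. a displayed ratio
of 1.60 from occupancies displayed as 9.0/5.7).

The KS distance between two motif-length distributions is the plain
sup-difference of their discrete empirical CDFs over the union of observed
lengths, with no continuity correction. It is used as a descriptive
distance with a conventional similarity threshold of 0.100, not as a
hypothesis test; the tests verify symmetry, identity of indiscernibles (at
the CDF level) and the triangle inequality.

Element-length bins are right-closed — (0,100], (100,200], …, (900,1000],
(1000,2000], … — matching the conventional labels "≤100", "101–200",
"1,001–2,000". Per-bin sampling is uniform without replacement; a bin with
fewer members than requested contributes all of them.

## Structure filtering

Loops are classified from the pairing table by walking each helix-closing
pair's interior: no child helix → hairpin; one child → internal loop (bulge
when one side is empty); two or more → multibranch; unpaired positions
enclosed by no pair are exterior. Pseudoknots (crossing pairs) are rejected
with the offending pair named, not silently broken — the target inputs
(Mfold, SHAPE-MaP) are pseudoknot-free.

A motif's *usable length* is the longest run of consecutive motif positions
that are unpaired, of an eligible loop type, and in the same loop instance;
a `contiguous=False` option instead counts all eligible positions. Eligible
types default to {hairpin, internal, bulge}: bulges are internal loops with
one empty side, while multibranch and exterior positions are excluded by
default (switchable) because the loop counting being reproduced speaks of
hairpin/internal single-stranded loops only. A motif is retained when its
usable length still meets the minimum motif length. Motifs spanning two
loops separated by a helix never join runs across the helix — a documented
edge rule, since the original counting was manual and leaves such cases
unspecified.

## Paired-element comparison

Copies are aligned with an affine-gap global aligner
(Bio.Align.PairwiseAligner; match +1, mismatch −2, and a gap of length L
costing 5 + 2L by default — BLASTN-like, configurable). Identity is the
percentage of identical alignment columns, gap fraction the percentage of
columns containing a gap; published BLAST identities are approximate
reference points, not exact equivalents, since BLAST reports local-alignment
statistics. A motif is "completely matched" iff its projected alignment
columns are gap-free in both rows and residue-identical throughout; matched
fractions are reported against both elements' motif counts. Strict full-span
matching is used (no tolerance for ±1-nt boundary shifts). The alignment
score is validated against a brute-force Gotoh dynamic program in the tests.

## Kinetic Monte Carlo model

State: N boolean sites, all initially dissociated. Per step, a bound site
unbinds with probability k_off; a dissociated site binds with probability
A·k_on if at least one site was bound at the start of the step, else k_on.
The acceleration A models the linker effect — a bound site tethers the
molecule, shrinking the search space of the other sites — and is treated as
a constant (no conformational dependence). P_diss is the fraction of
post-burn-in steps in which all sites are unbound.

Numerical choices:

- **Update scheme.** Synchronous by default (all sites drawn each step).
  An asynchronous variant (one uniformly chosen site per step) is retained
  because its stationary distribution of the bound-site count is an exact
  birth-death law, π(m+1)/π(m) = (N−m)·k_on(m) / ((m+1)·k_off), which the
  tests use as an independent oracle.
- **Defaults.** k_on = 0.002, k_off = 0.2 per step (the weak-affinity
  regime, K_d ≈ 10⁻³ M), 10 runs × 20,000 steps, burn-in 0, grid
  N, A ∈ {1, 2, 5, 10, 15, 20}.
- **Randomness.** Each run draws from an independent generator spawned
  deterministically from the master seed (SeedSequence); sweep cells spawn
  their own sub-seeds. Results are bit-reproducible for a given seed.
- **Reported error.** The standard error is computed across the 10 per-run
  means. In the strongly cooperative corner of the grid the dynamics are
  metastable (long bound episodes alternating with long dissociated
  episodes), so a 20,000-step run contains only dozens of effective
  renewal cycles and the across-run SE there is of order 10⁻³–10⁻²,
  substantially larger than in the weak-coupling cells.
- **Checks.** N=1 is A-independent (acceleration never applies to the
  empty state) and matches k_off/(k_on+k_off); A=1 matches the independence
  product; P_diss is monotone non-increasing in A and in N within error
  (a diagnostics routine reports violations).

## Synthetic data

The generators define the study conditions for everything not taken from a
real dataset:

- **Planted-motif sequences.** Motif lengths are drawn from a geometric-like
  distribution over 5–17 nt (weight 0.6^(L−5); real motif-length
  distributions decay with length and 5–17 covers the observed ranges),
  classes are planted to target occupancies (default AG 15%, the L1-like
  regime; L1-like consensus generation adds UC 3%), placements are uniform
  with ≥2 background positions between plants, and each plant is flanked by
  an opposite-class base. A plant is therefore exactly one maximal class
  run, making scanner recall on plants exact; accidental background motifs
  are permitted and recoverable by scanning. Background composition is
  uniform by default (configurable). With a uniform ACGT background the
  accidental-site occupancy is a few percent — the recall assertions
  compare coordinates, not counts.
- **L1-like families.** Elements are 3′-anchored suffixes of one consensus
  (5′ truncation); the default length law is exponential with mean one
  third of the consensus plus a 10% full-length fraction, emulating
  pervasive 5′ truncation. A RepeatMasker-dialect annotation fixture is
  written alongside. Because all elements share the consensus 3′ end,
  motif occupancy and motif-length distributions are length-independent by
  construction — which is exactly the property the family statistics are
  tested against.
- **Mutated pairs.** Per-site substitutions (transition fraction 0.67,
  roughly the genomic transition bias) and optional indels (lengths 1–3,
  biased to 1); the emitted edit list reconstructs the mutant exactly.
- **Structure fixtures.** Dot-bracket strings built from hairpin modules;
  forced windows stay unpaired and are enclosed in their own helix where
  flanking space allows, so they classify as hairpin loops.

What the synthetic data does *not* emulate: real retrotransposition
artifacts (target-site duplications, poly-A tails, 3′ transduction),
subfamily structure, genomic base-composition skew, or thermodynamically
realistic secondary structures. Tests passing on these fixtures therefore
demonstrate the correctness of the implemented statistics and the internal
consistency of the motif properties, not biological claims about real
genomes; real-data mode (FASTA + RepeatMasker + folded structures) exists
for that purpose, including an optional NCBI accession fetch helper.

## Problem sizes

The test suite and the acceptance script run the simulations at their
published sizes (10 × 20,000 steps per grid cell; the full 6×6 sweep) and
the oracle comparisons at 1,000 random sequences of ≤ 60 nt, 10-kb
planted-motif sequences and 6-kb consensus families — sizes chosen so the
whole suite completes in well under a minute per module on one core.

## Known limitations

- The scanner treats each strand independently; annotation-driven scans use
  the annotated strand only (opposite-strand motif content is an
  interpretation layer, not a scan mode).
- The motif criteria are defined over the four bases only; ambiguity codes
  collapse to N and break motifs.
- The MC model is a discrete-time two-state model: no continuous-time
  (Gillespie) dynamics, no spatial or linker-geometry detail, no
  conformational dependence of A.
- Alignment-based motif identity depends mildly on the gap-scoring scheme;
  with the default scoring, ties between equal-scoring alignments are
  broken deterministically by the aligner's first optimum.
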