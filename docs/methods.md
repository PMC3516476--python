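# Methods

## Coordinate model

All internal coordinates are 1-based inclusive.  Circular molecules are
first-class: a feature, repeat arm or match may wrap the origin, in which
case `end < start` and a `wraps` flag is set.  Every detector operates on a
doubled copy of a circular sequence and canonicalises results to a start
inside `[1, length]`; `subsequence()` is the single extraction primitive
and is property-tested against a doubled-string oracle.  External formats
keep their native conventions (GenBank/GFF3 1-based inclusive, BED 0-based
half-open); GFF3 features that wrap are written with `end > length`
(the circular-landmark convention) and folded back on read.

## GC skew and ori/ter calling

Skew is `(G−C)/(G+C)` per window, windows tiled every `step_bp` (defaults:
window 500 bp, step 100 bp — chosen so a ~37 kb plasmid yields a few
hundred windows, enough to average composition noise while keeping ~500 bp
positional resolution).  The optional `w/c` weighting multiplies each
window's skew by window length over molecule length.  Windows with
`G+C = 0` contribute 0 and carry a degenerate flag rather than being
skipped, so window indexing stays uniform; an all-degenerate profile yields
an explicit no-call with zero confidence.

Ori is placed at the cumulative-skew minimum and ter at the maximum
(`ori_at="max"` flips the convention, since the deposited orientation of a
plasmid is arbitrary).  On circular profiles the extremum search runs on
the *mean-detrended* cumulative curve: subtracting the per-window mean
closes the curve over one revolution, which makes the call exactly
equivariant under rotation of the input — without detrending, a nonzero
total skew tilts the partial sums and the argmin depends on where the
deposited sequence happens to start.  The `SkewProfile.cumulative` field
itself remains the plain running sum.  Confidence is the max−min amplitude
of the (detrended) curve.  Ties break toward the smallest coordinate.

## att-site prediction

The attachment-site criterion is perfect identity between the element and
the 3′ end of a host tRNA gene, so the matcher enumerates *maximal exact
matches* anchored at tRNA 3′ termini (seed = the terminal `min_match_bp`
bases, default 10 bp; extension leftward into the tRNA body; both target
strands; circular wrap honoured).  At these word lengths exact matching is
equivalent to a high-identity word search and needs no aligner.  An option
relaxes the anchor to matches ending within a configurable offset of the
terminus; such a match is only reported when it cannot be extended toward
the terminus (otherwise it is contained in a smaller-offset match).

Candidates are ranked, not thresholded, by an expectation score: the
expected count of equal-or-longer exact matches of the core under a
mononucleotide null model of the target,

    E = S · L · ∏_b p(b),   S = 2 if both strands are searched,

with `p` the target's empirical base composition (Ns excluded).  This uses
`L` rather than `L − k + 1` placements; on a circular target `L` is exact,
and on kb-scale linear targets the difference is well under the Monte-Carlo
noise the calibration test allows.  The score is strictly decreasing in
match length for any composition, so longer cores always rank first.

Intergenic status means the candidate span overlaps no CDS or tRNA
feature; genomic-island membership is taken from user-supplied BED
intervals (externally predicted islands are an input here, not something
this package computes).

`build_trna_library` strand-corrects each tRNA gene so its 3′ terminus is
the last `terminus_bp` characters (default 25 bp — comfortably longer than
known att cores, short enough to stay inside the tRNA) and keeps
`flank_bp = 500` of context on each side; entries with N in the terminus
are flagged and their ambiguous seeds never match.

## Campbell integration

`integrate()` performs the single crossover within a shared core: the
cointegrate is `host[1..attB_end] + rotated plasmid + host[attB_end+1..]`,
where the circular element is rotated to begin just after its attP core
and therefore end with it.  Length is conserved exactly and the core is
duplicated — once at the attL junction, once at attR; junction strings
carry a configurable flank (width 0 yields the bare core).  `excise()`
inverts the operation at the duplicated cores, returning the host exactly
and the element up to rotation.  When the host match covers more than the
element's core (e.g. the whole tRNA gene), `shared_core_pairs()` trims both
candidates to their longest shared 3′-terminal core before integration.

## Repeat detection

**Inverted repeats** are found by seed-and-extend along anti-diagonals: an
exact seed pair (k-mer vs its reverse complement) is extended outward and
inward to the maximal run.  For `max_mismatch = 0` every maximal pair with
arm ≥ `min_arm` contains an exact seed and all seeds inside one pair
converge to the same maximal run, so the finder is exhaustive — this is
verified against a brute-force oracle that labels anti-diagonal runs of
the full comparison matrix.  With mismatches allowed, seeds shrink by
pigeonhole (`min_arm // (mm+1)`) and extension is greedy with terminal
mismatches trimmed; this path is heuristic but every reported pair still
verifies its own definition.  oriT hairpin reporting clusters overlapping
alternatives and puts the minimal-spacer pair first within a cluster.

**Iterons** (tandem direct repeats) are found per unit length `u` by the
shifted self-comparison `s[i] == s[i+u]`, growing runs that tolerate
`max_mismatch_per_copy` disagreements per aligned copy; after a run is
recorded, scanning resumes just past the *first* mismatch inside it, so a
clean array hidden behind one lucky leading match is still enumerated.
Copies are re-validated against the per-column majority consensus and
trailing divergent copies trimmed.  Overlapping reports (the same array
seen at `u` and `2u`, or phase-shifted) are merged keeping the longest
span, then the fewest total mismatches, then the smallest unit.  A
Shannon-entropy guard (< 1.0 bit/symbol) suppresses homopolymer artifacts.
Defaults: unit 15–25 bp, ≥ 3 copies — typical Rep-binding iterons.

**Motifs** (DnaA box, terminal-repeat copies) are scanned on both strands
with a per-window substitution count (N never matches).  The DnaA default
`TTATCCACA` with ≤ 1 mismatch is the canonical proteobacterial box;
9 bp at that tolerance yields occasional background hits on a 37 kb
molecule, which is why the module report cross-references the skew call
with iteron arrays rather than trusting any single signal.

**AT-rich windows** are maximal merged runs of windows (default 50 bp)
whose A+T fraction exceeds a threshold (default 0.8).  Being window-based,
their boundaries are only localised to within one window.

**Composite transposons**: copies of a terminal-repeat seed (≥ 20 bp,
default identity 0.9) are located on both strands; a transposable unit is
the span between two *oppositely oriented* copies, inclusive, because
Tn3-family ends are inverted relative to each other.  Three copies in
+/+/− orientation therefore yield exactly the nested outer and inner units
of a composite element.  Without a seed, candidate seeds are taken de novo
from the arms of long inverted-repeat pairs; de-novo seeds may carry a
base or two of lucky flanking extension, so their unit boundaries are
accurate only to a couple of bases, whereas a supplied seed gives exact
coordinates.  The scan returns copies and units together, since one copy
is reportable even when no unit can be called.

## ORF calling and statistics

Six-frame scanning with translation table 11 and start codons
{ATG, GTG, TTG}; within each stop-to-stop segment the longest reading from
the first accepted start is reported, and exactly one ORF is kept per
genomic stop codon — on a circular molecule a reading that wraps the origin
supersedes a shorter co-terminating one found inside the linear copy.
Homology-based start refinement is out of scope; the longest-ORF convention
stands in for it.  GC content excludes Ns from numerator and denominator
and is reported to 2 dp; coding density is the union of CDS spans over the
molecule length (wrap intervals split at the origin), reported to 1 dp.
`replicon_stats` computes these from a record's own annotation so the
numbers are comparable with deposited GenBank records.

The module report groups annotation and detector output into
replication / partition / mobilization / integration / degradation /
mobile-element modules via a configurable keyword map over feature
qualifiers (first match in priority order wins; unmatched features go to
`unassigned`), and cross-references a skew-based ori call with any iteron
array within 2 kb.

## Synthetic replicons

`make_plasmid` draws an i.i.d. background at the requested GC (default
62 %) with a position-dependent G↔C bias of amplitude 0.3 switching sign
at the planted ori (19,000) and ter (500) on a 37,000 bp circle — the
two-replichore signature, with no higher-order sequence structure.  Into
it are spliced: a 21 bp × 4 iteron array, the DnaA box, an 85 % AT window
(80 bp), a GC-rich hairpin (12 bp arms, 6 nt loop), a 14 bp att core in an
intergenic gap, and three copies of a random 38 bp terminal repeat in
+/+/− orientation delimiting nested transposable units.  CDS features are
tiled around reserved element windows to ~90 % coding density, with a few
products named (RepA, integrase, relaxase, transposase) so the keyword
rules have something to classify.  The generator pins the bases flanking
the exact-coordinate elements (iteron array, hairpin) and redraws payloads
that happen to recur elsewhere, so each planted element is *exactly* its
truth interval — recovery tests can then demand zero coordinate error
instead of fuzzy overlap.  `make_host` plants one tRNA gene whose 3′
terminus ends in the plasmid's att core (the base before the core chosen
so the anchored match cannot extend past it).  All randomness flows from a
single seed; there is no unseeded path.

What the generator does *not* emulate: codon structure and realistic ORF
content (CDS features are annotation intervals over background sequence),
compositional heterogeneity beyond the two skew arms, degenerate bases,
and repeat families with internal divergence.  Passing recovery tests
therefore demonstrate correctness of the detectors' logic and coordinate
arithmetic under the stated noise model, not performance on real genomes,
where copy divergence and low-complexity DNA dominate the difficulty.

## Numerical and testing choices

Problem sizes in the test-suite were chosen to exercise each algorithm's
asymptotic behaviour while keeping the whole suite around a minute: oracle
equivalence runs on 200 random instances ≤ 5 kb (att), 100 × 2 kb
(inverted repeats), toys ≤ 3 kb (ORFs), 50 × 2.4 kb (skew properties);
synthetic recovery uses 20 seeds at full 37 kb scale; score calibration
uses 1,000 Monte-Carlo replicates of 1 kb circular targets with a 3-SE
band.  Determinism: every stochastic test seeds its generator; pipeline
outputs are byte-identical across reruns given config + seed.  One
acceptance test requires the deposited GenBank record and hence network
access; offline it fails with an explicit message rather than being
skipped.

## Known limitations

- Mismatched inverted-repeat enumeration (`max_mismatch > 0`) is heuristic;
  exhaustiveness is only guaranteed at zero mismatches.
- The expectation score uses a mononucleotide null; GC-skewed or repetitive
  targets violate it and the score is a ranking device, not a p-value.
- Iteron consensus is per-column majority with no gap handling; indel-bearing
  iteron arrays fragment into shorter runs.
- Campbell integration assumes one contiguous, non-wrapping shared core on
  each molecule after normalisation.
- ORF starts follow the longest-reading convention, not homology evidence,
  so annotated start codons of real records will differ.
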