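# Methods

## Overview

`readstitch` improves a draft assembly with long reads in one pass over
three inputs: the draft FASTA, the read-to-split-assembly PAF and the
split-assembly self PAF.  The pass runs split → correct → bridge →
scaffold-graph traversal → gap fill → finish.  Alignments are taken as
given; mapping itself (and downstream polishing) are external.  Further
iterations are possible by re-mapping the reads against the improved
assembly and calling the pipeline again.

All coordinates are 0-based half-open (PAF convention).  A contig end is
`(name, 'l'|'r')`; an oriented scaffold step is `(scaffold, strand,
distance-from-previous)`.

## Mapping-level filters

Records with mapping quality < `min_mapq` (default 20) or aligned read span
< `min_aln_len` (default 500 bp) are dropped; secondary alignments
(`tp:A:S`) are excluded at parse time while supplementary split mappings are
kept — split mappings across contig ends *are* the scaffolding signal.  For
PacBio CLR, one subread per ZMW is kept (the one with the most aligned
bases; lexicographic name as tie-break) so repeatedly sequenced short
fragments do not dominate counts.  The defaults suppress random placements
at typical long-read error rates; both are CLI flags.

## Misassembly correction

An alignment that stops ≥ 200 bp (`min_break_clearance`) before a contig
end while ≥ 200 bp of the read remains unaligned marks a break candidate at
the stop position.  Support counts candidates within ±100 bp (`vicinity`,
including itself); vetoes count alignments spanning the whole window.  A
candidate is accepted when support reaches the bridge minimum count **and**
the vetoes' coverage probability (negative-binomial CDF at the veto count,
smallest bin size) is not `prob_factor` (10) times the support's — the same
rule that arbitrates competing bridges.  Accepted positions within the
vicinity merge to their centre; the contig is broken there and the broken
join retains no original-gap record.  Divergent alignments whose candidate
was vetoed are removed (they are wrong-copy or chimeric placements).
Afterwards contig ends without alignments are trimmed to the outermost
aligned base, and contigs whose trimmed length is ≤ 1.2 × `min_aln_len` are
dropped — the slack avoids the on/off boundary where a handful of bases
decides whether a read can align at all.

## Bridges and their three filters

A bridge joins the exit end of one mapping to the entry end of the next
mapping of the same read; its distance is the read gap between the anchors
(negative when they overlap).  Same-end self-bridges must exceed
2 × `min_aln_len` in distance to exclude hairpin/palindrome artifacts.
Bridges with the same endpoint key are clustered greedily by ascending
distance; a member joins while its distance is within
max(0.2 × |mean|, 100 bp) of the running cluster mean.  Draft N-run lengths
are ignored throughout — they are routinely inaccurate.

1. **Minimum count** (default 3): removes connections supported by one or
   two (typically chimeric) reads at the 20–30× coverages the tool targets.
2. **Exceedance test** (threshold 0.01): per cluster, four one-sided tests
   compare remaining read lengths on each side within the group sharing
   that side's end and within the group sharing the other end.  The
   remaining length on a side is the aligned read span from the read's
   outermost accepted mapping to the junction, so a wrong-repeat-copy
   mapping (unaligned head or tail where the read leaves the copy) shows a
   truncated distribution.  The cluster with the longest remaining length
   is the control; the test maximum is adjusted upward by the positive
   distance difference (a longer gap legitimately consumes more read).  The
   p-value C(n_c, r)/C(n_c + n_t, r) is the probability, under
   exchangeability, that the r largest pooled values are all controls; it
   is computed exactly.  Ends left without any bridge get one bridge back:
   among removed bridges joining two such bare ends, the one with the
   largest minimum p-value (ties: higher count, then key).
3. **Coverage probability** (factor 10): per bin size (read-length
   quantiles, 10 by default, each bin full-length and centred within its
   contig) the lower half of the cumulative per-bin read-count distribution
   is least-squares-fitted with a negative-binomial CDF, initialized from
   lower-half moments and bounded positive.  Fitting only the lower half
   keeps collapsed repeats out of the estimate.  A cluster's probability is
   the fitted CDF at its count under the smallest bin size ≥ its mean
   distance; clusters beyond every bin size are exempt.  Competing clusters
   at an end are compared from high to low combined anchor quality
   (cumulative counts; lower quality of the two anchors first), and the
   highest level that produces a ≥ 10× probability ratio decides.

## Scaffold graph

Ends touched by exactly one surviving cluster whose partner end is equally
exclusive merge transitively into scaffolds (reciprocal-best).  Reads
traversing ≥ 3 scaffolds over accepted bridges become long-range
connections; windows of n scaffolds (n = 3, 4, …) compete against windows
sharing their other n−1 scaffolds under the same exceedance machinery, with
the count requirement lifted and removal demanding failure on **both**
sides; connections split at the outer scaffolds of removed windows.  The
count-expectation comparison does not arise here: a three-scaffold window
spans more than any coverage bin, which exempts it by the distance rule.
Every scaffold of every surviving connection contributes its paths to both
connection ends as graph entries; pairwise clusters contribute length-1
entries; paths contained as a prefix of a longer path from the same start
are removed, and entry support counts the reads extending the entry.
Long-range distances inherit the pairwise cluster means, so equal paths
compare exactly.

Contigs covered ≥ 95% by a self-alignment (or an order/orientation-
consistent chain) from another contig that ends within 2 kb of both its
ends are duplicates.  Where the duplicate and its template mirror each
other's entries, the lower-support member is removed from those shared
paths (ties: shorter scaffold, then larger id).

## Origin–extension pairs and traversal

A pair conditions a scaffold's continuation (extension) on the path leaving
its other side (origin).  Origins of a centre side are compared pairwise;
from each first-divergence branch point, graph paths consistent with the
origin are followed back through the centre, and the union of their
remainders across branch points defines the allowed extensions (processing
order therefore does not matter — an interpretive choice where the
procedure is described positionally).  Sides with a single origin are never
filtered; a pair invalid directly but valid with origin and extension
swapped is kept; and the pair set is closed so that following any extension
one scaffold keeps the extended scaffold's origins paired consistently.
When no consistent path reaches the centre at all the pair is kept — the
conservative reading.

Initial paths chain reciprocally unique origin–extension first steps, with
links mirrored onto terminal scaffolds (which have no pairs of their own).
Loops are scaffolds repeated within one graph path, closed over in-between
scaffolds and merged when overlapping; loop units are greedily extended
cycles (candidates come from the entry anchored deepest in the existing
path — the greedy choice that can legitimately miss a unit when a longer
entry forces an early decision) and must be found in both walk directions.
A bridged loop takes the exit-to-exit read path verbatim; otherwise exactly
two unbridged exits are connected unit by unit, each attachment validated
by the path-combination test, non-best connections penalized, and the
minimum-penalty (then shortest) path wins; loops with more exits decompose
into single scaffolds rather than guessing.  Inverted repeats are included
when bridged, or with exactly two exits after excluding configurations that
also admit a two-haplotype reading.

The combination test walks origins matching a path's combining end (full
matches preferred, else longest continuous match), takes their valid
extensions, and looks for a full-length match with the other path,
recursing one scaffold deeper while the comparison stays an undecided
prefix; both directions must validate.  The main loop alternates merging
(paths sharing both end scaffolds stack as haplotypes, up to the ploidy,
after removing exact duplicates, distance-only variants and pure-deletion
paths; haplotype order is by successive minima of junction support) and
combining (unique best end overlaps, re-validated at join time), then
removes contained paths, inserts paths with a single valid base position as
an extra haplotype, and finishes: duplicated path ends whose continuation
is on the same side are cut, paths whose two duplicated ends overlap
disassemble, circular paths lose one copy of the overlap, and unconnected
duplicate-marked scaffolds are dropped.  Pairwise haplotype alignment is a
global alignment on (scaffold, strand) tokens with matched ends,
substitutions preferred over deletions (costs 0/2/3) — the description of
staged filtering fixes no cost model, so this lexicographic one (fewer
deletions on ties) is the package's choice.  A hard cap of 20 main-loop
rounds guards termination.

## Gap filling

A read aligns to a path when its mapping sequence follows the path contig
by contig — order, relative strand and junction distances (clustering
tolerance) — until the read or the path ends.  Junctions no read covers
split the path (or would drop the haplotype in multi-haplotype positions).
Per read, a contig's duplication count is its number of occurrences among
the read's valid placements; placements whose minimum count exceeds one are
removed unless that leaves a junction bare, in which case the lowest-count
placement is restored trimmed to that junction.  Per junction the spanning
reads are ranked by lower anchor mapping quality, higher anchor quality,
|gap − cluster mean|, then matching bases (lower side first); full ties
resolve to the lexicographically smallest read name — a deterministic
substitute for an arbitrary pick.  The winning read's inter-anchor
subsequence fills the gap verbatim (upper-cased, reverse-complemented when
the read runs against the path); consensus polishing is downstream work.
Negative distances trim the downstream contig instead of inserting
sequence.  Junctions without any candidate become N-gaps at the cluster
mean (floor 1), and adjacent original contigs that the traversal left
untouched are re-joined with their original N-run.

## Synthetic worlds

The generator emulates the pipeline's inputs with full knowledge of the
truth: a random (optionally diploid) genome assembled left to right from
contigs and gap segments; a draft whose N-runs mis-state the true gap by
±40%; injected chimeric contigs (cross-joined halves of two distant
contigs, the displaced halves surviving as their own scaffolds); a diverged
two-copy repeat placed at the *start* of two contigs with unique flanks; a
collapsed repeat (one contig, two genome loci, optionally inverted); and
duplicated near-identical contigs.  Reads are uniformly placed, log-normal
(median 12 kb, σ = 0.4, minimum 1 kb, 30× default — the regime the tool
targets), and PAF records are computed exactly from the placements, never
by running a mapper.

Two deliberate idealizations matter for interpreting green tests.  First,
the error model is i.i.d. substitutions only: coordinates stay exact and
matching-base counts drop, which exercises every count- and length-based
decision but not indel-induced coordinate jitter.  Second, mapper behaviour
at repeats is emulated: a read that enters a diverged repeat copy and ends
inside it is, with probability 0.25, assigned to the wrong copy (mapq 30,
matches scaled by the divergence), producing exactly the truncated
remaining-length signal the exceedance filter targets; reads fully inside a
repeat get mapq 3 and vanish in the prefilter.  Real mappers produce
messier mixtures, so passing tests demonstrate the decision logic, not
robustness to any particular mapper's quirks.

Evaluation against truth follows the bridge rule: a surviving cluster is a
true positive when it joins the right ends in the right orientation with a
mean distance within 0.5–1.5 of the true distance (zero-distance joins use
the 150 bp clustering floor instead).  Fraction Possibilities Kept is the
fraction of pre-filter true joins that a surviving cluster still realizes —
the desk-scale reading of "still covered by a new contig", since every join
here is between two known contigs.  Per-base identity is exact-substring
containment where possible, otherwise edit distance (edlib, infix mode)
normalized by scaffold length.

## Problem sizes and defaults

The bundled fixtures use 60–200 kb genomes, 7–13 contigs, 15–30× coverage
and 12 kb (6 kb for loop topologies) median reads; the full pipeline runs
in well under a second per fixture and the complete test suite plus the
acceptance script in a few seconds.  These sizes were chosen so every
stage — including the loop and repeat machinery — is exercised with
non-trivial counts while brute-force oracles (exhaustive rank enumeration,
quadratic graph reconstruction, exhaustive unit-sequence search) remain
feasible as independent checks.

Key defaults in one place: `min_mapq` 20, `min_aln_len` 500, clustering
0.2 relative / 100 bp floor, `min_count` 3, exceedance threshold 0.01,
`prob_factor` 10, 10 bin sizes, `vicinity` 100, `min_break_clearance` 200,
drop slack 1.2, ploidy 2.

## Known limitations

The emitted assembly follows each path's primary (best-supported)
haplotype; alternative haplotypes influence traversal but are not emitted
as ALT scaffolds.  Multi-part duplicate removal from the graph substitutes
one scaffold at a time (chains are combined at detection, not during graph
substitution).  Long-range filtering applies the exceedance machinery only,
as discussed above.  The generator does not model platform-specific error
profiles, GC-coverage bias or mappability, and the coverage model inherits
that: on real data the negative-binomial fit absorbs some bias but the
probability comparisons remain relative for exactly that reason.  One
mapping pass is one improvement iteration; iterating further requires
re-mapping externally.
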