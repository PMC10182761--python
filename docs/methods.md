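# Methods

## The problem

Most chloroplast genomes (plastomes, typically 120–170 kb, circular) have a
tetrad organization: a large single-copy region (LSC), a small single-copy
region (SSC), and two inverted-repeat arms (IRb, IRa) that are reverse
complements of each other. The four boundaries between these regions — the
junction sites JLB (LSC/IRb), JSB (IRb/SSC), JSA (SSC/IRa) and JLA
(IRa/LSC) — shift over evolutionary time as the IR expands or contracts,
moving genes such as *rps19*, *ycf1*, *ndhF* and *trnH* between single-copy
and duplicated territory. Comparing the genes flanking each junction across
related species is therefore a standard assay of plastome structural
evolution.

The practical obstacle is that a deposited GenBank record linearizes the
circle at an arbitrary point. Most records start at the first base of the
LSC, but a substantial minority start inside the LSC, the SSC, or either IR
arm, in which case a region (or a gene) wraps the origin and naive
junction-finding produces wrong coordinates or fails outright. `irdraw`
normalizes any rotation before analysis.

## Detection pipeline

1. **Canonical k-mer scan.** Every window of `k` bp (default 55, step 1;
   windows wrap the origin on circular records) is keyed by the
   lexicographically smaller of the k-mer and its reverse complement, so a
   sequence inside either IR arm contributes twice to its canonical key
   while single-copy sequence contributes once. Windows containing
   ambiguity codes are skipped (conservatively treated as not single-copy).

2. **Rotation into single-copy territory.** The rotation point is the
   midpoint of the longest run of consecutive single-copy windows. The
   longest such run lies in the larger single-copy region, so the rotated
   sequence starts as far as possible from both arms and neither arm can
   straddle the new origin. The midpoint rule is parameter-free: any rule
   that merely requires *N* consecutive single-copy windows is satisfied by
   the midpoint of the longest run for every feasible *N*. Linear records
   are not rotated (rotating a linear molecule is meaningless); if the
   detected arm touches a sequence end it is reported as truncated.

3. **Inverted-repeat search.** On the rotated, wrap-free sequence the
   longest pair of non-overlapping reverse-complementary substrings is
   found by anti-diagonal seed-and-extend: if position `p` pairs with
   position `q` (base at `p` equals the complement of the base at `q`),
   every extension preserves `p + q`, so exact inverted matches live on
   anti-diagonals. 12-mer seeds are indexed, mirrored hits are merged per
   diagonal, extended base-by-base, and capped at the diagonal center so
   the arms cannot overlap. Matches on the same diagonal separated by at
   most `chain_gap` bp (default 10) are chained into one arm, tolerating
   the few point divergences some deposited records carry between their
   arms; the divergent-base count is recorded on the result. Ties on
   length are broken by the leftmost left arm. Arms whose exact stretches
   are all shorter than the seed are only guaranteed to be found on tiny
   inputs (≤ 64 bp), where an exhaustive per-diagonal scan replaces the
   seeded search — irrelevant in practice because sub-12 bp "IRs" are far
   below the filter threshold.

4. **Mapping back and classification.** Arm coordinates are mapped to
   deposited coordinates (`deposited = ((rotated − 1 + offset) mod L) + 1`,
   wrap encoded as start > end). Of the two single-copy gaps between the
   arms, the longer is the LSC and the shorter the SSC; the arm that
   follows the LSC in ascending wrap-aware order is IRb. An equal-gap tie
   is resolved toward the gap containing deposited base 1, then the lower
   start. Arms that abut (a zero-length gap) are rejected as a degenerate
   tetrad rather than given an empty SSC.

5. **Filter.** Genomes whose longest arm is shorter than `min_ir_len`
   (default 100 bp, a strict less-than: exactly 100 bp passes) and genomes
   with no `/gene` annotation are excluded, with the failed rule named.
   The 100 bp default separates true IRs from the tRNA-scale repeats
   common in IR-less genomes.

6. **Standardization.** The record is re-rotated so the LSC starts at
   base 1 and IRa ends at base `L`; gene segments are remapped, and split
   segments that become contiguous (origin-wrapping genes) are merged.
   All junction reporting and drawing happens in this frame.

Records can also be classified by where deposited base 1 falls: codes
`a/c/e/g` for the first base of LSC/IRb/SSC/IRa, `b/d/f/h` for strictly
inside those regions, plus a separate flag for genomes whose IRa, IRb or
SSC holds at most one gene. The flag is reported alongside the positional
code rather than replacing it, since a gene-sparse genome still has a
well-defined starting point.

## Junction contexts and plotting rules

The junction "position" is the last base of the upstream region; the
junction line sits between `position` and `position + 1`, which makes a
distance of 0 well-defined for abutting genes. Distances count the bases
strictly between a gene's junction-proximal boundary and the line. A gene
covering both `position` and `position + 1` spans the junction and is
reported with its base counts on either side; for multi-segment genes the
overall wrap-order extent is used, and the side-count identity is only
guaranteed for single-segment genes. JLA sits at the end of the
standardized sequence, so genes near base 1 flank it from the right and an
origin-wrapping gene spans it. No distance cutoff is applied — the nearest
gene on each side is always reported.

Per region, the figure follows a 0/1/≥2 rule: no genes, nothing drawn; one
gene, drawn mid-region with the region's endpoint coordinates printed; two
or more, only the first and last gene (by start, walking forward from the
region start) drawn at their true locations. Region membership is decided
by the gene's midpoint, so a junction-spanning gene belongs to the region
holding most of it.

## Rendering

One row per genome, rows in input order on a shared 1500-unit canvas.
Region block widths are proportional to region lengths within each row
(per-row scaling keeps genomes of different sizes comparable), with a
46-unit minimum so a 2–3 kb SSC remains visible; its true size is always
printed. Gene glyphs are arrows — rightward for the plus strand, leftward
for minus. Colliding text labels are nudged downward in 13-unit steps with
leader lines back to their anchors; the emitted SVG is checked to contain
no overlapping label boxes at the package's own font metrics. Layout uses
no randomness or timestamps, so identical input yields byte-identical SVG.
PDF and PNG are produced by rasterizing the package's own SVG subset with
Pillow; conversion is best-effort and the SVG remains canonical.

## Synthetic fixtures

The generator builds miniature tetrad molecules — uniform-random
single-copy regions, IRa the exact (or point-mutated) reverse complement
of IRb — rotated to realize each deposited start group, with a planted
gene catalog that includes the classic junction-spanning genes (*rps19*
over JLB, *ndhF* over JSB, *ycf1* over JSA, *ycf2* wrapping JLA) and
duplicated IR genes. Default region sizes are 900/300/200 bp
(LSC/IR/SSC), roughly a 1:50 scale model of a real plastome; the tests and
the acceptance script also sweep 2000/500/400 and 5000/1000/600 bp. Two
construction details matter:

* each molecule is screened with the exhaustive anti-diagonal oracle and
  regenerated from the next seed if any inverted repeat ≥ k bp exists
  outside the planted arms (uniqueness is verified, not assumed);
* the first base of each single-copy region is adjusted so it does not
  complement that region's last base — otherwise a 1-in-4 chance match at
  each junction would legitimately extend the longest exact pair past the
  planted boundary, and planted-truth recovery would fail for a reason
  that has nothing to do with the detector.

What the fixtures do **not** emulate: realistic base composition or gene
catalogs, sequencing error, pseudogenes, indel divergence between arms
(only substitutions, pairwise ≥ 13 bp apart so chaining can bridge them),
and multi-repeat or IR-less architectures. Passing the suite therefore
demonstrates correct coordinate arithmetic, rotation handling and exact
repeat detection at reduced scale, not robustness to assembly artifacts.
Fixture sizes were chosen so the exhaustive screening oracle (quadratic
work, vectorized per diagonal) stays fast; full-size plastomes are handled
by the seeded finder, whose cost scales with seed hits rather than length.

## Published reference coordinates

`irdraw.reference` carries the deposited tetrad coordinates of eighteen
representative RefSeq plastomes, two per start group, used as offline
oracles for wrap notation, tetrad binding and start-group classification.
Two quirks are recorded there explicitly: one record's printed IR arms
differ by a single base, which no genome length can reconcile with the
equal-arm invariant (kept parse-only); and for mid-LSC/mid-SSC starts the
genome length is underdetermined by the coordinates alone, so the minimal
consistent length is bound — every length-invariant property (partition,
classification) is unaffected. `scripts/refseq_check.py` re-detects these
records from sequence when network access is available.

## Numerical and degenerate-input choices

* Coordinates are 1-based inclusive everywhere; origin wrap is encoded as
  start > end (never negative or zero coordinates).
* Ambiguity codes never match anything in repeat detection and never count
  as single-copy.
* A genome that is one giant repeat (no single-copy window) is an error;
  a repeat-free genome rotates trivially (offset 0).
* Gene features lacking a `/gene` qualifier are ignored; duplicated
  gene/CDS/tRNA/rRNA features with identical name, strand and segments
  plot once.
* The filter threshold comparison is strict (`< min_ir_len` fails).

## Known limitations

Only the single longest IR pair is reported; tripartite or otherwise
aberrant architectures are reduced to their dominant pair. Divergence
between arms beyond spaced point substitutions (indels, clustered edits
inside one seed length) breaks chaining and shortens the detected arm.
The renderer draws junction neighborhoods, not whole-genome maps, and has
no interactive output.
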