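"""Inverted-repeat detection and tetrad classification.

The deposited (GenBank) starting point of a circular plastome can fall
anywhere on the molecule, including inside an IR arm, which makes the arm
appear split across the origin.  The detection pipeline therefore:

1. counts canonical k-mers (a k-mer identified with its reverse complement)
   over every circular window;
2. rotates the sequence so that it starts in the middle of the longest run
   of single-copy k-mers — territory guaranteed free of the IR, so neither
   arm can cross the new origin;
3. finds the longest pair of reverse-complementary substrings (the IR arms)
   on the rotated, wrap-free sequence by anti-diagonal seed-and-extend with
   optional chaining across small mismatch gaps;
4. maps the arms back to deposited coordinates and labels the two
   single-copy gaps between them LSC (longer) and SSC (shorter);
5. optionally re-rotates the whole record so the LSC starts at base 1, the
   convention under which junctions are reported and drawn.

All public coordinates are 1-based inclusive; start > end wraps the origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

from .genbank_io import (
    AnnotatedGenome,
    GeneFeature,
    Region,
    Tetrad,
    circular_contains,
    circular_length,
    next_base,
)

__all__ = [
    "DetectionParams",
    "IRPair",
    "StartGroup",
    "DetectionError",
    "revcomp",
    "canonical_kmer_counts",
    "find_rotation_point",
    "rotate",
    "find_longest_inverted_repeat",
    "map_to_original",
    "classify_tetrad",
    "passes_filter",
    "standardize_start",
    "classify_start_group",
    "detect_tetrad",
]

logger = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")
_ACGT = frozenset("ACGT")

# Seed length for the inverted-repeat finder.  Exact arms (or exact
# sub-stretches between mismatches) of at least this length are always
# found; tiny inputs fall back to an exhaustive anti-diagonal scan.
_SEED_LEN = 12
_EXHAUSTIVE_MAX_N = 64


class DetectionError(ValueError):
    """Raised when IR detection cannot proceed on a genome."""


def revcomp(seq: str) -> str:
    """Reverse complement (ACGT only; other letters pass through complemented
    to themselves-unknown and never match)."""
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectionParams:
    """Tunable knobs of IR detection.

    k:          window size for canonical k-mer counting (bp)
    step:       window step (bp)
    min_ir_len: arm length below which a genome is filtered out
    run_mode:   rule picking the rotation point inside single-copy territory
    chain_gap:  maximum gap (bp) bridged when chaining collinear exact
                inverted matches into one arm, tolerating point divergences
                between the two deposited arms
    """

    k: int = 55
    step: int = 1
    min_ir_len: int = 100
    run_mode: str = "longest-run-midpoint"
    chain_gap: int = 10

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.min_ir_len < 1:
            raise ValueError("min_ir_len must be >= 1")
        if self.chain_gap < 0:
            raise ValueError("chain_gap must be >= 0")
        if self.run_mode != "longest-run-midpoint":
            raise ValueError(f"unknown run_mode {self.run_mode!r}")


@dataclass(frozen=True)
class IRPair:
    """The two arms of an inverted repeat, 1-based inclusive, wrap-capable.

    ``mismatches`` counts the bases inside chained gaps where the arms
    diverge; 0 means the arms are exact reverse complements.
    """

    arm_b: tuple[int, int]
    arm_a: tuple[int, int]
    length: int
    mismatches: int = 0


@dataclass(frozen=True)
class StartGroup:
    """Starting-point class of the deposited record.

    ``code`` in a..h records where deposited base 1 falls: a/c/e/g on the
    first base of LSC/IRb/SSC/IRa, b/d/f/h strictly inside the same regions.
    ``sparse_ir_or_ssc`` is the additional 'i' flag for genomes whose IRa,
    IRb, or SSC carries at most one gene.
    """

    code: str
    sparse_ir_or_ssc: bool = False


# ---------------------------------------------------------------------------
# Canonical k-mer scan and rotation
# ---------------------------------------------------------------------------

def canonical_kmer_counts(
    sequence: str, k: int, step: int = 1, topology: str = "linear"
) -> dict[str, int]:
    """Count canonical k-mers over all windows of ``sequence``.

    Each window contributes one count keyed by the lexicographically smaller
    of the k-mer and its reverse complement.  On circular topology the
    windows wrap the origin so every ``step``-th base starts one window.
    Windows containing non-ACGT letters are skipped.
    """
    n = len(sequence)
    if n < k:
        raise ValueError(f"sequence length {n} shorter than k={k}")
    if topology == "circular":
        ext = sequence + sequence[: k - 1]
        starts = range(0, n, step)
    else:
        ext = sequence
        starts = range(0, n - k + 1, step)
    counts: dict[str, int] = {}
    for i in starts:
        w = ext[i : i + k]
        if not _ACGT.issuperset(w):
            continue
        rc = revcomp(w)
        key = w if w <= rc else rc
        counts[key] = counts.get(key, 0) + 1
    return counts


def _single_copy_mask(sequence: str, params: DetectionParams, topology: str) -> list[bool]:
    counts = canonical_kmer_counts(sequence, params.k, params.step, topology)
    n = len(sequence)
    if topology == "circular":
        ext = sequence + sequence[: params.k - 1]
        starts = range(0, n, params.step)
    else:
        ext = sequence
        starts = range(0, n - params.k + 1, params.step)
    mask = []
    for i in starts:
        w = ext[i : i + params.k]
        if not _ACGT.issuperset(w):
            mask.append(False)
            continue
        rc = revcomp(w)
        key = w if w <= rc else rc
        mask.append(counts[key] == 1)
    return mask


def find_rotation_point(genome: AnnotatedGenome, params: DetectionParams) -> int:
    """0-based rotation offset placing the new start mid-way through the
    longest run of single-copy k-mer windows.

    The longest single-copy run lies in the larger single-copy region, so
    the rotated sequence starts far from both IR arms and neither arm can
    straddle the new origin.
    """
    mask = _single_copy_mask(genome.sequence, params, genome.topology)
    m = len(mask)
    if not any(mask):
        raise DetectionError("no single-copy region found")
    if all(mask):
        return 0  # repeat-free molecule: any start works
    # longest maximal run of True; on circular records runs may wrap the
    # mask boundary, so measure each run start in a doubled copy
    wrap = genome.topology == "circular"
    doubled = mask + mask if wrap else mask
    if wrap:
        run_starts = [i for i in range(m) if mask[i] and not mask[i - 1]]
    else:
        run_starts = [
            i for i in range(m) if mask[i] and (i == 0 or not mask[i - 1])
        ]
    best_len, best_start = 0, 0
    for s in run_starts:
        j = s
        while j < len(doubled) and doubled[j] and j - s < m:
            j += 1
        if j - s > best_len:
            best_len, best_start = j - s, s
    mid_index = (best_start + best_len // 2) % m
    return (mid_index * params.step) % len(genome.sequence)


def rotate(sequence: str, offset: int) -> str:
    """Rotate so the character at 0-based ``offset`` becomes the first."""
    if not 0 <= offset < max(len(sequence), 1):
        raise ValueError(f"offset {offset} outside [0, {len(sequence)})")
    return sequence[offset:] + sequence[:offset]


def map_to_original(
    interval: tuple[int, int], offset: int, genome_length: int
) -> tuple[int, int]:
    """Map a 1-based interval from rotated back to deposited coordinates.

    The result may wrap (start > end) when the interval crosses the
    deposited origin.
    """
    s, e = interval
    return (
        (s - 1 + offset) % genome_length + 1,
        (e - 1 + offset) % genome_length + 1,
    )


# ---------------------------------------------------------------------------
# Inverted-repeat search (anti-diagonal seed-and-extend)
# ---------------------------------------------------------------------------
#
# If seq[p] pairs with seq[q] in an inverted repeat (seq[p] == complement
# of seq[q]) then every extension keeps p + q constant: matches live on
# anti-diagonals d = p + q.  A maximal run of pairing positions on diagonal
# d with p < d - p is an inverted-repeat pair with the left arm [p1, p2]
# and the right arm [d - p2, d - p1].

def _good(seq: str, comp: str, d: int, p: int, n: int) -> bool:
    q = d - p
    if not (0 <= p < n and 0 <= q < n):
        return False
    return seq[p] == comp[q] and seq[p] in _ACGT


def _candidates_exhaustive(seq: str, comp: str) -> dict[int, list[list[int]]]:
    n = len(seq)
    diags: dict[int, list[list[int]]] = {}
    for d in range(1, 2 * n - 2):
        hi = (d - 1) // 2  # keep left arm strictly left of right arm
        lo = max(0, d - n + 1)
        runs: list[list[int]] = []
        run_start = None
        for p in range(lo, hi + 2):
            if p <= hi and _good(seq, comp, d, p, n):
                if run_start is None:
                    run_start = p
            elif run_start is not None:
                runs.append([run_start, p - 1])
                run_start = None
        if runs:
            diags[d] = runs
    return diags


def _candidates_seeded(seq: str, comp: str) -> dict[int, list[list[int]]]:
    n = len(seq)
    s = _SEED_LEN
    index: dict[str, list[int]] = {}
    for i in range(n - s + 1):
        w = seq[i : i + s]
        if _ACGT.issuperset(w):
            index.setdefault(w, []).append(i)
    diags: dict[int, set[tuple[int, int]]] = {}
    for i in range(n - s + 1):
        w = seq[i : i + s]
        if not _ACGT.issuperset(w):
            continue
        for j in index.get(revcomp(w), ()):
            if j < i:
                continue  # the (j, i) seed covers the mirrored interval
            d = i + j + s - 1
            diags.setdefault(d, set()).add((i, i + s - 1))
    out: dict[int, list[list[int]]] = {}
    for d, ivs in diags.items():
        hi_cap = (d - 1) // 2
        merged: list[list[int]] = []
        for a, b in sorted(ivs):
            if merged and a <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        runs: list[list[int]] = []
        for a, b in merged:
            # extend the exact match base-by-base beyond the seeds
            while _good(seq, comp, d, a - 1, n):
                a -= 1
            while _good(seq, comp, d, b + 1, n):
                b += 1
            b = min(b, hi_cap)
            if a <= b:
                if runs and a <= runs[-1][1] + 1:
                    runs[-1][1] = max(runs[-1][1], b)
                else:
                    runs.append([a, b])
        if runs:
            out[d] = runs
    return out


def find_longest_inverted_repeat(
    sequence: str, params: DetectionParams = DetectionParams()
) -> Optional[IRPair]:
    """Longest pair of non-overlapping reverse-complementary substrings.

    Collinear exact matches on the same anti-diagonal separated by gaps of
    at most ``params.chain_gap`` bp are chained into a single arm, which
    tolerates the point divergences some deposited records carry between
    their IR arms.  Returns ``None`` when nothing is found (consumed by the
    downstream filter).  Ties on length are broken by the leftmost left-arm
    start, then by the leftmost right arm.

    Exact arms shorter than the internal seed length (12 bp) are only
    guaranteed to be found on tiny inputs, where an exhaustive scan is used.
    """
    seq = sequence.upper()
    n = len(seq)
    if n < 2:
        return None
    comp = seq.translate(_COMP)
    if n <= _EXHAUSTIVE_MAX_N:
        diags = _candidates_exhaustive(seq, comp)
    else:
        diags = _candidates_seeded(seq, comp)

    best: Optional[tuple[int, int, int, int]] = None  # (-len, start, d, mism)
    for d, runs in diags.items():
        # chain runs separated by <= chain_gap divergent bases
        chained: list[tuple[int, int, int]] = []  # (a, b, mismatches)
        ca, cb, cm = runs[0][0], runs[0][1], 0
        for a, b in runs[1:]:
            gap = a - cb - 1
            if 0 <= gap <= params.chain_gap:
                cm += gap
                cb = b
            else:
                chained.append((ca, cb, cm))
                ca, cb, cm = a, b, 0
        chained.append((ca, cb, cm))
        for a, b, m in chained:
            length = b - a + 1
            cand = (-length, a, d, m)
            if best is None or cand < best:
                best = cand
    if best is None:
        return None
    neg_len, a, d, m = best
    length = -neg_len
    b = a + length - 1
    return IRPair(
        arm_b=(a + 1, b + 1),
        arm_a=(d - b + 1, d - a + 1),
        length=length,
        mismatches=m,
    )


# ---------------------------------------------------------------------------
# Tetrad classification
# ---------------------------------------------------------------------------

def classify_tetrad(ir: IRPair, genome_length: int) -> Tetrad:
    """Label the two single-copy gaps between the arms LSC/SSC and the arms
    IRb/IRa, in whatever (possibly wrapped) coordinate frame ``ir`` uses.

    The longer gap is the LSC; the arm that follows it in ascending
    wrap-aware order is IRb.  An equal-gap tie is resolved in favour of the
    gap containing base 1 (failing that, the gap with the lower start).  A
    zero-length gap means the arms abut and the tetrad is degenerate.
    """
    L = genome_length
    arm1, arm2 = ir.arm_b, ir.arm_a
    gap1 = (arm1[1], arm2[0])  # after arm1, before arm2
    gap2 = (arm2[1], arm1[0])  # after arm2, before arm1 (around the circle)

    def gap_region(gap: tuple[int, int]) -> tuple[int, int, int]:
        start = next_base(gap[0], L)
        end = (gap[1] - 2) % L + 1
        length = (gap[1] - gap[0] - 1) % L
        return start, end, length

    s1, e1, len1 = gap_region(gap1)
    s2, e2, len2 = gap_region(gap2)
    if len1 == 0 or len2 == 0:
        raise DetectionError("degenerate tetrad: IR arms abut, a single-copy gap is empty")

    if len1 != len2:
        lsc_first = len1 > len2
    elif circular_contains(s1, e1, L, 1) != circular_contains(s2, e2, L, 1):
        lsc_first = circular_contains(s1, e1, L, 1)
    else:
        lsc_first = s1 < s2
    if lsc_first:
        lsc = Region("LSC", s1, e1)
        irb = Region("IRb", *arm2)
        ssc = Region("SSC", s2, e2)
        ira = Region("IRa", *arm1)
    else:
        lsc = Region("LSC", s2, e2)
        irb = Region("IRb", *arm1)
        ssc = Region("SSC", s1, e1)
        ira = Region("IRa", *arm2)
    tetrad = Tetrad(lsc, irb, ssc, ira, genome_length=L)
    tetrad.validate()
    return tetrad


def passes_filter(
    genome: AnnotatedGenome,
    tetrad_or_ir: object,
    params: DetectionParams = DetectionParams(),
) -> tuple[bool, str]:
    """Apply the acceptance filter: genomes whose longest IR arm is shorter
    than ``min_ir_len`` and genomes without gene annotation are excluded.

    ``tetrad_or_ir`` may be a Tetrad, an IRPair, or None (nothing found).
    Returns ``(verdict, reason)``; the reason names the failed rule.
    """
    if isinstance(tetrad_or_ir, Tetrad):
        arm_len = tetrad_or_ir.irb.length(tetrad_or_ir.genome_length or genome.length)
    elif isinstance(tetrad_or_ir, IRPair):
        arm_len = tetrad_or_ir.length
    else:
        arm_len = 0
    if arm_len < params.min_ir_len:
        return False, f"IR < {params.min_ir_len} bp"
    if not genome.is_annotated:
        return False, "unannotated"
    return True, "ok"


# ---------------------------------------------------------------------------
# Standardization and start grouping
# ---------------------------------------------------------------------------

def _map_point(pos: int, offset: int, L: int) -> int:
    """Deposited 1-based position -> standardized 1-based position."""
    return (pos - 1 - offset) % L + 1


def _map_segment(seg: tuple[int, int], offset: int, L: int) -> tuple[int, int]:
    return (_map_point(seg[0], offset, L), _map_point(seg[1], offset, L))


def _merge_contiguous(
    segments: list[tuple[int, int]], L: int
) -> tuple[tuple[int, int], ...]:
    merged: list[tuple[int, int]] = []
    for seg in segments:
        if merged and next_base(merged[-1][1], L) == seg[0]:
            merged[-1] = (merged[-1][0], seg[1])
        else:
            merged.append(seg)
    return tuple(merged)


def standardize_start(
    genome: AnnotatedGenome, tetrad: Tetrad
) -> tuple[AnnotatedGenome, Tetrad]:
    """Rotate the record so the LSC starts at base 1.

    Gene segments and region coordinates are remapped; split segments that
    become contiguous after the rotation (origin-wrapping genes) are merged
    back into one interval.  The returned gene list is carried on the
    returned genome.
    """
    L = genome.length
    tetrad = tetrad.with_genome_length(L)
    offset = tetrad.lsc.start - 1
    new_seq = rotate(genome.sequence, offset)
    new_regions = {
        r.label: Region(r.label, _map_point(r.start, offset, L), _map_point(r.end, offset, L))
        for r in tetrad.regions()
    }
    new_tetrad = Tetrad(
        new_regions["LSC"],
        new_regions["IRb"],
        new_regions["SSC"],
        new_regions["IRa"],
        genome_length=L,
    )
    new_tetrad.validate()

    new_genes = []
    for gene in genome.genes:
        segs = [_map_segment(s, offset, L) for s in gene.segments]
        new_genes.append(replace(gene, segments=_merge_contiguous(segs, L)))
    new_genome = replace(genome, sequence=new_seq, genes=tuple(new_genes))
    return new_genome, new_tetrad


def _gene_midpoint(gene: GeneFeature, L: int) -> int:
    """The base at the middle of the gene, walking its segments in order."""
    total = gene.total_length(L)
    target = (total + 1) // 2
    walked = 0
    for s, e in gene.segments:
        seg_len = circular_length(s, e, L)
        if walked + seg_len >= target:
            return (s - 1 + (target - walked - 1)) % L + 1
        walked += seg_len
    return gene.segments[-1][1]


def genes_in_region(
    genes: tuple[GeneFeature, ...], region: Region, L: int
) -> list[GeneFeature]:
    """Genes assigned to a region by the wrap-aware midpoint rule."""
    return [g for g in genes if region.contains(_gene_midpoint(g, L), L)]


def classify_start_group(genome: AnnotatedGenome, tetrad: Tetrad) -> StartGroup:
    """Classify where deposited base 1 falls relative to the tetrad (codes
    a-h) and flag genomes whose IRa, IRb, or SSC holds at most one gene."""
    L = tetrad.genome_length or genome.length
    tetrad = tetrad.with_genome_length(L)
    first = {"LSC": "a", "IRb": "c", "SSC": "e", "IRa": "g"}
    inside = {"LSC": "b", "IRb": "d", "SSC": "f", "IRa": "h"}
    code = None
    for reg in tetrad.regions():
        if reg.start == 1:
            code = first[reg.label]
            break
        if reg.contains(1, L):
            code = inside[reg.label]
            break
    assert code is not None  # the four regions cover the circle
    sparse = any(
        len(genes_in_region(genome.genes, tetrad.region(lab), L)) <= 1
        for lab in ("IRb", "SSC", "IRa")
    )
    return StartGroup(code=code, sparse_ir_or_ssc=sparse)


# ---------------------------------------------------------------------------
# Full detection driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectionResult:
    tetrad: Tetrad  # deposited coordinates
    ir: IRPair  # deposited coordinates
    rotation_offset: int
    truncated_at_end: bool = False  # linear record whose IR touches an end


def detect_tetrad(
    genome: AnnotatedGenome, params: DetectionParams = DetectionParams()
) -> DetectionResult:
    """Run rotation + IR search + classification on one genome, returning
    the tetrad in deposited coordinates.

    Linear records are searched as-is (rotating a linear molecule is
    meaningless); circular records are first rotated into single-copy
    territory so the IR cannot straddle the origin.
    """
    L = genome.length
    if genome.topology == "circular":
        offset = find_rotation_point(genome, params)
        working = rotate(genome.sequence, offset)
    else:
        offset = 0
        working = genome.sequence
    ir_rot = find_longest_inverted_repeat(working, params)
    if ir_rot is None:
        raise DetectionError("no IR found")
    truncated = False
    if genome.topology == "linear":
        if ir_rot.arm_b[0] == 1 or ir_rot.arm_a[1] == L:
            truncated = True
            logger.warning("%s: IR truncated at sequence end", genome.accession)
    ir = IRPair(
        arm_b=map_to_original(ir_rot.arm_b, offset, L),
        arm_a=map_to_original(ir_rot.arm_a, offset, L),
        length=ir_rot.length,
        mismatches=ir_rot.mismatches,
    )
    tetrad = classify_tetrad(ir, L)
    # classify_tetrad decides which arm is IRb; reorder the pair to match
    ir = IRPair(
        arm_b=(tetrad.irb.start, tetrad.irb.end),
        arm_a=(tetrad.ira.start, tetrad.ira.end),
        length=ir_rot.length,
        mismatches=ir_rot.mismatches,
    )
    logger.info(
        "%s: rotation offset %d, IRb %s, IRa %s, arm length %d (%d mismatches)",
        genome.accession, offset, ir.arm_b, ir.arm_a, ir.length, ir.mismatches,
    )
    return DetectionResult(
        tetrad=tetrad, ir=ir, rotation_offset=offset, truncated_at_end=truncated
    )
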