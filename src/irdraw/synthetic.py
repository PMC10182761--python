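"""Ground-truth plastome fixtures for testing without downloads.

A fixture is a miniature tetrad molecule — random LSC, IRb and SSC with
IRa the exact (or point-mutated) reverse complement of IRb — rotated so
that the deposited starting point falls in any of the eight positional
classes a-h (first base of / strictly inside each region), plus the 'i'
scenario of a gene-sparse SSC.  The generator returns GenBank flat-file
text, the planted tetrad in deposited coordinates, and the planted gene
list, so every pipeline stage can be checked against known truth.

Single-copy uniqueness is not assumed: each molecule is screened with an
exhaustive anti-diagonal scan (independent of the production IR finder),
and regenerated from the next seed if a spurious inverted repeat at least
as long as the k-mer window shows up outside the planted arms.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .genbank_io import (
    AnnotatedGenome,
    GeneFeature,
    Region,
    Tetrad,
    genome_to_genbank_text,
)
from .ir_core import revcomp

__all__ = [
    "FixtureSpec",
    "Fixture",
    "GENE_PLAN_DEFAULT",
    "GROUP_OFFSETS",
    "generate",
    "generate_group_suite",
    "longest_inverted_pair_bruteforce",
    "inverted_runs_at_least",
]

# Offsets (as fractions of region starts) that realize each start group on a
# canonical LSC+IRb+SSC+IRa molecule. 'a' keeps the canonical orientation.
GROUP_CODES = ("a", "b", "c", "d", "e", "f", "g", "h")

# Default planted genes: (region, offset, length, strand, name).  A
# positive offset is 1-based from the region start; a negative offset
# anchors the gene near the region's end: the gene starts |offset| - 1
# bases before the base following the region, so a long enough gene runs
# across the downstream junction (rps19 over JLB, ycf1 over JSA — the
# classic junction-spanning genes; ycf2 wraps JLA into the LSC).  trnH
# sits near the start of the LSC, flanking JLA from the right.
GENE_PLAN_DEFAULT: tuple[tuple[str, int, int, str, str], ...] = (
    ("LSC", 45, 40, "+", "trnH"),
    ("LSC", 101, 120, "+", "psbA"),
    ("LSC", -60, 120, "+", "rps19"),   # covers JLB-59 .. JLB+60
    ("IRb", 41, 60, "-", "rpl2"),
    ("IRb", 151, 60, "-", "rrn16"),
    ("IRb", -19, 80, "-", "ndhF"),     # covers JSB-18 .. JSB+61
    ("SSC", 61, 90, "-", "ccsA"),
    ("SSC", -44, 90, "+", "ycf1"),     # covers JSA-43 .. JSA+46
    ("IRa", 101, 60, "+", "rpl2"),
    ("IRa", 201, 60, "+", "rrn16"),
    ("IRa", -9, 50, "+", "ycf2"),      # covers JLA-8 .. JLA+41 (wraps)
)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic plastome."""

    lsc_len: int = 900
    ir_len: int = 300
    ssc_len: int = 200
    start_group: str = "a"
    genes: tuple[tuple[str, int, int, str, str], ...] = GENE_PLAN_DEFAULT
    seed: int = 1
    mutations_in_ira: int = 0
    organism: str = "Synthetica plastoma"
    accession: str = "SYN_000001.1"
    k: int = 55  # spurious-repeat screening threshold (matches detection k)

    def __post_init__(self) -> None:
        if not (self.lsc_len >= self.ssc_len >= 1 and self.ir_len >= 1):
            raise ValueError("need lsc_len >= ssc_len >= 1 and ir_len >= 1")
        if self.start_group not in GROUP_CODES:
            raise ValueError(f"start_group must be one of {GROUP_CODES}")

    @property
    def genome_length(self) -> int:
        return self.lsc_len + 2 * self.ir_len + self.ssc_len


@dataclass(frozen=True)
class Fixture:
    """A generated molecule with its planted truth (deposited coordinates)."""

    gb_text: str
    genome: AnnotatedGenome
    tetrad: Tetrad
    genes: tuple[GeneFeature, ...]
    start_group: str
    rotation_offset: int  # deposited base 1 == canonical base offset+1
    spec: FixtureSpec


# ---------------------------------------------------------------------------
# Independent inverted-repeat oracle (exhaustive anti-diagonal scan, numpy)
# ---------------------------------------------------------------------------

_COMP_TABLE = np.zeros(256, dtype=np.uint8)
for _x, _y in zip(b"ACGT", b"TGCA"):
    _COMP_TABLE[_x] = _y


def _run_spans(good: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) index pairs into ``good``."""
    if not good.any():
        return []
    g = good.astype(np.int8)
    diff = np.diff(np.concatenate(([0], g, [0])))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1) - 1
    return list(zip(starts.tolist(), stops.tolist()))


def inverted_runs_at_least(
    seq: str, min_len: int
) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """All maximal exact inverted-repeat pairs with arms >= ``min_len`` bp,
    as 1-based ((left arm), (right arm)) with the left arm strictly left.

    Exhaustive over every anti-diagonal; O(n^2) work but vectorized per
    diagonal, serving as the independent oracle for the seeded finder.
    """
    n = len(seq)
    a = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    c = _COMP_TABLE[a]
    out = []
    for d in range(2 * min_len - 1, 2 * n - 2):
        lo = max(0, d - n + 1)
        hi = (d - 1) // 2
        if hi - lo + 1 < min_len:
            continue
        p = np.arange(lo, hi + 1)
        good = a[p] == c[d - p]
        for s_idx, e_idx in _run_spans(good):
            if e_idx - s_idx + 1 >= min_len:
                ps, pe = lo + s_idx, lo + e_idx
                out.append(((ps + 1, pe + 1), (d - pe + 1, d - ps + 1)))
    return out


def longest_inverted_pair_bruteforce(
    seq: str,
) -> Optional[tuple[tuple[int, int], tuple[int, int]]]:
    """The longest exact inverted pair by exhaustive scan (ties: leftmost
    left-arm start, then leftmost right arm); None when nothing pairs."""
    n = len(seq)
    a = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    c = _COMP_TABLE[a]
    best = None  # (-len, left_start, d)
    for d in range(1, 2 * n - 2):
        lo = max(0, d - n + 1)
        hi = (d - 1) // 2
        if hi < lo:
            continue
        p = np.arange(lo, hi + 1)
        good = a[p] == c[d - p]
        for s_idx, e_idx in _run_spans(good):
            length = e_idx - s_idx + 1
            cand = (-length, lo + s_idx, d)
            if best is None or cand < best:
                best = cand
    if best is None:
        return None
    neg_len, s, d = best
    e = s - neg_len - 1
    return ((s + 1, e + 1), (d - e + 1, d - s + 1))


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _block_extension(sc_region: str, rng: random.Random) -> str:
    """Ensure a single-copy region's first base is not the complement of its
    last base.  In the rotated frame both single-copy regions flank the IR
    arms on the pairing diagonal, so this single change pins the detected
    arm ends exactly at the planted junctions."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    if sc_region and sc_region[0] == comp[sc_region[-1]]:
        choices = [b for b in "ACGT" if b != comp[sc_region[-1]]]
        sc_region = rng.choice(choices) + sc_region[1:]
    return sc_region


def _mutate_arm(arm: str, count: int, rng: random.Random) -> str:
    """Substitute ``count`` interior bases, pairwise at least 13 bp apart and
    at least 20 bp from either end, so the production finder can chain the
    exact sub-matches across the gaps."""
    if count == 0:
        return arm
    n = len(arm)
    margin, spacing = 20, 13
    if n < 2 * margin + (count - 1) * spacing + 1:
        raise ValueError(f"arm of {n} bp too short for {count} spaced mutations")
    positions: list[int] = []
    attempts = 0
    while len(positions) < count and attempts < 10_000:
        p = rng.randrange(margin, n - margin)
        if all(abs(p - q) >= spacing for q in positions):
            positions.append(p)
        attempts += 1
    if len(positions) < count:
        raise ValueError("could not place spaced mutations")
    out = list(arm)
    for p in sorted(positions):
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


def _canonical_gene_coords(
    spec: FixtureSpec,
) -> list[tuple[str, int, int, str, str]]:
    """Resolve the gene plan to canonical absolute (name, start, end, strand,
    kind) coordinates; entries may run past their region's end (junction
    spanning) and past the molecule end (wrapping into the LSC)."""
    L = spec.genome_length
    region_start = {
        "LSC": 1,
        "IRb": spec.lsc_len + 1,
        "SSC": spec.lsc_len + spec.ir_len + 1,
        "IRa": spec.lsc_len + spec.ir_len + spec.ssc_len + 1,
    }
    region_len = {
        "LSC": spec.lsc_len,
        "IRb": spec.ir_len,
        "SSC": spec.ssc_len,
        "IRa": spec.ir_len,
    }
    out = []
    for region, off, length, strand, name in spec.genes:
        rlen = region_len[region]
        if off < 0:  # anchored |off|-1 bases before the downstream junction
            start = region_start[region] + rlen + off
        else:
            start = region_start[region] + off - 1
        end = start + length - 1
        if length > L:
            raise ValueError(f"gene {name} longer than the genome")
        kind = "tRNA" if name.startswith("trn") else "gene"
        out.append((name, (start - 1) % L + 1, (end - 1) % L + 1, kind, strand))
    return out


def _to_deposited(pos: int, offset: int, L: int) -> int:
    return (pos - 1 - offset) % L + 1


def _deposited_segments(
    start: int, end: int, offset: int, L: int
) -> tuple[tuple[int, int], ...]:
    s = _to_deposited(start, offset, L)
    e = _to_deposited(end, offset, L)
    if s <= e:
        return ((s, e),)
    return ((s, L), (1, e))  # split the origin-wrapping gene for the .gb join


def _group_offset(spec: FixtureSpec) -> int:
    l, r, s = spec.lsc_len, spec.ir_len, spec.ssc_len
    return {
        "a": 0,
        "b": l // 2,
        "c": l,
        "d": l + r // 2,
        "e": l + r,
        "f": l + r + s // 2,
        "g": l + r + s,
        "h": l + r + s + r // 2,
    }[spec.start_group]


def generate(spec: FixtureSpec, max_retries: int = 8) -> Fixture:
    """Build one fixture; deterministic given ``spec.seed``.

    The molecule is rebuilt from successive seeds when the screening oracle
    finds an inverted repeat >= ``spec.k`` bp outside the planted arms.
    """
    L = spec.genome_length
    last_err = None
    for attempt in range(max_retries):
        seed = spec.seed + 1_000_003 * attempt
        rng = random.Random(seed)
        lsc = _random_seq(rng, spec.lsc_len)
        irb = _random_seq(rng, spec.ir_len)
        ssc = _random_seq(rng, spec.ssc_len)
        # Sharpen the planted arm boundaries: the base flanking each arm
        # must not complement its mirror base, or a chance match would
        # extend the detected arm one base past the planted truth.
        lsc = _block_extension(lsc, rng)
        ssc = _block_extension(ssc, rng)
        ira = _mutate_arm(revcomp(irb), spec.mutations_in_ira, rng)
        canonical = lsc + irb + ssc + ira

        irb_iv = (spec.lsc_len + 1, spec.lsc_len + spec.ir_len)
        ira_iv = (L - spec.ir_len + 1, L)
        spurious = False
        for left, right in inverted_runs_at_least(canonical, spec.k):
            inside = (
                irb_iv[0] <= left[0] and left[1] <= irb_iv[1]
                and ira_iv[0] <= right[0] and right[1] <= ira_iv[1]
            )
            if not inside:
                spurious = True
                break
        if spurious:
            last_err = f"seed {seed}: spurious repeat >= {spec.k} bp"
            continue

        offset = _group_offset(spec)
        deposited = canonical[offset:] + canonical[:offset]

        def depos_region(label: str, start: int, end: int) -> Region:
            return Region(
                label,
                _to_deposited(start, offset, L),
                _to_deposited(end, offset, L),
            )

        tetrad = Tetrad(
            depos_region("LSC", 1, spec.lsc_len),
            depos_region("IRb", *irb_iv),
            depos_region("SSC", spec.lsc_len + spec.ir_len + 1, L - spec.ir_len),
            depos_region("IRa", *ira_iv),
            genome_length=L,
        )
        tetrad.validate()

        genes = tuple(
            GeneFeature(
                name=name,
                strand=strand,
                segments=_deposited_segments(cs, ce, offset, L),
                kind=kind,
            )
            for name, cs, ce, kind, strand in _canonical_gene_coords(spec)
        )
        genome = AnnotatedGenome(
            accession=spec.accession,
            organism=spec.organism,
            sequence=deposited,
            topology="circular",
            genes=genes,
        )
        return Fixture(
            gb_text=genome_to_genbank_text(genome),
            genome=genome,
            tetrad=tetrad,
            genes=genes,
            start_group=spec.start_group,
            rotation_offset=offset,
            spec=replace(spec, seed=seed),
        )
    raise RuntimeError(f"fixture generation failed after {max_retries} tries: {last_err}")


def generate_group_suite(
    base_spec: FixtureSpec = FixtureSpec(), seed: Optional[int] = None
) -> dict[str, Fixture]:
    """Nine fixtures keyed 'a'..'i'.

    Groups a-h are rotations of the *same* molecule (same seed), so their
    standardized tetrads and junction distances must agree exactly.  Group
    'i' is a separate molecule whose SSC is shrunk to carry a single gene.
    """
    if seed is not None:
        base_spec = replace(base_spec, seed=seed)
    suite: dict[str, Fixture] = {}
    for idx, code in enumerate(GROUP_CODES):
        spec = replace(
            base_spec,
            start_group=code,
            accession=f"SYN_{idx + 1:06d}.1",
            organism=f"Synthetica plastoma-{code}",
        )
        suite[code] = generate(spec)

    # group i: one short gene-poor SSC (IR expansion swallowed most of it)
    ssc_i = max(min(base_spec.ssc_len // 2, 120), 60)
    genes_i = tuple(
        g for g in base_spec.genes if g[0] != "SSC" and not (g[0] == "IRb" and g[1] < 0)
    ) + (("SSC", max(ssc_i // 2 - 10, 1), 20, "-", "ndhE"),)
    spec_i = replace(
        base_spec,
        start_group="a",
        ssc_len=ssc_i,
        genes=genes_i,
        accession="SYN_000009.1",
        organism="Synthetica plastoma-i",
    )
    suite["i"] = replace(generate(spec_i), start_group="i")
    return suite
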