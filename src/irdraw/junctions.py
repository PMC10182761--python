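"""Junction sites of a standardized plastome and their gene context.

The four junctions of the tetrad are named after the regions they separate:

====  =============  =========================================
name  boundary       position (standardized coordinates)
====  =============  =========================================
JLB   LSC / IRb      last base of the LSC
JSB   IRb / SSC      last base of the IRb
JSA   SSC / IRa      last base of the SSC
JLA   IRa / LSC      last base of the genome (wraps to base 1)
====  =============  =========================================

The junction line is drawn between ``position`` and ``position + 1``; a
gene whose boundary abuts the line has distance 0, and a gene covering both
sides spans the junction.  Genes moving across these lines between related
species are the signature of IR expansion and contraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

from .genbank_io import (
    AnnotatedGenome,
    GeneFeature,
    Region,
    Tetrad,
    circular_contains,
)
from .ir_core import genes_in_region

__all__ = [
    "JunctionSite",
    "JunctionGeneContext",
    "RegionGenePlan",
    "compute_junctions",
    "gene_context",
    "plan_region_genes",
    "junction_table_rows",
    "write_junction_table",
]

JUNCTION_NAMES = ("JLB", "JSB", "JSA", "JLA")


@dataclass(frozen=True)
class JunctionSite:
    name: str
    left_region: str
    right_region: str
    position: int  # last base of the upstream region


@dataclass(frozen=True)
class JunctionGeneContext:
    """The two genes flanking one junction, plus any junction-spanning gene.

    Distances count the bases strictly between the gene's junction-proximal
    boundary and the junction line (0 = abutting).  ``spanning`` carries the
    gene crossing the line with its base counts on either side; a spanning
    gene also serves as both flanks at distance 0.
    """

    junction: JunctionSite
    left_gene: Optional[GeneFeature] = None
    right_gene: Optional[GeneFeature] = None
    left_distance: Optional[int] = None
    right_distance: Optional[int] = None
    spanning: Optional[tuple[GeneFeature, int, int]] = None


@dataclass(frozen=True)
class RegionGenePlan:
    """Which genes of a region are drawn, and how.

    Zero genes: nothing drawn.  One gene: drawn mid-region with the region
    endpoints printed.  Two or more: only the first and last gene (by
    ascending start within the region), each at its true location.
    """

    region: Region
    plotted_genes: tuple[tuple[GeneFeature, str], ...]  # placement: at-location | mid-region
    endpoints_shown: bool


def compute_junctions(tetrad: Tetrad) -> tuple[JunctionSite, ...]:
    """The four junction sites of a standardized (LSC-first) tetrad."""
    L = tetrad.genome_length
    if L is None:
        raise ValueError("tetrad has no genome length bound")
    tetrad.validate()
    if tetrad.lsc.start != 1:
        raise ValueError("junctions are computed on standardized (LSC-first) tetrads")
    return (
        JunctionSite("JLB", "LSC", "IRb", tetrad.lsc.end),
        JunctionSite("JSB", "IRb", "SSC", tetrad.irb.end),
        JunctionSite("JSA", "SSC", "IRa", tetrad.ssc.end),
        JunctionSite("JLA", "IRa", "LSC", L),
    )


def _gene_bounds(gene: GeneFeature, L: int) -> tuple[int, int, int]:
    """(first base, last base, span length) of the gene's overall extent,
    walking its segments in wrap order."""
    first = gene.segments[0][0]
    last = gene.segments[-1][1]
    span = (last - first) % L + 1
    return first, last, span


def gene_context(
    genes: Iterable[GeneFeature], junction: JunctionSite, genome_length: int
) -> JunctionGeneContext:
    """Find the genes flanking (or spanning) one junction.

    The left flank is the gene whose junction-proximal boundary (its last
    base) is nearest the line from the left; the right flank likewise from
    the right.  JLA sits at the end of the standardized sequence, so its
    right side wraps: genes near base 1 flank it from the right and a gene
    wrapping the origin spans it.  No distance cutoff is applied.
    """
    L = genome_length
    pos = junction.position
    genes = list(genes)

    spanning = None
    for g in genes:
        first, last, span = _gene_bounds(g, L)
        covers_pos = circular_contains(first, last, L, pos)
        covers_next = circular_contains(first, last, L, pos % L + 1)
        if covers_pos and covers_next and span < L:
            on_left = (pos - first) % L + 1
            on_right = span - on_left
            spanning = (g, on_left, on_right)
            break

    if spanning is not None:
        g = spanning[0]
        return JunctionGeneContext(
            junction=junction,
            left_gene=g,
            right_gene=g,
            left_distance=0,
            right_distance=0,
            spanning=spanning,
        )

    left_gene = None
    left_dist = None
    right_gene = None
    right_dist = None
    for g in genes:
        first, last, _ = _gene_bounds(g, L)
        # distance from the gene's last base back to the junction line,
        # and from its first base forward past the line, both wrap-aware
        dl = (pos - last) % L
        dr = (first - pos - 1) % L
        if dl <= dr:  # the gene lies on the left of this junction
            if left_dist is None or dl < left_dist or (
                dl == left_dist and first < left_gene.segments[0][0]
            ):
                left_gene, left_dist = g, dl
        else:
            if right_dist is None or dr < right_dist or (
                dr == right_dist and first < right_gene.segments[0][0]
            ):
                right_gene, right_dist = g, dr
    return JunctionGeneContext(
        junction=junction,
        left_gene=left_gene,
        right_gene=right_gene,
        left_distance=left_dist,
        right_distance=right_dist,
        spanning=None,
    )


def plan_region_genes(
    genes: Iterable[GeneFeature], region: Region, genome_length: int
) -> RegionGenePlan:
    """Apply the 0/1/>=2 plotting rule to the genes of one region.

    Membership is decided by the gene's midpoint; order within the region
    follows each gene's start walking forward from the region start.
    """
    L = genome_length
    members = genes_in_region(tuple(genes), region, L)
    members.sort(key=lambda g: (g.segments[0][0] - region.start) % L)
    if not members:
        return RegionGenePlan(region=region, plotted_genes=(), endpoints_shown=False)
    if len(members) == 1:
        return RegionGenePlan(
            region=region,
            plotted_genes=((members[0], "mid-region"),),
            endpoints_shown=True,
        )
    return RegionGenePlan(
        region=region,
        plotted_genes=((members[0], "at-location"), (members[-1], "at-location")),
        endpoints_shown=False,
    )


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def junction_table_rows(
    genome: AnnotatedGenome, contexts: Iterable[JunctionGeneContext]
) -> list[str]:
    rows = []
    for ctx in contexts:
        if ctx.spanning is not None:
            span = f"{ctx.spanning[0].name}:{ctx.spanning[1]}|{ctx.spanning[2]}"
        else:
            span = ""
        rows.append(
            "\t".join(
                [
                    genome.accession,
                    ctx.junction.name,
                    str(ctx.junction.position),
                    ctx.left_gene.name if ctx.left_gene else "",
                    str(ctx.left_distance) if ctx.left_distance is not None else "",
                    ctx.right_gene.name if ctx.right_gene else "",
                    str(ctx.right_distance) if ctx.right_distance is not None else "",
                    span,
                ]
            )
        )
    return rows


def write_junction_table(
    entries: Iterable[tuple[AnnotatedGenome, Iterable[JunctionGeneContext]]],
    path: Union[str, Path],
) -> Path:
    path = Path(path)
    lines = [
        "accession\tjunction\tposition\tleft_gene\tleft_distance"
        "\tright_gene\tright_distance\tspanning"
    ]
    for genome, contexts in entries:
        lines.extend(junction_table_rows(genome, contexts))
    path.write_text("\n".join(lines) + "\n")
    return path
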