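"""Stacked junction-site figure: layout, SVG output, PDF/PNG conversion.

One horizontal row per genome, each row showing the four tetrad regions as
colored blocks of proportional width, the four junction lines (JLB, JSB,
JSA, JLA), the flanking/spanning genes with their distances to each line,
and per-region gene glyphs following the 0/1/>=2 plotting rule.  Gene
transcription direction is drawn as an arrow: right for the plus strand,
left for the minus strand.

Rows are normalized to a common canvas width with per-row bp->pixel
scaling, so genomes of different sizes stay visually comparable.  Layout is
fully deterministic: identical input yields byte-identical SVG.  Colliding
text labels are nudged vertically (greedy, with leader lines), so no two
labels overlap at the default font metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union
from xml.sax.saxutils import escape

from .genbank_io import AnnotatedGenome, Tetrad
from .junctions import JunctionGeneContext, JunctionSite, RegionGenePlan

__all__ = [
    "GenomeView",
    "FigureSpec",
    "GenomeRow",
    "layout",
    "to_svg",
    "convert",
    "render_figure",
]

logger = logging.getLogger(__name__)

# -- fixed visual defaults ---------------------------------------------------
CANVAS_W = 1500.0
MARGIN_L = 30.0
MARGIN_R = 30.0
MARGIN_T = 30.0
MARGIN_B = 30.0
ROW_H = 190.0
BAR_H = 26.0
MIN_BLOCK_W = 46.0  # tiny regions stay visible at this width
FONT = "Helvetica, Arial, sans-serif"
FONT_SIZE = 12.0
CHAR_W = 6.8  # estimated glyph advance at FONT_SIZE, used for label boxes
LABEL_H = 13.0
REGION_FILL = {
    "LSC": "#8fbf87",
    "IRb": "#7391c8",
    "SSC": "#e3c567",
    "IRa": "#7391c8",
}
GENE_COLOR = {"+": "#b0413e", "-": "#35618f"}


# ---------------------------------------------------------------------------
# Figure model
# ---------------------------------------------------------------------------

@dataclass
class Label:
    text: str
    x: float
    y: float
    anchor: str = "start"  # start | middle | end
    cls: str = "label"
    italic: bool = False
    size: float = FONT_SIZE
    leader_from: Optional[tuple[float, float]] = None

    def bbox(self) -> tuple[float, float, float, float]:
        w = CHAR_W * len(self.text) * (self.size / FONT_SIZE)
        if self.anchor == "middle":
            x0 = self.x - w / 2
        elif self.anchor == "end":
            x0 = self.x - w
        else:
            x0 = self.x
        return (x0, self.y - LABEL_H, x0 + w, self.y)


@dataclass
class Block:
    label: str
    x: float
    w: float
    y: float
    h: float
    fill: str
    start_bp: int
    end_bp: int
    length_bp: int


@dataclass
class JunctionLine:
    name: str
    x: float
    y1: float
    y2: float


@dataclass
class Glyph:
    """A gene arrow; drawn from (x1) to (x2) with a strand-direction head."""

    name: str
    x1: float
    x2: float
    y: float
    strand: str
    spanning: bool = False


@dataclass
class GenomeRow:
    organism: str
    accession: str
    total_length_bp: int
    y: float
    blocks: list[Block] = field(default_factory=list)
    junction_lines: list[JunctionLine] = field(default_factory=list)
    glyphs: list[Glyph] = field(default_factory=list)
    labels: list[Label] = field(default_factory=list)


@dataclass
class FigureSpec:
    rows: list[GenomeRow]
    width: float
    height: float


@dataclass(frozen=True)
class GenomeView:
    """Everything the renderer needs for one genome, in standardized
    (LSC-first) coordinates."""

    genome: AnnotatedGenome
    tetrad: Tetrad
    junctions: Sequence[JunctionSite]
    contexts: Sequence[JunctionGeneContext]
    plans: Sequence[RegionGenePlan]


# ---------------------------------------------------------------------------
# Layout
# ---------------------------------------------------------------------------

def _block_widths(lengths: Sequence[int], avail: float) -> list[float]:
    """Proportional widths with a minimum for tiny regions, renormalized so
    the row still spans the full available width."""
    total = sum(lengths)
    widths = [avail * (ln / total) for ln in lengths]
    small = [i for i, w in enumerate(widths) if w < MIN_BLOCK_W]
    if small:
        fixed = MIN_BLOCK_W * len(small)
        rest = avail - fixed
        rest_total = sum(lengths[i] for i in range(4) if i not in small)
        for i in range(4):
            widths[i] = MIN_BLOCK_W if i in small else rest * lengths[i] / rest_total
    return widths


def _resolve_label_overlaps(labels: list[Label]) -> None:
    """Greedy vertical nudging: move a colliding label down in LABEL_H steps
    and give it a leader line back to its anchor point."""

    def collides(a: Label, b: Label) -> bool:
        ax0, ay0, ax1, ay1 = a.bbox()
        bx0, by0, bx1, by1 = b.bbox()
        return ax0 < bx1 and bx0 < ax1 and ay0 < by1 and by0 < ay1

    placed: list[Label] = []
    for lab in labels:
        origin = (lab.x, lab.y)
        moved = False
        guard = 0
        while any(collides(lab, p) for p in placed) and guard < 60:
            lab.y += LABEL_H
            moved = True
            guard += 1
        if moved:
            lab.leader_from = origin
        placed.append(lab)


def _scaler(blocks: list[Block], tetrad: Tetrad):
    """Piecewise-linear bp -> x mapping honouring per-block widths."""
    L = tetrad.genome_length

    def x_of(pos: int) -> float:
        for blk, reg in zip(blocks, tetrad.regions()):
            if (pos - reg.start) % L <= (reg.end - reg.start) % L:
                frac = ((pos - reg.start) % L) / max(reg.length(L) - 1, 1)
                return blk.x + frac * blk.w
        return blocks[-1].x + blocks[-1].w

    return x_of


def _row_layout(view: GenomeView, y: float) -> GenomeRow:
    genome, tetrad = view.genome, view.tetrad
    L = tetrad.genome_length or genome.length
    avail = CANVAS_W - MARGIN_L - MARGIN_R
    regions = tetrad.regions()
    lengths = [r.length(L) for r in regions]
    widths = _block_widths(lengths, avail)

    bar_y = y + 86.0
    row = GenomeRow(
        organism=genome.organism,
        accession=genome.accession,
        total_length_bp=L,
        y=y,
    )
    x = MARGIN_L
    for reg, w, ln in zip(regions, widths, lengths):
        row.blocks.append(
            Block(
                label=reg.label,
                x=x,
                w=w,
                y=bar_y,
                h=BAR_H,
                fill=REGION_FILL[reg.label],
                start_bp=reg.start,
                end_bp=reg.end,
                length_bp=ln,
            )
        )
        x += w
    x_of = _scaler(row.blocks, tetrad)

    # junction lines at the right edge of each block
    for jct, blk in zip(view.junctions, row.blocks):
        row.junction_lines.append(
            JunctionLine(name=jct.name, x=blk.x + blk.w, y1=bar_y - 42, y2=bar_y + BAR_H + 34)
        )

    labels: list[Label] = []
    labels.append(
        Label(
            text=f"{genome.organism}  ({genome.accession})  {L:,} bp",
            x=MARGIN_L,
            y=y + 22.0,
            anchor="start",
            cls="organism",
            italic=True,
            size=14.0,
        )
    )
    for blk in row.blocks:
        labels.append(
            Label(
                text=f"{blk.label} {blk.length_bp:,} bp",
                x=blk.x + blk.w / 2,
                y=blk.y + BAR_H / 2 + 4.5,
                anchor="middle",
                cls="region-label",
            )
        )
    for jl in row.junction_lines:
        labels.append(
            Label(
                text=jl.name,
                x=jl.x,
                y=jl.y2 + 14,
                anchor="middle",
                cls="junction-name",
            )
        )

    # per-region gene glyphs (0/1/>=2 rule)
    gene_y = bar_y - 14.0
    drawn: set[tuple[str, tuple]] = set()
    for plan, blk in zip(view.plans, row.blocks):
        for gene, placement in plan.plotted_genes:
            first = gene.segments[0][0]
            last = gene.segments[-1][1]
            if placement == "mid-region":
                mid = blk.x + blk.w / 2
                half_w = min(max(gene.total_length(L) * blk.w / max(blk.length_bp, 1), 8.0), blk.w * 0.45) / 2
                gx1, gx2 = mid - half_w, mid + half_w
            else:
                gx1, gx2 = x_of(first), x_of(last)
                if gx2 < gx1:  # origin-wrapping gene: draw the dominant piece
                    gx1, gx2 = x_of(first), CANVAS_W - MARGIN_R
                if gx2 - gx1 < 8.0:
                    gx2 = gx1 + 8.0
            key = (gene.name, gene.segments)
            if key in drawn:
                continue
            drawn.add(key)
            row.glyphs.append(Glyph(name=gene.name, x1=gx1, x2=gx2, y=gene_y, strand=gene.strand))
            labels.append(
                Label(
                    text=gene.name,
                    x=(gx1 + gx2) / 2,
                    y=gene_y - 8,
                    anchor="middle",
                    cls="gene-name",
                    italic=True,
                )
            )
        if plan.endpoints_shown:
            labels.append(
                Label(
                    text=f"{plan.region.start:,}",
                    x=blk.x + 2,
                    y=blk.y + BAR_H + 14,
                    anchor="start",
                    cls="region-endpoint",
                    size=10.0,
                )
            )
            labels.append(
                Label(
                    text=f"{plan.region.end:,}",
                    x=blk.x + blk.w - 2,
                    y=blk.y + BAR_H + 14,
                    anchor="end",
                    cls="region-endpoint",
                    size=10.0,
                )
            )

    # junction gene context: distances and spanning glyphs
    dist_y = bar_y + BAR_H + 28.0
    for ctx in view.contexts:
        jx = next(jl.x for jl in row.junction_lines if jl.name == ctx.junction.name)
        if ctx.spanning is not None:
            gene, on_left, on_right = ctx.spanning
            span_px = max(on_left + on_right, 1)
            w_left = min(on_left / span_px * 90.0 + 10.0, 120.0)
            w_right = min(on_right / span_px * 90.0 + 10.0, 120.0)
            row.glyphs.append(
                Glyph(
                    name=gene.name,
                    x1=jx - w_left,
                    x2=jx + w_right,
                    y=gene_y - 22,
                    strand=gene.strand,
                    spanning=True,
                )
            )
            labels.append(
                Label(
                    text=f"{gene.name}  {on_left} bp | {on_right} bp",
                    x=jx,
                    y=gene_y - 32,
                    anchor="middle",
                    cls="spanning-annot",
                    italic=True,
                )
            )
            continue
        if ctx.left_gene is not None:
            labels.append(
                Label(
                    text=f"{ctx.left_gene.name}: {ctx.left_distance} bp",
                    x=jx - 4,
                    y=dist_y,
                    anchor="end",
                    cls="distance-annot",
                    size=10.5,
                )
            )
        if ctx.right_gene is not None:
            labels.append(
                Label(
                    text=f"{ctx.right_gene.name}: {ctx.right_distance} bp",
                    x=jx + 4,
                    y=dist_y,
                    anchor="start",
                    cls="distance-annot",
                    size=10.5,
                )
            )

    _resolve_label_overlaps(labels)
    row.labels = labels
    return row


def layout(genome_views: Sequence[GenomeView]) -> FigureSpec:
    """Deterministic stacked layout, one row per genome in input order."""
    if not genome_views:
        raise ValueError("at least one genome view is required")
    rows = [
        _row_layout(view, MARGIN_T + i * ROW_H) for i, view in enumerate(genome_views)
    ]
    height = MARGIN_T + len(rows) * ROW_H + MARGIN_B
    return FigureSpec(rows=rows, width=CANVAS_W, height=height)


# ---------------------------------------------------------------------------
# SVG serialization
# ---------------------------------------------------------------------------

def _fmt(v: float) -> str:
    return f"{v:.1f}"


def to_svg(figure: FigureSpec) -> str:
    """Serialize a FigureSpec to standalone SVG text (deterministic)."""
    if not figure.rows:
        raise ValueError("figure has no rows")
    out: list[str] = []
    out.append('<?xml version="1.0" encoding="UTF-8"?>')
    out.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_fmt(figure.width)}" '
        f'height="{_fmt(figure.height)}" '
        f'viewBox="0 0 {_fmt(figure.width)} {_fmt(figure.height)}">'
    )
    out.append(
        "<defs>"
        '<marker id="arrow-right" viewBox="0 0 10 10" refX="8" refY="5" '
        'markerWidth="6" markerHeight="6" orient="0">'
        '<path d="M0,0 L10,5 L0,10 z"/></marker>'
        '<marker id="arrow-left" viewBox="0 0 10 10" refX="2" refY="5" '
        'markerWidth="6" markerHeight="6" orient="0">'
        '<path d="M10,0 L0,5 L10,10 z"/></marker>'
        "</defs>"
    )
    out.append(f'<rect x="0" y="0" width="{_fmt(figure.width)}" height="{_fmt(figure.height)}" fill="#ffffff"/>')
    for row in figure.rows:
        out.append(f'<g class="genome-row" data-accession="{escape(row.accession)}">')
        for blk in row.blocks:
            out.append(
                f'<rect class="region-block" data-region="{blk.label}" '
                f'x="{_fmt(blk.x)}" y="{_fmt(blk.y)}" width="{_fmt(blk.w)}" '
                f'height="{_fmt(blk.h)}" fill="{blk.fill}" stroke="#333333" '
                f'stroke-width="0.8"/>'
            )
        for jl in row.junction_lines:
            out.append(
                f'<line class="junction-line" data-junction="{jl.name}" '
                f'x1="{_fmt(jl.x)}" y1="{_fmt(jl.y1)}" x2="{_fmt(jl.x)}" '
                f'y2="{_fmt(jl.y2)}" stroke="#555555" stroke-width="1" '
                f'stroke-dasharray="4,3"/>'
            )
        for g in row.glyphs:
            color = GENE_COLOR[g.strand]
            if g.strand == "+":
                x1, x2, marker = g.x1, g.x2, "arrow-right"
            else:
                x1, x2, marker = g.x2, g.x1, "arrow-left"
            cls = "gene-glyph spanning" if g.spanning else "gene-glyph"
            out.append(
                f'<line class="{cls}" data-gene="{escape(g.name)}" '
                f'data-strand="{g.strand}" x1="{_fmt(x1)}" y1="{_fmt(g.y)}" '
                f'x2="{_fmt(x2)}" y2="{_fmt(g.y)}" stroke="{color}" '
                f'stroke-width="5" marker-end="url(#{marker})"/>'
            )
        for lab in row.labels:
            if lab.leader_from is not None:
                out.append(
                    f'<line class="leader" x1="{_fmt(lab.leader_from[0])}" '
                    f'y1="{_fmt(lab.leader_from[1] - 4)}" x2="{_fmt(lab.x)}" '
                    f'y2="{_fmt(lab.y - 4)}" stroke="#aaaaaa" stroke-width="0.6"/>'
                )
            style = "font-style:italic;" if lab.italic else ""
            out.append(
                f'<text class="{lab.cls}" x="{_fmt(lab.x)}" y="{_fmt(lab.y)}" '
                f'text-anchor="{lab.anchor}" font-family="{FONT}" '
                f'font-size="{_fmt(lab.size)}" style="{style}">'
                f"{escape(lab.text)}</text>"
            )
        out.append("</g>")
    out.append("</svg>")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# PDF / PNG conversion (best-effort rasterization of our own SVG subset)
# ---------------------------------------------------------------------------

def convert(svg_text: str, fmt: str, path: Union[str, Path]) -> Optional[Path]:
    """Convert SVG text to ``pdf`` or ``png`` at ``path``.

    The converter rasterizes the rect/line/text subset this package emits
    (via Pillow); it is best-effort and never asserted pixel-exact.  When no
    drawing backend is available a warning is logged and None returned —
    the SVG remains the canonical output.
    """
    if fmt not in ("pdf", "png"):
        raise ValueError(f"unsupported format {fmt!r}")
    path = Path(path)
    try:
        img = _rasterize(svg_text, scale=2.0)
    except Exception as exc:  # degraded mode: SVG already on disk
        logger.warning("conversion to %s failed (%s); SVG output only", fmt, exc)
        return None
    if fmt == "png":
        img.save(path, "PNG")
    else:
        img.convert("RGB").save(path, "PDF", resolution=144)
    return path


def _rasterize(svg_text: str, scale: float = 2.0):
    from lxml import etree
    from PIL import Image, ImageDraw, ImageFont

    root = etree.fromstring(svg_text.encode())
    ns = {"s": "http://www.w3.org/2000/svg"}
    w = int(float(root.get("width")) * scale)
    h = int(float(root.get("height")) * scale)
    img = Image.new("RGBA", (w, h), "#ffffff")
    draw = ImageDraw.Draw(img)
    font = ImageFont.load_default()

    def sc(v: str) -> float:
        return float(v) * scale

    for el in root.iter():
        tag = etree.QName(el).localname
        if tag == "rect":
            x, y = sc(el.get("x", "0")), sc(el.get("y", "0"))
            rw, rh = sc(el.get("width", "0")), sc(el.get("height", "0"))
            fill = el.get("fill", "none")
            outline = el.get("stroke")
            draw.rectangle(
                [x, y, x + rw, y + rh],
                fill=None if fill == "none" else fill,
                outline=outline,
            )
        elif tag == "line":
            x1, y1 = sc(el.get("x1")), sc(el.get("y1"))
            x2, y2 = sc(el.get("x2")), sc(el.get("y2"))
            stroke = el.get("stroke", "#000000")
            width = max(int(float(el.get("stroke-width", "1")) * scale), 1)
            draw.line([x1, y1, x2, y2], fill=stroke, width=width)
            marker = el.get("marker-end", "")
            if "arrow" in marker:
                head = 5 * scale
                direction = 1 if x2 >= x1 else -1
                if "arrow-left" in marker:
                    direction = -1
                draw.polygon(
                    [
                        (x2, y2 - head / 2),
                        (x2 + direction * head, y2),
                        (x2, y2 + head / 2),
                    ],
                    fill=stroke,
                )
        elif tag == "text":
            x, y = sc(el.get("x")), sc(el.get("y"))
            anchor = el.get("text-anchor", "start")
            txt = el.text or ""
            tw = draw.textlength(txt, font=font)
            if anchor == "middle":
                x -= tw / 2
            elif anchor == "end":
                x -= tw
            draw.text((x, y - 10 * scale), txt, fill="#000000", font=font)
    return img


# ---------------------------------------------------------------------------
# Convenience driver
# ---------------------------------------------------------------------------

def render_figure(
    genome_views: Sequence[GenomeView],
    outdir: Union[str, Path],
    prefix: str = "cpgenomes",
    formats: Sequence[str] = ("svg",),
) -> dict[str, Optional[Path]]:
    """Lay out, serialize and write ``<prefix>.junctions.<ext>`` files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fig = layout(genome_views)
    svg_text = to_svg(fig)
    written: dict[str, Optional[Path]] = {}
    svg_path = outdir / f"{prefix}.junctions.svg"
    svg_path.write_text(svg_text)
    written["svg"] = svg_path
    for fmt in formats:
        if fmt == "svg":
            continue
        written[fmt] = convert(svg_text, fmt, outdir / f"{prefix}.junctions.{fmt}")
    return written
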