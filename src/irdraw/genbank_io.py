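"""GenBank and configuration-file I/O for plastome junction analysis.

Reads annotated chloroplast genome records from GenBank flat files into a
small internal data model (:class:`AnnotatedGenome`, :class:`GeneFeature`),
parses the two-column run configuration format, and writes per-genome region
tables.

Coordinate conventions
----------------------
All coordinates are 1-based inclusive, as in GenBank feature tables.  A
region or gene segment whose start is greater than its end wraps through the
origin of the circular sequence (it covers ``start..length`` followed by
``1..end``).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AnnotatedGenome",
    "GeneFeature",
    "ConfigEntry",
    "Region",
    "Tetrad",
    "GenBankParseError",
    "ConfigParseError",
    "parse_genbank",
    "read_genomes",
    "write_genbank",
    "genome_to_genbank_text",
    "parse_config",
    "parse_tetrad_string",
    "format_tetrad",
    "write_region_table",
]

# IUPAC nucleotide alphabet accepted in input sequences.
_ALPHABET = frozenset("ACGTNRYSWKMBDHV")

_GENE_KINDS = {"gene": "gene", "tRNA": "tRNA", "rRNA": "rRNA"}

REGION_LABELS = ("LSC", "IRb", "SSC", "IRa")


class GenBankParseError(ValueError):
    """Raised when a GenBank record cannot be read into the data model."""


class ConfigParseError(ValueError):
    """Raised when the tab-separated configuration file is malformed."""


# ---------------------------------------------------------------------------
# Circular-coordinate helpers (shared by the whole package)
# ---------------------------------------------------------------------------

def circular_length(start: int, end: int, genome_length: int) -> int:
    """Length in bp of the 1-based inclusive interval ``start..end`` on a
    circle of ``genome_length`` bp.  ``start > end`` wraps the origin."""
    return (end - start) % genome_length + 1


def circular_contains(start: int, end: int, genome_length: int, pos: int) -> bool:
    """True when base ``pos`` lies inside the wrap-capable interval."""
    return (pos - start) % genome_length <= (end - start) % genome_length


def next_base(pos: int, genome_length: int) -> int:
    """Successor of ``pos`` on the circle (wraps ``genome_length`` -> 1)."""
    return pos % genome_length + 1


def prev_base(pos: int, genome_length: int) -> int:
    """Predecessor of ``pos`` on the circle (wraps 1 -> ``genome_length``)."""
    return (pos - 2) % genome_length + 1


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene.

    ``segments`` are 1-based inclusive intervals in the order the feature
    reads along the forward strand of the deposited sequence; a segment with
    start > end wraps through the origin.  Multi-segment features come from
    ``join(...)`` locations.
    """

    name: str
    strand: str  # '+' or '-'
    segments: tuple[tuple[int, int], ...]
    kind: str = "gene"

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError(f"gene {self.name!r} has no segments")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.name!r} has invalid strand {self.strand!r}")

    def total_length(self, genome_length: int) -> int:
        return sum(circular_length(s, e, genome_length) for s, e in self.segments)

    @property
    def start(self) -> int:
        """Start of the first segment (lowest wrap-order coordinate)."""
        return self.segments[0][0]

    @property
    def end(self) -> int:
        return self.segments[-1][1]


@dataclass(frozen=True)
class Region:
    """One of the four tetrad regions in 1-based inclusive coordinates."""

    label: str  # LSC | IRb | SSC | IRa
    start: int
    end: int

    def length(self, genome_length: int) -> int:
        return circular_length(self.start, self.end, genome_length)

    def contains(self, pos: int, genome_length: int) -> bool:
        return circular_contains(self.start, self.end, genome_length, pos)

    @property
    def wraps(self) -> bool:
        return self.start > self.end


@dataclass(frozen=True)
class Tetrad:
    """The four-region LSC/IRb/SSC/IRa partition of a plastome.

    ``genome_length`` may be ``None`` for a tetrad parsed from a
    configuration string; call :meth:`with_genome_length` to bind and
    validate it against a concrete sequence.
    """

    lsc: Region
    irb: Region
    ssc: Region
    ira: Region
    genome_length: Optional[int] = None

    def regions(self) -> tuple[Region, Region, Region, Region]:
        return (self.lsc, self.irb, self.ssc, self.ira)

    def region(self, label: str) -> Region:
        return {r.label: r for r in self.regions()}[label]

    def with_genome_length(self, genome_length: int) -> "Tetrad":
        t = replace(self, genome_length=genome_length)
        t.validate()
        return t

    def validate(self) -> None:
        """Check the tetrad invariants; raises ValueError on violation."""
        L = self.genome_length
        if L is None:
            raise ValueError("tetrad has no genome length bound")
        lengths = {r.label: r.length(L) for r in self.regions()}
        if sum(lengths.values()) != L:
            raise ValueError(
                f"regions do not partition the circle: {lengths} vs length {L}"
            )
        if lengths["IRb"] != lengths["IRa"]:
            raise ValueError(
                f"IR arms differ in length: IRb={lengths['IRb']} IRa={lengths['IRa']}"
            )
        if lengths["LSC"] < lengths["SSC"]:
            raise ValueError("LSC shorter than SSC")
        # contiguity in LSC-IRb-SSC-IRa order around the circle
        order = [self.lsc, self.irb, self.ssc, self.ira]
        for a, b in zip(order, order[1:] + order[:1]):
            if next_base(a.end, L) != b.start:
                raise ValueError(
                    f"{a.label} (ends {a.end}) not followed by {b.label} "
                    f"(starts {b.start})"
                )


@dataclass(frozen=True)
class AnnotatedGenome:
    """One GenBank record: sequence, topology and gene annotation."""

    accession: str
    organism: str
    sequence: str
    topology: str  # 'circular' | 'linear'
    genes: tuple[GeneFeature, ...]

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_annotated(self) -> bool:
        return len(self.genes) > 0


@dataclass(frozen=True)
class ConfigEntry:
    """One line of the run configuration: a .gb path plus an optional
    user-supplied tetrad that overrides detection."""

    gb_path: Path
    custom_tetrad: Optional[Tetrad] = None


# ---------------------------------------------------------------------------
# GenBank reading
# ---------------------------------------------------------------------------

def _segments_from_location(location) -> tuple[tuple[int, int], ...]:
    parts = list(location.parts)
    # Biopython stores the parts of a minus-strand compound location in
    # reverse of their order in the feature table; restore file order so a
    # wrap-spanning complement(join(150..200,1..30)) keeps its wrap order.
    if len(parts) > 1 and all((p.strand or 1) < 0 for p in parts):
        parts = parts[::-1]
    return tuple((int(p.start) + 1, int(p.end)) for p in parts)


def _genome_from_record(record: SeqRecord) -> AnnotatedGenome:
    seq = str(record.seq).upper()
    if not seq:
        raise GenBankParseError(f"record {record.id}: missing sequence block")
    bad = set(seq) - _ALPHABET
    if bad:
        raise GenBankParseError(
            f"record {record.id}: non-IUPAC characters in sequence: {sorted(bad)}"
        )
    topology = record.annotations.get("topology", "linear")
    if topology not in ("circular", "linear"):
        topology = "linear"
    organism = record.annotations.get("organism", "") or ""
    accession = record.id if record.id not in ("", "<unknown id>") else record.name

    genes: list[GeneFeature] = []
    seen: dict[tuple, int] = {}
    for feat in record.features:
        if feat.type == "source":
            if not organism:
                organism = feat.qualifiers.get("organism", [""])[0]
            continue
        names = feat.qualifiers.get("gene")
        if not names:
            continue  # pseudogenes/ORFs without /gene are not plotted
        if feat.location is None:
            continue
        segments = _segments_from_location(feat.location)
        strand = "-" if (feat.location.strand or 1) < 0 else "+"
        kind = _GENE_KINDS.get(feat.type, "other")
        key = (names[0], strand, segments)
        if key in seen:
            # a gene + CDS/tRNA/rRNA pair plots once; keep the most
            # informative kind
            idx = seen[key]
            if genes[idx].kind == "gene" and kind in ("tRNA", "rRNA"):
                genes[idx] = replace(genes[idx], kind=kind)
            continue
        seen[key] = len(genes)
        genes.append(GeneFeature(name=names[0], strand=strand, segments=segments, kind=kind))

    n = len(seq)
    for g in genes:
        for s, e in g.segments:
            if not (1 <= s <= n and 1 <= e <= n):
                raise GenBankParseError(
                    f"record {accession}: gene {g.name} segment ({s},{e}) "
                    f"outside 1..{n}"
                )
    return AnnotatedGenome(
        accession=accession,
        organism=organism,
        sequence=seq,
        topology=topology,
        genes=tuple(genes),
    )


def read_genomes(path: Union[str, Path]) -> list[AnnotatedGenome]:
    """Read every record of a (possibly multi-record) GenBank flat file."""
    path = Path(path)
    with open(path) as fh:
        records = list(SeqIO.parse(fh, "genbank"))
    if not records:
        raise GenBankParseError(f"{path}: no GenBank records found")
    return [_genome_from_record(r) for r in records]


def parse_genbank(path: Union[str, Path]) -> AnnotatedGenome:
    """Read the first record of a GenBank flat file."""
    return read_genomes(path)[0]


# ---------------------------------------------------------------------------
# GenBank writing (round-trip support and fixture output)
# ---------------------------------------------------------------------------

def _location_from_segments(
    segments: Sequence[tuple[int, int]], strand: str, genome_length: int
):
    strand_i = -1 if strand == "-" else 1
    parts: list[SimpleLocation] = []
    for s, e in segments:
        if s <= e:
            parts.append(SimpleLocation(s - 1, e, strand_i))
        else:  # wraps the origin: split into two parts in wrap order
            parts.append(SimpleLocation(s - 1, genome_length, strand_i))
            parts.append(SimpleLocation(0, e, strand_i))
    if len(parts) == 1:
        return parts[0]
    # mirror of _segments_from_location: Biopython expects minus-strand
    # compound parts in reverse file order
    if strand_i < 0:
        parts = parts[::-1]
    return CompoundLocation(parts)


def _record_from_genome(genome: AnnotatedGenome) -> SeqRecord:
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.accession,
        name=genome.accession.split(".")[0][:16] or "PLASTOME",
        description=f"{genome.organism} chloroplast, complete genome".strip(),
    )
    record.annotations.update(
        molecule_type="DNA",
        topology=genome.topology,
        organism=genome.organism,
        source=genome.organism,
    )
    record.features.append(
        SeqFeature(
            SimpleLocation(0, genome.length, 1),
            type="source",
            qualifiers={"organism": [genome.organism]},
        )
    )
    for gene in genome.genes:
        loc = _location_from_segments(gene.segments, gene.strand, genome.length)
        ftype = gene.kind if gene.kind in ("gene", "tRNA", "rRNA") else "gene"
        record.features.append(
            SeqFeature(loc, type=ftype, qualifiers={"gene": [gene.name]})
        )
    return record


def genome_to_genbank_text(genome: AnnotatedGenome) -> str:
    """Serialize a genome to GenBank flat-file text."""
    buf = io.StringIO()
    SeqIO.write(_record_from_genome(genome), buf, "genbank")
    return buf.getvalue()


def write_genbank(genome: AnnotatedGenome, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.write_text(genome_to_genbank_text(genome))
    return path


# ---------------------------------------------------------------------------
# Tetrad strings and the configuration file
# ---------------------------------------------------------------------------

_REGION_RE = re.compile(
    r"^\s*(LSC|IRB|SSC|IRA)\s*:\s*(\d+)\s*[-–—]\s*(\d+)\s*$",
    re.IGNORECASE,
)


def parse_tetrad_string(text: str) -> Tetrad:
    """Parse ``LSC:s-e;IRb:s-e;SSC:s-e;IRa:s-e`` into a Tetrad.

    Separators ';' or ',' and ASCII/en/em dashes are accepted; a start
    greater than its end denotes an origin-wrapping region.  The returned
    tetrad carries no genome length; bind one with
    :meth:`Tetrad.with_genome_length` before validating the partition.
    """
    fields = [f for f in re.split(r"[;,]", text) if f.strip()]
    found: dict[str, Region] = {}
    for fld in fields:
        m = _REGION_RE.match(fld)
        if not m:
            raise ConfigParseError(f"unparseable region field {fld.strip()!r}")
        label = {"LSC": "LSC", "IRB": "IRb", "SSC": "SSC", "IRA": "IRa"}[
            m.group(1).upper()
        ]
        if label in found:
            raise ConfigParseError(f"region {label} given twice")
        found[label] = Region(label, int(m.group(2)), int(m.group(3)))
    missing = [lab for lab in REGION_LABELS if lab not in found]
    if missing:
        raise ConfigParseError(f"missing region(s): {', '.join(missing)}")
    for reg in found.values():
        if reg.start < 1 or reg.end < 1:
            raise ConfigParseError(f"region {reg.label}: coordinates must be >= 1")
    return Tetrad(found["LSC"], found["IRb"], found["SSC"], found["IRa"])


def format_tetrad(t: Tetrad) -> str:
    return ";".join(f"{r.label}:{r.start}-{r.end}" for r in t.regions())


def parse_config(path: Union[str, Path]) -> list[ConfigEntry]:
    """Read the two-column tab-separated run configuration.

    Column 1 is a .gb file path; the optional column 2 is a tetrad string
    overriding junction detection for that genome.  Blank lines and lines
    starting with '#' are ignored.  Relative paths are resolved against the
    configuration file's directory.
    """
    path = Path(path)
    entries: list[ConfigEntry] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.split("\t")
        gb = Path(cols[0].strip())
        if not gb.is_absolute():
            gb = path.parent / gb
        tetrad = None
        if len(cols) > 1 and cols[1].strip():
            try:
                tetrad = parse_tetrad_string(cols[1])
            except ConfigParseError as exc:
                raise ConfigParseError(f"{path}:{lineno}: {exc}") from exc
        entries.append(ConfigEntry(gb_path=gb, custom_tetrad=tetrad))
    return entries


# ---------------------------------------------------------------------------
# Region table output
# ---------------------------------------------------------------------------

def write_region_table(
    rows: Iterable[tuple[AnnotatedGenome, Tetrad]], path: Union[str, Path]
) -> Path:
    """Write a TSV of region coordinates, one line per region per genome."""
    path = Path(path)
    lines = ["accession\torganism\tregion\tstart\tend\tlength"]
    for genome, tetrad in rows:
        L = tetrad.genome_length or genome.length
        for reg in tetrad.regions():
            lines.append(
                f"{genome.accession}\t{genome.organism}\t{reg.label}\t"
                f"{reg.start}\t{reg.end}\t{reg.length(L)}"
            )
    path.write_text("\n".join(lines) + "\n")
    return path
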