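"""Published tetrad coordinates of representative RefSeq plastomes.

Eighteen complete chloroplast genomes, two per starting-point group, with
their region coordinates in deposited (as-submitted) 1-based coordinates; a
start greater than the end marks a region wrapping the origin.  Together
they span every way a deposited record can be rotated — LSC-first, mid-LSC,
IR-first, mid-IR, SSC-first, mid-SSC — plus genomes with a nearly gene-free
SSC or a sub-kilobase IR, and serve as offline oracles for the coordinate
arithmetic (wrap handling, start-group classification, junction positions).

The genome length is not printed alongside the coordinates.  Where the
tetrad ends at the genome end, or an IR arm wraps the origin, the length
is recovered here (for a wrapping arm, from the equality of the two arm
lengths); where a single-copy region wraps (mid-LSC and mid-SSC starts)
the length is genuinely underdetermined and is recorded as ``None`` — the
partition and classification invariants then hold for *every* consistent
length, and :func:`reference_tetrad` binds the minimal one.

Re-detecting these coordinates from sequence requires the RefSeq records
themselves; ``scripts/refseq_check.py`` fetches them and replays detection
when network access is available.
"""

from __future__ import annotations

from typing import Optional

from .genbank_io import Tetrad, parse_tetrad_string

__all__ = ["REFERENCE_PLASTOMES", "reference_tetrad", "minimal_consistent_length"]

# accession -> (organism, start-group code implied by the coordinates,
#               region string, genome length or None when underdetermined)
#
# NC_050170.1 (Cyperus rotundus) is deposited with its SSC at base 1, so
# the coordinates imply code 'e' (start with SSC) even though the record
# sits among the mid-SSC genomes in the published grouping.
# NC_053746.1 / NC_061648.1 are the gene-sparse ('i'-flag) examples; their
# positional codes from the coordinates are 'a' and 'b'.
REFERENCE_PLASTOMES: dict[str, tuple[str, str, str, Optional[int]]] = {
    "NC_036102.1": ("Sophora alopecuroides", "a",
                    "LSC:1-84221;IRb:84222-110095;SSC:110096-128234;IRa:128235-154108", 154108),
    "NC_056151.1": ("Sophora moorcroftiana", "a",
                    "LSC:1-83342;IRb:83343-107133;SSC:107134-125139;IRa:125140-148930", 148930),
    "NC_062457.1": ("Zingiber teres", "b",
                    "LSC:163399-88112;IRb:88113-117864;SSC:117865-133646;IRa:133647-163398", None),
    "NC_062475.1": ("Solanum velardei", "b",
                    "LSC:155437-86008;IRb:86009-111535;SSC:111536-129909;IRa:129910-155436", None),
    "NC_038203.1": ("Machilus pauhoi", "c",
                    "LSC:58951-152621;IRb:1-20074;SSC:20075-38876;IRa:38877-58950", 152621),
    "NC_038204.1": ("Machilus thunbergii", "c",
                    "LSC:58901-152551;IRb:1-20050;SSC:20051-38850;IRa:38851-58900", 152551),
    "NC_053720.1": ("Colobanthus nivicola", "d",
                    "LSC:58978-142328;IRb:142329-16445;SSC:16446-33651;IRa:33652-58977", 151209),
    "NC_053721.1": ("Colobanthus lycopodioides", "d",
                    "LSC:58937-142581;IRb:142582-16439;SSC:16440-33616;IRa:33617-58936", 151462),
    "NC_057956.1": ("Camellia achrysantha", "e",
                    "LSC:44327-130575;IRb:130576-156658;SSC:1-18243;IRa:18244-44326", 156658),
    "NC_057957.1": ("Camellia chrysanthoides", "e",
                    "LSC:44332-130895;IRb:130896-156959;SSC:1-18267;IRa:18268-44331", 156959),
    "NC_048463.1": ("Wolffia globosa", "f",
                    "LSC:45381-137551;IRb:137552-169361;SSC:169362-13570;IRa:13571-45380", None),
    "NC_050170.1": ("Cyperus rotundus", "e",
                    "LSC:47738-148698;IRb:148699-186119;SSC:1-10315;IRa:10316-47737", 186119),
    "NC_050999.1": ("Heterotis rotundifolia", "g",
                    "LSC:26740-112476;IRb:112477-139215;SSC:139216-156336;IRa:1-26739", 156336),
    "NC_056142.1": ("Verbena officinalis", "g",
                    "LSC:25809-110326;IRb:110327-136134;SSC:136135-153491;IRa:1-25808", 153491),
    "NC_062509.1": ("Solanum caripense", "h",
                    "LSC:2-85726;IRb:85727-109824;SSC:109825-130908;IRa:130909-1", 155005),
    "NC_060516.1": ("Cymbidium cyperifolium", "h",
                    "LSC:688-85961;IRb:85962-111550;SSC:111551-127763;IRa:127764-687", 152665),
    "NC_053746.1": ("Rhododendron platypodum", "a",
                    "LSC:1-109134;IRb:109135-153784;SSC:153785-156397;IRa:156398-201047", 201047),
    "NC_061648.1": ("Larix kongboensis", "b",
                    "LSC:91317-34931;IRb:34932-35367;SSC:35368-90880;IRa:90881-91316", None),
}


# Rows whose printed coordinates are internally inconsistent and cannot be
# bound to any genome length.  NC_050170.1's two IR arms differ by one base
# (37,421 vs 37,422 bp), so the strict equal-arm invariant rejects it; it
# remains available for parsing and wrap-notation checks.
KNOWN_INCONSISTENT: frozenset[str] = frozenset({"NC_050170.1"})


def minimal_consistent_length(accession: str) -> int:
    """The smallest genome length compatible with the printed coordinates:
    every start and end must be a valid base position and, when the LSC
    wraps the origin, its resolved length must still reach the SSC's."""
    coords = REFERENCE_PLASTOMES[accession][2]
    t = parse_tetrad_string(coords)
    length = max(max(r.start, r.end) for r in t.regions())
    if t.lsc.wraps and not t.ssc.wraps:
        ssc_len = t.ssc.end - t.ssc.start + 1
        # |LSC| = L - (lsc.start - lsc.end - 1) must be >= |SSC|
        length = max(length, ssc_len + t.lsc.start - t.lsc.end - 1)
    return length


def reference_tetrad(accession: str) -> Tetrad:
    """The published tetrad of one reference record, with a genome length
    bound and the partition invariants validated."""
    organism, group, coords, length = REFERENCE_PLASTOMES[accession]
    if length is None:
        length = minimal_consistent_length(accession)
    return parse_tetrad_string(coords).with_genome_length(length)
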