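"""Junction positions, flanking-gene contexts, and region plotting plans."""

import pytest

from irdraw.genbank_io import GeneFeature, Region, parse_tetrad_string
from irdraw.ir_core import detect_tetrad, standardize_start
from irdraw.junctions import (
    compute_junctions,
    gene_context,
    plan_region_genes,
)
from irdraw.reference import KNOWN_INCONSISTENT, REFERENCE_PLASTOMES, reference_tetrad


def _gene(name, s, e, strand="+"):
    return GeneFeature(name=name, strand=strand, segments=((s, e),))


class TestComputeJunctions:
    def test_reference_lsc_first_row(self):
        t = parse_tetrad_string(
            "LSC:1-84221;IRb:84222-110095;SSC:110096-128234;IRa:128235-154108"
        ).with_genome_length(154108)
        names_pos = [(j.name, j.position) for j in compute_junctions(t)]
        assert names_pos == [
            ("JLB", 84221), ("JSB", 110095), ("JSA", 128234), ("JLA", 154108)
        ]

    def test_toy_tetrad(self):
        t = parse_tetrad_string("LSC:1-4;IRb:5-6;SSC:7-8;IRa:9-10").with_genome_length(10)
        assert [j.position for j in compute_junctions(t)] == [4, 6, 8, 10]

    def test_positions_strictly_increasing_for_all_reference_rows(self):
        for acc in REFERENCE_PLASTOMES:
            if acc in KNOWN_INCONSISTENT:
                continue
            t = reference_tetrad(acc)
            std = _standardized(t)
            pos = [j.position for j in compute_junctions(std)]
            assert pos == sorted(pos) and len(set(pos)) == 4, acc

    def test_requires_standardized_tetrad(self):
        t = parse_tetrad_string(
            "LSC:2-85726;IRb:85727-109824;SSC:109825-130908;IRa:130909-1"
        ).with_genome_length(155005)
        with pytest.raises(ValueError, match="standardized"):
            compute_junctions(t)


def _standardized(t):
    """Re-express a deposited tetrad with the LSC at base 1 (lengths only)."""
    L = t.genome_length
    lengths = [r.length(L) for r in t.regions()]
    starts = [1]
    for ln in lengths[:-1]:
        starts.append(starts[-1] + ln)
    regs = [
        Region(lab, s, s + ln - 1)
        for lab, s, ln in zip(("LSC", "IRb", "SSC", "IRa"), starts, lengths)
    ]
    return type(t)(*regs, genome_length=L)


class TestGeneContext:
    def _jlb(self, pos=84221):
        t = parse_tetrad_string(
            "LSC:1-84221;IRb:84222-110095;SSC:110096-128234;IRa:128235-154108"
        ).with_genome_length(154108)
        return compute_junctions(t), 154108

    def test_spanning_gene_side_lengths(self):
        (jlb, _, _, _), L = self._jlb()
        ctx = gene_context([_gene("rps19", 84100, 84300)], jlb, L)
        assert ctx.spanning is not None
        gene, on_left, on_right = ctx.spanning
        assert (on_left, on_right) == (122, 79)
        assert ctx.left_distance == 0 and ctx.right_distance == 0
        assert ctx.left_gene is gene and ctx.right_gene is gene

    def test_abutting_gene_distance_zero(self):
        (jlb, _, _, _), L = self._jlb()
        ctx = gene_context([_gene("rpl22", 84000, 84221)], jlb, L)
        assert ctx.left_gene.name == "rpl22" and ctx.left_distance == 0
        assert ctx.spanning is None

    def test_empty_gene_list(self):
        (jlb, _, _, _), L = self._jlb()
        ctx = gene_context([], jlb, L)
        assert ctx.left_gene is None and ctx.right_gene is None

    def test_jla_right_flank_wraps_to_base_one(self):
        (_, _, _, jla), L = self._jlb()
        ctx = gene_context([_gene("trnH", 10, 80), _gene("ndhF", 120000, 120500)], jla, L)
        assert ctx.right_gene.name == "trnH" and ctx.right_distance == 9

    def test_origin_wrapping_gene_spans_jla(self):
        (_, _, _, jla), L = self._jlb()
        wrap = GeneFeature("ycf2", "+", ((L - 9, L), (1, 41)))
        ctx = gene_context([wrap], jla, L)
        assert ctx.spanning is not None
        assert ctx.spanning[1:] == (10, 41)

    def test_flank_flips_when_gene_crosses_junction(self):
        (jlb, _, _, _), L = self._jlb()
        before = gene_context([_gene("x", 84150, 84211)], jlb, L)
        after = gene_context([_gene("x", 84232, 84293)], jlb, L)
        assert before.left_gene and before.left_distance == 10
        assert after.right_gene and after.right_distance == 10
        assert before.right_gene is None and after.left_gene is None


class TestRegionPlans:
    REGION = Region("LSC", 1, 100)

    def test_zero_genes_empty_plan(self):
        plan = plan_region_genes([], self.REGION, 1000)
        assert plan.plotted_genes == () and not plan.endpoints_shown

    def test_single_gene_mid_region_with_endpoints(self):
        plan = plan_region_genes([_gene("a", 40, 60)], self.REGION, 1000)
        assert [p for _, p in plan.plotted_genes] == ["mid-region"]
        assert plan.endpoints_shown

    def test_three_genes_keep_first_and_last(self):
        genes = [_gene("g5", 5, 20), _gene("g40", 40, 55), _gene("g90", 90, 99)]
        plan = plan_region_genes(genes, self.REGION, 1000)
        assert [(g.name, p) for g, p in plan.plotted_genes] == [
            ("g5", "at-location"), ("g90", "at-location")
        ]

    def test_membership_by_midpoint_for_spanning_gene(self):
        # gene mostly downstream of the region end belongs to the next region
        spanning = _gene("s", 95, 140)
        plan = plan_region_genes([spanning], self.REGION, 1000)
        assert plan.plotted_genes == ()


class TestDistancesOnFixtures:
    def test_planted_junction_gene_geometry(self, small_fixture):
        """The planted catalog fixes every junction's context exactly."""
        fx = small_fixture
        res = detect_tetrad(fx.genome)
        std_g, std_t = standardize_start(fx.genome, res.tetrad)
        sites = compute_junctions(std_t)
        L = std_t.genome_length
        ctxs = {s.name: gene_context(std_g.genes, s, L) for s in sites}
        assert ctxs["JLB"].spanning[0].name == "rps19"
        assert ctxs["JLB"].spanning[1:] == (60, 60)
        assert ctxs["JSB"].spanning[0].name == "ndhF"
        assert ctxs["JSB"].spanning[1:] == (19, 61)
        assert ctxs["JSA"].spanning[0].name == "ycf1"
        assert ctxs["JSA"].spanning[1:] == (44, 46)
        assert ctxs["JLA"].spanning[0].name == "ycf2"
        assert ctxs["JLA"].spanning[1:] == (9, 41)
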