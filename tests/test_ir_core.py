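"""k-mer scan, rotation, IR search, tetrad classification, filtering."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irdraw.genbank_io import AnnotatedGenome
from irdraw.ir_core import (
    DetectionError,
    DetectionParams,
    IRPair,
    canonical_kmer_counts,
    classify_start_group,
    classify_tetrad,
    detect_tetrad,
    find_longest_inverted_repeat,
    find_rotation_point,
    map_to_original,
    passes_filter,
    revcomp,
    rotate,
    standardize_start,
)
from irdraw.reference import KNOWN_INCONSISTENT, REFERENCE_PLASTOMES, reference_tetrad
from irdraw.synthetic import (
    FixtureSpec,
    generate,
    longest_inverted_pair_bruteforce,
)


def _bare(length, topology="circular", genes=()):
    return AnnotatedGenome("X.1", "Testus", "A" * length, topology, tuple(genes))


class TestCanonicalKmers:
    def test_homopolymer(self):
        assert canonical_kmer_counts("AAAAAA", 3, topology="linear") == {"AAA": 4}

    def test_palindromic_kmer_counts_once(self):
        assert canonical_kmer_counts("ACGT", 4, topology="linear") == {"ACGT": 1}

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            canonical_kmer_counts("ACG", 4)

    def test_circular_windows_wrap(self):
        # every base starts a window on a circle
        counts = canonical_kmer_counts("ACGTA", 3, topology="circular")
        assert sum(counts.values()) == 5

    def test_planted_arm_kmers_count_two(self):
        rng = random.Random(11)
        x = "".join(rng.choice("ACGT") for _ in range(200))
        a = "".join(rng.choice("ACGT") for _ in range(120))
        y = "".join(rng.choice("ACGT") for _ in range(160))
        seq = x + a + y + revcomp(a)
        k = 25
        counts = canonical_kmer_counts(seq, k, topology="linear")
        # brute-force oracle: count canonical k-mers directly
        brute = {}
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            key = min(w, revcomp(w))
            brute[key] = brute.get(key, 0) + 1
        assert counts == brute
        for i in range(200, 200 + 120 - k + 1):
            w = seq[i : i + k]
            assert counts[min(w, revcomp(w))] == 2


class TestRotation:
    @pytest.mark.parametrize("offset,expect", [(0, "ABCDEF"), (2, "CDEFAB")])
    def test_rotate_examples(self, offset, expect):
        assert rotate("ABCDEF", offset) == expect

    @settings(max_examples=30, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=80), st.integers(0, 79))
    def test_rotate_inverse(self, s, r):
        r %= len(s)
        assert rotate(rotate(s, r), (len(s) - r) % len(s)) == s

    def test_rotation_point_lands_in_single_copy_region(self):
        fx = generate(FixtureSpec(start_group="d", seed=2))
        params = DetectionParams()
        offset = find_rotation_point(fx.genome, params)
        # the fixture knows the planted map: the new start must be inside
        # LSC or SSC (single-copy territory)
        L = fx.genome.length
        pos = offset + 1
        assert fx.tetrad.lsc.contains(pos, L) or fx.tetrad.ssc.contains(pos, L)

    def test_all_repeat_genome_has_no_single_copy_run(self):
        g = _bare(64)  # poly-A: every canonical 8-mer occurs many times
        with pytest.raises(DetectionError, match="single-copy"):
            find_rotation_point(g, DetectionParams(k=8))


class TestMapToOriginal:
    def test_zero_offset_is_identity(self):
        assert map_to_original((3, 9), 0, 20) == (3, 9)

    def test_shift(self):
        assert map_to_original((1, 10), 5, 20) == (6, 15)

    def test_wrap(self):
        assert map_to_original((18, 20), 5, 20) == (3, 5)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(1, 500), st.integers(1, 500), st.integers(0, 499))
    def test_matches_positionwise_enumeration(self, s, e, off):
        L = 500
        got = map_to_original((s, e), off, L)
        assert got == (((s - 1 + off) % L) + 1, ((e - 1 + off) % L) + 1)


class TestInvertedRepeatFinder:
    def test_tiny_palindromic_sequence_matches_bruteforce(self):
        seq = "AAACCCGGGTTT"
        got = find_longest_inverted_repeat(seq, DetectionParams(chain_gap=0))
        exp = longest_inverted_pair_bruteforce(seq)
        assert (got.arm_b, got.arm_a) == exp
        b = seq[got.arm_b[0] - 1 : got.arm_b[1]]
        a = seq[got.arm_a[0] - 1 : got.arm_a[1]]
        assert a == revcomp(b)

    def test_planted_arms_found_exactly(self):
        rng = random.Random(5)
        x = "".join(rng.choice("ACGT") for _ in range(180))
        arm = "".join(rng.choice("ACGT") for _ in range(120))
        y = "".join(rng.choice("ACGT") for _ in range(140))
        seq = x + arm + y + revcomp(arm)
        got = find_longest_inverted_repeat(seq, DetectionParams(chain_gap=0))
        # the found pair must contain the planted arms (chance complement
        # matches at the boundaries may lengthen it by a base or two) and
        # agree with the exhaustive oracle
        assert got.arm_b[0] <= 181 and got.arm_b[1] >= 300
        assert got.arm_a[0] <= 441 and got.arm_a[1] >= 560
        assert got.mismatches == 0
        assert (got.arm_b, got.arm_a) == longest_inverted_pair_bruteforce(seq)

    def test_chaining_bridges_point_mutations(self):
        rng = random.Random(9)
        x = "".join(rng.choice("ACGT") for _ in range(150))
        arm = "".join(rng.choice("ACGT") for _ in range(150))
        y = "".join(rng.choice("ACGT") for _ in range(100))
        mutated = list(revcomp(arm))
        mutated[60] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[60]]
        seq = x + arm + y + "".join(mutated)
        exact = find_longest_inverted_repeat(seq, DetectionParams(chain_gap=0))
        chained = find_longest_inverted_repeat(seq, DetectionParams(chain_gap=5))
        assert exact.length < 150
        assert chained.length >= 150 and chained.mismatches == 1
        assert chained.arm_b[0] <= 151 and chained.arm_b[1] >= 300

    def test_random_sequence_without_long_repeat_is_filtered(self):
        rng = random.Random(3)
        seq = "".join(rng.choice("ACGT") for _ in range(2000))
        got = find_longest_inverted_repeat(seq, DetectionParams(chain_gap=0))
        g = _bare(2000, genes=())
        ok, reason = passes_filter(g, got, DetectionParams())
        assert not ok and reason == "IR < 100 bp"

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_bruteforce_on_planted_randoms(self, seed):
        rng = random.Random(100 + seed)
        n = rng.randint(600, 2500)
        arm_len = rng.randint(40, 150)
        seq = list(rng.choice("ACGT") for _ in range(n))
        p0 = rng.randint(0, n // 3 - arm_len)
        p1 = rng.randint(n // 2, n - arm_len)
        arm = "".join(seq[p0 : p0 + arm_len])
        seq[p1 : p1 + arm_len] = revcomp(arm)
        seq = "".join(seq)
        got = find_longest_inverted_repeat(seq, DetectionParams(chain_gap=0))
        exp = longest_inverted_pair_bruteforce(seq)
        assert (got.arm_b, got.arm_a) == exp


class TestClassifyTetrad:
    def test_reference_group_h_shape(self):
        # wrap-closing arms of the mid-IRa Solanum record
        ir = IRPair(arm_b=(85727, 109824), arm_a=(130909, 1), length=24098)
        t = classify_tetrad(ir, 155005)
        assert (t.lsc.start, t.lsc.end) == (2, 85726)
        assert (t.ssc.start, t.ssc.end) == (109825, 130908)
        assert t.irb.label == "IRb" and (t.irb.start, t.irb.end) == (85727, 109824)

    def test_symmetric_tie_prefers_gap_with_base_one(self):
        ir = IRPair(arm_b=(101, 150), arm_a=(251, 300), length=50)
        t = classify_tetrad(ir, 400)
        assert (t.lsc.start, t.lsc.end) == (301, 100)
        assert (t.irb.start, t.irb.end) == (101, 150)

    def test_abutting_arms_rejected(self):
        ir = IRPair(arm_b=(101, 150), arm_a=(151, 200), length=50)
        with pytest.raises(DetectionError, match="degenerate"):
            classify_tetrad(ir, 400)


class TestFilter:
    @pytest.mark.parametrize("arm_len,accepted", [(50, False), (99, False), (100, True), (150, True)])
    def test_threshold_is_strict_less_than(self, arm_len, accepted):
        fx = generate(FixtureSpec(ir_len=max(arm_len, 100), seed=6))
        ir = IRPair(arm_b=(1, arm_len), arm_a=(1000, 1000 + arm_len - 1), length=arm_len)
        ok, reason = passes_filter(fx.genome, ir, DetectionParams())
        assert ok is accepted
        if not accepted:
            assert reason == "IR < 100 bp"

    def test_unannotated_genome_rejected(self):
        fx = generate(FixtureSpec(seed=7))
        bare = AnnotatedGenome(
            fx.genome.accession, fx.genome.organism, fx.genome.sequence, "circular", ()
        )
        ok, reason = passes_filter(bare, fx.tetrad, DetectionParams())
        assert not ok and reason == "unannotated"

    def test_no_detection_rejected(self):
        g = _bare(500, genes=())
        ok, reason = passes_filter(g, None, DetectionParams())
        assert not ok and reason.startswith("IR <")


class TestStandardizeAndGroups:
    def test_group_a_is_identity(self, small_fixture):
        fx = small_fixture
        std_g, std_t = standardize_start(fx.genome, fx.tetrad)
        assert std_g.sequence == fx.genome.sequence
        assert std_t == fx.tetrad

    def test_group_e_standardizes_to_lsc_first(self):
        fx = generate(FixtureSpec(start_group="e", seed=2))
        std_g, std_t = standardize_start(fx.genome, fx.tetrad)
        assert std_t.lsc.start == 1
        assert std_t.ira.end == std_t.genome_length

    def test_wrapping_gene_becomes_contiguous(self):
        fx = generate(FixtureSpec(start_group="f", seed=2))
        wrapped = [g for g in fx.genome.genes if len(g.segments) == 2]
        assert wrapped  # the deposited origin splits at least one gene
        std_g, _ = standardize_start(fx.genome, fx.tetrad)
        by_name = {g.name: g for g in std_g.genes}
        for g in wrapped:
            assert len(by_name[g.name].segments) == 1

    def test_standardized_sequence_is_rotation(self):
        fx = generate(FixtureSpec(start_group="c", seed=3))
        std_g, _ = standardize_start(fx.genome, fx.tetrad)
        assert std_g.sequence in fx.genome.sequence + fx.genome.sequence

    def test_reference_start_groups(self):
        for acc, (org, code, coords, L) in REFERENCE_PLASTOMES.items():
            if acc in KNOWN_INCONSISTENT:
                continue
            t = reference_tetrad(acc)
            g = AnnotatedGenome(acc, org, "A" * t.genome_length, "circular", ())
            assert classify_start_group(g, t).code == code, acc


class TestDetectTetrad:
    def test_ir_arms_are_reverse_complements(self, small_fixture):
        fx = small_fixture
        res = detect_tetrad(fx.genome)
        std_g, std_t = standardize_start(fx.genome, res.tetrad)
        L = std_t.genome_length
        irb = std_g.sequence[std_t.irb.start - 1 : std_t.irb.end]
        ira = std_g.sequence[std_t.ira.start - 1 : std_t.ira.end]
        assert ira == revcomp(irb)

    def test_partition_invariant(self, group_suite):
        for code, fx in group_suite.items():
            res = detect_tetrad(fx.genome)
            L = fx.genome.length
            assert sum(r.length(L) for r in res.tetrad.regions()) == L

    def test_mutated_arms_recovered_with_chaining(self):
        fx = generate(FixtureSpec(start_group="b", seed=8, mutations_in_ira=2))
        res = detect_tetrad(fx.genome)
        assert res.tetrad == fx.tetrad
        assert res.ir.mismatches == 2
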