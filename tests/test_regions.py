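"""Interval arithmetic and element-catalog construction rules."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fmlbias as F
from fmlbias.genome import ReferenceGenome
from fmlbias.regions import RegionConfig, total_length

I = lambda a, b, strand=".": F.GenomicInterval("chr1", a, b, strand)


class TestMergeSubtract:
    @pytest.mark.parametrize(
        "ivs,expected",
        [
            ([(10, 20), (15, 30)], [(10, 30)]),          # overlap union
            ([(10, 20), (20, 25)], [(10, 25)]),          # adjacency merges
            ([(30, 40), (10, 20)], [(10, 20), (30, 40)]),  # disjoint, sorted
            ([], []),
        ],
    )
    def test_merge_examples(self, ivs, expected):
        got = F.merge_intervals([I(a, b) for a, b in ivs])
        assert [(iv.start, iv.end) for iv in got] == expected

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([(0, 100)], [(40, 60)], [(0, 40), (60, 100)]),   # split
            ([(0, 10)], [(0, 10)], []),                       # annihilation
            ([(0, 10)], [(20, 30)], [(0, 10)]),               # no overlap
        ],
    )
    def test_subtract_examples(self, a, b, expected):
        got = F.subtract_intervals([I(*t) for t in a], [I(*t) for t in b])
        assert [(iv.start, iv.end) for iv in got] == expected

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        a=st.lists(st.tuples(st.integers(0, 500), st.integers(1, 60)), max_size=8),
        b=st.lists(st.tuples(st.integers(0, 500), st.integers(1, 60)), max_size=8),
    )
    def test_against_per_base_membership_oracle(self, a, b):
        """merge/subtract agree with brute-force per-base set arithmetic."""
        ia = F.merge_intervals([I(s, s + l) for s, l in a])
        ib = F.merge_intervals([I(s, s + l) for s, l in b])
        base_a = {p for iv in ia for p in range(iv.start, iv.end)}
        base_b = {p for iv in ib for p in range(iv.start, iv.end)}
        merged = {p for iv in ia for p in range(iv.start, iv.end)}
        assert merged == base_a
        diff = F.subtract_intervals(ia, ib)
        base_diff = {p for iv in diff for p in range(iv.start, iv.end)}
        assert base_diff == base_a - base_b
        assert total_length(diff) == len(base_a - base_b)
        # output intervals are disjoint and separated
        for x, y in zip(diff, diff[1:]):
            assert x.end < y.start


class TestSpliceRegions:
    def test_long_intron_yields_two_flanks(self):
        got = F.build_splice_regions([I(1000, 1200)], flank=50)
        assert [(iv.start, iv.end) for iv in got] == [(1000, 1050), (1150, 1200)]

    def test_short_intron_yields_single_region_without_double_counting(self):
        got = F.build_splice_regions([I(1000, 1060)], flank=50)
        assert [(iv.start, iv.end) for iv in got] == [(1000, 1060)]

    def test_flanks_exactly_tiling_the_intron_merge(self):
        got = F.build_splice_regions([I(1000, 1100)], flank=50)
        assert [(iv.start, iv.end) for iv in got] == [(1000, 1100)]


class TestPromoters:
    @pytest.fixture
    def genome(self):
        return ReferenceGenome({"chr1": "A" * 20_000})

    def test_plus_strand_window(self, genome):
        got = F.build_promoters([("chr1", 10_001, "+")], 2500, genome)
        assert [(iv.start, iv.end) for iv in got] == [(7500, 10_000)]

    def test_minus_strand_window_mirrors_plus(self, genome):
        got = F.build_promoters([("chr1", 10_000, "-")], 2500, genome)
        assert [(iv.start, iv.end) for iv in got] == [(10_000, 12_500)]

    def test_clipped_at_chromosome_start(self, genome):
        got = F.build_promoters([("chr1", 100, "+")], 2500, genome)
        assert [(iv.start, iv.end) for iv in got] == [(0, 99)]

    def test_tss_beyond_chromosome_is_an_error(self, genome):
        with pytest.raises(ValueError, match="outside"):
            F.build_promoters([("chr1", 30_000, "+")], 2500, genome)


def _gtf(lines):
    return list(lines)


def _attrs(gid, btype, name=None):
    name = name or gid
    return (
        f'gene_id "{gid}"; transcript_id "{gid}.1"; gene_type "{btype}"; '
        f'transcript_type "{btype}"; gene_name "{name}";'
    )


class TestBuildCatalog:
    @pytest.fixture
    def genome(self):
        return ReferenceGenome({"chr1": "ACGT" * 5000})

    def test_utr_overlapping_own_cds_loses_the_overlap(self, genome):
        a = _attrs("G1", "protein_coding")
        lines = [
            f"chr1\tx\tgene\t1001\t1400\t.\t+\t.\t{a}",
            f"chr1\tx\ttranscript\t1001\t1400\t.\t+\t.\t{a}",
            f"chr1\tx\texon\t1001\t1400\t.\t+\t.\t{a}",
            f"chr1\tx\tCDS\t1101\t1400\t.\t+\t.\t{a}",
            f"chr1\tx\tUTR\t1001\t1150\t.\t+\t.\t{a}",  # overlaps CDS by 50
        ]
        cat = F.build_catalog(lines, genome)
        utr5 = cat["G1:utr5"]
        assert [(s.start, s.end) for s in utr5.segments] == [(1000, 1100)]

    def test_five_prime_utr_loses_three_prime_overlap(self, genome):
        a1 = _attrs("G1", "protein_coding")
        a2 = _attrs("G2", "protein_coding")
        lines = [
            # G1 on +: CDS then a 3' UTR at [2000,2100)
            f"chr1\tx\tgene\t1001\t2100\t.\t+\t.\t{a1}",
            f"chr1\tx\ttranscript\t1001\t2100\t.\t+\t.\t{a1}",
            f"chr1\tx\texon\t1001\t2100\t.\t+\t.\t{a1}",
            f"chr1\tx\tCDS\t1001\t2000\t.\t+\t.\t{a1}",
            f"chr1\tx\tUTR\t2001\t2100\t.\t+\t.\t{a1}",
            # G2 on +: its 5' UTR (left of its CDS) overlaps G1's 3' UTR
            f"chr1\tx\tgene\t2051\t3000\t.\t+\t.\t{a2}",
            f"chr1\tx\ttranscript\t2051\t3000\t.\t+\t.\t{a2}",
            f"chr1\tx\texon\t2051\t3000\t.\t+\t.\t{a2}",
            f"chr1\tx\tCDS\t2151\t3000\t.\t+\t.\t{a2}",
            f"chr1\tx\tUTR\t2051\t2150\t.\t+\t.\t{a2}",
        ]
        cat = F.build_catalog(lines, genome)
        utr5 = cat["G2:utr5"]
        # G2's 5' UTR [2050,2150) loses [2050,2100) to G1's 3' UTR
        assert [(s.start, s.end) for s in utr5.segments] == [(2100, 2150)]
        assert [(s.start, s.end) for s in cat["G1:utr3"].segments] == [(2000, 2100)]

    def test_promoter_loses_any_gene_cds_overlap(self, genome):
        a1 = _attrs("UP", "protein_coding")
        a2 = _attrs("DN", "protein_coding")
        lines = [
            # upstream gene whose CDS sits inside DN's promoter window
            f"chr1\tx\tgene\t8001\t9000\t.\t+\t.\t{a1}",
            f"chr1\tx\ttranscript\t8001\t9000\t.\t+\t.\t{a1}",
            f"chr1\tx\texon\t8001\t9000\t.\t+\t.\t{a1}",
            f"chr1\tx\tCDS\t8001\t9000\t.\t+\t.\t{a1}",
            f"chr1\tx\tgene\t10001\t11000\t.\t+\t.\t{a2}",
            f"chr1\tx\ttranscript\t10001\t11000\t.\t+\t.\t{a2}",
            f"chr1\tx\texon\t10001\t11000\t.\t+\t.\t{a2}",
            f"chr1\tx\tCDS\t10001\t11000\t.\t+\t.\t{a2}",
        ]
        cat = F.build_catalog(lines, genome)
        promoter = cat["DN:promoter"]  # window [7500,10000) minus CDS [8000,9000)
        assert [(s.start, s.end) for s in promoter.segments] == [(7500, 8000), (9000, 10_000)]

    def test_lincrna_exons_merged_and_masked(self, genome):
        a1 = _attrs("PC", "protein_coding")
        a2 = _attrs("L1", "lincRNA")
        lines = [
            f"chr1\tx\tgene\t1001\t1500\t.\t+\t.\t{a1}",
            f"chr1\tx\ttranscript\t1001\t1500\t.\t+\t.\t{a1}",
            f"chr1\tx\texon\t1001\t1500\t.\t+\t.\t{a1}",
            f"chr1\tx\tCDS\t1001\t1500\t.\t+\t.\t{a1}",
            f"chr1\tx\tgene\t1401\t2000\t.\t+\t.\t{a2}",
            f"chr1\tx\ttranscript\t1401\t2000\t.\t+\t.\t{a2}",
            f"chr1\tx\texon\t1401\t1700\t.\t+\t.\t{a2}",
            f"chr1\tx\texon\t1601\t2000\t.\t+\t.\t{a2}",
        ]
        cat = F.build_catalog(lines, genome)
        # exons merge to [1400,2000), CDS [1000,1500) masks the head
        assert [(s.start, s.end) for s in cat["L1:lncrna"].segments] == [(1500, 2000)]

    def test_blacklist_drops_elements(self, genome):
        a = _attrs("G1", "protein_coding")
        lines = [
            f"chr1\tx\tgene\t1001\t1400\t.\t+\t.\t{a}",
            f"chr1\tx\ttranscript\t1001\t1400\t.\t+\t.\t{a}",
            f"chr1\tx\texon\t1001\t1400\t.\t+\t.\t{a}",
            f"chr1\tx\tCDS\t1001\t1400\t.\t+\t.\t{a}",
        ]
        cat = F.build_catalog(lines, genome, RegionConfig(blacklist=frozenset({"G1"})))
        assert len(cat) == 0


class TestCatalogInvariants:
    def test_no_base_shared_between_promoter_or_utr_and_cds(self, toy_world):
        cds_bases = set()
        for el in toy_world.catalog:
            if el.element_type == "cds":
                cds_bases |= {p for p in el.positions()}
        for el in toy_world.catalog:
            if el.element_type in ("promoter", "utr5", "utr3", "lncrna"):
                assert cds_bases.isdisjoint(el.positions()), el.element_id

    def test_utr5_and_utr3_do_not_overlap(self, toy_world):
        utr3 = set()
        for el in toy_world.catalog:
            if el.element_type == "utr3":
                utr3 |= set(el.positions())
        for el in toy_world.catalog:
            if el.element_type == "utr5":
                assert utr3.isdisjoint(el.positions()), el.element_id

    def test_index_lookup_covers_every_element_base(self, mini_world):
        for el in mini_world.catalog:
            for pos1 in el.positions():
                assert el.element_id in mini_world.catalog.lookup(el.chrom, pos1)

    def test_catalog_tsv_round_trip(self, mini_world, tmp_path):
        path = tmp_path / "elements.tsv"
        mini_world.catalog.to_tsv(str(path))
        back = F.ElementCatalog.from_tsv(str(path))
        assert set(back.elements) == set(mini_world.catalog.elements)
        for eid, el in back.elements.items():
            assert el.segments == mini_world.catalog[eid].segments
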