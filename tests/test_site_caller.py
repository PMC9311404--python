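import numpy as np
import pytest

from conftest import make_read, sl_read
from sltscan.formats import GeneModel
from sltscan.mispred_scan import MispredictionReport
from sltscan.site_caller import (call_sites, classify_junction,
                                 filter_read_pairs, logo_matrix, read_site,
                                 summarize_sites)
from sltscan.sl_motif import CONSERVED_SL


def pair(rid, clip3_a=0, clip3_b=0, nm_a=0, nm_b=0, proper=True):
    c1 = [("S", 20), ("M", 130)]
    if clip3_a:
        c1 = c1 + [("S", clip3_a)]
    r1 = make_read(start=100, cigar=c1, nm=nm_a, proper=proper,
                   rid=rid)
    # mate is reverse: its biological 3' end is the leading (left) clip
    c2 = ([("S", clip3_b)] if clip3_b else []) + [("M", 150 - clip3_b)]
    r2 = make_read(start=300, cigar=c2, nm=nm_b, proper=proper, rev=True,
                   rid=rid)
    return [r1, r2]


class TestFilterReadPairs:
    def test_five_prime_clips_allowed(self):
        # 5' clips of 20/0, 3' clips 0/3, NM 2/0 -> retained
        kept = filter_read_pairs(pair("p", clip3_b=3, nm_a=2))
        assert len(kept) == 2

    def test_three_prime_clip_boundary(self):
        assert len(filter_read_pairs(pair("p", clip3_a=5))) == 2
        assert len(filter_read_pairs(pair("p", clip3_a=6))) == 0

    def test_edit_distance_boundary(self):
        assert len(filter_read_pairs(pair("p", nm_b=5))) == 2
        assert len(filter_read_pairs(pair("p", nm_b=6))) == 0

    def test_not_properly_paired_dropped(self):
        assert filter_read_pairs(pair("p", proper=False)) == []

    def test_orphan_dropped(self):
        assert filter_read_pairs(pair("p")[:1]) == []


class TestReadSite:
    def test_motif_in_aligned_prefix(self):
        # motif aligned at read start; first base after it maps to 200 + 12
        seq = CONSERVED_SL + "A" * 138
        r = make_read(start=200, cigar=[("M", 150)], seq=seq)
        assert read_site(r) == 212

    def test_motif_ends_at_clip_boundary(self):
        # conserved region is the last 12 clipped bases: site = first mapped
        r = sl_read("g1", site=200, n_clip=12)
        assert read_site(r) == 200

    def test_motif_wholly_inside_larger_clip(self):
        r = sl_read("g1", site=350, n_clip=20)
        assert read_site(r) == 350

    def test_no_motif(self):
        assert read_site(make_read(cigar=[("M", 50)])) is None

    def test_cigar_walk_over_deletion(self):
        # deletion between motif end and next aligned base shifts the
        # reference position: oracle by explicit CIGAR arithmetic
        seq = CONSERVED_SL + "G" * 38
        r = make_read(start=100, cigar=[("M", 12), ("D", 5), ("M", 38)],
                      seq=seq)
        assert read_site(r) == 100 + 12 + 5

    def test_motif_ending_in_insertion(self):
        seq = "T" * 10 + CONSERVED_SL[:8] + CONSERVED_SL[8:] + "G" * 28
        r = make_read(start=50, cigar=[("M", 18), ("I", 4), ("M", 28)],
                      seq=seq)
        # motif ends at read offset 22 inside the insertion (18..21)... the
        # first aligned base at or after offset 22 maps to 50 + 18
        assert read_site(r) == 68


class TestCallSites:
    def test_site_called_and_counted(self):
        reads = [sl_read("g1", 200, rid=f"s{i}") for i in range(15)]
        reads += [make_read("g1", start=150, cigar=[("M", 150)],
                            rid=f"b{i}") for i in range(5)]
        (site,) = call_sites(reads, cds_lengths={"g1": 1000})
        assert site.position == 200
        assert site.supporting_reads == 15
        assert site.depth == 20
        assert site.support_fraction == pytest.approx(0.75)

    @pytest.mark.parametrize("n,called", [(10, False), (11, True)])
    def test_strictly_more_than_ten_reads(self, n, called):
        reads = [sl_read("g1", 200, rid=f"s{i}") for i in range(n)]
        assert bool(call_sites(reads)) is called

    def test_mispredicted_region_suppresses(self):
        reads = [sl_read("g1", 150, rid=f"s{i}") for i in range(15)]
        rep = MispredictionReport("g1", [210], (50, 250))
        assert call_sites(reads, mispred={"g1": rep}) == []  # |210-150|=60
        far = MispredictionReport("g1", [251], (50, 300))
        assert len(call_sites(reads, mispred={"g1": far})) == 1

    def test_exclusion_distance_inclusive(self):
        reads = [sl_read("g1", 150, rid=f"s{i}") for i in range(15)]
        rep = MispredictionReport("g1", [250], (50, 300))
        assert call_sites(reads, mispred={"g1": rep}) == []  # exactly 100

    def test_min_support_monotonic(self):
        rng = np.random.default_rng(5)
        reads = []
        for j, pos in enumerate([50, 120, 300]):
            for i in range(int(rng.integers(5, 30))):
                reads.append(sl_read("g1", pos, rid=f"{j}_{i}"))
        prev = None
        for ms in range(0, 40, 5):
            n = len(call_sites(reads, min_support=ms))
            if prev is not None:
                assert n <= prev
            prev = n

    def test_emitted_invariants(self, sim):
        from sltscan.site_caller import call_sites_with_mispred_screen
        from sltscan import formats
        from sltscan.site_caller import filter_read_pairs
        reads = formats.read_sam(sim.outdir / "reads.sam")
        filtered = filter_read_pairs(reads)
        genes = {g.gene_id: g for g in sim.genes}
        sites = call_sites_with_mispred_screen(filtered, genes)
        assert sites
        for s in sites:
            assert s.depth > 0
            assert s.supporting_reads <= s.depth
            assert s.supporting_reads >= 11


class TestClassifyJunction:
    @pytest.fixture()
    def gene(self):
        # CDS pieces of lengths 100, 80, 120 -> junction starts 101, 181
        return GeneModel("g", "c", "+",
                         [(1, 100), (201, 280), (401, 520)],
                         [(1, 100), (201, 280), (401, 520)], "A" * 300)

    def test_classes(self, gene):
        assert classify_junction(1, gene) == "position_1"
        assert classify_junction(101, gene) == "precise_junction"
        assert classify_junction(103, gene, near_window=2) == "near_junction"
        assert classify_junction(104, gene, near_window=2) == "internal"
        assert classify_junction(50, gene) == "internal"

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_agrees_with_genomic_boundary_oracle(self, strand):
        # independent oracle: map every genomic exon start (in transcription
        # order) to CDS coordinates via the formats-level coordinate mapping
        gene = GeneModel("g", "c", strand,
                         [(11, 110), (211, 290), (411, 530)],
                         [(11, 110), (211, 290), (411, 530)], "A" * 300)
        order = gene.cds_intervals if strand == "+" else \
            gene.cds_intervals[::-1]
        starts = set()
        for s, e in order[1:]:
            g5 = s if strand == "+" else e
            starts.add(gene.genomic_to_cds(g5))
        for pos in range(1, 301):
            expected = ("position_1" if pos == 1 else
                        "precise_junction" if pos in starts else
                        "near_junction" if any(abs(pos - j) <= 2
                                               for j in starts) else
                        "internal")
            assert classify_junction(pos, gene) == expected, pos


class TestSummaries:
    def make_site(self, pos, frac, rel):
        from sltscan.site_caller import SLAdditionSite
        return SLAdditionSite("g", pos, max(int(frac * 100), 1), 100, frac,
                              rel)

    def test_single_site_at_one(self):
        s = summarize_sites([self.make_site(1, 0.5, 0.0)])
        assert s.mean_relative_position_pct == 0.0

    def test_above_below_groups(self):
        # fractions 0.2/0.8 at relative positions 10%/2%:
        # mean support 50%, above-mean group mean position = 2%
        s = summarize_sites([self.make_site(11, 0.2, 10.0),
                             self.make_site(3, 0.8, 2.0)])
        assert s.mean_support_pct == pytest.approx(50.0)
        assert s.mean_relpos_above_mean_support == pytest.approx(2.0)
        assert s.mean_relpos_below_mean_support == pytest.approx(10.0)

    def test_equal_fractions_undefined_groups(self):
        s = summarize_sites([self.make_site(11, 0.5, 10.0),
                             self.make_site(3, 0.5, 2.0)])
        assert np.isnan(s.mean_relpos_above_mean_support)


class TestLogo:
    def make_site(self, gene, pos):
        from sltscan.site_caller import SLAdditionSite
        return SLAdditionSite(gene, pos, 12, 20, 0.6, 1.0,
                              context_class="internal")

    def test_perfect_acceptor_context(self):
        # every context has A at -2 and G at -1: frequency 1, 2 bits
        cds = {}
        sites = []
        rng = np.random.default_rng(3)
        for i in range(20):
            seq = "".join("ACGT"[j] for j in rng.integers(0, 4, 40))
            pos = 20
            seq = seq[:pos - 3] + "AG" + seq[pos - 1:]
            cds[f"g{i}"] = seq
            sites.append(self.make_site(f"g{i}", pos))
        logo = logo_matrix(sites, cds)
        assert logo.frequency("A", -2) == 1.0
        assert logo.frequency("G", -1) == 1.0
        assert logo.information_bits[logo.positions.index(-2)] == \
            pytest.approx(2.0)
        assert logo.information_bits[logo.positions.index(-1)] == \
            pytest.approx(2.0)

    def test_uniform_contexts_carry_no_information(self):
        rng = np.random.default_rng(99)
        cds, sites = {}, []
        for i in range(10_000):
            cds[f"g{i}"] = "".join("ACGT"[j]
                                   for j in rng.integers(0, 4, 21))
            sites.append(self.make_site(f"g{i}", 11))
        logo = logo_matrix(sites, cds)
        assert (logo.information_bits <= 0.05).all()

    def test_site_near_cds_end_excluded(self):
        cds = {"g0": "A" * 40}
        with pytest.raises(ValueError):
            logo_matrix([self.make_site("g0", 3)], cds)

    def test_frequencies_sum_to_one(self):
        cds = {"g0": "ACGTACGTACGTACGTACGTA"}
        logo = logo_matrix([self.make_site("g0", 11)], cds)
        assert np.allclose(logo.base_frequencies.sum(axis=0), 1.0)
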