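import numpy as np
import pytest

from sltscan.formats import GeneModel, GenomeSequence, revcomp
from sltscan.genome_survey import (GenomeSLHit, classify_hit, pad_partial,
                                   recycling_candidates, scan_genome_for_sl)
from sltscan.sl_motif import CHROMATOPHORA_SL, FULL_SL, KR01_SL


def rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestScan:
    def test_full_hit_recovered(self):
        rng = np.random.default_rng(1)
        seq = rand_seq(rng, 500) + FULL_SL + rand_seq(rng, 500)
        hits = scan_genome_for_sl([GenomeSequence("s", seq)],
                                  max_mismatches=0)
        full = [h for h in hits if h.classification == "full"]
        assert any(h.start == 501 and h.end == 520 and h.strand == "+"
                   and (h.q_start, h.q_end) == (1, 20) for h in full)

    def test_partial_suffix_recovered(self):
        rng = np.random.default_rng(2)
        left = rand_seq(rng, 300)
        # guard base breaks any accidental leftward extension
        guard = "A" if FULL_SL[9] != "A" else "C"
        seq = left + guard + FULL_SL[-10:] + rand_seq(rng, 300)
        hits = scan_genome_for_sl([GenomeSequence("s", seq)],
                                  max_mismatches=0)
        part = [h for h in hits if h.classification == "partial"]
        assert any((h.q_start, h.q_end) == (11, 20) and h.start == 302
                   for h in part)

    def test_minus_strand_hit(self):
        rng = np.random.default_rng(3)
        seq = rand_seq(rng, 200) + revcomp(FULL_SL) + rand_seq(rng, 200)
        hits = scan_genome_for_sl([GenomeSequence("s", seq)],
                                  max_mismatches=0)
        full = [h for h in hits if h.classification == "full"]
        assert any(h.strand == "-" and h.start == 201 and h.end == 220
                   for h in full)

    def test_random_genome_mostly_empty_at_high_stringency(self):
        # expected chance hits ~ 2 * 1e5 / 4^12 << 1
        rng = np.random.default_rng(7)
        seq = rand_seq(rng, 100_000)
        hits = scan_genome_for_sl([GenomeSequence("s", seq)],
                                  min_hit_len=12, max_mismatches=0)
        assert len(hits) == 0

    def test_one_mismatch_tolerated(self):
        rng = np.random.default_rng(5)
        mutated = list(FULL_SL)
        mutated[10] = {"A": "C"}.get(mutated[10], "A")
        seq = rand_seq(rng, 300) + "".join(mutated) + rand_seq(rng, 300)
        hits = scan_genome_for_sl([GenomeSequence("s", seq)],
                                  max_mismatches=1)
        assert any(h.q_end == 20 and h.q_start <= 2 and h.mismatches == 1
                   for h in hits)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(9)
        seq = (rand_seq(rng, 150) + FULL_SL + rand_seq(rng, 90)
               + FULL_SL[-12:] + rand_seq(rng, 150))
        fwd = scan_genome_for_sl([GenomeSequence("s", seq)],
                                 max_mismatches=0)
        rev = scan_genome_for_sl([GenomeSequence("s", revcomp(seq))],
                                 max_mismatches=0)
        key = lambda h: (h.q_start, h.q_end, h.classification,
                         len(seq) - h.end + 1 if h.strand == "-" else h.start)
        flip = lambda h: (h.q_start, h.q_end, h.classification,
                          h.start if h.strand == "+" else
                          len(seq) - h.end + 1)
        # reverse-complementing the genome swaps strands but preserves the
        # classification multiset
        assert sorted((h.q_start, h.q_end, h.classification) for h in fwd) \
            == sorted((h.q_start, h.q_end, h.classification) for h in rev)
        assert sorted(h.strand for h in fwd) == \
            sorted({"+": "-", "-": "+"}[h.strand] for h in rev)


class TestClassify:
    def hit(self, q_start, q_end):
        return GenomeSLHit("s", 1, 20, "+", q_start, q_end)

    def test_species_start_rule(self):
        assert classify_hit(self.hit(1, 20), KR01_SL.full_start_position) \
            == "full"
        assert classify_hit(self.hit(2, 20), KR01_SL.full_start_position) \
            == "partial"
        assert classify_hit(self.hit(2, 20),
                            CHROMATOPHORA_SL.full_start_position) == "full"

    def test_must_end_at_20(self):
        assert classify_hit(self.hit(1, 19), 1) == "neither"


class TestPadPartial:
    def test_plus_strand_window(self):
        rng = np.random.default_rng(11)
        seq = rand_seq(rng, 600)
        # 10-bp hit occupying genomic 500-509: pad = bases 490-509
        hit = GenomeSLHit("s", 500, 509, "+", 11, 20)
        pad = pad_partial(hit, {"s": seq})
        assert pad == seq[489:509] and len(pad) == 20

    def test_near_scaffold_start_discarded(self):
        rng = np.random.default_rng(12)
        seq = rand_seq(rng, 100)
        hit = GenomeSLHit("s", 5, 14, "+", 11, 20)
        assert pad_partial(hit, {"s": seq}) is None

    def test_minus_strand_window(self):
        rng = np.random.default_rng(13)
        core = rand_seq(rng, 600)
        frag = FULL_SL[-10:]
        seq = core[:300] + revcomp(frag) + core[300:]
        hit = GenomeSLHit("s", 301, 310, "-", 11, 20)
        pad = pad_partial(hit, {"s": seq})
        assert len(pad) == 20
        # SL-orientation 3' 10 bases are the hit's own (reverse-complemented)
        assert pad[-10:] == frag

    def test_pad_matches_hit_bases_when_exact(self):
        rng = np.random.default_rng(14)
        guard = "A" if FULL_SL[-13] != "A" else "C"
        seq = rand_seq(rng, 300) + guard + FULL_SL[-12:] + rand_seq(rng, 300)
        hits = [h for h in scan_genome_for_sl([GenomeSequence("s", seq)],
                                              max_mismatches=0)
                if h.classification == "partial" and h.start == 302]
        pad = pad_partial(hits[0], {"s": seq})
        assert pad is not None and pad[-12:] == FULL_SL[-12:]


class TestRecycling:
    def gene(self, start, end, strand="+", gid="g1"):
        return GeneModel(gid, "s", strand, [(start, end)], [(start, end)],
                         "A" * (end - start + 1))

    def hit(self, start, end, q_len, strand="+"):
        return GenomeSLHit("s", start, end, strand, 21 - q_len, 20,
                           classification="partial" if q_len < 20 else "full")

    @pytest.mark.parametrize("q_len,dist,expected", [
        (16, 50, True),    # coverage 80%, 50 bp upstream
        (12, 50, False),   # coverage 60% rejected
        (16, 150, False),  # too far upstream
        (14, 50, False),   # coverage exactly 70.0 rejected
    ])
    def test_rules(self, q_len, dist, expected):
        gene = self.gene(1000, 1600)
        hit = self.hit(1000 - dist - q_len + 1, 1000 - dist, q_len)
        cands = recycling_candidates([hit], [gene])
        assert bool(cands) is expected
        if cands:
            assert cands[0][2] == dist

    def test_minus_strand_gene(self):
        gene = self.gene(1000, 1600, strand="-")
        # SL on minus strand downstream in genomic coordinates: its 3' end
        # is the hit start
        hit = self.hit(1650, 1665, 16, strand="-")
        (cand,) = recycling_candidates([hit], [gene])
        assert cand[2] == 50

    def test_strand_mismatch_rejected(self):
        gene = self.gene(1000, 1600)
        hit = self.hit(930, 945, 16, strand="-")
        assert recycling_candidates([hit], [gene]) == []

    def test_overlapping_gene_body_rejected(self):
        gene = self.gene(1000, 1600)
        hit = self.hit(995, 1010, 16)
        assert recycling_candidates([hit], [gene]) == []

    def test_all_pairs_distance_oracle(self, sim):
        from sltscan import genome_survey as gs
        hits = gs.scan_genome_for_sl(sim.genome, max_mismatches=0)
        cands = gs.recycling_candidates(hits, sim.genes)
        # brute force: every (gene, hit) pair with the rule applied directly
        expected = set()
        for g in sim.genes:
            lo = min(s for s, _ in g.exons)
            hi = max(e for _, e in g.exons)
            five = lo if g.strand == "+" else hi
            for h in hits:
                if (h.scaffold_id != g.scaffold_id or h.strand != g.strand
                        or h.coverage_pct <= 70):
                    continue
                if h.end >= lo and h.start <= hi:
                    continue
                d = (five - h.end) if g.strand == "+" else (h.start - five)
                if 0 < d < 100:
                    expected.add((g.gene_id, h.start, d))
        assert {(gid, h.start, d) for gid, h, d in cands} == expected


class TestPlantedLoci:
    def test_full_and_partial_recovery(self, recovery):
        assert recovery.full_locus_sensitivity == 1.0
        assert recovery.partial_locus_sensitivity == 1.0
        assert recovery.recycling_sensitivity == 1.0
        assert recovery.recycling_precision == 1.0
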