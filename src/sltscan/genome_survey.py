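"""Survey of genome assemblies for SL sequences.

SL RNA genes leave full copies of the 20-nt leader in the genome; decayed or
divergent copies leave 3'-anchored fragments (the 3' end of the SL is its
most conserved part, so informative partial hits must end at SL position
20).  A hit covering the full SL starts at position 1 (KR01, *P. ovalis*) or
2 (*P. chromatophora*, whose leader begins with C).  Recycled mRNAs —
reverse-transcribed, reintegrated copies of SL-bearing transcripts — are
detected as genes with a high-coverage SL hit just upstream of their 5' end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats import GeneModel, GenomeSequence, revcomp
from .sl_motif import KR01_SL, SLDefinition

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass
class GenomeSLHit:
    """An ungapped match between the SL query and a genomic window.

    ``start``/``end`` are 1-based inclusive genomic coordinates of the
    matched region on the forward strand of the scaffold; ``q_start`` and
    ``q_end`` are 1-based positions on the SL query.
    """

    scaffold_id: str
    start: int
    end: int
    strand: str
    q_start: int
    q_end: int
    mismatches: int = 0
    classification: str = "neither"
    padded_sequence: str | None = None

    @property
    def coverage_pct(self) -> float:
        return (self.q_end - self.q_start + 1) / 20 * 100

    @property
    def three_prime_end(self) -> int:
        """Genomic coordinate of the hit's SL-3' end (strand aware)."""
        return self.end if self.strand == "+" else self.start


def _encode(seq: str) -> np.ndarray:
    return np.frompyfunc(_BASE_CODE.__getitem__, 1, 1)(
        np.array(list(seq.upper()))).astype(np.int8)


def _maximal_segments(match: np.ndarray, min_len: int,
                      max_mm: int) -> list[tuple[int, int, int]]:
    """Maximal (q_start0, q_end0, mismatches) segments of a boolean match
    vector containing <= max_mm mismatches; segments start and end on a
    match and cannot be extended in either direction within the budget.

    The greedy right-reach from start i is non-decreasing in i, so the
    maximal segments are exactly, for each distinct reach, the segment from
    the smallest match-anchored start achieving it.
    """
    k = len(match)
    by_end: dict[int, int] = {}
    for i in range(k):
        if not match[i]:
            continue
        mm, last, j = 0, -1, i
        while j < k:
            if not match[j]:
                if mm == max_mm:
                    break
                mm += 1
            else:
                last = j
            j += 1
        if last >= i and last - i + 1 >= min_len and last not in by_end:
            by_end[last] = i
    return [(i, last, int(np.count_nonzero(~match[i:last + 1])))
            for last, i in sorted(by_end.items())]


def _scan_oriented(seq_code: np.ndarray, sl_code: np.ndarray, min_len: int,
                   max_mm: int) -> list[tuple[int, int, int, int]]:
    """Hits on one orientation: (diag0, q_start0, q_end0, mismatches) where
    diag0 is the 0-based position where SL position 1 aligns."""
    G, k = len(seq_code), len(sl_code)
    if G < min_len:
        return []
    n_diag = G - k + 1
    hits = []
    if n_diag > 0:
        m = np.empty((n_diag, k), dtype=bool)
        for q in range(k):
            m[:, q] = seq_code[q:q + n_diag] == sl_code[q]
        rowsum = m.sum(axis=1)
        for d in np.nonzero(rowsum >= min_len - max_mm)[0]:
            for lo, hi, mm in _maximal_segments(m[d], min_len, max_mm):
                hits.append((int(d), lo, hi, mm))
    # diagonals where the SL overhangs the scaffold 3' end (partial suffix of
    # the *query start*); the informative 3'-anchored hits never need the
    # overhang past the start, so also scan diagonals hanging off the 5' end
    for d in range(-(k - min_len), 0):
        q_lo, q_hi = -d, min(k, G - d)
        if q_hi - q_lo < min_len:
            continue
        vec = seq_code[d + q_lo:d + q_hi] == sl_code[q_lo:q_hi]
        for lo, hi, mm in _maximal_segments(vec, min_len, max_mm):
            hits.append((d, q_lo + lo, q_lo + hi, mm))
    for d in range(max(n_diag, 0), G - min_len + 1):
        q_hi = G - d
        if q_hi < min_len:
            continue
        vec = seq_code[d:d + q_hi] == sl_code[:q_hi]
        for lo, hi, mm in _maximal_segments(vec, min_len, max_mm):
            hits.append((d, lo, hi, mm))
    return hits


def scan_genome_for_sl(genome: list[GenomeSequence],
                       sl: SLDefinition = KR01_SL, min_hit_len: int = 8,
                       max_mismatches: int = 1) -> list[GenomeSLHit]:
    """Report every maximal ungapped match of an SL substring on both
    strands, with length >= ``min_hit_len`` and at most ``max_mismatches``
    mismatches, then classify each against the species' full-hit rule."""
    query = sl.full_sequence
    sl_code = _encode(query)
    hits: list[GenomeSLHit] = []
    for scaf in genome:
        L = len(scaf.sequence)
        for strand, seq in (("+", scaf.sequence),
                            ("-", revcomp(scaf.sequence))):
            code = _encode(seq)
            for d, q_lo, q_hi, mm in _scan_oriented(
                    code, sl_code, min_hit_len, max_mismatches):
                s_or = d + q_lo + 1  # 1-based on oriented sequence
                e_or = d + q_hi + 1
                if strand == "+":
                    g_s, g_e = s_or, e_or
                else:
                    g_s, g_e = L - e_or + 1, L - s_or + 1
                hit = GenomeSLHit(
                    scaffold_id=scaf.scaffold_id, start=g_s, end=g_e,
                    strand=strand, q_start=q_lo + 1, q_end=q_hi + 1,
                    mismatches=mm)
                hit.classification = classify_hit(hit, sl.full_start_position)
                hits.append(hit)
    hits.sort(key=lambda h: (h.scaffold_id, h.start, h.strand, h.q_start))
    return hits


def classify_hit(hit: GenomeSLHit, species_full_start: int = 1) -> str:
    """Full/partial classification of a genomic SL hit.

    Hits must end at SL position 20 to be informative; those starting at or
    before the species' full-start position (1 for KR01 and *P. ovalis*, 2
    for *P. chromatophora*) are full, later starts are partial.
    """
    if hit.q_end != 20:
        return "neither"
    if hit.q_start <= species_full_start:
        return "full"
    return "partial"


def pad_partial(hit: GenomeSLHit, genome: dict[str, str] | list[GenomeSequence],
                sl: SLDefinition = KR01_SL) -> str | None:
    """Extract a 20-nt strand-aware window ending at a partial hit's 3'
    genomic end (upstream genomic bases supply the pad); None when the
    scaffold boundary truncates the window."""
    if isinstance(genome, list):
        genome = {g.scaffold_id: g.sequence for g in genome}
    seq = genome[hit.scaffold_id]
    L = len(seq)
    target = len(sl.full_sequence)
    if hit.strand == "+":
        end = hit.end
        start = end - target + 1
        if start < 1:
            return None
        return seq[start - 1:end]
    else:
        start = hit.start
        end = start + target - 1
        if end > L:
            return None
        return revcomp(seq[start - 1:end])


def recycling_candidates(hits: list[GenomeSLHit], genes: list[GeneModel],
                         min_coverage: float = 70.0, max_distance: int = 100
                         ) -> list[tuple[str, GenomeSLHit, int]]:
    """Genes with a high-coverage SL hit just upstream of their 5' end.

    Retained iff the hit's query coverage exceeds ``min_coverage`` percent
    and the distance from the hit's SL-3' end to the gene's strand-aware 5'
    start is strictly between 0 and ``max_distance`` bp.  Hits overlapping
    the gene body, or on the other strand, are excluded.
    """
    out: list[tuple[str, GenomeSLHit, int]] = []
    for gene in genes:
        g_lo = min(s for s, _ in gene.exons)
        g_hi = max(e for _, e in gene.exons)
        five_prime = g_lo if gene.strand == "+" else g_hi
        for hit in hits:
            if hit.scaffold_id != gene.scaffold_id or hit.strand != gene.strand:
                continue
            if hit.coverage_pct <= min_coverage:
                continue
            if hit.end >= g_lo and hit.start <= g_hi:
                continue  # overlaps gene body
            if gene.strand == "+":
                dist = five_prime - hit.three_prime_end
            else:
                dist = hit.three_prime_end - five_prime
            if 0 < dist < max_distance:
                out.append((gene.gene_id, hit, dist))
    return out
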