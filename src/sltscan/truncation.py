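"""Identification of SL-truncated transcripts.

An assembled transcript that carries the SL near its 5' end, aligns cleanly
to the genome with the same intron structure as a reference gene, and whose
BLAST hit against that gene's CDS starts more than 100 bp into the CDS is an
"SL-truncated" variant: trans-splicing attached the leader part way along
the gene.  The CDS position where the hit starts is the SL truncation point.
Variants are Type 1 when reads evidencing the SL at that point are in the
majority, Type 2 otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .formats import AlignedRead, GeneModel, TabularHit
from .mispred_scan import scan_region
from .site_caller import read_site
from .sl_motif import KR01_SL, SLDefinition

logger = logging.getLogger(__name__)


@dataclass
class TranscriptAlignment:
    """A spliced transcript-to-genome placement (validated-alignment
    semantics: blocks are genomic intervals, sorted and non-overlapping)."""

    transcript_id: str
    scaffold_id: str
    strand: str
    blocks: list[tuple[int, int]]
    avg_identity_pct: float
    percent_aligned: float

    def __post_init__(self) -> None:
        self.blocks = sorted(tuple(b) for b in self.blocks)

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive blocks, as genomic intervals."""
        return [(self.blocks[i][1] + 1, self.blocks[i + 1][0] - 1)
                for i in range(len(self.blocks) - 1)]

    @property
    def span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]


@dataclass
class TruncationEvent:
    """An SL-truncated transcript mapped onto its reference gene."""

    transcript_id: str
    gene_id: str
    truncation_point: int
    sl_read_count: int = 0
    non_sl_read_count: int = 0
    type: int | None = None
    categories: frozenset[str] = frozenset()
    review_mean_nm: float = float("nan")
    review_coverage_cv: float = float("nan")


def validate_alignment(aln: TranscriptAlignment, min_identity: float = 95.0,
                       min_aligned: float = 90.0) -> bool:
    """Alignment-validation thresholds (both inclusive): average percent
    identity >= 95 and percent of transcript bases aligned >= 90."""
    return aln.avg_identity_pct >= min_identity and aln.percent_aligned >= min_aligned


def gene_introns(gene: GeneModel) -> list[tuple[int, int]]:
    return [(gene.exons[i][1] + 1, gene.exons[i + 1][0] - 1)
            for i in range(len(gene.exons) - 1)]


def intron_chain_class(aln: TranscriptAlignment, gene: GeneModel) -> str:
    """Compare a transcript's intron chain to a reference gene's.

    ``equal``: identical ordered intron lists (same scaffold and strand).
    ``contained``: the transcript's introns are a contiguous sub-list of the
    gene's, the transcript lies within the gene's exonic span, and its
    terminal blocks do not cross the bounding reference introns; a mono-exon
    transcript wholly inside one reference exon is also contained.
    Anything else (including a different scaffold) is ``other``.
    """
    if aln.scaffold_id != gene.scaffold_id or aln.strand != gene.strand:
        return "other"
    t_introns = aln.introns
    g_intr = gene_introns(gene)
    if t_introns == g_intr and len(t_introns) == len(g_intr):
        return "equal"
    span = aln.span
    gene_span = (gene.exons[0][0], gene.exons[-1][1])
    if span[0] < gene_span[0] or span[1] > gene_span[1]:
        return "other"
    if not t_introns:
        # mono-exon: must sit inside a single reference exon
        for s, e in gene.exons:
            if s <= span[0] and span[1] <= e:
                return "contained"
        return "other"
    n, m = len(t_introns), len(g_intr)
    for i in range(m - n + 1):
        if g_intr[i:i + n] == t_introns:
            left_ok = i == 0 or span[0] > g_intr[i - 1][1]
            right_ok = i + n == m or span[1] < g_intr[i + n][0]
            if left_ok and right_ok:
                return "contained"
    return "other"


def truncation_point_from_hit(hit: TabularHit, transcript_len: int,
                              cds_len: int, max_q_start: int = 2,
                              min_end_frac: float = 0.95,
                              min_cds_start: int = 100) -> int | None:
    """Filter a transcript-vs-CDS hit down to a truncation point.

    Retained iff the hit starts within ``max_q_start`` bp of the (SL-trimmed)
    transcript 5' end, ends beyond ``min_end_frac`` of the transcript OR of
    the CDS (the transcript may run into the 3' UTR), and starts strictly
    more than ``min_cds_start`` bp along the CDS.  Returns ``s_start``.
    """
    if hit.strand != "+":
        return None
    if hit.q_start > max_q_start:
        return None
    if not (hit.q_end > min_end_frac * transcript_len
            or hit.s_end > min_end_frac * cds_len):
        return None
    if hit.s_start <= min_cds_start:
        return None
    return hit.s_start


def count_reads_at_point(reads: list[AlignedRead], gene_id: str, point: int,
                         sl: SLDefinition = KR01_SL) -> tuple[int, int]:
    """(SL-evidencing, non-SL) read counts at a truncation point.

    Reads counted are the filtered reads whose alignment covers the point;
    SL-evidencing means the read's conserved-region match places the SL
    addition at exactly that point.
    """
    n_sl = n_other = 0
    for r in reads:
        if r.target_id != gene_id or not r.covers(point):
            continue
        if read_site(r, sl) == point:
            n_sl += 1
        else:
            n_other += 1
    return n_sl, n_other


def classify_type(sl_read_count: int, non_sl_read_count: int) -> int:
    """Type 1 when SL-evidencing reads are the strict majority at the
    truncation point; ties and minorities are Type 2."""
    if sl_read_count + non_sl_read_count <= 0:
        raise ValueError("no reads at truncation point")
    return 1 if sl_read_count > non_sl_read_count else 2


def truncation_pipeline(
        trimmed_transcripts: dict[str, str],
        alignments: dict[str, TranscriptAlignment],
        genes: dict[str, GeneModel],
        hits: list[TabularHit],
        filtered_reads: list[AlignedRead],
        sl: SLDefinition = KR01_SL,
        min_identity: float = 95.0, min_aligned: float = 90.0,
        **scan_kwargs) -> list[TruncationEvent]:
    """Full truncation funnel: alignment validation, intron-chain matching,
    hit filtering, misprediction screening, and Type assignment.

    Events are emitted only for transcripts whose genome alignment validates,
    whose intron chain is equal to or contained in the reference gene's,
    whose CDS hit passes the truncation-point filters, and whose surrounding
    region scans clean for misprediction.
    """
    events: list[TruncationEvent] = []
    for hit in sorted(hits, key=lambda h: (h.query_id, h.subject_id)):
        tid, gid = hit.query_id, hit.subject_id
        if tid not in trimmed_transcripts or tid not in alignments:
            continue
        gene = genes.get(gid)
        if gene is None:
            logger.warning("hit subject %s has no gene model; skipped", gid)
            continue
        aln = alignments[tid]
        if not validate_alignment(aln, min_identity, min_aligned):
            continue
        if intron_chain_class(aln, gene) not in ("equal", "contained"):
            continue
        point = truncation_point_from_hit(
            hit, len(trimmed_transcripts[tid]), gene.cds_length)
        if point is None:
            continue
        report = scan_region(gene, point, filtered_reads, **scan_kwargs)
        if not report.clean:
            continue
        n_sl, n_other = count_reads_at_point(filtered_reads, gid, point, sl)
        if n_sl + n_other == 0:
            continue
        events.append(TruncationEvent(
            transcript_id=tid, gene_id=gid, truncation_point=point,
            sl_read_count=n_sl, non_sl_read_count=n_other,
            type=classify_type(n_sl, n_other),
            review_mean_nm=report.mean_nm,
            review_coverage_cv=report.coverage_cv))
    return events


def strip_poly_a(seq: str, min_run: int = 6) -> str:
    """Trivial terminal poly-A stripper: removes a trailing run of >=min_run
    A's (the full poly-A cleaning toolchain is out of scope)."""
    n = len(seq)
    i = n
    while i > 0 and seq[i - 1] == "A":
        i -= 1
    return seq[:i] if n - i >= min_run else seq
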