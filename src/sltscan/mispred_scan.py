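"""Sliding-window screen for mispredicted gene-model regions.

Ab initio gene prediction can extend a CDS 5' of the true start codon (into
or beyond the 5' UTR).  Such artificial extensions attract little or no RNA
read coverage, so a 20-base window (step 1) is slid over the region around an
anchor (an SL truncation point or addition site) and the reads that span the
*entire* window are counted; a window with fewer than 10 fully spanning reads
flags its 5'-most base as potentially mispredicted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .formats import AlignedRead, GeneModel


@dataclass
class MispredictionReport:
    """Windows failing the spanning-read test for one gene.

    ``flagged_positions`` holds the 1-based CDS position of the 5'-most base
    of each failing window; ``scanned_region`` is the inclusive interval that
    was examined.  ``mean_nm`` and ``coverage_cv`` are review statistics over
    the scanned region (the manual-curation signal: high mismatch levels or
    uneven coverage) and never trigger automatic removal.
    """

    gene_id: str
    flagged_positions: list[int]
    scanned_region: tuple[int, int]
    mean_nm: float = float("nan")
    coverage_cv: float = float("nan")

    @property
    def clean(self) -> bool:
        return not self.flagged_positions

    def min_distance(self, pos: int) -> float:
        """Distance from ``pos`` to the nearest flagged position (inf if none)."""
        if not self.flagged_positions:
            return math.inf
        return min(abs(p - pos) for p in self.flagged_positions)


def spanning_read_count(reads: list[AlignedRead], gene_id: str,
                        window: tuple[int, int]) -> int:
    """Count reads on ``gene_id`` whose aligned span covers ``window``
    entirely (soft-clipped bases do not count as aligned)."""
    s, e = window
    return sum(1 for r in reads
               if r.target_id == gene_id and r.start <= s and r.reference_end >= e)


def _review_stats(reads: list[AlignedRead], region: tuple[int, int]
                  ) -> tuple[float, float]:
    a, b = region
    if b < a:
        return float("nan"), float("nan")
    cov = np.zeros(b - a + 1)
    nms = []
    for r in reads:
        lo, hi = max(r.start, a), min(r.reference_end, b)
        if lo <= hi:
            cov[lo - a:hi - a + 1] += 1
            if r.edit_distance is not None:
                nms.append(r.edit_distance)
    mean_nm = float(np.mean(nms)) if nms else float("nan")
    m = cov.mean()
    cv = float(cov.std() / m) if m > 0 else float("nan")
    return mean_nm, cv


def _scan(gene_id: str, cds_len: int, region: tuple[int, int],
          reads: list[AlignedRead], window: int,
          min_spanning: int) -> MispredictionReport:
    a, b = region
    gene_reads = [r for r in reads if r.target_id == gene_id]
    # reads with an aligned span shorter than the window can never span it;
    # with them excluded, any remaining read ending before a window's right
    # edge necessarily starts at or before its left edge, so the spanning
    # count for [s, s+w-1] is #{start <= s} - #{end < s+w-1}
    long_reads = [r for r in gene_reads
                  if r.reference_end - r.start + 1 >= window]
    starts = np.sort(np.array([r.start for r in long_reads], dtype=int))
    ends = np.sort(np.array([r.reference_end for r in long_reads], dtype=int))
    flagged = []
    for s in range(a, b + 1):
        if s + window - 1 > b:
            break  # windows must lie entirely within the scanned region
        n_start_ok = int(np.searchsorted(starts, s, side="right"))
        n_end_short = int(np.searchsorted(ends, s + window - 1, side="left"))
        if n_start_ok - n_end_short < min_spanning:
            flagged.append(s)
    mean_nm, cv = _review_stats(gene_reads, region)
    return MispredictionReport(gene_id=gene_id, flagged_positions=flagged,
                               scanned_region=region, mean_nm=mean_nm,
                               coverage_cv=cv)


def scan_region(gene: GeneModel | tuple[str, int], anchor: int,
                reads: list[AlignedRead], window: int = 20,
                min_spanning: int = 10, upstream: int = 100,
                downstream: int = 50) -> MispredictionReport:
    """Scan the region around an anchor position for misprediction evidence.

    The region runs from ``upstream`` bases before the anchor to
    ``downstream`` after, clipped to the CDS; for anchors < 200 bp along the
    CDS the upstream bound is instead halfway between the CDS 5' end and the
    anchor (``ceil(anchor / 2)``).  A window fails when fewer than
    ``min_spanning`` reads span it end to end.
    """
    gene_id, cds_len = ((gene.gene_id, gene.cds_length)
                        if isinstance(gene, GeneModel) else gene)
    if not 1 <= anchor <= cds_len:
        raise ValueError(f"anchor {anchor} outside CDS 1..{cds_len}")
    start = math.ceil(anchor / 2) if anchor < 200 else anchor - upstream
    region = (max(start, 1), min(anchor + downstream, cds_len))
    return _scan(gene_id, cds_len, region, reads, window, min_spanning)


def scan_interval(gene: GeneModel | tuple[str, int], interval: tuple[int, int],
                  reads: list[AlignedRead], window: int = 20,
                  min_spanning: int = 10) -> MispredictionReport:
    """Apply the spanning-read window test to an arbitrary CDS interval
    (used when checking the stretch from a feature's 5' end to a site)."""
    gene_id, cds_len = ((gene.gene_id, gene.cds_length)
                        if isinstance(gene, GeneModel) else gene)
    a, b = interval
    if not (1 <= a and b <= cds_len and a <= b):
        raise ValueError(f"interval {interval} outside CDS 1..{cds_len}")
    return _scan(gene_id, cds_len, (a, b), reads, window, min_spanning)
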