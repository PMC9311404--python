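"""Calling SL addition sites on CDSs from filtered read alignments.

An SL addition site is the CDS position of the first transcript base retained
after the spliced leader.  Reads evidence a site in one of two ways: the
conserved SL 12-mer sits in the aligned 5' portion of the read and the first
base after it is mapped (the site is that base's reference position), or the
motif lies wholly within the read's 5' soft clip (the aligner trimmed the
leader because it does not match the CDS) and the site is the first mapped
base.  A position becomes a site when more than ``min_support`` retained
reads place it there and no mispredicted window lies nearby.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .formats import AlignedRead, GeneModel
from .mispred_scan import MispredictionReport, scan_region
from .sl_motif import KR01_SL, SLDefinition, find_sl_in_read

logger = logging.getLogger(__name__)

CONTEXT_CLASSES = ("position_1", "precise_junction", "near_junction", "internal")


@dataclass
class SLAdditionSite:
    """A supported SL attachment position on a CDS."""

    gene_id: str
    position: int
    supporting_reads: int
    depth: int
    support_fraction: float
    relative_position_pct: float
    context_class: str | None = None

    def __post_init__(self) -> None:
        if self.depth <= 0 or not 0 < self.support_fraction <= 1:
            raise ValueError("site must have depth > 0 and fraction in (0, 1]")
        if self.supporting_reads > self.depth:
            raise ValueError("supporting reads exceed depth")


# ---------------------------------------------------------------------------
# read-pair filtering
# ---------------------------------------------------------------------------

def filter_read_pairs(reads: list[AlignedRead]) -> list[AlignedRead]:
    """Retain concordant, well-aligned read pairs.

    A pair survives iff both mates are properly paired (SAM flag 0x2), each
    mate has at most 5 bp of soft clipping at its 3' end, and each has edit
    distance (NM) <= 5.  5' soft clips of any length are allowed, since the
    SL itself produces them.  Orphan mates are dropped and counted in the log.
    """
    by_id: dict[str, list[AlignedRead]] = defaultdict(list)
    for r in reads:
        by_id[r.read_id].append(r)
    kept: list[AlignedRead] = []
    orphans = 0
    for rid, mates in by_id.items():
        if len(mates) != 2:
            orphans += 1
            continue
        if all(m.properly_paired and m.clip3 <= 5
               and m.edit_distance is not None and m.edit_distance <= 5
               for m in mates):
            kept.extend(mates)
    if orphans:
        logger.info("filter_read_pairs: dropped %d orphan read groups", orphans)
    return kept


# ---------------------------------------------------------------------------
# per-read site extraction
# ---------------------------------------------------------------------------

def _ref_pos_after_offset(read: AlignedRead, offset: int) -> int | None:
    """Reference position (1-based) of the first aligned base at read offset
    >= ``offset`` (0-based, in stored orientation); None if no such base."""
    r, ref = 0, read.start
    want = offset
    for op, n in read.cigar:
        if op in ("S", "I"):
            if r <= want < r + n:
                want = r + n  # skip past unaligned stretch
            r += n
        elif op == "M":
            if want < r + n:
                return ref + max(want - r, 0)
            r += n
            ref += n
        elif op == "D":
            ref += n
    return None


def read_site(read: AlignedRead, sl: SLDefinition = KR01_SL) -> int | None:
    """CDS position evidenced by one read, or None.

    Searches the stored (reference-oriented) sequence for the conserved
    region; SL bases are mRNA sense so they appear forward on a CDS target
    regardless of mate strand.  Indels between motif end and the site resolve
    to the reference position of the first aligned base after the motif.
    """
    offset = find_sl_in_read(read.sequence, sl)
    if offset is None:
        return None
    return _ref_pos_after_offset(read, offset)


# ---------------------------------------------------------------------------
# site calling
# ---------------------------------------------------------------------------

def _depth_at(reads: list[AlignedRead], pos: int) -> int:
    return sum(1 for r in reads if r.covers(pos))


def call_sites(filtered_reads: list[AlignedRead],
               sl: SLDefinition = KR01_SL,
               min_support: int = 10,
               mispred: dict[str, MispredictionReport] | None = None,
               exclusion_distance: int = 100,
               cds_lengths: dict[str, int] | None = None,
               genes: dict[str, GeneModel] | None = None,
               near_window: int = 2) -> list[SLAdditionSite]:
    """Call SL addition sites from filtered reads.

    Positions supported by strictly more than ``min_support`` SL-evidencing
    reads are emitted, unless a flagged mispredicted position lies within
    ``exclusion_distance`` bp (inclusive: the paper keeps only sites
    *further than* that distance from a mispredicted region).  ``mispred``
    maps gene_id to a :class:`MispredictionReport`.  When ``genes`` is given
    each site's context class is filled via :func:`classify_junction`.
    """
    support: dict[tuple[str, int], int] = defaultdict(int)
    by_target: dict[str, list[AlignedRead]] = defaultdict(list)
    for r in filtered_reads:
        by_target[r.target_id].append(r)
        pos = read_site(r, sl)
        if pos is not None:
            support[(r.target_id, pos)] += 1
    if cds_lengths is None:
        cds_lengths = {}
    if genes:
        cds_lengths = {**{g: m.cds_length for g, m in genes.items()},
                       **cds_lengths}
    sites: list[SLAdditionSite] = []
    for (gene_id, pos), n_sl in sorted(support.items()):
        if n_sl <= min_support:
            continue
        if mispred is not None and gene_id in mispred:
            if mispred[gene_id].min_distance(pos) <= exclusion_distance:
                continue
        depth = _depth_at(by_target[gene_id], pos)
        L = cds_lengths.get(gene_id)
        rel = (pos - 1) / L * 100 if L else float("nan")
        ctx = None
        if genes and gene_id in genes:
            ctx = classify_junction(pos, genes[gene_id], near_window)
        sites.append(SLAdditionSite(
            gene_id=gene_id, position=pos, supporting_reads=n_sl, depth=depth,
            support_fraction=n_sl / depth, relative_position_pct=rel,
            context_class=ctx))
    return sites


def call_sites_with_mispred_screen(
        filtered_reads: list[AlignedRead],
        genes: dict[str, GeneModel],
        sl: SLDefinition = KR01_SL,
        min_support: int = 10,
        exclusion_distance: int = 100,
        window: int = 20, min_spanning: int = 10,
        upstream: int = 100, downstream: int = 50,
        near_window: int = 2) -> list[SLAdditionSite]:
    """Two-pass site calling: call support-passing candidates, scan each
    candidate's surrounding region for misprediction, then drop candidates
    with a flagged position within ``exclusion_distance``."""
    candidates = call_sites(filtered_reads, sl, min_support, mispred=None,
                            genes=genes, near_window=near_window)
    reports: dict[str, MispredictionReport] = {}
    for c in candidates:
        gene = genes.get(c.gene_id)
        if gene is None:
            continue
        rep = scan_region(gene, c.position, filtered_reads, window=window,
                          min_spanning=min_spanning, upstream=upstream,
                          downstream=downstream)
        prev = reports.get(c.gene_id)
        if prev is None:
            reports[c.gene_id] = rep
        else:  # merge flags from multiple anchors on one gene
            prev.flagged_positions = sorted(
                set(prev.flagged_positions) | set(rep.flagged_positions))
    return [c for c in candidates
            if c.gene_id not in reports
            or reports[c.gene_id].min_distance(c.position) > exclusion_distance]


def position_one_fold(site: SLAdditionSite, read_length: int = 150) -> bool:
    """Whether a site folds into the position-1 class.

    Position-1 sites conflate SL addition before the first CDS base with
    addition anywhere within one read length upstream of the start (the 5'
    UTR): CDS-aligned reads cannot distinguish them.
    """
    return site.position == 1


def classify_junction(position: int, gene: GeneModel,
                      near_window: int = 2) -> str:
    """Classify a site's position relative to exon boundaries in CDS space.

    Exon starts in CDS coordinates are 1 + cumulative exon-in-CDS lengths;
    position 1 is its own class, an exact match to a non-first exon start is
    ``precise_junction``, within ``near_window`` bp of one is
    ``near_junction``, anything else ``internal``.
    """
    if position == 1:
        return "position_1"
    cum = np.cumsum(gene.cds_piece_lengths()[:-1])
    starts = set(int(c) + 1 for c in cum)
    if position in starts:
        return "precise_junction"
    if any(abs(position - s) <= near_window for s in starts):
        return "near_junction"
    return "internal"


# ---------------------------------------------------------------------------
# summaries and the sequence-context logo
# ---------------------------------------------------------------------------

@dataclass
class SiteSummary:
    n_sites: int
    mean_support_pct: float
    mean_relative_position_pct: float
    mean_relpos_above_mean_support: float
    mean_relpos_below_mean_support: float


def summarize_sites(sites: list[SLAdditionSite]) -> SiteSummary:
    """Unweighted per-site means: support fraction (as a percent), relative
    CDS position, and the relative-position means of the above- and
    below-average-support groups (NaN when a group is empty)."""
    if not sites:
        raise ValueError("no sites to summarize")
    frac = np.array([s.support_fraction for s in sites]) * 100
    rel = np.array([s.relative_position_pct for s in sites])
    mean_frac = float(frac.mean())
    above = rel[frac > mean_frac]
    below = rel[frac < mean_frac]
    return SiteSummary(
        n_sites=len(sites),
        mean_support_pct=mean_frac,
        mean_relative_position_pct=float(rel.mean()),
        mean_relpos_above_mean_support=(float(above.mean()) if above.size
                                        else float("nan")),
        mean_relpos_below_mean_support=(float(below.mean()) if below.size
                                        else float("nan")))


BASES = "ACGT"


@dataclass
class LogoMatrix:
    """Base frequencies around SL addition sites (positions -flank..+flank,
    0 = the first base after the SL; the arrow position of a sequence logo).

    ``base_frequencies`` has shape (4, 2*flank+1) over rows A, C, G, T;
    ``information_bits`` is 2 minus the Shannon entropy per column.
    """

    positions: list[int]
    base_frequencies: np.ndarray
    information_bits: np.ndarray
    n_sites: int

    def frequency(self, base: str, position: int) -> float:
        return float(self.base_frequencies[BASES.index(base),
                                           self.positions.index(position)])


def logo_matrix(sites: list[SLAdditionSite], cds_sequences: dict[str, str],
                flank: int = 5) -> LogoMatrix:
    """Build the sequence-context matrix from internal sites.

    Only sites classified ``internal`` with a full +/- ``flank`` context
    inside the CDS are used (sites too close to either end are the "close to
    the end of the transcript" exclusions).  Information content per column
    is ``2 + sum f log2 f`` bits.
    """
    contexts = []
    for s in sites:
        if s.context_class is not None and s.context_class != "internal":
            continue
        seq = cds_sequences.get(s.gene_id)
        if seq is None:
            continue
        lo, hi = s.position - flank, s.position + flank  # 1-based inclusive
        if lo < 1 or hi > len(seq):
            continue
        contexts.append(seq[lo - 1:hi])
    if not contexts:
        raise ValueError("no usable sites for logo (all lack full flanks)")
    width = 2 * flank + 1
    counts = np.zeros((4, width))
    for ctx in contexts:
        for j, base in enumerate(ctx):
            if base in BASES:
                counts[BASES.index(base), j] += 1
    totals = counts.sum(axis=0)
    totals[totals == 0] = 1
    freqs = counts / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    info = 2.0 + plogp.sum(axis=0)
    return LogoMatrix(positions=list(range(-flank, flank + 1)),
                      base_frequencies=freqs, information_bits=info,
                      n_sites=len(contexts))


def write_logo_tsv(path, logo: LogoMatrix) -> None:
    with open(path, "w") as fh:
        fh.write("position\tA\tC\tG\tT\tinformation_bits\n")
        for j, p in enumerate(logo.positions):
            row = "\t".join(f"{logo.base_frequencies[i, j]:.6f}"
                            for i in range(4))
            fh.write(f"{p}\t{row}\t{logo.information_bits[j]:.6f}\n")


def plot_logo(path, logo: LogoMatrix) -> None:
    """Render the logo as information-scaled stacked letters (matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    fig, ax = plt.subplots(figsize=(7, 2.5))
    for j, pos in enumerate(logo.positions):
        heights = logo.base_frequencies[:, j] * logo.information_bits[j]
        order = np.argsort(heights)
        y = 0.0
        for i in order:
            h = heights[i]
            if h <= 0:
                continue
            base = BASES[i]
            ax.text(pos, y + h / 2, base, ha="center", va="center",
                    fontsize=6 + 14 * h / 2, color=colors[base],
                    fontweight="bold")
            y += h
    ax.axvline(-0.5, color="k", lw=0.8, ls="--")
    ax.set_xlim(logo.positions[0] - 1, logo.positions[-1] + 1)
    ax.set_ylim(0, 2)
    ax.set_xlabel("position relative to SL addition site")
    ax.set_ylabel("bits")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
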