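"""Synthetic SL trans-splicing datasets with planted ground truth.

The generator emulates the data the analysis consumes: a small multi-scaffold
genome with multi-exon gene models; stranded paired-end reads aligned locally
to the CDSs, where SL-evidencing reads carry 12-20 leader bases in a 5' soft
clip ending at the planted addition site; assembled transcripts (full-length
and SL-truncated) with their genome placements and CDS hits; protein feature
annotations; and per-gene expected counts with a planted group difference.
Every planted signal is recorded in a machine-readable truth manifest so
recovery can be scored exactly.

Reads are simulated directly as alignments (SAM), not FASTQ plus an external
aligner, so no alignment tool is a test dependency; :func:`export_fastq`
exists for users who want to run a real toolchain.  Fragments sample a 130-nt
5' UTR so that coverage is flat across the CDS start (the UTR bases appear as
5' soft clips, exactly as a local aligner would leave them).  Internal sites
are placed immediately after an AG dinucleotide, mimicking a cis-splicing
acceptor.  Recycled paralogs are intron-less copies of a source gene with a
full SL 20-mer planted fewer than 100 bp upstream.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import formats
from .formats import AlignedRead, FeatureAnnotation, GeneModel, GenomeSequence
from .sl_motif import FULL_SL, CONSERVED_SL, KR01_SL, SLDefinition
from .truncation import TranscriptAlignment

BASES = "ACGT"
NON_ATG_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES
                  if a + b + c != "ATG"]


# ---------------------------------------------------------------------------
# configuration and truth
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Knobs of the synthetic dataset.

    Defaults are the desk-scale study conditions: 60 genes (~0.2 Mb genome),
    2x150 bp reads at ~50x CDS coverage with zero sequencing error, half the
    genes carrying SL addition sites whose context mix follows the observed
    split (about 54% at CDS position 1, 26% at exon junctions, 20% at
    internal acceptor-mimic AG sites), planted support fractions of 0.3-0.9,
    and SL/non-SL expression means of 62.95 and 22.72 TPM.
    """

    seed: int = 1
    n_genes: int = 60
    n_scaffolds: int = 3
    exons_per_gene: tuple[int, int] = (1, 5)
    cds_length_range: tuple[int, int] = (600, 1800)
    min_exon_cds: int = 90
    intron_length_range: tuple[int, int] = (60, 150)
    intergenic_range: tuple[int, int] = (200, 500)
    utr_length: int = 130
    read_length: int = 150
    fragment_mean: float = 300.0
    fragment_sd: float = 30.0
    min_fragment: int = 160
    depth: float = 50.0
    error_rate: float = 0.0
    sl_gene_fraction: float = 0.5
    site_context_mix: dict = field(default_factory=lambda: {
        "position_1": 0.54, "junction": 0.26, "internal": 0.20})
    support_fraction_range: tuple[float, float] = (0.3, 0.9)
    min_sl_reads: int = 12
    n_mispredicted: int = 2
    mispredicted_extension: int = 120
    n_recycled: int = 2
    n_sl_loci: int = 3
    n_partial_loci: int = 3
    partial_length_range: tuple[int, int] = (10, 15)
    expression_mean_sl: float = 62.95
    expression_mean_other: float = 22.72
    expression_shape: float = 8.0
    n_replicates: int = 3

    def validate(self) -> None:
        if abs(sum(self.site_context_mix.values()) - 1.0) > 1e-9:
            raise ValueError("site context proportions must sum to 1")
        lo, hi = self.support_fraction_range
        if not 0 < lo <= hi <= 1:
            raise ValueError("support fractions must lie in (0, 1]")
        if self.cds_length_range[0] < 600:
            raise ValueError("CDS length minimum below 600 cannot host "
                             "truncation events and SL fragments")
        for name in ("n_genes", "n_mispredicted", "n_recycled",
                     "n_sl_loci", "n_partial_loci", "n_replicates"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class PlantedSite:
    gene_id: str
    position: int
    support_fraction: float  # realized: sl reads / reads covering position
    context_class: str


@dataclass
class PlantedEvent:
    transcript_id: str
    gene_id: str
    truncation_point: int
    type: int
    categories: list[str]


@dataclass
class TruthManifest:
    planted_sites: list[PlantedSite]
    mispredicted_genes: list[dict]       # {gene_id, true_cds_start_offset}
    sl_loci: list[dict]                  # {scaffold_id, start, end, strand}
    partial_loci: list[dict]             # + q_start, q_end
    recycled_paralogs: list[dict]        # {source_gene, new_gene, distance, ...}
    truncation_events: list[PlantedEvent]
    expression_groups: dict              # gene_id -> {group, mean}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            d = json.load(fh)
        d["planted_sites"] = [PlantedSite(**s) for s in d["planted_sites"]]
        d["truncation_events"] = [PlantedEvent(**e)
                                  for e in d["truncation_events"]]
        return cls(**d)

    @property
    def site_set(self) -> set[tuple[str, int]]:
        return {(s.gene_id, s.position) for s in self.planted_sites}

    @property
    def sl_gene_ids(self) -> set[str]:
        return {s.gene_id for s in self.planted_sites}


@dataclass
class SimResult:
    config: SimulationConfig
    outdir: Path
    genome: list[GenomeSequence]
    genes: list[GeneModel]
    true_cds: dict[str, str]      # sans mispredicted 5' extension
    transcripts: list[tuple[str, str]]
    alignments: dict[str, TranscriptAlignment]
    read_pairs: list[tuple[AlignedRead, AlignedRead]]
    hits: list[formats.TabularHit]
    features: list[FeatureAnnotation]
    counts: "object"              # pandas DataFrame, long format
    truth: TruthManifest


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _scrub_motif(seq: list[str], motif: str, rng: np.random.Generator,
                 protected: set[int]) -> None:
    """Destroy every occurrence of ``motif`` in place by mutating one
    unprotected base per occurrence."""
    k = len(motif)
    s = "".join(seq)
    i = s.find(motif)
    guard = 0
    while i >= 0 and guard < 10000:
        guard += 1
        targets = [j for j in range(i, i + k) if j not in protected]
        if targets:
            j = targets[len(targets) // 2]
            old = seq[j]
            seq[j] = BASES[(BASES.index(old) + 1 + int(rng.integers(0, 3))) % 4]
            if seq[j] == old:
                seq[j] = BASES[(BASES.index(old) + 1) % 4]
        s = "".join(seq)
        i = s.find(motif, i + 1 if not targets else max(i - k, 0))


# ---------------------------------------------------------------------------
# gene construction
# ---------------------------------------------------------------------------

@dataclass
class _GeneDraft:
    gene_id: str
    cds: list[str]                      # mutable sequence
    piece_lengths: list[int]            # exon-in-CDS lengths
    utr: list[str]
    sites: list[tuple[int, str, float]] = field(default_factory=list)
    planted_atg: list[int] = field(default_factory=list)
    control_atg: bool = False           # True: no in-frame ATG except planted
    mispredicted_ext: int = 0
    role: str = "plain"
    strand: str = "+"
    scaffold_id: str = ""
    genomic_exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def cds_str(self) -> str:
        return "".join(self.cds)

    @property
    def cds_len(self) -> int:
        return len(self.cds)

    def junction_starts(self) -> list[int]:
        cum = np.cumsum(self.piece_lengths[:-1])
        return [int(c) + 1 for c in cum]


def _split_lengths(rng, total: int, n: int, minimum: int) -> list[int]:
    """Random composition of ``total`` into n parts each >= minimum."""
    if n * minimum > total:
        n = max(1, total // minimum)
    extra = total - n * minimum
    if n == 1:
        return [total]
    cuts = np.sort(rng.integers(0, extra + 1, size=n - 1))
    parts = np.diff(np.concatenate([[0], cuts, [extra]]))
    return [minimum + int(p) for p in parts]


def _make_cds(rng, n_codons: int, control_atg: bool) -> list[str]:
    if control_atg:
        body = rng.integers(0, len(NON_ATG_CODONS), size=n_codons - 1)
        codons = ["ATG"] + [NON_ATG_CODONS[i] for i in body]
        return list("".join(codons))
    seq = ["A", "T", "G"] + list(_random_seq(rng, 3 * (n_codons - 1)))
    return seq


def _plant_ag(draft: _GeneDraft, pos: int, protected: set[int]) -> None:
    """Place the acceptor-mimic AG immediately 5' of CDS position ``pos``."""
    draft.cds[pos - 3] = "A"
    draft.cds[pos - 2] = "G"
    protected.update({pos - 3, pos - 2})


def _plant_atg(draft: _GeneDraft, pos: int, protected: set[int]) -> None:
    draft.cds[pos - 1:pos + 2] = ["A", "T", "G"]
    draft.planted_atg.append(pos)
    protected.update({pos - 1, pos, pos + 1})


def _scrub_gene(draft: _GeneDraft, rng, protected: set[int]) -> None:
    """Remove chance conserved-motif occurrences from the CDS, the UTR, and
    the UTR/CDS boundary (clipped reads straddle it) so planted SL evidence
    is the only motif signal."""
    _scrub_motif(draft.cds, CONSERVED_SL, rng, protected)
    _scrub_motif(draft.utr, CONSERVED_SL, rng, set())
    u = len(draft.utr)
    combined = draft.utr + draft.cds[:11]
    _scrub_motif(combined, CONSERVED_SL, rng, set(range(u, u + 11)))
    draft.utr[:] = combined[:u]


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def generate(config: SimulationConfig | None = None,
             outdir: str | Path = ".") -> SimResult:
    """Generate the full synthetic dataset into ``outdir``.

    Writes genome.fa, genes.gff3, cds.fa, transcripts.fa, reads.sam,
    alignments.tsv, hits.tsv, features.tsv, counts.tsv and truth.json.
    Deterministic given ``config.seed``: running twice produces byte-identical
    files.
    """
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sl = KR01_SL
    rl = cfg.read_length

    # ---- role assignment -------------------------------------------------
    n = cfg.n_genes
    n_event = 4 if n >= 12 else 0   # category constructs A, B, C, D
    n_sl = max(int(round(cfg.sl_gene_fraction * n)), n_event)
    ids = [f"g{i + 1:03d}" for i in range(n)]
    event_roles = ["catA", "catB", "catC", "catD"][:n_event]
    drafts: list[_GeneDraft] = []
    features: list[FeatureAnnotation] = []

    # non-SL genes supply mispredicted and recycling-source roles
    n_plain = n - n_sl
    if cfg.n_mispredicted + cfg.n_recycled > n_plain:
        raise ValueError("not enough non-SL genes for mispredicted + recycled "
                         "roles")

    for gi, gene_id in enumerate(ids):
        is_sl = gi < n_sl
        role = event_roles[gi] if gi < n_event else ("sl" if is_sl else "plain")
        if role.startswith("cat"):
            piece_lengths = [150, 300, 450]
            cds_len = 900
            control = True
        else:
            cds_len = 3 * int(rng.integers(cfg.cds_length_range[0] // 3,
                                           cfg.cds_length_range[1] // 3 + 1))
            n_ex = int(rng.integers(cfg.exons_per_gene[0],
                                    cfg.exons_per_gene[1] + 1))
            piece_lengths = _split_lengths(rng, cds_len, n_ex,
                                           cfg.min_exon_cds)
            control = False
        draft = _GeneDraft(
            gene_id=gene_id, cds=_make_cds(rng, cds_len // 3, control),
            piece_lengths=piece_lengths,
            utr=list(_random_seq(rng, cfg.utr_length)),
            control_atg=control, role=role)
        drafts.append(draft)

    plain = [d for d in drafts if d.role == "plain"]
    for d in plain[:cfg.n_mispredicted]:
        d.role = "mispred"
        d.mispredicted_ext = cfg.mispredicted_extension
        d.piece_lengths = [d.cds_len]  # single annotated exon
    recycle_sources = plain[cfg.n_mispredicted:
                            cfg.n_mispredicted + cfg.n_recycled]

    # ---- plant sites -----------------------------------------------------
    truth_sites_raw: list[tuple[str, int, str, float]] = []
    contexts = sorted(cfg.site_context_mix)
    probs = np.array([cfg.site_context_mix[c] for c in contexts])
    f_lo, f_hi = cfg.support_fraction_range

    def draw_f() -> float:
        return float(np.round(rng.uniform(f_lo, f_hi), 3))

    for draft in drafts:
        protected: set[int] = {0, 1, 2}
        if draft.role in ("plain", "mispred"):
            continue
        L = draft.cds_len
        if draft.role == "catA":
            specs = [(301, "internal", 0.6)]
            _plant_atg(draft, 391, protected)
            features.append(FeatureAnnotation(draft.gene_id,
                                              "targeting_signal", 1, 30,
                                              "mTP"))
        elif draft.role == "catB":
            specs = [(301, "internal", 0.6)]
            _plant_atg(draft, 313, protected)
            features.append(FeatureAnnotation(draft.gene_id, "domain", 10, 60,
                                              "PF_demo"))
        elif draft.role == "catC":
            specs = [(301, "internal", 0.4)]  # no downstream ATG planted
        elif draft.role == "catD":
            specs = [(301, "internal", 0.55), (601, "internal", 0.55)]
            _plant_atg(draft, 313, protected)
            _plant_atg(draft, 613, protected)
        else:  # generic SL gene
            ctx = contexts[int(rng.choice(len(contexts), p=probs))]
            # junction sites must leave room for SL fragments and mates
            junctions = [j for j in draft.junction_starts()
                         if j <= L - 280]
            if ctx == "junction" and not junctions:
                ctx = "internal"
            if ctx == "position_1":
                pos = 1
            elif ctx == "junction":
                pos = junctions[int(rng.integers(0, len(junctions)))]
            else:
                # codon-start positions clear of junctions and both CDS ends
                hi = L - max(280, rl + 10)
                cand = [p for p in range(130, hi + 1, 3)
                        if all(abs(p - j) > 3 for j in junctions)]
                pos = int(cand[int(rng.integers(0, len(cand)))])
            specs = [(pos, ctx, draw_f())]
        for pos, ctx, f in specs:
            if pos > draft.cds_len:
                raise ValueError(f"planted site {pos} deeper than CDS of "
                                 f"{draft.gene_id}")
            if ctx == "internal":
                _plant_ag(draft, pos, protected)
            draft.sites.append((pos, ctx, f))
            truth_sites_raw.append((draft.gene_id, pos, ctx, f))
        _scrub_gene(draft, rng, protected)

    for draft in drafts:
        if not draft.sites:
            _scrub_gene(draft, rng, {0, 1, 2})

    # ---- recycled paralogs ----------------------------------------------
    recycled: list[dict] = []
    for ri, src in enumerate(recycle_sources):
        rid = f"r{ri + 1:03d}"
        d = _GeneDraft(gene_id=rid, cds=list(src.cds),
                       piece_lengths=[src.cds_len],
                       utr=list(_random_seq(rng, cfg.utr_length)),
                       role="recycled")
        _scrub_gene(d, rng, {0, 1, 2})
        recycled.append({"source_gene": src.gene_id, "new_gene": rid,
                         "sl_upstream_distance": int(rng.integers(20, 81))})
        drafts.append(d)

    # ---- genome layout ---------------------------------------------------
    scaffold_parts: list[list[str]] = [[] for _ in range(cfg.n_scaffolds)]
    scaffold_len = [0] * cfg.n_scaffolds
    genes: list[GeneModel] = []
    rec_by_new = {r["new_gene"]: r for r in recycled}
    sl_loci: list[dict] = []

    def append_seq(si: int, seq: str) -> tuple[int, int]:
        start = scaffold_len[si] + 1
        scaffold_parts[si].append(seq)
        scaffold_len[si] += len(seq)
        return start, scaffold_len[si]

    for gi, draft in enumerate(drafts):
        si = gi % cfg.n_scaffolds
        scaf = f"scaffold_{si + 1}"
        draft.scaffold_id = scaf
        strand = "+" if rng.random() < 0.5 else "-"
        draft.strand = strand
        append_seq(si, _random_seq(
            rng, int(rng.integers(*cfg.intergenic_range))))
        rec = rec_by_new.get(draft.gene_id)
        if rec is not None and strand == "+":
            d = rec["sl_upstream_distance"]
            s, e = append_seq(si, FULL_SL)
            rec.update(scaffold_id=scaf, sl_start=s, sl_end=e, strand="+")
            if d > 1:
                append_seq(si, _random_seq(rng, d - 1))
        # annotated CDS (with any mispredicted 5' extension) becomes the
        # gene body; introns separate the exon pieces
        ext = draft.mispredicted_ext
        ext_seq = _random_seq(rng, ext)
        annotated = ext_seq + draft.cds_str
        pieces = list(draft.piece_lengths)
        pieces[0] += ext
        chunks, off = [], 0
        bounds = []
        for k, plen in enumerate(pieces):
            chunks.append(annotated[off:off + plen])
            bounds.append((off, off + plen))
            off += plen
        introns = [_random_seq(rng, int(rng.integers(
            *cfg.intron_length_range))) for _ in range(len(pieces) - 1)]
        pre = chunks[0] + "".join(i + c for i, c in zip(introns, chunks[1:]))
        # exon offsets within the pre-mRNA
        exon_off, off = [], 0
        for k, chunk in enumerate(chunks):
            exon_off.append((off, off + len(chunk)))
            off += len(chunk)
            if k < len(introns):
                off += len(introns[k])
        body = pre if strand == "+" else formats.revcomp(pre)
        g_s, g_e = append_seq(si, body)
        M = len(pre)
        exons = []
        for a, b in exon_off:  # 0-based half-open within pre
            if strand == "+":
                exons.append((g_s + a, g_s + b - 1))
            else:
                exons.append((g_s + (M - b), g_s + (M - a) - 1))
        exons.sort()
        draft.genomic_exons = exons
        genes.append(GeneModel(
            gene_id=draft.gene_id, scaffold_id=scaf, strand=strand,
            exons=exons, cds_intervals=list(exons), cds_sequence=annotated))
        if rec is not None and strand == "-":
            d = rec["sl_upstream_distance"]
            if d > 1:
                append_seq(si, _random_seq(rng, d - 1))
            s, e = append_seq(si, formats.revcomp(FULL_SL))
            rec.update(scaffold_id=scaf, sl_start=s, sl_end=e, strand="-")

    # planted SL RNA loci and decayed partial copies in scaffold tails
    partial_loci: list[dict] = []
    # tail fillers stay > 100 bp so planted loci never sit within recycling
    # distance of the last gene on a scaffold
    for li in range(cfg.n_sl_loci):
        si = li % cfg.n_scaffolds
        strand = "+" if li % 2 == 0 else "-"
        append_seq(si, _random_seq(rng, int(rng.integers(120, 200))))
        seq = FULL_SL if strand == "+" else formats.revcomp(FULL_SL)
        s, e = append_seq(si, seq)
        sl_loci.append({"scaffold_id": f"scaffold_{si + 1}", "start": s,
                        "end": e, "strand": strand})
    for li in range(cfg.n_partial_loci):
        si = li % cfg.n_scaffolds
        strand = "+" if li % 2 == 1 else "-"
        m = int(rng.integers(cfg.partial_length_range[0],
                             cfg.partial_length_range[1] + 1))
        frag = FULL_SL[-m:]
        q_start = 20 - m + 1
        # force a mismatch immediately 5' of the fragment so the maximal
        # exact run starts exactly at q_start
        prev_sl_base = FULL_SL[-m - 1]
        guard = BASES[(BASES.index(prev_sl_base) + 1) % 4]
        filler = _random_seq(rng, int(rng.integers(120, 200)))
        if strand == "+":
            append_seq(si, filler + guard)
            s, e = append_seq(si, frag)
        else:
            append_seq(si, filler)
            s, e = append_seq(si, formats.revcomp(frag))
            append_seq(si, formats.revcomp(guard))
        partial_loci.append({"scaffold_id": f"scaffold_{si + 1}", "start": s,
                             "end": e, "strand": strand,
                             "q_start": q_start, "q_end": 20})
    for si in range(cfg.n_scaffolds):
        append_seq(si, _random_seq(rng, 100))

    genome = [GenomeSequence(f"scaffold_{si + 1}", "".join(scaffold_parts[si]))
              for si in range(cfg.n_scaffolds)]

    # ---- reads -----------------------------------------------------------
    read_pairs: list[tuple[AlignedRead, AlignedRead]] = []
    coverage: dict[str, np.ndarray] = {}

    def add_errors(seq: list[str], aligned: slice) -> int:
        if cfg.error_rate <= 0:
            return 0
        nm = 0
        for j in range(aligned.start, aligned.stop):
            if rng.random() < cfg.error_rate:
                seq[j] = BASES[(BASES.index(seq[j]) + 1
                                + int(rng.integers(0, 3))) % 4]
                nm += 1
        return nm

    for draft in sorted(drafts, key=lambda d: d.gene_id):
        annotated = (_annotated_cds(draft))
        L = len(annotated)
        cov = np.zeros(L + 1, dtype=int)
        c0 = draft.mispredicted_ext + 1  # no reads over a 5' extension
        region = L - c0 + 1
        n_frag = int(round(cfg.depth * region / (2 * rl)))
        utr = "".join(draft.utr)
        u = len(utr)
        for i in range(n_frag):
            fl = int(np.clip(rng.normal(cfg.fragment_mean, cfg.fragment_sd),
                             cfg.min_fragment, region))
            t_lo = max(c0 - (u if c0 == 1 else 0), (rl + 1) - fl + (c0 - 1),
                       c0 - (rl - 20))
            t_hi = L - fl + 1
            if t_hi < t_lo:
                continue
            t = int(rng.integers(t_lo, t_hi + 1))
            rid = f"{draft.gene_id}:bg{i}"
            if t >= c0:
                seq1 = list(annotated[t - 1:t + rl - 1])
                nm1 = add_errors(seq1, slice(0, rl))
                r1 = AlignedRead(rid, draft.gene_id, t, [("M", rl)],
                                 "".join(seq1), True, nm1)
            else:
                clip = c0 - t
                seq1 = list(utr[u - clip:] + annotated[c0 - 1:
                                                       c0 - 1 + rl - clip])
                nm1 = add_errors(seq1, slice(clip, rl))
                r1 = AlignedRead(rid, draft.gene_id, c0,
                                 [("S", clip), ("M", rl - clip)],
                                 "".join(seq1), True, nm1)
            s2 = t + fl - rl
            seq2 = list(annotated[s2 - 1:s2 + rl - 1])
            nm2 = add_errors(seq2, slice(0, rl))
            r2 = AlignedRead(rid, draft.gene_id, s2, [("M", rl)],
                             "".join(seq2), True, nm2, is_reverse=True)
            cov[r1.start:r1.reference_end + 1] += 1
            cov[r2.start:r2.reference_end + 1] += 1
            read_pairs.append((r1, r2))
        coverage[draft.gene_id] = cov

    # SL-evidencing fragments; support counts are set from the realized
    # background depth so the planted fraction is met exactly
    realized_sites: list[PlantedSite] = []
    for draft in sorted(drafts, key=lambda d: d.gene_id):
        if not draft.sites:
            continue
        annotated = _annotated_cds(draft)
        L = len(annotated)
        cov = coverage[draft.gene_id]
        for pos, ctx, f in sorted(draft.sites):
            apos = pos + draft.mispredicted_ext
            d_bg = int(cov[apos])
            n_sl_reads = max(cfg.min_sl_reads,
                             int(round(f / (1 - f) * d_bg)) if f < 1 else
                             cfg.min_sl_reads + d_bg)
            for i in range(n_sl_reads):
                k = int(rng.integers(12, 21))
                rid = f"{draft.gene_id}:sl{pos}:{i}"
                seq1 = list(FULL_SL[-k:] + annotated[apos - 1:
                                                     apos - 1 + rl - k])
                nm1 = add_errors(seq1, slice(k, rl))
                r1 = AlignedRead(rid, draft.gene_id, apos,
                                 [("S", k), ("M", rl - k)],
                                 "".join(seq1), True, nm1)
                s2_lo = apos + 10
                s2_hi = min(apos + rl, L - rl + 1)
                s2 = int(rng.integers(s2_lo, max(s2_hi, s2_lo) + 1))
                seq2 = list(annotated[s2 - 1:s2 + rl - 1])
                nm2 = add_errors(seq2, slice(0, rl))
                r2 = AlignedRead(rid, draft.gene_id, s2, [("M", rl)],
                                 "".join(seq2), True, nm2, is_reverse=True)
                cov[r1.start:r1.reference_end + 1] += 1
                cov[r2.start:r2.reference_end + 1] += 1
                read_pairs.append((r1, r2))
            realized_sites.append(PlantedSite(
                gene_id=draft.gene_id, position=apos,
                support_fraction=n_sl_reads / (n_sl_reads + d_bg),
                context_class=ctx))

    # ---- transcripts, alignments, hits (truncation inputs) ---------------
    transcripts: list[tuple[str, str]] = []
    alignments: dict[str, TranscriptAlignment] = {}
    hits: list[formats.TabularHit] = []
    events: list[PlantedEvent] = []
    draft_by_id = {d.gene_id: d for d in drafts}
    gene_by_id = {g.gene_id: g for g in genes}
    cat_labels = {"catA": ["A"], "catB": ["B"], "catC": ["C"], "catD": ["D"]}

    for draft in sorted(drafts, key=lambda d: d.gene_id):
        if not draft.role.startswith("cat"):
            continue
        pos, ctx, f = sorted(draft.sites)[0]
        gene = gene_by_id[draft.gene_id]
        tid = f"t_{draft.gene_id}"
        lead = _random_seq(rng, int(rng.integers(0, 7)))
        trimmed = draft.cds_str[pos - 1:]
        transcripts.append((tid, lead + FULL_SL + trimmed))
        alignments[tid] = _alignment_for_suffix(gene, pos, tid)
        hits.append(formats.TabularHit(
            query_id=tid, subject_id=draft.gene_id, q_start=1,
            q_end=len(trimmed), s_start=pos, s_end=gene.cds_length,
            identity_pct=100.0, aln_length=len(trimmed)))
        n_sl_reads = sum(1 for r1, _ in read_pairs
                         if r1.read_id.startswith(f"{draft.gene_id}:sl{pos}:"))
        d_total = int(coverage[draft.gene_id][pos])
        ptype = 1 if n_sl_reads > d_total - n_sl_reads else 2
        events.append(PlantedEvent(
            transcript_id=tid, gene_id=draft.gene_id, truncation_point=pos,
            type=ptype, categories=sorted(cat_labels[draft.role])))

    # one full-length SL transcript: its hit starts at CDS base 1 and must
    # be rejected by the >100 bp truncation filter
    full_sl_drafts = [d for d in drafts
                      if any(p == 1 for p, _, _ in d.sites)]
    if full_sl_drafts:
        d0 = sorted(full_sl_drafts, key=lambda d: d.gene_id)[0]
        gene = gene_by_id[d0.gene_id]
        tid = f"t5_{d0.gene_id}"
        transcripts.append((tid, FULL_SL + d0.cds_str))
        alignments[tid] = TranscriptAlignment(
            transcript_id=tid, scaffold_id=gene.scaffold_id,
            strand=gene.strand, blocks=list(gene.exons),
            avg_identity_pct=100.0, percent_aligned=100.0)
        hits.append(formats.TabularHit(
            query_id=tid, subject_id=d0.gene_id, q_start=1,
            q_end=gene.cds_length, s_start=1, s_end=gene.cds_length,
            identity_pct=100.0, aln_length=gene.cds_length))

    # ---- expression ------------------------------------------------------
    import pandas as pd
    sl_gene_ids = {s.gene_id for s in realized_sites}
    rows = []
    expression_groups = {}
    for draft in sorted(drafts, key=lambda d: d.gene_id):
        group = "sl" if draft.gene_id in sl_gene_ids else "non_sl"
        mean = (cfg.expression_mean_sl if group == "sl"
                else cfg.expression_mean_other)
        expression_groups[draft.gene_id] = {"group": group, "mean": mean}
        L = len(_annotated_cds(draft))
        for rep in range(cfg.n_replicates):
            tpm_draw = rng.gamma(cfg.expression_shape,
                                 mean / cfg.expression_shape)
            rows.append({"gene_id": draft.gene_id,
                         "replicate_id": f"rep{rep + 1}",
                         "expected_count": round(tpm_draw * L / 1000, 3)})
    counts = pd.DataFrame(rows)

    # ---- truth + write ---------------------------------------------------
    truth = TruthManifest(
        planted_sites=realized_sites,
        mispredicted_genes=[{"gene_id": d.gene_id,
                             "true_cds_start_offset": d.mispredicted_ext}
                            for d in drafts if d.mispredicted_ext],
        sl_loci=sl_loci, partial_loci=partial_loci,
        recycled_paralogs=recycled, truncation_events=events,
        expression_groups=expression_groups)

    formats.write_fasta(outdir / "genome.fa",
                        [(g.scaffold_id, g.sequence) for g in genome])
    formats.write_gff3_genes(outdir / "genes.gff3", genes)
    formats.write_fasta(outdir / "cds.fa",
                        [(g.gene_id, g.cds_sequence) for g in genes])
    formats.write_fasta(outdir / "transcripts.fa", transcripts)
    formats.write_sam(outdir / "reads.sam", read_pairs,
                      {g.gene_id: g.cds_length for g in genes})
    write_alignments(outdir / "alignments.tsv", alignments)
    formats.write_tabular_hits(outdir / "hits.tsv", hits)
    formats.write_features(outdir / "features.tsv", features)
    formats.write_counts(outdir / "counts.tsv", counts)
    truth.to_json(outdir / "truth.json")

    return SimResult(config=cfg, outdir=outdir, genome=genome, genes=genes,
                     true_cds={d.gene_id: d.cds_str for d in drafts},
                     transcripts=transcripts, alignments=alignments,
                     read_pairs=read_pairs, hits=hits, features=features,
                     counts=counts, truth=truth)


def _annotated_cds(draft: _GeneDraft) -> str:
    # the 5' extension sequence is already folded into the gene model; for
    # read generation only the covered part matters, so pad with A's of the
    # right length (reads never touch the extension)
    return "A" * draft.mispredicted_ext + draft.cds_str


def _alignment_for_suffix(gene: GeneModel, pos: int,
                          tid: str) -> TranscriptAlignment:
    """Genome placement of the CDS suffix starting at CDS position ``pos``."""
    blocks: list[tuple[int, int]] = []
    # contiguous genomic runs of CDS positions pos..L
    gpos = [gene.cds_to_genomic(p) for p in range(pos, gene.cds_length + 1)]
    gpos.sort()
    start = prev = gpos[0]
    for g in gpos[1:]:
        if g == prev + 1:
            prev = g
        else:
            blocks.append((start, prev))
            start = prev = g
    blocks.append((start, prev))
    return TranscriptAlignment(
        transcript_id=tid, scaffold_id=gene.scaffold_id, strand=gene.strand,
        blocks=blocks, avg_identity_pct=100.0, percent_aligned=100.0)


# ---------------------------------------------------------------------------
# alignment TSV round-trip (blocks serialized as "s-e;s-e")
# ---------------------------------------------------------------------------

def write_alignments(path, alignments: dict[str, TranscriptAlignment]) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tscaffold_id\tstrand\tblocks\t"
                 "avg_identity_pct\tpercent_aligned\n")
        for tid in sorted(alignments):
            a = alignments[tid]
            blocks = ";".join(f"{s}-{e}" for s, e in a.blocks)
            fh.write(f"{tid}\t{a.scaffold_id}\t{a.strand}\t{blocks}\t"
                     f"{a.avg_identity_pct:.2f}\t{a.percent_aligned:.2f}\n")


def read_alignments(path) -> dict[str, TranscriptAlignment]:
    out: dict[str, TranscriptAlignment] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("transcript_id\t") or not line.strip():
                continue
            tid, scaf, strand, blocks, ident, aligned = \
                line.rstrip("\n").split("\t")
            bl = [tuple(int(x) for x in b.split("-"))
                  for b in blocks.split(";")]
            out[tid] = TranscriptAlignment(
                transcript_id=tid, scaffold_id=scaf, strand=strand,
                blocks=bl, avg_identity_pct=float(ident),
                percent_aligned=float(aligned))
    return out


def export_fastq(sim: SimResult, prefix: str | Path) -> None:
    """Write the simulated pairs as plain FASTQ (constant quality) for users
    who want to run a real alignment toolchain."""
    prefix = Path(prefix)
    with open(f"{prefix}_R1.fastq", "w") as f1, \
            open(f"{prefix}_R2.fastq", "w") as f2:
        for r1, r2 in sim.read_pairs:
            for fh, r in ((f1, r1), (f2, r2)):
                seq = formats.revcomp(r.sequence) if r.is_reverse else r.sequence
                fh.write(f"@{r.read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# end-to-end recovery
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    site_sensitivity: float
    site_precision: float
    n_sites_called: int
    truncation_sensitivity: float
    truncation_precision: float
    type_agreement: float
    category_agreement: float
    full_locus_sensitivity: float
    partial_locus_sensitivity: float
    recycling_sensitivity: float
    recycling_precision: float
    funnel: dict


def end_to_end_check(sim: SimResult) -> RecoveryReport:
    """Run the full pipeline from the files on disk and score recovery
    against the truth manifest (exact-match site and event coordinates)."""
    from . import consequence as cons
    from . import genome_survey as gs
    from . import site_caller as sc
    from . import sl_motif
    from . import truncation as trunc

    outdir = sim.outdir
    genome = [GenomeSequence(n, s)
              for n, s in formats.read_fasta(outdir / "genome.fa")]
    genes = formats.read_gff3_genes(outdir / "genes.gff3", genome)
    genes_d = {g.gene_id: g for g in genes}
    reads = formats.read_sam(outdir / "reads.sam")
    truth = TruthManifest.from_json(outdir / "truth.json")

    filtered = sc.filter_read_pairs(reads)
    sites = sc.call_sites_with_mispred_screen(filtered, genes_d)
    called = {(s.gene_id, s.position) for s in sites}
    planted = truth.site_set
    site_sens = len(called & planted) / len(planted) if planted else 1.0
    site_prec = len(called & planted) / len(called) if called else 1.0

    # truncation funnel
    raw_tx = dict(formats.read_fasta(outdir / "transcripts.fa"))
    trimmed: dict[str, str] = {}
    for tid, seq in sorted(raw_tx.items()):
        hit = sl_motif.find_sl_in_transcript(seq, transcript_id=tid)
        if hit is not None:
            trimmed[tid] = sl_motif.trim_sl(seq, hit)
    alignments = read_alignments(outdir / "alignments.tsv")
    hits = formats.read_tabular_hits(outdir / "hits.tsv")
    events = trunc.truncation_pipeline(trimmed, alignments, genes_d, hits,
                                       filtered)
    ev_called = {(e.gene_id, e.truncation_point) for e in events}
    ev_truth = {(e.gene_id, e.truncation_point)
                for e in truth.truncation_events}
    ev_sens = len(ev_called & ev_truth) / len(ev_truth) if ev_truth else 1.0
    ev_prec = len(ev_called & ev_truth) / len(ev_called) if ev_called else 1.0
    truth_types = {(e.gene_id, e.truncation_point): e.type
                   for e in truth.truncation_events}
    type_hits = [e.type == truth_types.get((e.gene_id, e.truncation_point))
                 for e in events
                 if (e.gene_id, e.truncation_point) in truth_types]
    type_agree = (sum(type_hits) / len(type_hits)) if type_hits else 1.0

    # categories
    feats = formats.read_features(outdir / "features.tsv")
    cds = dict(formats.read_fasta(outdir / "cds.fa"))
    sites_per_gene: dict[str, int] = {}
    for s in sites:
        sites_per_gene[s.gene_id] = sites_per_gene.get(s.gene_id, 0) + 1
    truth_cats = {(e.gene_id, e.truncation_point): set(e.categories)
                  for e in truth.truncation_events}
    cat_hits = []
    for e in events:
        key = (e.gene_id, e.truncation_point)
        if key not in truth_cats:
            continue
        call = cons.categorize(e, feats, cds[e.gene_id],
                               sites_per_gene.get(e.gene_id, 1))
        cat_hits.append(set(call.categories) == truth_cats[key])
    cat_agree = (sum(cat_hits) / len(cat_hits)) if cat_hits else 1.0

    # genome survey + recycling (exact scan so planted q_start is literal)
    g_hits = gs.scan_genome_for_sl(genome, max_mismatches=0)
    full_found = {(h.scaffold_id, h.start, h.end, h.strand) for h in g_hits
                  if h.classification == "full"}
    part_found = {(h.scaffold_id, h.start, h.end, h.strand, h.q_start)
                  for h in g_hits if h.classification == "partial"}
    full_truth = {(l["scaffold_id"], l["start"], l["end"], l["strand"])
                  for l in truth.sl_loci}
    full_truth |= {(r["scaffold_id"], r["sl_start"], r["sl_end"], r["strand"])
                   for r in truth.recycled_paralogs}
    part_truth = {(l["scaffold_id"], l["start"], l["end"], l["strand"],
                   l["q_start"]) for l in truth.partial_loci}
    full_sens = (len(full_found & full_truth) / len(full_truth)
                 if full_truth else 1.0)
    part_sens = (len(part_found & part_truth) / len(part_truth)
                 if part_truth else 1.0)

    cands = gs.recycling_candidates(g_hits, genes)
    cand_set = {(gid, d) for gid, _, d in cands}
    rec_truth = {(r["new_gene"], r["sl_upstream_distance"])
                 for r in truth.recycled_paralogs}
    rec_sens = (len(cand_set & rec_truth) / len(rec_truth)
                if rec_truth else 1.0)
    rec_prec = (len(cand_set & rec_truth) / len(cand_set)
                if cand_set else 1.0)

    funnel = {
        "reads_total": len(reads), "reads_filtered": len(filtered),
        "sites_called": len(sites),
        "transcripts_total": len(raw_tx), "transcripts_sl": len(trimmed),
        "events": len(events),
        "genome_hits": len(g_hits),
        "recycling_candidates": len(cands),
    }
    return RecoveryReport(
        site_sensitivity=site_sens, site_precision=site_prec,
        n_sites_called=len(sites),
        truncation_sensitivity=ev_sens, truncation_precision=ev_prec,
        type_agreement=type_agree, category_agreement=cat_agree,
        full_locus_sensitivity=full_sens,
        partial_locus_sensitivity=part_sens,
        recycling_sensitivity=rec_sens, recycling_precision=rec_prec,
        funnel=funnel)
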