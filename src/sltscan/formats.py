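"""Readers and writers for the external file formats used by the pipeline.

All genomic coordinates (GFF3, SAM, tabular hits) are 1-based inclusive;
any BED emitted is 0-based half-open.  CDS-relative positions used by the
rest of the package are in mRNA sense: the strand is resolved at load time,
so downstream code never sees a minus-strand coordinate system.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import gffutils

DNA_ALPHABET = set("ACGTN")

HIT_COLUMNS = [
    "query_id", "subject_id", "identity_pct", "aln_length", "mismatches",
    "gap_opens", "q_start", "q_end", "s_start", "s_end", "evalue", "bitscore",
]

FEATURE_KINDS = {"domain", "transmembrane", "coil", "targeting_signal"}


class FormatError(ValueError):
    """Raised for malformed input files."""


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeSequence:
    scaffold_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"empty sequence for scaffold {self.scaffold_id}")
        bad = set(self.sequence.upper()) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"non-DNA characters {sorted(bad)} in scaffold {self.scaffold_id}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A predicted gene: genomic exon/CDS structure plus its spliced CDS.

    ``exons`` and ``cds_intervals`` are 1-based inclusive genomic intervals,
    sorted ascending and non-overlapping.  ``cds_sequence`` is the
    mRNA-sense CDS (reverse-complemented for minus-strand genes).
    """

    gene_id: str
    scaffold_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds_intervals: list[tuple[int, int]]
    cds_sequence: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not self.exons:
            raise FormatError(f"gene {self.gene_id} has no exons")
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds_intervals = sorted(tuple(c) for c in self.cds_intervals)

    @property
    def cds_length(self) -> int:
        return len(self.cds_sequence)

    def _ordered_cds(self) -> list[tuple[int, int]]:
        """CDS intervals in transcription order."""
        return self.cds_intervals if self.strand == "+" else self.cds_intervals[::-1]

    def cds_piece_lengths(self) -> list[int]:
        """Lengths of CDS pieces in transcription order (exon-in-CDS lengths)."""
        return [e - s + 1 for s, e in self._ordered_cds()]

    def cds_to_genomic(self, pos: int) -> int:
        """Map a 1-based mRNA-sense CDS position to its genomic coordinate."""
        if not 1 <= pos <= self.cds_length:
            raise ValueError(f"CDS position {pos} outside 1..{self.cds_length}")
        off = pos - 1
        for s, e in self._ordered_cds():
            n = e - s + 1
            if off < n:
                return s + off if self.strand == "+" else e - off
            off -= n
        raise AssertionError("unreachable")

    def genomic_to_cds(self, gpos: int) -> int | None:
        """Inverse of :meth:`cds_to_genomic`; None if gpos is not a CDS base."""
        off = 0
        for s, e in self._ordered_cds():
            if s <= gpos <= e:
                return off + (gpos - s + 1 if self.strand == "+" else e - gpos + 1)
            off += e - s + 1
        return None


@dataclass
class AlignedRead:
    """A locally aligned read (SAM semantics; soft clips kept).

    ``cigar`` is an ordered list of ``(op, length)`` with op in M/I/D/S.
    ``edit_distance`` is the NM tag (mismatch + indel bases in the aligned
    portion; soft-clipped bases excluded).  ``is_reverse`` records SAM flag
    0x10 and orients the 5'/3' clip accessors.
    """

    read_id: str
    target_id: str
    start: int
    cigar: list[tuple[str, int]]
    sequence: str
    properly_paired: bool
    edit_distance: int | None
    mate_of: str | None = None
    is_reverse: bool = False

    def __post_init__(self) -> None:
        ops = [op for op, _ in self.cigar]
        inner = ops[1:-1] if len(ops) > 2 else []
        if "S" in inner:
            raise FormatError(f"internal soft clip in read {self.read_id}")
        read_len = sum(n for op, n in self.cigar if op in "MIS")
        if read_len != len(self.sequence):
            raise FormatError(
                f"CIGAR length {read_len} != sequence length "
                f"{len(self.sequence)} for read {self.read_id}")

    @property
    def leading_clip(self) -> int:
        return self.cigar[0][1] if self.cigar and self.cigar[0][0] == "S" else 0

    @property
    def trailing_clip(self) -> int:
        return self.cigar[-1][1] if self.cigar and self.cigar[-1][0] == "S" else 0

    @property
    def clip5(self) -> int:
        """Soft clip at the read's biological 5' end."""
        return self.trailing_clip if self.is_reverse else self.leading_clip

    @property
    def clip3(self) -> int:
        """Soft clip at the read's biological 3' end."""
        return self.leading_clip if self.is_reverse else self.trailing_clip

    @property
    def reference_end(self) -> int:
        """1-based inclusive rightmost reference position covered."""
        return self.start + sum(n for op, n in self.cigar if op in "MD") - 1

    def covers(self, pos: int) -> bool:
        return self.start <= pos <= self.reference_end


@dataclass
class TabularHit:
    """One row of BLAST outfmt-6-like tabular output."""

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    identity_pct: float
    aln_length: int

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise FormatError(
                f"q_start > q_end in hit {self.query_id} vs {self.subject_id}")
        if not 0.0 <= self.identity_pct <= 100.0:
            raise FormatError(f"identity {self.identity_pct} outside [0, 100]")

    @property
    def strand(self) -> str:
        return "+" if self.s_start <= self.s_end else "-"


@dataclass
class FeatureAnnotation:
    """A protein feature in 1-based inclusive amino-acid coordinates."""

    gene_id: str
    kind: str
    aa_start: int
    aa_end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise FormatError(f"unknown feature kind {self.kind!r}")
        if not 1 <= self.aa_start <= self.aa_end:
            raise FormatError(
                f"bad aa interval {self.aa_start}-{self.aa_end} on {self.gene_id}")

    @property
    def nt_start(self) -> int:
        """First CDS nucleotide of the feature (aa i -> nt 3i-2)."""
        return 3 * self.aa_start - 2

    @property
    def nt_end(self) -> int:
        return 3 * self.aa_end


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` preserving order."""
    try:
        return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    except ValueError as exc:  # Bio raises ValueError with offending content
        raise FormatError(f"malformed FASTA {path}: {exc}") from exc


def write_fasta(path, records) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta-2line")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3_genes(path, genome) -> list[GeneModel]:
    """Load gene models from GFF3 and extract their spliced CDS sequences.

    ``genome`` is a list of :class:`GenomeSequence` (or a mapping of
    scaffold_id to sequence string).  Exon rows out of order in the file are
    sorted on load; the spliced CDS is reverse-complemented for minus-strand
    genes so that ``cds_sequence`` is always mRNA sense.
    """
    if not isinstance(genome, dict):
        genome = {g.scaffold_id: g.sequence for g in genome}
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique")
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        exons, cds = [], []
        for child in db.children(gene.id, order_by="start"):
            if child.featuretype == "exon":
                exons.append((child.start, child.end))
            elif child.featuretype == "CDS":
                cds.append((child.start, child.end))
        if not exons:
            exons = [(gene.start, gene.end)]
        if not cds:
            cds = list(exons)
        seq = genome.get(gene.seqid)
        if seq is None:
            raise FormatError(f"scaffold {gene.seqid} absent from genome")
        for s, e in cds:
            if s < 1 or e > len(seq):
                raise FormatError(
                    f"CDS {s}-{e} of {gene.id} outside scaffold {gene.seqid} "
                    f"bounds 1-{len(seq)}")
        spliced = "".join(seq[s - 1:e] for s, e in sorted(cds))
        if gene.strand == "-":
            spliced = revcomp(spliced)
        genes.append(GeneModel(
            gene_id=gene.id, scaffold_id=gene.seqid, strand=gene.strand,
            exons=sorted(exons), cds_intervals=sorted(cds), cds_sequence=spliced))
    return genes


def write_gff3_genes(path, genes: list[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            span = (min(s for s, _ in g.exons), max(e for _, e in g.exons))
            fh.write(f"{g.scaffold_id}\tsltscan\tgene\t{span[0]}\t{span[1]}\t."
                     f"\t{g.strand}\t.\tID={g.gene_id}\n")
            fh.write(f"{g.scaffold_id}\tsltscan\tmRNA\t{span[0]}\t{span[1]}\t."
                     f"\t{g.strand}\t.\tID={g.gene_id}.t1;Parent={g.gene_id}\n")
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(f"{g.scaffold_id}\tsltscan\texon\t{s}\t{e}\t."
                         f"\t{g.strand}\t.\tID={g.gene_id}.e{i};"
                         f"Parent={g.gene_id}.t1\n")
            for i, (s, e) in enumerate(g.cds_intervals, 1):
                fh.write(f"{g.scaffold_id}\tsltscan\tCDS\t{s}\t{e}\t."
                         f"\t{g.strand}\t0\tID={g.gene_id}.c{i};"
                         f"Parent={g.gene_id}.t1\n")


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

_CIGAR_OPS = "MIDNSHP=X"


def read_sam(path, require_nm: bool = False) -> list[AlignedRead]:
    """Read a text SAM file; unmapped records are skipped.

    A mapped read lacking the NM tag gets ``edit_distance=None`` and a
    warning (such reads fail NM-based filters downstream); with
    ``require_nm=True`` it is an error instead.
    """
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            nm = rec.get_tag("NM") if rec.has_tag("NM") else None
            if nm is None:
                if require_nm:
                    raise FormatError(f"read {rec.query_name} lacks NM tag")
                warnings.warn(f"read {rec.query_name} lacks NM tag; "
                              "it will fail edit-distance filters")
            cigar = [(_CIGAR_OPS[op], n) for op, n in rec.cigartuples]
            reads.append(AlignedRead(
                read_id=rec.query_name,
                target_id=rec.reference_name,
                start=rec.reference_start + 1,
                cigar=cigar,
                sequence=rec.query_sequence,
                properly_paired=rec.is_proper_pair,
                edit_distance=nm,
                mate_of=rec.query_name if rec.is_paired else None,
                is_reverse=rec.is_reverse))
    return reads


def write_sam(path, reads_by_mate: list[tuple[AlignedRead, AlignedRead | None]],
              references: dict[str, int]) -> None:
    """Write read pairs as text SAM with proper flags and NM tags."""
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": name, "LN": ln} for name, ln in references.items()]}
    ref_ids = {name: i for i, name in enumerate(references)}

    def to_rec(read: AlignedRead, mate: AlignedRead | None, first: bool):
        rec = pysam.AlignedSegment()
        rec.query_name = read.read_id
        rec.query_sequence = read.sequence
        rec.reference_id = ref_ids[read.target_id]
        rec.reference_start = read.start - 1
        rec.mapping_quality = 60
        rec.cigartuples = [(_CIGAR_OPS.index(op), n) for op, n in read.cigar]
        flag = 0
        if mate is not None:
            flag |= 0x1 | (0x40 if first else 0x80)
            if read.properly_paired:
                flag |= 0x2
            if mate.is_reverse:
                flag |= 0x20
            rec.next_reference_id = ref_ids[mate.target_id]
            rec.next_reference_start = mate.start - 1
        if read.is_reverse:
            flag |= 0x10
        rec.flag = flag
        if read.edit_distance is not None:
            rec.set_tag("NM", int(read.edit_distance))
        return rec

    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r1, r2 in reads_by_mate:
            out.write(to_rec(r1, r2, True))
            if r2 is not None:
                out.write(to_rec(r2, r1, False))


# ---------------------------------------------------------------------------
# tabular
# ---------------------------------------------------------------------------

def read_tabular_hits(path) -> list[TabularHit]:
    """Read BLAST outfmt-6 (12 column, fixed order) tabular hits."""
    hits = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise FormatError(f"{path}: row {i}: expected 12 columns, "
                                  f"got {len(parts)}")
            hits.append(TabularHit(
                query_id=parts[0], subject_id=parts[1],
                identity_pct=float(parts[2]), aln_length=int(parts[3]),
                q_start=int(parts[6]), q_end=int(parts[7]),
                s_start=int(parts[8]), s_end=int(parts[9])))
    return hits


def write_tabular_hits(path, hits: list[TabularHit]) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join(map(str, [
                h.query_id, h.subject_id, f"{h.identity_pct:.2f}", h.aln_length,
                0, 0, h.q_start, h.q_end, h.s_start, h.s_end, "0.0", "0.0",
            ])) + "\n")


def read_features(path) -> list[FeatureAnnotation]:
    """Read protein feature annotations from TSV
    (gene_id, kind, aa_start, aa_end, label)."""
    feats = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}: row {i}: expected >=4 columns")
            feats.append(FeatureAnnotation(
                gene_id=parts[0], kind=parts[1],
                aa_start=int(parts[2]), aa_end=int(parts[3]),
                label=parts[4] if len(parts) > 4 else ""))
    return feats


def write_features(path, feats: list[FeatureAnnotation]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tkind\taa_start\taa_end\tlabel\n")
        for f in feats:
            fh.write(f"{f.gene_id}\t{f.kind}\t{f.aa_start}\t{f.aa_end}"
                     f"\t{f.label}\n")


def read_counts(path) -> pd.DataFrame:
    """Read per-gene expected counts (TSV: gene_id, replicate_id,
    expected_count) into a long-format DataFrame."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "replicate_id": str})
    expected = {"gene_id", "replicate_id", "expected_count"}
    if not expected <= set(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(expected)}")
    return df


def write_counts(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_bed6(path, rows) -> None:
    """Write (chrom, start0, end0, name, score, strand) rows as BED6
    (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom, s, e, name, score, strand in rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\t{score}\t{strand}\n")
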