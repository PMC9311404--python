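# Methods

This note documents the models, rules, defaults and numerical choices
implemented in `sltscan`, and what the synthetic-data tests do and do not
demonstrate about real data.

## The SL model

The spliced leader is modeled as a fixed 20-nt sequence
(`TGGATAATCCGGCTTTTCTG`) whose 3′ half (positions 9–20, `CCGGCTTTTCTG`) is
the operational detection motif: transcript 5′ ends assemble poorly, so the
full leader is rarely recovered intact, while the 3′ conserved region is.
Matching is exact — zero mismatches, `N` never matches — because the motif
is short and a single mismatch tolerance would admit far too many chance
hits (a 12-mer occurs by chance once per ~17 Mb per strand; with one
mismatch allowed, ~37× more often). Species differences are carried by
`SLDefinition`: the match motif, the maximum number of bases allowed to
precede it in a transcript (default 14, i.e. a 1-based motif start ≤ 15),
and the genome-survey "full-hit" start position (1 for KR01 and
*P. ovalis*; 2 for *P. chromatophora*, whose leader begins with C rather
than T).

Orientation: the forward strand of a transcript is tested first and the
reverse complement only if the forward test fails; if both orientations
happen to contain a valid motif, forward therefore wins. Multiple valid
matches within the 15-base window use the leftmost (this maximizes the
retained sequence) and the ambiguity is flagged in the hit record.

## Site calling from read alignments

Reads are assumed locally aligned to CDS sequences (SAM), so leader bases —
absent from the reference — surface as 5′ soft clips. The pair filter keeps
a pair only when both mates are properly paired (flag 0x2), have ≤ 5 bp of
3′ soft clipping and NM ≤ 5; unlimited 5′ clipping is deliberate, since an
SL-bearing read *should* be clipped there. Orienting "5′" vs "3′" clips
requires the SAM reverse flag, which the `AlignedRead` type retains.

A read places a site at the reference position of the first aligned base
after the conserved motif, walking the CIGAR so that insertions and
deletions between the motif end and the next aligned base resolve
correctly; a motif lying wholly within the 5′ clip places the site at the
read's first mapped base. A position becomes a site when **more than 10**
reads (≥ 11; the wording is strict) support it and no flagged mispredicted
window lies within 100 bp (inclusive: sites must be *further than* 100 bp
away). The support denominator is the number of retained reads whose
aligned span covers the position — "aligned reads at that position".

Sites at CDS position 1 form their own class: with UTR-less gene models,
CDS-aligned reads cannot distinguish SL addition at the start codon from
addition anywhere within one read length upstream, so position-1 sites
deliberately conflate true 5′-UTR trans-splicing with CDS-start events.

Exon context in CDS coordinates: exon starts are 1 + cumulative
exon-in-CDS lengths; a site exactly at a non-first exon start is a
`precise_junction`, within `near_window` (default 2 bp, configurable) a
`near_junction`, else `internal`. The distinction between "at a junction"
and "precisely at the splice site" has no published window, so the default
is a recorded package decision, not an external constant.

The sequence-context logo uses internal sites with a full ±5 bp flank
inside the CDS (sites closer to either end are excluded as "close to the
transcript end"). Information content per column is `2 + Σ f·log₂ f` bits.
Rendering is a small matplotlib letter-stack; the primary artifact is the
TSV matrix.

## Misprediction screening

Ab initio gene models in this lineage are frequently 5′-extended beyond the
true start, producing a stretch of CDS with no read support. The screen
slides a 20-base window (step 1) over the region from 100 bp upstream to
50 bp downstream of an anchor; when the anchor is < 200 bp along the CDS
the upstream bound is halfway between the CDS start and the anchor,
`ceil(anchor/2)` (the rounding direction is a package choice; the halfway
rule itself gives 75 for an anchor of 150). A window with fewer than 10
*fully spanning* reads — aligned span covering all 20 bases; soft-clipped
bases do not count — flags its 5′-most base. Windows are only evaluated
when they fit entirely inside the scanned region; a 20-base test cannot be
applied to a truncated window. The upstream manual-curation step (uneven
coverage, high mismatch levels) is surfaced as per-region review statistics
(mean NM, coverage CV) and never triggers automatic removal.

## Truncation events and Types

The truncation funnel mirrors the validated-alignment semantics of the
standard toolchain: alignments pass at average identity ≥ 95 % and
≥ 90 % of transcript bases aligned (both inclusive); intron chains must be
equal to a reference gene's or contained in it — a contiguous sub-list of
its introns with the transcript inside the gene's exonic span and terminal
blocks not crossing the bounding introns (a mono-exon transcript inside one
exon counts as contained). Transcript-vs-CDS hits are kept when they start
≤ 2 bp into the trimmed transcript, end > 95 % along the transcript *or*
the CDS (3′-UTR overrun tolerance), and start strictly > 100 bp along the
CDS; the retained `s_start` is the SL truncation point. Externally produced
outfmt-6 hit tables are accepted as-is, so the original toolchain can be
substituted for any stage. A clean misprediction scan around the point is
required before an event is emitted.

Type 1 means SL-evidencing reads are the strict majority at the truncation
point (the truncated variant out-expresses the full-length one); ties fall
to Type 2, since a tie is not a majority.

## Consequence categories

Protein features arrive in amino-acid coordinates and are converted as
aa *i* → nt [3i−2, 3i]. The retained start is the smallest in-frame ATG at
or after the truncation point. Category C covers both missing starts and a
retained protein shorter than `min_remaining` (default 0.25) of the
original — the threshold for "significantly shorter" is not published, so
it is an explicit, configurable package decision. Category A requires a
`targeting_signal` feature entirely 5′ of the retained start; B any
domain/transmembrane/coil whose 5′ end is upstream of it (removed *or*
truncated); D is ≥ 2 sites on the gene and can co-occur with A–C.
Overlapping or bookended features of one kind are merged before use.
Feature-relative site retrieval reproduces `closest -t first` tie behavior
(first feature in sorted order) and applies the > 60 nt offset rule for
sites overlapping a feature, measured in nucleotide space.

## Genome survey and recycling

The genome scanner reports, per strand, maximal ungapped matches of SL
substrings with length ≥ `min_hit_len` (default 8) and at most
`max_mismatches` (default 1) mismatches; these defaults emulate the
sensitivity of a short-word BLAST search, whose e-value model is out of
scope — external hit tables are accepted where exact fidelity to that
toolchain matters. Informative hits must end at SL position 20 (the 3′ end
is the conserved part); full hits start at or before the species start
position, later starts are partial. Partial hits are padded upstream,
strand-aware, to exactly 20 nt and discarded when a scaffold edge truncates
the window. Recycling candidates are genes with a > 70 %-coverage hit whose
SL-3′ end lies strictly between 0 and 100 bp upstream of the gene's
strand-aware 5′ start; hits overlapping the gene body or on the other
strand are excluded (overlap handling is unspecified upstream and is a
package decision).

## Expression

TPM is computed from expected counts and CDS lengths,
`tpm_i = (c_i/L_i)/Σ_j(c_j/L_j) × 10⁶`, normalized within each replicate;
per-gene expression is the arithmetic mean of per-replicate TPM (averaging,
not pooling — the source description is ambiguous between the two).
Zero-length genes are excluded with a warning. The SL vs non-SL comparison
is a two-sample Welch t-test computed in closed form (Welch–Satterthwaite
degrees of freedom) with the two-tailed p from the t distribution; tests
cross-check it against an independent reference implementation to 1e−10.

## The synthetic generator

The generator emulates the structure the analysis consumes, not sequencing
physics. Defaults (the study conditions for all recovery tests): 60 genes
on 3 scaffolds, CDS lengths 600–1800 nt in 1–5 exons, 2×150 bp pairs with
~300 ± 30 bp fragments at ~50× coverage, zero sequencing error, half of
genes carrying one SL site whose context mix follows the observed split
(54 % position 1, 26 % exon junction, 20 % internal), support fractions
0.3–0.9, two mispredicted genes (120-nt dead 5′ extensions), two recycled
paralogs, three full and three partial SL loci, and SL / non-SL expression
means of 62.95 / 22.72 in arbitrary TPM-proportional units (gamma noise,
shape 8, three replicates).

Design points worth knowing:

* **Reads are emitted directly as SAM**, so no aligner is a test
  dependency; a FASTQ export exists for users who want the real toolchain.
  Pairs are generated as forward + reverse mates with proper-pair flags and
  NM tags equal to the planted error count.
* **Fragments sample a 130-nt 5′ UTR**, appearing as 5′ soft clips exactly
  as a local aligner would leave them. This reproduces the read pile-up at
  CDS position 1 that real libraries show; without it, spanning-read
  coverage would ramp from zero at the CDS start and the misprediction
  screen would flag every gene's 5′ end.
* **SL-evidencing reads** carry 12–20 leader bases in a 5′ soft clip ending
  at the planted site. The number of such reads is set from the realized
  background depth so the planted support fraction is met exactly;
  position-1 sites get a floor of 12 supporting reads (mirroring the
  5′-end pile-up of complete transcripts), and the realized fraction is
  what the truth manifest records.
* **Internal sites sit immediately after a planted AG** dinucleotide
  (acceptor mimic), at codon-boundary positions so the edit cannot create
  an in-frame ATG.
* **Category constructs** are built codon-wise with no in-frame ATG except
  where planted, giving exact control of the retained start: a
  targeting-signal gene (A), a domain gene (B), an ATG-free tail (C), and a
  dual-site gene (D), at support fractions that make their planted Types
  both 1 and 2.
* **Chance motif hits are scrubbed**: any occurrence of the conserved
  12-mer in a CDS, UTR, or UTR/CDS boundary outside planted positions is
  destroyed by a single-base edit, so planted truth is the unique signal
  above threshold. Planted partial SL loci get a mismatching guard base at
  their 5′ flank so the maximal exact match starts exactly at the planted
  query position.
* **Determinism**: one `numpy` generator seeded from the config; the same
  seed produces byte-identical files.

What passing recovery tests shows: the decision rules, coordinate
arithmetic, and thresholds are implemented exactly, and under clean,
well-supported signals the pipeline is lossless. What it does not show:
robustness to sequencing error models, multi-mapping between paralogs,
alternative isoforms, uneven coverage, or assembly artifacts — the features
of real data that motivated the original manual-curation steps, which this
package surfaces as review statistics rather than automating.

## Problem sizes

All tests and the acceptance script run the default desk-scale conditions
(60 genes, ~28k reads, ~0.2 Mb genome); the full suite completes in well
under a minute on one CPU, and each seeded end-to-end run takes ~3 s. The
same code paths scale linearly in reads and genome length; the genome
scanner is vectorized per 20-mer diagonal.

## Known limitations

* UTR-aware site calling is out of scope beyond the position-1 convention;
  sites in 5′ UTRs are only visible when within one read length of the CDS.
* The internal genome scanner is not an e-value model; for survey counts
  that must match a BLAST run exactly, feed the external tabular hits in.
* Fuzzy or divergent SL variants are not detected (exact-match motif by
  design).
* The Welch comparison assumes per-gene mean TPM is the right unit; no
  multiple-testing machinery is included because a single test is
  performed.
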