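# sltscan

Detection and characterization of **spliced-leader trans-splicing (SLTS)**
from RNA-seq data, built around the biology of the photosynthetic amoeba
*Paulinella micropora* KR01. In SLTS, a short conserved spliced-leader (SL)
sequence — in *Paulinella*, the 20-mer `TGGATAATCCGGCTTTTCTG` donated by a
non-coding SL RNA — is spliceosomally attached to the 5′ end of pre-mRNAs.
When the acceptor site lies *inside* a coding region, the result is a
5′-truncated transcript whose protein product may lose a targeting peptide,
a functional domain, or its start codon entirely. `sltscan` finds these
events and predicts their consequences.

The package is for researchers working on trans-splicing, organellogenesis,
or gene-model curation in SL-bearing lineages (rhizarians, dinoflagellates,
euglenozoans, some metazoans) who have standard inputs — a genome, predicted
gene models, CDS-aligned reads (SAM), assembled transcripts, and tabular
BLAST-style hits — and want a tested, scriptable reimplementation of the
whole analysis rather than a pile of one-off shell commands.

## What it computes

* **SL detection and trimming** in assembled transcripts: an exact match of
  the conserved SL 3′ region (positions 9–20, `CCGGCTTTTCTG`) starting
  within the first 15 bases of the transcript (reverse complement checked
  when the forward strand fails); the leader and anything upstream of it is
  trimmed.
* **SL addition sites** on CDSs from locally aligned read pairs. Pairs are
  kept when both mates are properly paired, 3′ soft-clipping is ≤ 5 bp, and
  edit distance (NM) ≤ 5; 5′ clips of any length are allowed because the SL
  itself produces them. A read evidences the site at the first mapped base
  after the conserved motif (or at its first mapped base when the motif
  sits wholly inside the 5′ soft clip). Sites need **> 10** supporting
  reads and must lie > 100 bp from any mispredicted region. Each site gets
  a support fraction, a relative CDS position, and an exon-context class
  (position 1 / precise junction / near junction / internal), plus a ±5 bp
  sequence logo of internal sites (which recovers the canonical `AG`
  acceptor dinucleotide at −2/−1).
* **Gene-model misprediction screening**: a 20-base window slid at 1-bp
  steps over the −100/+50 bp neighborhood of an anchor (halfway to the CDS
  5′ end when the anchor is < 200 bp in); a window with < 10 fully spanning
  reads flags its 5′-most base.
* **SL-truncated transcripts**: transcript-to-genome alignments validated
  at ≥ 95 % identity and ≥ 90 % aligned, intron chains equal to or
  contained in a reference gene, and a transcript-vs-CDS hit starting ≤ 2
  bp into the transcript, ending > 95 % along transcript or CDS, and
  starting > 100 bp into the CDS (the *SL truncation point*). Events are
  **Type 1** when SL-evidencing reads are the majority at the point,
  **Type 2** otherwise.
* **Protein consequences** (Categories, co-occurring): **A** — targeting
  signal upstream of the retained start codon (retargeting); **B** — a
  domain/transmembrane/coil region removed or truncated; **C** — no
  in-frame downstream AUG, or a severely shortened product (translation
  suppression); **D** — multiple SL addition sites on one gene.
* **Genome survey**: full vs partial SL copies (full hits start at SL
  position 1 for KR01 / *P. ovalis*, position 2 for *P. chromatophora*;
  both must end at position 20), 20-bp padded extraction of partial hits,
  and **mRNA-recycling candidates** — genes with a > 70 %-coverage SL hit
  < 100 bp upstream of their 5′ end, the signature of a reverse-transcribed,
  reintegrated SL-bearing mRNA.
* **Expression**: per-gene TPM from expected counts,
  `tpm_i = (c_i/L_i) / Σ_j (c_j/L_j) × 10⁶`, and a two-sample Welch
  (unequal-variance) t-test of SL vs non-SL genes.

A first-class synthetic-data module generates a complete toy dataset —
genome, GFF3 gene models, CDS and transcript FASTA, SAM alignments, feature
and count tables — with every planted signal recorded in a JSON truth
manifest, so the entire pipeline is testable end to end in seconds.

## Worked example

```bash
sltscan demo --seed 1 --outdir demo_out
```

simulates 60 genes (~0.2 Mb genome, 2×150 bp pairs at ~50× coverage, 31
planted SL sites, 4 truncation constructs, 2 recycled paralogs) and runs
every stage. It prints, among other fields:

```json
{
 "site_sensitivity": 1.0,
 "site_precision": 1.0,
 "n_sites_called": 31,
 "truncation_sensitivity": 1.0,
 "type_agreement": 1.0,
 "category_agreement": 1.0,
 "recycling_sensitivity": 1.0,
 "funnel": {
  "reads_total": 27988,
  "reads_filtered": 27988,
  "sites_called": 31,
  "transcripts_total": 5,
  "transcripts_sl": 5,
  "events": 4,
  "recycling_candidates": 2
 }
}
```

Every planted SL addition site was called at its exact coordinate with no
false positives; all four planted truncation constructs came back with
their planted Type and Category labels; both planted recycled paralogs were
recovered. The individual stages are available as subcommands
(`find-sl`, `call-sites`, `scan-mispred`, `truncations`, `classify`,
`survey-genome`, `recycling`, `logo`, `expression`) for running on real
data; see `sltscan <cmd> --help`.

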