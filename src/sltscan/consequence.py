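"""Predicted protein consequences of SL truncation.

A truncated transcript can only be translated from an in-frame start codon
at or downstream of the truncation point.  Comparing the retained protein
with the full-length annotation yields four (co-occurring) categories:

* **A** — a targeting signal lies wholly upstream of the retained start:
  the protein loses its organelle-targeting leader (e.g. becomes cytosolic).
* **B** — a functional domain, transmembrane helix, or coiled-coil region
  begins upstream of the retained start: it is removed or truncated.
* **C** — no in-frame AUG remains downstream, or the retained protein is a
  small fraction of the original: translation is likely suppressed.
* **D** — the gene has multiple SL addition sites (may include A-C).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .formats import AlignedRead, FeatureAnnotation, GeneModel
from .mispred_scan import scan_interval
from .site_caller import SLAdditionSite
from .truncation import TruncationEvent


@dataclass
class ConsequenceCall:
    event: TruncationEvent
    retained_start: int | None
    remaining_fraction: float
    categories: frozenset[str]
    removed_features: list[FeatureAnnotation]


def downstream_start(cds_sequence: str, truncation_point: int) -> int | None:
    """Smallest in-frame ATG position at or after the truncation point.

    In-frame means position p with p == 1 (mod 3) in the CDS reading frame.
    Returns the 1-based CDS position of the A, or None if no in-frame start
    codon remains.
    """
    L = len(cds_sequence)
    if not 1 <= truncation_point <= L:
        raise ValueError(f"truncation point {truncation_point} outside CDS")
    p = truncation_point
    if p % 3 != 1:
        p += (1 - p) % 3  # next codon boundary
    seq = cds_sequence.upper()
    while p + 2 <= L:
        if seq[p - 1:p + 2] == "ATG":
            return p
        p += 3
    return None


def remaining_fraction(cds_len: int, retained_start: int | None) -> float:
    """Retained / full protein length; 0 when untranslatable."""
    if retained_start is None:
        return 0.0
    full_aa = cds_len // 3
    retained_aa = (cds_len - retained_start + 1) // 3
    return retained_aa / full_aa if full_aa else 0.0


def categorize(event: TruncationEvent, features: list[FeatureAnnotation],
               cds_sequence: str, n_sites_on_gene: int = 1,
               min_remaining: float = 0.25) -> ConsequenceCall:
    """Assign consequence categories A-D to a truncation event.

    Features are given in protein coordinates and converted to CDS
    nucleotides (aa i -> nt [3i-2, 3i]).  Categories may co-occur; D is
    independent of the others.
    """
    L = len(cds_sequence)
    gene_feats = [f for f in features if f.gene_id == event.gene_id]
    for f in gene_feats:
        if f.nt_end > L:
            raise ValueError(
                f"feature {f.label or f.kind} exceeds protein length on "
                f"{event.gene_id}")
    start = downstream_start(cds_sequence, event.truncation_point)
    frac = remaining_fraction(L, start)
    cats: set[str] = set()
    removed: list[FeatureAnnotation] = []
    if start is None or frac < min_remaining:
        cats.add("C")
    if start is not None:
        for f in gene_feats:
            if f.kind == "targeting_signal" and f.nt_end < start:
                cats.add("A")
                removed.append(f)
            elif f.kind in ("domain", "transmembrane", "coil") \
                    and f.nt_start < start:
                cats.add("B")
                removed.append(f)
    if n_sites_on_gene >= 2:
        cats.add("D")
    return ConsequenceCall(event=event, retained_start=start,
                           remaining_fraction=frac,
                           categories=frozenset(cats),
                           removed_features=removed)


def merge_features(features: list[FeatureAnnotation]
                   ) -> list[FeatureAnnotation]:
    """Merge overlapping or bookended features of the same kind per gene
    (interval union; labels joined with '+')."""
    by_key: dict[tuple[str, str], list[FeatureAnnotation]] = {}
    for f in features:
        by_key.setdefault((f.gene_id, f.kind), []).append(f)
    merged: list[FeatureAnnotation] = []
    for (gene_id, kind), fs in sorted(by_key.items()):
        fs = sorted(fs, key=lambda f: (f.aa_start, f.aa_end))
        cur_s, cur_e, labels = fs[0].aa_start, fs[0].aa_end, [fs[0].label]
        for f in fs[1:]:
            if f.aa_start <= cur_e + 1:  # overlap or bookended
                cur_e = max(cur_e, f.aa_end)
                if f.label and f.label not in labels:
                    labels.append(f.label)
            else:
                merged.append(FeatureAnnotation(
                    gene_id, kind, cur_s, cur_e,
                    "+".join(l for l in labels if l)))
                cur_s, cur_e, labels = f.aa_start, f.aa_end, [f.label]
        merged.append(FeatureAnnotation(
            gene_id, kind, cur_s, cur_e, "+".join(l for l in labels if l)))
    return merged


def sites_relative_to_features(
        sites: list[SLAdditionSite],
        features: list[FeatureAnnotation],
        genes: dict[str, GeneModel],
        filtered_reads: list[AlignedRead],
        min_offset: int = 60,
        window: int = 20, min_spanning: int = 10,
        ) -> tuple[list[tuple[SLAdditionSite, FeatureAnnotation]],
                   list[tuple[SLAdditionSite, FeatureAnnotation]]]:
    """Retrieve sites downstream of, or overlapping, protein features.

    Set 1: sites strictly downstream of their nearest upstream
    non-overlapping feature (``closest -t first`` tie behavior: first
    feature in sorted order wins), with the interval from the feature's 5'
    end to the site scanning clean for misprediction.

    Set 2: sites inside a feature, positioned strictly more than
    ``min_offset`` nt from the feature's 5' end, scan clean.

    Features should be pre-merged (:func:`merge_features`); offsets are
    measured in nucleotides on the CDS.
    """
    merged = merge_features(features)
    by_gene: dict[str, list[FeatureAnnotation]] = {}
    for f in merged:
        by_gene.setdefault(f.gene_id, []).append(f)
    for fs in by_gene.values():
        fs.sort(key=lambda f: (f.nt_start, f.nt_end, f.kind))
    downstream_set: list[tuple[SLAdditionSite, FeatureAnnotation]] = []
    overlap_set: list[tuple[SLAdditionSite, FeatureAnnotation]] = []
    for site in sites:
        gene = genes.get(site.gene_id)
        feats = by_gene.get(site.gene_id, [])
        if gene is None or not feats:
            continue
        pos = site.position
        upstreams = [f for f in feats if f.nt_end < pos]
        if upstreams:
            # nearest = greatest nt_end; ties broken by input (sorted) order
            best_end = max(f.nt_end for f in upstreams)
            nearest = next(f for f in upstreams if f.nt_end == best_end)
            rep = scan_interval(gene, (nearest.nt_start, pos),
                                filtered_reads, window, min_spanning)
            if rep.clean:
                downstream_set.append((site, nearest))
        overlapping = [f for f in feats if f.nt_start <= pos <= f.nt_end]
        if overlapping:
            f = overlapping[0]
            if pos - f.nt_start > min_offset:
                rep = scan_interval(gene, (f.nt_start, pos),
                                    filtered_reads, window, min_spanning)
                if rep.clean:
                    overlap_set.append((site, f))
    return downstream_set, overlap_set
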