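"""The spliced-leader (SL) sequence and its detection in transcripts and reads.

The *Paulinella* SL is a conserved 20-nt leader donated from a non-coding SL
RNA to the 5' end of pre-mRNAs.  Because assembled transcript 5' ends are
unreliable, only the well-recovered 3' conserved region (positions 9-20 of
the full leader) is matched, exactly and with no mismatches.  A transcript
qualifies if the conserved region starts within the first 15 bases (i.e. at
most 14 bases precede it); if the forward orientation has no valid match the
reverse complement is checked.
"""

from __future__ import annotations

from dataclasses import dataclass

from .formats import DNA_ALPHABET, revcomp

FULL_SL = "TGGATAATCCGGCTTTTCTG"
CONSERVED_SL = "CCGGCTTTTCTG"


@dataclass(frozen=True)
class SLDefinition:
    """The SL sequence and the species-specific matching rules.

    ``full_start_position`` is 1 for *P. micropora* KR01 and *P. ovalis* and
    2 for *P. chromatophora* (whose SL begins with C rather than T), used by
    the genome survey's full-hit rule.  ``max_leading_bases`` bounds how far
    from a transcript's 5' end the conserved region may start.
    """

    full_sequence: str = FULL_SL
    conserved_region: str = CONSERVED_SL
    full_start_position: int = 1
    max_leading_bases: int = 14

    def __post_init__(self) -> None:
        if not self.full_sequence.endswith(self.conserved_region):
            raise ValueError("conserved region must be a suffix of the full SL")
        if self.full_start_position not in (1, 2):
            raise ValueError("full_start_position must be 1 or 2")

    @property
    def conserved_length(self) -> int:
        return len(self.conserved_region)


KR01_SL = SLDefinition(full_start_position=1)
CHROMATOPHORA_SL = SLDefinition(full_start_position=2)

SPECIES_SL = {
    "kr01": KR01_SL,
    "ovalis": KR01_SL,
    "chromatophora": CHROMATOPHORA_SL,
}


@dataclass(frozen=True)
class SLHitInTranscript:
    """A validated SL match near a transcript's 5' end.

    ``conserved_start`` is the 1-based start of the conserved-region match on
    the *oriented* transcript (the reverse complement if
    ``orientation == "reverse_complement"``); ``trim_point`` is the first
    retained transcript base after the SL.  ``n_matches`` counts valid
    in-window matches (leftmost used; >1 flags ambiguity).
    """

    transcript_id: str
    orientation: str
    conserved_start: int
    trim_point: int
    n_matches: int = 1


def _check_alphabet(seq: str) -> None:
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")


def _valid_starts(seq: str, sl: SLDefinition) -> list[int]:
    """1-based starts of exact conserved-region matches within the lead
    window.  N never matches any motif base."""
    motif, k = sl.conserved_region, sl.conserved_length
    out = []
    for start0 in range(0, sl.max_leading_bases + 1):
        if seq[start0:start0 + k] == motif:
            out.append(start0 + 1)
    return out


def find_sl_in_transcript(seq: str, sl: SLDefinition = KR01_SL,
                          transcript_id: str = "") -> SLHitInTranscript | None:
    """Find a valid SL match in a transcript, checking forward then
    reverse-complement orientation.

    Returns None when neither orientation carries an exact conserved-region
    match starting at position <= max_leading_bases + 1.  When both
    orientations match, forward wins (the reverse complement is only
    consulted when the forward check fails); multiple in-window matches use
    the leftmost and are flagged via ``n_matches``.
    """
    seq = seq.upper()
    _check_alphabet(seq)
    if len(seq) < sl.conserved_length:
        return None
    for orientation, s in (("forward", seq), ("reverse_complement", revcomp(seq))):
        starts = _valid_starts(s, sl)
        if starts:
            return SLHitInTranscript(
                transcript_id=transcript_id, orientation=orientation,
                conserved_start=starts[0],
                trim_point=starts[0] + sl.conserved_length,
                n_matches=len(starts))
    return None


def trim_sl(seq: str, hit: SLHitInTranscript) -> str:
    """Remove the SL and all upstream bases, returning the oriented remainder
    (from ``trim_point`` to the transcript 3' end)."""
    seq = seq.upper()
    if hit.orientation == "reverse_complement":
        seq = revcomp(seq)
    return seq[hit.trim_point - 1:]


def find_sl_in_read(read_sequence: str, sl: SLDefinition = KR01_SL) -> int | None:
    """Leftmost exact occurrence of the conserved region in a read sequence.

    Returns the 0-based offset into the read of the first base *after* the
    match, or None if the motif is absent.
    """
    idx = read_sequence.upper().find(sl.conserved_region)
    if idx < 0:
        return None
    return idx + sl.conserved_length
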