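"""5' transcript-leader (TL) feature annotation.

The TL — the transcript sequence 5' of the principal start codon — carries
most of the cis-acting information governing ribosome recruitment.  This
module catalogues the features with documented translational impact:

* upstream AUG codons (uAUGs) and the upstream open reading frames (uORFs)
  they initiate, classified as *upstream* (terminates before the main
  start), *overlapping* (out of frame, runs into or past the main ORF), or
  *in_frame_extension* (in frame with the main ORF, no intervening stop —
  a potential N-terminal extension);
* the Kozak initiation context of each AUG: the -3 and +4 positions around
  the AUG dominate initiation efficiency, with the ideal context
  (A/G)CCATGG.  *strong* = purine at -3 and G at +4, *moderate* = exactly
  one of the two, *weak* = neither;
* cap-proximity: an AUG only a few nucleotides from the 5' cap is reached
  before the scanning 43S complex is competent to initiate, so such uAUGs
  are flagged (default threshold 15 nt).

Codon counts include the initiator AUG and exclude the stop, so the
printed size of a minimal AUG-stop uORF is 1 codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from translatome.io import TranscriptRecord, canonical_sequence

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
PURINES = frozenset("AG")

DEFAULT_CAP_THRESHOLD = 15


@dataclass
class UORFRecord:
    """One uAUG and the reading frame it opens."""

    start: int  # 0-based transcript offset of the uAUG
    frame: int  # (start - cds_start) mod 3; 0 = in frame with the main ORF
    orf_class: str  # upstream | overlapping | in_frame_extension
    n_codons: Optional[int]  # sense codons incl. the AUG, excl. the stop
    stop_end: Optional[int]  # offset one past the stop codon, when terminated
    gap_to_main: Optional[int]  # nt between stop and main AUG (upstream only)
    cap_distance: int  # = start
    kozak_class: str
    context: str  # 7-mer, positions -3..+4, N-padded at edges


@dataclass
class TLAnnotation:
    """Full TL report for one transcript."""

    transcript_id: str
    tl_length: int
    uaug_positions: list[int]
    uorfs: list[UORFRecord]
    main_kozak_class: str
    main_kozak_context: str
    cap_proximal_flags: list[int] = field(default_factory=list)


def extract_tl(record: TranscriptRecord) -> str:
    """The transcript leader: sequence[0, cds_start), possibly empty."""
    return record.sequence[: record.cds_start]


def scan_uaugs(tl: str) -> list[int]:
    """All 0-based offsets of ATG triplets in the TL, overlapping included."""
    tl = canonical_sequence(tl)
    hits = []
    pos = tl.find("ATG")
    while pos != -1:
        hits.append(pos)
        pos = tl.find("ATG", pos + 1)
    return hits


def classify_kozak(sequence: str, aug_pos: int) -> tuple[str, str]:
    """Kozak class and the -3..+4 context 7-mer for the AUG at aug_pos.

    Positions beyond the sequence ends are padded with N, which satisfies
    neither criterion.
    """
    sequence = canonical_sequence(sequence)
    if sequence[aug_pos : aug_pos + 3] != "ATG":
        raise ValueError(f"triplet at offset {aug_pos} is not ATG")
    padded = "NNN" + sequence + "NNN"
    context = padded[aug_pos : aug_pos + 7]  # -3 -2 -1 A T G +4
    minus3_purine = context[0] in PURINES
    plus4_g = context[6] == "G"
    if minus3_purine and plus4_g:
        cls = "strong"
    elif minus3_purine or plus4_g:
        cls = "moderate"
    else:
        cls = "weak"
    return cls, context


def _first_stop(sequence: str, start: int) -> Optional[int]:
    """Offset of the first in-frame stop codon at or after start, else None."""
    for pos in range(start, len(sequence) - 2, 3):
        if sequence[pos : pos + 3] in STOP_CODONS:
            return pos
    return None


def enumerate_uorfs(record: TranscriptRecord) -> list[UORFRecord]:
    """Enumerate and classify the uORF opened by every uAUG.

    Translation proceeds from each uAUG through the full transcript to the
    first in-frame stop; nested uAUGs sharing a stop each get their own
    record.
    """
    seq = record.sequence
    cds_start = record.cds_start
    records = []
    for start in scan_uaugs(extract_tl(record)):
        frame = (start - cds_start) % 3
        stop = _first_stop(seq, start)
        stop_end = None if stop is None else stop + 3
        n_codons: Optional[int] = None
        gap: Optional[int] = None
        if frame == 0 and (stop is None or stop_end > cds_start):
            # In frame with the main ORF and nothing terminates it first:
            # the uAUG extends the main protein N-terminally.
            orf_class = "in_frame_extension"
            stop_end = None
        elif stop_end is not None and stop_end <= cds_start:
            orf_class = "upstream"
            n_codons = (stop - start) // 3
            gap = cds_start - stop_end
        else:
            orf_class = "overlapping"
            if stop is not None:
                n_codons = (stop - start) // 3
        kozak_class, context = classify_kozak(seq, start)
        records.append(
            UORFRecord(
                start=start,
                frame=frame,
                orf_class=orf_class,
                n_codons=n_codons,
                stop_end=stop_end,
                gap_to_main=gap,
                cap_distance=start,
                kozak_class=kozak_class,
                context=context,
            )
        )
    return records


def annotate_transcript(
    record: TranscriptRecord, cap_threshold: int = DEFAULT_CAP_THRESHOLD
) -> TLAnnotation:
    """Assemble the complete TL annotation for one transcript."""
    uorfs = enumerate_uorfs(record)
    main_class, main_context = classify_kozak(record.sequence, record.cds_start)
    return TLAnnotation(
        transcript_id=record.transcript_id,
        tl_length=record.cds_start,
        uaug_positions=[u.start for u in uorfs],
        uorfs=uorfs,
        main_kozak_class=main_class,
        main_kozak_context=main_context,
        cap_proximal_flags=[u.start for u in uorfs if u.cap_distance < cap_threshold],
    )
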