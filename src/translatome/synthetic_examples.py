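"""Synthetic stand-in transcript leaders with published feature geometry.

These are NOT the real RefSeq transcripts: the nucleotide backgrounds are
random.  Only the *reported architecture* of each leader — uORF codon
counts, uORF-to-start spacing, cap-to-uAUG distances, leader lengths, and
the Kozak context of the main start — matches what has been described for
the TSS variants of the breast-cancer-associated genes 53BP1, WNT5B and
CLDN7:

* 53BP1 V3 — a 5-codon uORF ending 15 nt upstream of the main start.
* WNT5B V1 — two short uORFs of 1 and 3 codons, the second ending 62 nt
  upstream of a main AUG in an ACCATGC context.
* WNT5B V2 — a single 6-codon uORF whose uAUG sits only 12 nt from the
  5' cap.
* CLDN7 V1/3 — a 902-nt leader with no uAUG at all.
* CLDN7 V2 — a short leader carrying a 50-codon uORF.

Running the annotator on these constructs checks that it reports exactly
the published metrics under this package's conventions (codon counts
include the initiator AUG and exclude the stop; gaps count nucleotides
strictly between the stop codon and the main AUG).
"""

from __future__ import annotations

import numpy as np

from translatome.io import TranscriptRecord
from translatome.simulate import plant_transcript


def _set_main_context(record: TranscriptRecord, minus3: str, plus4: str) -> TranscriptRecord:
    """Rewrite the -3..-1 and +4 positions around the main start codon."""
    seq = list(record.sequence)
    cds = record.cds_start
    seq[cds - 3 : cds] = list(minus3)
    seq[cds + 3] = plus4
    return TranscriptRecord(
        record.transcript_id, record.gene_id, record.tss_id, "".join(seq), cds
    )


def worked_example_transcripts(seed: int = 0) -> dict[str, TranscriptRecord]:
    """Build the five synthetic stand-in leader variants, keyed by name."""
    rng = np.random.default_rng(seed)
    out: dict[str, TranscriptRecord] = {}

    # 53BP1 V3: 5-codon uORF (18 nt incl. stop) ending 15 nt before the start
    tl = 120
    rec, _ = plant_transcript(
        rng, tl, [(tl - 15 - 18, 5)], transcript_id="53BP1_V3", gene_id="53BP1", tss_id="TSS20205"
    )
    out["53BP1_V3"] = rec

    # WNT5B V1: 1-codon and 3-codon uORFs; second ends 62 nt before the start
    tl = 160
    rec, _ = plant_transcript(
        rng,
        tl,
        [(20, 1), (tl - 62 - 12, 3)],
        transcript_id="WNT5B_V1",
        gene_id="WNT5B",
        tss_id="WNT5B_TSS1",
    )
    out["WNT5B_V1"] = _set_main_context(rec, "ACC", "C")

    # WNT5B V2: one 6-codon uORF, uAUG 12 nt from the cap
    rec, _ = plant_transcript(
        rng, 80, [(12, 6)], transcript_id="WNT5B_V2", gene_id="WNT5B", tss_id="WNT5B_TSS2"
    )
    out["WNT5B_V2"] = rec

    # CLDN7 V1/3: 902-nt leader, no uAUG
    rec, _ = plant_transcript(
        rng, 902, [], transcript_id="CLDN7_V1_3", gene_id="CLDN7", tss_id="TSS14046"
    )
    out["CLDN7_V1_3"] = rec

    # CLDN7 V2: 50-codon uORF (153 nt incl. stop) in a shorter leader
    rec, _ = plant_transcript(
        rng, 200, [(20, 50)], transcript_id="CLDN7_V2", gene_id="CLDN7", tss_id="CLDN7_TSS2"
    )
    out["CLDN7_V2"] = rec
    return out
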