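"""Tidy report tables for the human-readable TSV outputs.

Internal coordinates are 0-based half-open; these reports convert to
1-based inclusive, the convention readers of annotation tables expect.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from translatome.tl_features import TLAnnotation


def tl_report(annotations: Sequence[TLAnnotation]) -> pd.DataFrame:
    """One summary row per transcript plus one row per uORF.

    uORF start/end are 1-based inclusive (end covers the stop codon).
    """
    rows = []
    for ann in annotations:
        rows.append(
            {
                "transcript_id": ann.transcript_id,
                "row_type": "transcript",
                "tl_length": ann.tl_length,
                "n_uaugs": len(ann.uaug_positions),
                "kozak_class": ann.main_kozak_class,
                "kozak_context": ann.main_kozak_context,
                "start": np.nan,
                "end": np.nan,
                "frame": np.nan,
                "orf_class": "",
                "n_codons": np.nan,
                "gap_to_main": np.nan,
                "cap_distance": np.nan,
                "cap_proximal": "",
            }
        )
        for u in ann.uorfs:
            rows.append(
                {
                    "transcript_id": ann.transcript_id,
                    "row_type": "uorf",
                    "tl_length": ann.tl_length,
                    "n_uaugs": len(ann.uaug_positions),
                    "kozak_class": u.kozak_class,
                    "kozak_context": u.context,
                    "start": u.start + 1,
                    "end": np.nan if u.stop_end is None else u.stop_end,
                    "frame": u.frame,
                    "orf_class": u.orf_class,
                    "n_codons": np.nan if u.n_codons is None else u.n_codons,
                    "gap_to_main": np.nan if u.gap_to_main is None else u.gap_to_main,
                    "cap_distance": u.cap_distance,
                    "cap_proximal": "yes" if u.start in ann.cap_proximal_flags else "no",
                }
            )
    return pd.DataFrame(rows)
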