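"""Annotate the simulated transcript leaders, check the planted uORFs are
recovered exactly, and annotate the synthetic worked-example leaders."""

from pathlib import Path

import pandas as pd

from translatome.io import read_transcript_table
from translatome.reports import tl_report
from translatome.synthetic_examples import worked_example_transcripts
from translatome.tl_features import annotate_transcript, enumerate_uorfs

SIM = Path("results/sim")
OUT = Path("results")


def main() -> None:
    records = read_transcript_table(SIM / "transcripts.fa", SIM / "transcripts.tsv")
    annotations = [annotate_transcript(r) for r in records]
    tl_report(annotations).to_csv(OUT / "tl_report.tsv", sep="\t", index=False)

    truth = pd.read_csv(SIM / "truth_tl_uorfs.tsv", sep="\t")
    found = sum(len(a.uorfs) for a in annotations)
    exact = 0
    by_tx = truth.groupby("transcript_id")
    for rec, ann in zip(records, annotations):
        want = (
            by_tx.get_group(rec.transcript_id)[["start", "n_codons"]].values.tolist()
            if rec.transcript_id in by_tx.groups
            else []
        )
        got = [[u.start, u.n_codons] for u in ann.uorfs]
        exact += got == sorted(want)
    print(f"{found} uORFs annotated across {len(records)} transcripts; "
          f"{exact}/{len(records)} transcripts match the planted truth exactly")

    print("\nsynthetic worked-example leaders:")
    for name, rec in worked_example_transcripts(seed=17).items():
        ann = annotate_transcript(rec)
        uorfs = [(u.n_codons, u.gap_to_main, u.orf_class) for u in ann.uorfs]
        print(f"  {name}: TL {ann.tl_length} nt, main Kozak {ann.main_kozak_context} "
              f"({ann.main_kozak_class}), uORFs (codons, gap, class) = {uorfs}")


if __name__ == "__main__":
    main()
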