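"""Generate the simulated polysome-profiling experiment used by the later steps.

Writes counts, sample sheet, transcripts, abundances, and the planted
ground truth under results/sim/.
"""

from pathlib import Path

from translatome.io import write_counts, write_sample_sheet, write_transcript_table
from translatome.simulate import SimSpec, simulate_counts, simulate_transcripts, simulate_usage

OUT = Path("results/sim")
SEED = 17


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = SimSpec(seed=SEED)

    counts, sheet, truth = simulate_counts(spec)
    write_counts(counts, OUT / "counts.tsv")
    write_sample_sheet(sheet, OUT / "samples.tsv")
    truth.write(OUT, prefix="truth_counts")
    n_reg = int(truth.genes["regulated"].sum())
    print(f"simulated {spec.n_genes} genes x {len(sheet.sample_ids)} samples "
          f"({n_reg} with a planted {spec.effect_size}-log2 TE shift)")

    records, truth_tx = simulate_transcripts(spec, n_transcripts=300)
    write_transcript_table(records, OUT / "transcripts.fa", OUT / "transcripts.tsv")
    truth_tx.write(OUT, prefix="truth_tl")
    print(f"simulated {len(records)} transcripts with {len(truth_tx.uorfs)} planted uORFs")

    abundances, _, usage_records, truth_usage = simulate_usage(spec)
    abundances.to_csv(OUT / "expr.tsv", sep="\t")
    write_transcript_table(usage_records, OUT / "usage_transcripts.fa", OUT / "usage_transcripts.tsv")
    truth_usage.write(OUT, prefix="truth_usage")
    n_shift = truth_usage.usage.groupby("gene_id")["shifted"].first().sum()
    print(f"simulated TSS usage for {spec.n_usage_genes} multi-TSS genes "
          f"({n_shift} with shifted polysomal usage)")


if __name__ == "__main__":
    main()
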