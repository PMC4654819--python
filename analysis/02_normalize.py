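"""Depth-equalise the simulated libraries and verify the conservation law."""

from pathlib import Path

import numpy as np

from translatome.io import read_counts, read_sample_sheet, write_counts
from translatome.normalization import compute_rescale_factors, downsample_counts

SIM = Path("results/sim")
OUT = Path("results")


def main() -> None:
    counts = read_counts(SIM / "counts.tsv")
    sheet = read_sample_sheet(SIM / "samples.tsv")
    factors = compute_rescale_factors(counts, sheet, grouping="by-fraction")
    norm = downsample_counts(counts, factors)
    factors.to_tsv(OUT / "rescale_factors.tsv")
    write_counts(norm, OUT / "normalized.tsv")

    print("rescale factors (depth / lowest group depth):")
    print(factors.table.to_string(index=False))
    sums = norm.to_frame().sum()
    for frac in ("total", "polysomal"):
        group = sums[sheet.samples_for(fraction=frac)].to_numpy()
        print(f"{frac}: column sums after down-sampling agree to "
              f"{np.ptp(group) / group.max():.2e} relative")


if __name__ == "__main__":
    main()
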