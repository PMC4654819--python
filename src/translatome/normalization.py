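"""Depth-equalising down-sampling normalisation.

Sequencing depth differs between libraries, so raw fragment counts are not
comparable across samples.  Each sample's counts are divided by a rescale
factor, the ratio of its depth to the lowest depth in its group:

    factor_n = x_n / min_i(x_i)

where x_n is the total number of assigned fragments in sample n.  The
division is deterministic (no stochastic sub-sampling) and leaves fractional
counts; after it, every sample in a group has the same column sum, and the
lowest-depth sample of each group is untouched.  Total and polysomal
libraries are normalised independently by default, because the two gradient
fractions have systematically different yields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from translatome.io import CountMatrix, SampleSheet


@dataclass
class RescaleFactors:
    """Per-sample depths, group minima, and rescale factors."""

    table: pd.DataFrame  # columns: sample_id, group, depth, group_min, factor

    def __post_init__(self) -> None:
        t = self.table
        if (t["factor"] < 1 - 1e-12).any():
            raise ValueError("rescale factor below 1; depths inconsistent with group minima")

    def factor_for(self, sample_id: str) -> float:
        row = self.table.loc[self.table["sample_id"] == sample_id, "factor"]
        if row.empty:
            raise KeyError(f"no rescale factor for sample {sample_id!r}")
        return float(row.iloc[0])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def compute_rescale_factors(
    counts: CountMatrix, sheet: SampleSheet, grouping: str = "by-fraction"
) -> RescaleFactors:
    """Compute per-sample rescale factors.

    grouping="by-fraction" takes the minimum depth separately within the
    total and within the polysomal libraries; "all" uses one global minimum.
    """
    if grouping not in ("by-fraction", "all"):
        raise ValueError(f"unknown grouping {grouping!r}")
    sheet.validate_against(counts)
    depth = counts.depth()
    zero = depth[depth <= 0]
    if not zero.empty:
        raise ValueError(f"zero-depth sample(s): {list(zero.index)}")
    frac_of = dict(zip(sheet.table["sample_id"], sheet.table["fraction"]))
    rows = []
    for sample_id in counts.sample_ids:
        group = frac_of[sample_id] if grouping == "by-fraction" else "all"
        rows.append({"sample_id": sample_id, "group": group, "depth": depth[sample_id]})
    table = pd.DataFrame(rows)
    table["group_min"] = table.groupby("group")["depth"].transform("min")
    table["factor"] = table["depth"] / table["group_min"]
    return RescaleFactors(table)


def downsample_counts(counts: CountMatrix, factors: RescaleFactors) -> CountMatrix:
    """Divide each sample's counts by its rescale factor.

    Counts are kept as reals; rounding would break the property that
    within-group column sums are identical after normalisation.
    """
    missing = set(counts.sample_ids) - set(factors.table["sample_id"])
    if missing:
        raise KeyError(f"no rescale factor for sample(s): {sorted(missing)}")
    fvec = np.array([factors.factor_for(s) for s in counts.sample_ids])
    return CountMatrix(
        list(counts.gene_ids), list(counts.sample_ids), counts.counts / fvec[np.newaxis, :]
    )
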