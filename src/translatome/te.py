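"""Translational efficiency (TE) and expression-binned Z-score calling.

TE for a gene in one condition is the ratio of its polysomal to its total
mean normalised count.  The statistic for differential translation is the
log2 fold change of TE between case and control,

    delta = log2( (E[case,poly]/E[case,total]) / (E[ctrl,poly]/E[ctrl,total]) ),

standardised against genes of similar expression: genes are sorted by their
minimum expression over the four condition x fraction means, grouped into
bins of 300, and each gene's Z-score is its delta standardised by the mean
and standard deviation of the deltas in its bin.  This compares a gene's TE
shift with the stochastic variation expected at its expression level, which
is much larger for weakly expressed genes.  |Z| > 2 (strict) calls a gene
up- or down-regulated in translation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from translatome.io import CONDITIONS, FRACTIONS, CountMatrix, SampleSheet

E_COLUMNS = [f"E_{c}_{f}" for c in CONDITIONS for f in FRACTIONS]

DEFAULT_BIN_SIZE = 300
DEFAULT_Z_THRESHOLD = 2.0


def summarize_expression(norm_counts: CountMatrix, sheet: SampleSheet) -> pd.DataFrame:
    """Per-gene mean normalised count for each condition x fraction cell.

    Returns a frame indexed by gene_id with columns E_case_total,
    E_case_polysomal, E_control_total, E_control_polysomal.
    """
    sheet.validate_against(norm_counts)
    frame = norm_counts.to_frame()
    out = pd.DataFrame(index=frame.index)
    out.index.name = "gene_id"
    for cond in CONDITIONS:
        for frac in FRACTIONS:
            samples = sheet.samples_for(cond, frac)
            if not samples:
                raise ValueError(f"no samples for condition={cond}, fraction={frac}")
            out[f"E_{cond}_{frac}"] = frame[samples].mean(axis=1)
    return out


def filter_genes(
    expression: pd.DataFrame, min_count: float = 0.0, pseudocount: float = 0.0
) -> pd.Series:
    """Mark genes analysable for TE.

    A gene is filtered when any of its four expression means, after adding
    the optional global pseudocount, is <= min_count.  The default
    (min_count=0, no pseudocount) drops exactly the genes with a zero cell,
    which would make a TE ratio undefined.

    Returns a boolean Series (True = analysable) aligned to the input.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    values = expression[E_COLUMNS] + pseudocount
    return (values > min_count).all(axis=1)


def compute_te_delta(expression: pd.DataFrame, log2: bool = True) -> pd.DataFrame:
    """TE per condition and the case/control TE fold change.

    Expects analysable genes only (all four E > 0).  With log2=True (the
    default) delta is the log2 TE ratio, making up- and down-regulation
    symmetric around 0; log2=False returns the raw ratio for sensitivity
    analysis.
    """
    E = expression
    if (E[E_COLUMNS] <= 0).any().any():
        bad = E.index[(E[E_COLUMNS] <= 0).any(axis=1)][0]
        raise ValueError(
            f"non-positive expression reached TE computation (gene {bad!r}); "
            "filter_genes must be applied first"
        )
    out = pd.DataFrame(index=E.index)
    out["TE_case"] = E["E_case_polysomal"] / E["E_case_total"]
    out["TE_control"] = E["E_control_polysomal"] / E["E_control_total"]
    ratio = out["TE_case"] / out["TE_control"]
    out["delta"] = np.log2(ratio) if log2 else ratio
    return out


def assign_bins(min_expressions: pd.Series, bin_size: int = DEFAULT_BIN_SIZE) -> pd.Series:
    """Group genes into expression bins of ``bin_size``.

    Genes are sorted ascending by minimum expression (ties broken by
    gene id for determinism) and cut into consecutive blocks; a trailing
    remainder smaller than bin_size is merged into the preceding bin so no
    bin has an unstable standard deviation.
    """
    n = len(min_expressions)
    if n < 2:
        raise ValueError("need at least 2 analysable genes to form a bin")
    if bin_size < 2:
        raise ValueError("bin_size must be >= 2")
    order = min_expressions.reset_index()
    order.columns = ["gene_id", "min_expression"]
    order = order.sort_values(["min_expression", "gene_id"], kind="mergesort")
    ranks = np.arange(n)
    bins = ranks // bin_size
    n_full = n // bin_size
    if n_full == 0:
        bins[:] = 0
    elif n % bin_size:
        bins[bins >= n_full] = n_full - 1  # merge remainder into last full bin
    result = pd.Series(bins, index=order["gene_id"].to_numpy(), name="bin_index")
    return result.reindex(min_expressions.index)


def binned_zscore(deltas: pd.Series, bin_indices: pd.Series) -> pd.Series:
    """Standardise each delta against its expression bin (sd with n-1)."""
    aligned = pd.DataFrame({"delta": deltas, "bin": bin_indices})
    if aligned.isna().any().any():
        raise ValueError("deltas and bin_indices must cover the same genes")
    grouped = aligned.groupby("bin")["delta"]
    mean = grouped.transform("mean")
    sd = grouped.transform(lambda x: x.std(ddof=1))
    sizes = grouped.size()
    small = sizes[sizes < 2]
    if not small.empty:
        raise ValueError(f"bin(s) with fewer than 2 genes: {list(small.index)}")
    zero_sd = aligned["bin"][sd == 0].unique()
    if len(zero_sd):
        raise ValueError(f"zero within-bin standard deviation in bin(s): {sorted(zero_sd)}")
    z = (aligned["delta"] - mean) / sd
    z.name = "z"
    return z


def classify_te(z: pd.Series, threshold: float = DEFAULT_Z_THRESHOLD) -> pd.Series:
    """Call each gene up/down/unchanged by strict |z| > threshold."""
    if not np.isfinite(z).all():
        raise ValueError("non-finite Z-score")
    calls = pd.Series("unchanged", index=z.index, name="call")
    calls[z > threshold] = "up"
    calls[z < -threshold] = "down"
    return calls


def run_te_analysis(
    norm_counts: CountMatrix,
    sheet: SampleSheet,
    bin_size: int = DEFAULT_BIN_SIZE,
    threshold: float = DEFAULT_Z_THRESHOLD,
    min_count: float = 0.0,
    pseudocount: float = 0.0,
    log2: bool = True,
) -> pd.DataFrame:
    """Full TE pipeline on a normalised count matrix.

    Returns one row per gene: the four expression means, min_expression,
    TE_case, TE_control, delta, bin_index, z, and call (with filtered genes
    carrying call='filtered' and NaN statistics).
    """
    expression = summarize_expression(norm_counts, sheet)
    analysable = filter_genes(expression, min_count=min_count, pseudocount=pseudocount)
    result = expression.copy()
    if pseudocount:
        result[E_COLUMNS] = result[E_COLUMNS] + pseudocount
    result["min_expression"] = result[E_COLUMNS].min(axis=1)
    for col in ("TE_case", "TE_control", "delta", "z"):
        result[col] = np.nan
    result["bin_index"] = pd.array([pd.NA] * len(result), dtype="Int64")
    result["call"] = "filtered"

    sub = result.loc[analysable]
    te = compute_te_delta(sub[E_COLUMNS], log2=log2)
    bins = assign_bins(sub["min_expression"], bin_size=bin_size)
    z = binned_zscore(te["delta"], bins)
    calls = classify_te(z, threshold=threshold)

    result.loc[analysable, ["TE_case", "TE_control", "delta"]] = te[
        ["TE_case", "TE_control", "delta"]
    ]
    result.loc[analysable, "bin_index"] = bins.astype("Int64")
    result.loc[analysable, "z"] = z
    result.loc[analysable, "call"] = calls
    return result
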