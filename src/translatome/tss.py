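"""TSS-usage fingerprints and polysome-gradient distributions.

A gene transcribed from several transcription start sites (TSSs) produces
mRNAs with different 5' transcript leaders.  The *TSS fingerprint* of a
gene in an RNA population is the vector of relative abundances of its TSS
variants.  Comparing fingerprints between the total RNA (transcriptome)
and the polysomal RNA (translatome), or between two cell states, reveals
selective ribosomal recruitment of particular leader variants.

Fingerprint differences are scored with the Jensen-Shannon divergence
(JSD, base-2 logs, range [0, 1]); an optional permutation test over
replicate labels attaches a descriptive p-value.  Gradient RT-PCR
intensity profiles across sucrose-gradient fractions are summarised as
normalised distributions with polysomal and heavy-polysomal mass shares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import rel_entr

from translatome.io import CONDITIONS, FRACTIONS, SampleSheet, TranscriptRecord


@dataclass
class TSSUsageProfile:
    """Per-gene TSS-variant abundances and proportions in each cell.

    ``abundance`` and ``proportions`` map (condition, fraction) to vectors
    aligned with ``tss_ids``; a cell with zero gene total has proportions
    None (undefined, not zero).  ``divergences`` holds the JSD between
    total and polysomal usage per condition and between case and control
    usage per fraction.
    """

    gene_id: str
    tss_ids: list[str]
    abundance: dict[tuple[str, str], np.ndarray]
    proportions: dict[tuple[str, str], Optional[np.ndarray]]
    divergences: dict[str, Optional[float]]
    pvalues: dict[str, float] | None = None


@dataclass
class GradientProfile:
    """Distribution of one transcript variant across gradient fractions."""

    variant_id: str
    fraction_labels: list[str]
    intensities: np.ndarray
    distribution: np.ndarray
    polysome_share: float
    heavy_share: float


def usage_divergence(p: Sequence[float], q: Sequence[float]) -> float:
    """Jensen-Shannon divergence between two proportion vectors, in bits.

    JSD(p, q) = H(m) - (H(p) + H(q))/2 with m = (p+q)/2 and base-2 logs;
    symmetric, 0 iff p == q, and at most 1.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError("p and q must be 1-D vectors of equal length")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("proportions must be non-negative")
    for name, v in (("p", p), ("q", q)):
        if abs(v.sum() - 1.0) > 1e-8:
            raise ValueError(f"{name} must sum to 1 (got {v.sum()!r})")
    m = 0.5 * (p + q)
    # rel_entr handles 0 log 0 = 0; convert nats to bits
    jsd = 0.5 * (rel_entr(p, m).sum() + rel_entr(q, m).sum()) / np.log(2.0)
    return float(min(max(jsd, 0.0), 1.0))


def _cell_means(
    abundances: pd.DataFrame, sheet: SampleSheet
) -> dict[tuple[str, str], pd.Series]:
    means = {}
    for cond in CONDITIONS:
        for frac in FRACTIONS:
            samples = sheet.samples_for(cond, frac)
            means[(cond, frac)] = abundances[samples].mean(axis=1)
    return means


def compute_usage(
    abundances: pd.DataFrame,
    transcripts: Sequence[TranscriptRecord],
    sheet: SampleSheet,
) -> list[TSSUsageProfile]:
    """TSS fingerprints for every multi-TSS gene.

    ``abundances`` is a transcript x sample table.  Transcripts sharing a
    tss_id are pooled; abundances are averaged over replicates per
    condition x fraction cell and converted to within-gene proportions.
    Genes with a single TSS carry no usage information and are excluded.
    """
    tx_meta = {t.transcript_id: (t.gene_id, t.tss_id) for t in transcripts}
    unknown = [t for t in abundances.index if t not in tx_meta]
    if unknown:
        raise ValueError(f"abundance table transcripts missing from the transcript table: {unknown[:5]}")
    if (abundances.to_numpy() < 0).any():
        raise ValueError("abundances must be non-negative")
    missing = set(sheet.sample_ids) - set(abundances.columns)
    if missing:
        raise ValueError(f"abundance table lacks sample column(s): {sorted(missing)}")

    meta = pd.DataFrame(
        [(tx, g, s) for tx, (g, s) in tx_meta.items() if tx in set(abundances.index)],
        columns=["transcript_id", "gene_id", "tss_id"],
    ).set_index("transcript_id")
    cell_means = _cell_means(abundances, sheet)

    profiles = []
    for gene_id, gene_meta in meta.groupby("gene_id", sort=True):
        tss_ids = sorted(gene_meta["tss_id"].unique())
        if len(tss_ids) < 2:
            continue
        abundance: dict[tuple[str, str], np.ndarray] = {}
        proportions: dict[tuple[str, str], Optional[np.ndarray]] = {}
        for cell, series in cell_means.items():
            vec = np.array(
                [
                    series[gene_meta.index[gene_meta["tss_id"] == tss]].sum()
                    for tss in tss_ids
                ]
            )
            abundance[cell] = vec
            total = vec.sum()
            proportions[cell] = vec / total if total > 0 else None
        divergences: dict[str, Optional[float]] = {}
        for cond in CONDITIONS:
            p, q = proportions[(cond, "total")], proportions[(cond, "polysomal")]
            divergences[f"jsd_total_vs_polysomal_{cond}"] = (
                usage_divergence(p, q) if p is not None and q is not None else None
            )
        for frac in FRACTIONS:
            p, q = proportions[("case", frac)], proportions[("control", frac)]
            divergences[f"jsd_case_vs_control_{frac}"] = (
                usage_divergence(p, q) if p is not None and q is not None else None
            )
        profiles.append(
            TSSUsageProfile(
                gene_id=gene_id,
                tss_ids=tss_ids,
                abundance=abundance,
                proportions=proportions,
                divergences=divergences,
            )
        )
    return profiles


def permutation_pvalue(
    group_a: Sequence[Sequence[float]],
    group_b: Sequence[Sequence[float]],
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Permutation p-value for the JSD between two groups of usage vectors.

    The statistic is the JSD between the two group-mean proportion vectors.
    Replicate labels are shuffled n_perm times; the add-one rule
    p = (1 + #{perm >= obs}) / (n_perm + 1) keeps p > 0 and makes the
    smallest attainable value 1/(n_perm+1).  Deterministic given seed.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("groups must be 2-D with matching vector length")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 replicates per group")

    def stat(x: np.ndarray, y: np.ndarray) -> float:
        p = x.mean(axis=0)
        q = y.mean(axis=0)
        return usage_divergence(p / p.sum(), q / q.sum())

    observed = stat(a, b)
    pooled = np.vstack([a, b])
    n_a = a.shape[0]
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        if stat(pooled[perm[:n_a]], pooled[perm[n_a:]]) >= observed - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def gradient_distribution(
    intensities: Sequence[float],
    fraction_labels: Sequence[str],
    polysome_mask: Sequence[bool],
    heavy_mask: Sequence[bool],
    variant_id: str = "",
) -> GradientProfile:
    """Normalise a gradient intensity vector and compute mass shares.

    ``polysome_mask`` marks the fractions at or beyond disomes;
    ``heavy_mask`` (a subset of it) marks the heavy-polysome fractions.
    The fraction boundaries are an experimental labelling choice, so the
    masks are supplied by the caller, never inferred.
    """
    x = np.asarray(intensities, dtype=float)
    poly = np.asarray(polysome_mask, dtype=bool)
    heavy = np.asarray(heavy_mask, dtype=bool)
    labels = list(fraction_labels)
    if not (len(x) == len(labels) == len(poly) == len(heavy)):
        raise ValueError("intensities, labels and masks must have equal length")
    if (x < 0).any():
        raise ValueError("intensities must be non-negative")
    if x.sum() == 0:
        raise ValueError("all-zero intensity vector")
    if (heavy & ~poly).any():
        raise ValueError("heavy fractions must be a subset of polysome fractions")
    dist = x / x.sum()
    return GradientProfile(
        variant_id=variant_id,
        fraction_labels=labels,
        intensities=x,
        distribution=dist,
        polysome_share=float(dist[poly].sum()),
        heavy_share=float(dist[heavy].sum()),
    )


def usage_report(profiles: Sequence[TSSUsageProfile]) -> pd.DataFrame:
    """Flatten usage profiles into a tidy per-gene-per-TSS report table."""
    rows = []
    for prof in profiles:
        for i, tss in enumerate(prof.tss_ids):
            row: dict = {"gene_id": prof.gene_id, "tss_id": tss}
            for (cond, frac), vec in prof.abundance.items():
                row[f"abundance_{cond}_{frac}"] = vec[i]
                props = prof.proportions[(cond, frac)]
                row[f"proportion_{cond}_{frac}"] = np.nan if props is None else props[i]
            for key, val in prof.divergences.items():
                row[key] = np.nan if val is None else val
            rows.append(row)
    return pd.DataFrame(rows)
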