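"""Ground-truthed synthetic data for every pipeline stage.

The generator emulates a polysome-profiling experiment: two cell states
(case/control), two gradient fractions (total/polysomal), three biological
replicates each, negative-binomial gene counts with unequal library depths,
a minority of genes carrying a planted multiplicative shift in
translational efficiency, transcript leaders with planted uAUGs/uORFs on
an ATG-free background, and multi-TSS genes with fraction-specific usage
proportions.  Every planted quantity is emitted in a :class:`SimTruth`
record so downstream recovery can be scored exactly.

Counts are negative binomial with variance mu + phi*mu^2 (phi = dispersion,
default 0.1, a typical bulk RNA-seq value); phi = 0 falls back to Poisson.
A single master seed drives everything through fixed per-component
substreams, so identical specs give bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from translatome.io import (
    CONDITIONS,
    FRACTIONS,
    CountMatrix,
    SampleSheet,
    TranscriptRecord,
)

_STOPS = ("TAA", "TAG", "TGA")
_BASES = np.array(list("ACGT"))

# fixed substream keys so the three generators never share a random stream
_STREAM_COUNTS = 0
_STREAM_TRANSCRIPTS = 1
_STREAM_USAGE = 2


@dataclass
class SimSpec:
    """Parameters of the simulated experiment.

    Defaults mirror the profiled design: 3 biological replicates per
    condition x fraction, overdispersed counts (phi=0.1), a 5% minority of
    genes with a 2-log2-unit TE shift planted on well-expressed genes
    (baseline mean >= 50), and library depths varying about 2-fold.
    """

    n_genes: int = 6000
    n_replicates: int = 3
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 2.0
    dispersion: float = 0.1
    libsize_range: tuple[float, float] = (0.7, 1.4)
    fraction_regulated: float = 0.05
    effect_size: float = 2.0
    regulated_min_mean: float = 50.0
    # transcript-leader simulation
    tl_length_range: tuple[int, int] = (60, 300)
    uorf_count_probs: tuple[float, ...] = (0.45, 0.35, 0.20)  # P(0), P(1), P(2) uORFs
    uorf_codon_range: tuple[int, int] = (1, 20)
    gc_content: float = 0.5
    # TSS-usage simulation
    n_usage_genes: int = 200
    fraction_shifted: float = 0.2
    usage_dispersion: float = 0.05
    usage_concentration: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_replicates < 1:
            raise ValueError("n_genes and n_replicates must be positive")
        if self.dispersion < 0 or self.usage_dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for frac in (self.fraction_regulated, self.fraction_shifted):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must lie in (0, 1)")
        lo, hi = self.libsize_range
        if lo <= 0 or hi < lo:
            raise ValueError("libsize_range must be positive and ordered")
        if abs(sum(self.uorf_count_probs) - 1.0) > 1e-9:
            raise ValueError("uorf_count_probs must sum to 1")
        lo, hi = self.uorf_codon_range
        if lo < 1 or hi < lo:
            raise ValueError("uorf_codon_range must be >= 1 and ordered")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stream,)))


@dataclass
class SimTruth:
    """Planted ground truth emitted alongside a simulated dataset."""

    genes: Optional[pd.DataFrame] = None  # gene_id, baseline_mean, true_delta, regulated
    library_factors: Optional[pd.DataFrame] = None  # sample_id, factor
    uorfs: Optional[pd.DataFrame] = None  # transcript-level planted uORF coordinates
    transcripts: Optional[pd.DataFrame] = None  # transcript_id, tl_length, n_uorfs
    usage: Optional[pd.DataFrame] = None  # gene x tss true proportions per cell

    def write(self, outdir: str | Path, prefix: str = "truth") -> None:
        outdir = Path(outdir)
        for name in ("genes", "library_factors", "uorfs", "transcripts", "usage"):
            frame = getattr(self, name)
            if frame is not None:
                frame.to_csv(outdir / f"{prefix}_{name}.tsv", sep="\t", index=False)


def _make_sheet(n_replicates: int) -> SampleSheet:
    rows = [
        {
            "sample_id": f"{cond}_{frac}_{rep}",
            "condition": cond,
            "fraction": frac,
            "replicate": rep,
        }
        for cond in CONDITIONS
        for frac in FRACTIONS
        for rep in range(1, n_replicates + 1)
    ]
    return SampleSheet(pd.DataFrame(rows))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mean + dispersion*mean^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(spec: SimSpec) -> tuple[CountMatrix, SampleSheet, SimTruth]:
    """Simulate the paired total/polysomal count experiment.

    Total-fraction means are drawn per gene from a log2-normal baseline and
    shared between conditions; the polysomal mean is the total mean times
    the gene's TE, which is 1 in control and 2**(+-effect_size) for the
    regulated minority in case.  Planting the effect on the polysomal mean
    only keeps transcription and translation separable in the truth table.
    """
    rng = spec.rng(_STREAM_COUNTS)
    gene_ids = [f"g{i:05d}" for i in range(spec.n_genes)]
    baseline = 2.0 ** rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd, spec.n_genes)

    n_regulated = int(round(spec.fraction_regulated * spec.n_genes))
    eligible = np.flatnonzero(baseline >= spec.regulated_min_mean)
    if n_regulated > len(eligible):
        raise ValueError(
            f"cannot plant {n_regulated} regulated genes: only {len(eligible)} genes "
            f"have baseline mean >= {spec.regulated_min_mean}"
        )
    regulated = rng.choice(eligible, size=n_regulated, replace=False) if n_regulated else np.array([], dtype=int)
    direction = np.zeros(spec.n_genes)
    if n_regulated:
        signs = rng.choice([-1.0, 1.0], size=n_regulated)
        direction[regulated] = signs
    true_delta = direction * spec.effect_size

    sheet = _make_sheet(spec.n_replicates)
    lo, hi = spec.libsize_range
    lib = {s: rng.uniform(lo, hi) for s in sheet.sample_ids}

    columns = {}
    for row in sheet.table.itertuples(index=False):
        mu = baseline.copy()
        if row.fraction == "polysomal":
            te = np.ones(spec.n_genes)
            if row.condition == "case":
                te = 2.0 ** true_delta
            mu = mu * te
        columns[row.sample_id] = _nb_draw(rng, mu * lib[row.sample_id], spec.dispersion)

    counts = CountMatrix(
        gene_ids,
        sheet.sample_ids,
        np.column_stack([columns[s] for s in sheet.sample_ids]).astype(float),
    )
    truth = SimTruth(
        genes=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "baseline_mean": baseline,
                "true_delta": true_delta,
                "regulated": direction != 0,
            }
        ),
        library_factors=pd.DataFrame(
            {"sample_id": list(lib), "factor": [lib[s] for s in lib]}
        ),
    )
    return counts, sheet, truth


def _random_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    return _BASES[rng.choice(4, size=length, p=probs)]


def _random_codon(rng: np.random.Generator, exclude_atg: bool = True) -> str:
    """A random sense codon; optionally also excluding ATG."""
    while True:
        codon = "".join(_BASES[rng.integers(0, 4, 3)])
        if codon in _STOPS:
            continue
        if exclude_atg and codon == "ATG":
            continue
        return codon


def _uorf_sequence(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons-1) sense codons + stop, with no internal ATG."""
    while True:
        body = "".join(_random_codon(rng) for _ in range(n_codons - 1))
        stop = _STOPS[rng.integers(0, 3)]
        seq = "ATG" + body + stop
        if seq.find("ATG", 1) == -1:
            return seq


def plant_transcript(
    rng: np.random.Generator,
    tl_length: int,
    uorf_specs: Sequence[tuple[int, int]],
    gc: float = 0.5,
    cds_codons: int = 20,
    transcript_id: str = "tx",
    gene_id: str = "g",
    tss_id: str = "t",
) -> tuple[TranscriptRecord, pd.DataFrame]:
    """Build a transcript with uORFs planted at exact coordinates.

    ``uorf_specs`` is a list of (start, n_codons); each uORF occupies
    3*(n_codons+1) nucleotides (AUG + sense codons + stop) and must fit in
    the TL without overlap.  The background is scrubbed of accidental ATG
    triplets, so the planted coordinates are the exact expected annotation.
    """
    specs = sorted(uorf_specs)
    occupied: list[tuple[int, int]] = []
    for start, n_codons in specs:
        end = start + 3 * (n_codons + 1)
        if start < 0 or end > tl_length:
            raise ValueError(
                f"uORF at {start} with {n_codons} codons does not fit in TL of {tl_length} nt"
            )
        if occupied and start < occupied[-1][1]:
            raise ValueError(f"uORF at {start} overlaps the previous uORF")
        occupied.append((start, end))

    tl = _random_background(rng, tl_length, gc)
    for (start, n_codons), (s, e) in zip(specs, occupied):
        tl[s:e] = list(_uorf_sequence(rng, n_codons))

    # scrub unplanned ATGs: mutate a background base (never a planted one) to C
    planted_starts = [s for s, _ in occupied]
    in_planted = np.zeros(tl_length, dtype=bool)
    for s, e in occupied:
        in_planted[s:e] = True
    tl_str = "".join(tl)
    pos = tl_str.find("ATG")
    while pos != -1:
        if pos not in planted_starts:
            free = [i for i in (pos, pos + 1, pos + 2) if not in_planted[i]]
            assert free, "unplanned ATG inside a planted uORF body"
            tl[free[0]] = "C"
            tl_str = "".join(tl)
            pos = tl_str.find("ATG", pos)
        else:
            pos = tl_str.find("ATG", pos + 1)

    cds = "ATG" + "".join(_random_codon(rng, exclude_atg=False) for _ in range(cds_codons - 2))
    cds += _STOPS[rng.integers(0, 3)]
    sequence = "".join(tl) + cds
    record = TranscriptRecord(
        transcript_id=transcript_id,
        gene_id=gene_id,
        tss_id=tss_id,
        sequence=sequence,
        cds_start=tl_length,
    )
    rows = []
    for start, n_codons in specs:
        stop_pos = start + 3 * n_codons
        rows.append(
            {
                "transcript_id": transcript_id,
                "start": start,
                "n_codons": n_codons,
                "stop_end": stop_pos + 3,
                "frame": (start - tl_length) % 3,
                "orf_class": "upstream",
                "gap_to_main": tl_length - (stop_pos + 3),
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "start",
            "n_codons",
            "stop_end",
            "frame",
            "orf_class",
            "gap_to_main",
        ],
    )
    return record, truth


def simulate_transcripts(
    spec: SimSpec, n_transcripts: int = 100
) -> tuple[list[TranscriptRecord], SimTruth]:
    """Random transcripts with planted, exactly recoverable uORFs."""
    rng = spec.rng(_STREAM_TRANSCRIPTS)
    lo_len, hi_len = spec.tl_length_range
    lo_cod, hi_cod = spec.uorf_codon_range
    records: list[TranscriptRecord] = []
    uorf_frames: list[pd.DataFrame] = []
    summary = []
    for i in range(n_transcripts):
        tl_length = int(rng.integers(lo_len, hi_len + 1))
        n_uorfs = int(rng.choice(len(spec.uorf_count_probs), p=spec.uorf_count_probs))
        # draw codon counts that fit, smallest-first packing with random gaps
        specs: list[tuple[int, int]] = []
        cursor = 0
        for _ in range(n_uorfs):
            remaining = tl_length - cursor
            max_codons = remaining // 3 - 1
            if max_codons < lo_cod:
                break
            n_codons = int(rng.integers(lo_cod, min(hi_cod, max_codons) + 1))
            size = 3 * (n_codons + 1)
            slack = tl_length - cursor - size
            offset = int(rng.integers(0, max(1, slack // 2 + 1)))
            start = cursor + offset
            specs.append((start, n_codons))
            cursor = start + size
        record, truth = plant_transcript(
            rng,
            tl_length,
            specs,
            gc=spec.gc_content,
            cds_codons=int(rng.integers(10, 31)),
            transcript_id=f"tx{i:04d}",
            gene_id=f"g{i:04d}",
            tss_id=f"tss{i:04d}",
        )
        records.append(record)
        if not truth.empty:
            uorf_frames.append(truth)
        summary.append(
            {"transcript_id": record.transcript_id, "tl_length": tl_length, "n_uorfs": len(specs)}
        )
    uorfs = (
        pd.concat(uorf_frames, ignore_index=True)
        if uorf_frames
        else pd.DataFrame(
            columns=["transcript_id", "start", "n_codons", "stop_end", "frame", "orf_class", "gap_to_main"]
        )
    )
    return records, SimTruth(uorfs=uorfs, transcripts=pd.DataFrame(summary))


def simulate_usage(
    spec: SimSpec,
) -> tuple[pd.DataFrame, SampleSheet, list[TranscriptRecord], SimTruth]:
    """Transcript-level abundances for multi-TSS genes with usage shifts.

    Every gene gets 2-3 TSS variants with Dirichlet-drawn usage
    proportions.  For a planted subset, the polysomal proportions are an
    independent Dirichlet draw ("differential recruitment"); otherwise
    polysomal usage equals total usage.  Observed abundances are
    negative-binomial around expression x proportion x library factor.
    """
    rng = spec.rng(_STREAM_USAGE)
    sheet = _make_sheet(spec.n_replicates)
    lo, hi = spec.libsize_range
    lib = {s: rng.uniform(lo, hi) for s in sheet.sample_ids}

    n_shifted = int(round(spec.fraction_shifted * spec.n_usage_genes))
    shifted = set(rng.choice(spec.n_usage_genes, size=n_shifted, replace=False).tolist())

    records: list[TranscriptRecord] = []
    truth_rows = []
    tx_means: dict[str, dict[tuple[str, str], float]] = {}
    for g in range(spec.n_usage_genes):
        gene_id = f"ug{g:04d}"
        n_tss = int(rng.integers(2, 4))
        tss_ids = [f"{gene_id}_tss{k}" for k in range(n_tss)]
        expr = 2.0 ** rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd / 2)
        alpha = np.full(n_tss, spec.usage_concentration)
        p_total = rng.dirichlet(alpha)
        p_poly = rng.dirichlet(alpha) if g in shifted else p_total.copy()
        props = {"total": p_total, "polysomal": p_poly}
        for k, tss in enumerate(tss_ids):
            # occasionally a TSS carries two spliced transcripts sharing its leader
            n_tx = 2 if rng.random() < 0.2 else 1
            for j in range(n_tx):
                tx_id = f"{tss}_v{j}"
                records.append(
                    TranscriptRecord(
                        transcript_id=tx_id,
                        gene_id=gene_id,
                        tss_id=tss,
                        sequence="ATGGCCTAA",
                        cds_start=0,
                    )
                )
                tx_means[tx_id] = {
                    (cond, frac): expr * props[frac][k] / n_tx
                    for cond in CONDITIONS
                    for frac in FRACTIONS
                }
        for frac in FRACTIONS:
            for k, tss in enumerate(tss_ids):
                truth_rows.append(
                    {
                        "gene_id": gene_id,
                        "tss_id": tss,
                        "fraction": frac,
                        "true_proportion": props[frac][k],
                        "shifted": g in shifted,
                    }
                )

    tx_ids = [r.transcript_id for r in records]
    data = {}
    for row in sheet.table.itertuples(index=False):
        mean = np.array(
            [tx_means[tx][(row.condition, row.fraction)] for tx in tx_ids]
        ) * lib[row.sample_id]
        data[row.sample_id] = _nb_draw(rng, mean, spec.usage_dispersion).astype(float)
    abundances = pd.DataFrame(data, index=tx_ids)
    abundances.index.name = "transcript_id"
    truth = SimTruth(usage=pd.DataFrame(truth_rows))
    return abundances, sheet, records, truth
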