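"""Readers, writers, and the shared data model.

All tabular files are tab-separated UTF-8 with ``#`` comment lines ignored.
Coordinates are 0-based half-open internally; human-readable reports use
1-based inclusive coordinates.  Sequences are canonicalised to uppercase
DNA (``U`` mapped to ``T``) on the way in, so downstream code scans ``ATG``
regardless of whether the source used RNA or DNA notation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

CONDITIONS = ("case", "control")
FRACTIONS = ("total", "polysomal")

_RNA_TO_DNA = str.maketrans("ACGTUN", "ACGTTN")


class FormatError(ValueError):
    """Raised when an input file violates the data-model contract."""


def canonical_sequence(seq: str) -> str:
    """Uppercase a nucleotide string and map RNA U to DNA T.

    Raises :class:`FormatError` on characters outside ``ACGTUN`` (either case).
    """
    up = seq.upper()
    out = up.translate(_RNA_TO_DNA)
    bad = set(out) - set("ACGTN")
    if bad:
        raise FormatError(f"sequence contains non-nucleotide characters: {sorted(bad)}")
    return out


@dataclass
class CountMatrix:
    """Gene x sample fragment counts.

    ``counts`` holds non-negative reals: raw input counts are integers, but
    depth-equalised (down-sampled) counts are fractional by design.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_genes, n_samples)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for label, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise FormatError(f"duplicate {label} id(s): {dupes}")
        if not np.all(np.isfinite(self.counts)):
            raise FormatError("counts contain non-finite values")
        if (self.counts < 0).any():
            bad = self.gene_ids[int(np.argwhere(self.counts < 0)[0][0])]
            raise FormatError(f"negative count for gene {bad!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def depth(self) -> pd.Series:
        """Per-sample total assigned fragments (column sums)."""
        return pd.Series(self.counts.sum(axis=0), index=self.sample_ids)


@dataclass
class SampleSheet:
    """Per-sample metadata: condition, gradient fraction, replicate."""

    table: pd.DataFrame  # columns: sample_id, condition, fraction, replicate

    def __post_init__(self) -> None:
        required = ["sample_id", "condition", "fraction", "replicate"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise FormatError(f"sample sheet missing column(s): {missing}")
        t = self.table = self.table.reset_index(drop=True)
        dupes = _duplicates(t["sample_id"].tolist())
        if dupes:
            raise FormatError(f"duplicate sample id(s): {dupes}")
        for col, vocab in (("condition", CONDITIONS), ("fraction", FRACTIONS)):
            bad = sorted(set(t[col]) - set(vocab))
            if bad:
                raise FormatError(f"unknown {col} token(s) {bad}; expected one of {vocab}")
        reps = pd.to_numeric(t["replicate"], errors="coerce")
        if reps.isna().any() or (reps < 1).any() or (reps != reps.astype(int)).any():
            raise FormatError("replicate must be a positive integer for every sample")
        t["replicate"] = reps.astype(int)
        triples = list(zip(t["condition"], t["fraction"], t["replicate"]))
        dupes = _duplicates(triples)
        if dupes:
            raise FormatError(f"duplicate (condition, fraction, replicate) triple(s): {dupes}")
        for cond in CONDITIONS:
            for frac in FRACTIONS:
                n = ((t["condition"] == cond) & (t["fraction"] == frac)).sum()
                if n == 0:
                    raise FormatError(f"no sample for condition={cond}, fraction={frac}")

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def samples_for(self, condition: str | None = None, fraction: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        if condition is not None:
            mask &= self.table["condition"] == condition
        if fraction is not None:
            mask &= self.table["fraction"] == fraction
        return self.table.loc[mask, "sample_id"].tolist()

    def validate_against(self, counts: CountMatrix) -> None:
        """Cross-check that the sheet and count matrix describe the same samples."""
        sheet = set(self.sample_ids)
        matrix = set(counts.sample_ids)
        if sheet != matrix:
            only_sheet = sorted(sheet - matrix)
            only_matrix = sorted(matrix - sheet)
            raise FormatError(
                f"sample sheet / count matrix mismatch: only in sheet {only_sheet}, "
                f"only in counts {only_matrix}"
            )


@dataclass
class TranscriptRecord:
    """One transcript: sequence 5'->3' plus the 0-based principal start offset.

    The 5' transcript leader (TL) is ``sequence[:cds_start]``; the triplet at
    ``cds_start`` must be the ATG of the principal open reading frame.
    """

    transcript_id: str
    gene_id: str
    tss_id: str
    sequence: str
    cds_start: int

    def __post_init__(self) -> None:
        self.sequence = canonical_sequence(self.sequence)
        self.cds_start = int(self.cds_start)
        if not (0 <= self.cds_start <= len(self.sequence) - 3):
            raise FormatError(
                f"{self.transcript_id}: cds_start {self.cds_start} out of bounds "
                f"for sequence of length {len(self.sequence)}"
            )
        codon = self.sequence[self.cds_start : self.cds_start + 3]
        if codon != "ATG":
            raise FormatError(
                f"{self.transcript_id}: triplet at cds_start is {codon!r}, expected 'ATG'"
            )

    @property
    def tl(self) -> str:
        return self.sequence[: self.cds_start]


def _duplicates(items: Iterable) -> list:
    seen: set = set()
    dupes: list = []
    for x in items:
        if x in seen and x not in dupes:
            dupes.append(x)
        seen.add(x)
    return dupes


def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str, encoding="utf-8")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc


def read_counts(path: str | Path) -> CountMatrix:
    """Read a gene x sample count table (first column gene ids, header sample ids)."""
    raw = _read_tsv(path)
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: need a gene-id column plus at least one sample column")
    gene_ids = raw.iloc[:, 0].tolist()
    sample_ids = list(raw.columns[1:])
    body = raw.iloc[:, 1:].apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any():
        r, c = np.argwhere(body.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric count for gene {gene_ids[r]!r}, sample {sample_ids[c]!r}"
        )
    return CountMatrix(gene_ids, sample_ids, body.to_numpy(dtype=float))


def write_counts(counts: CountMatrix, path: str | Path) -> None:
    frame = counts.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t", encoding="utf-8")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    return SampleSheet(_read_tsv(path))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_transcript_table(fasta: str | Path, table: str | Path) -> list[TranscriptRecord]:
    """Join a transcript annotation table with its FASTA sequences.

    The table needs columns transcript_id, gene_id, tss_id, cds_start; every
    transcript_id must have a FASTA record.
    """
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}
    meta = _read_tsv(table)
    required = ["transcript_id", "gene_id", "tss_id", "cds_start"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise FormatError(f"{table}: missing column(s): {missing}")
    dupes = _duplicates(meta["transcript_id"].tolist())
    if dupes:
        raise FormatError(f"{table}: duplicate transcript id(s): {dupes}")
    records = []
    for row in meta.itertuples(index=False):
        if row.transcript_id not in seqs:
            raise FormatError(f"{fasta}: no sequence for transcript {row.transcript_id!r}")
        try:
            cds_start = int(row.cds_start)
        except ValueError as exc:
            raise FormatError(
                f"{table}: non-integer cds_start for {row.transcript_id!r}"
            ) from exc
        records.append(
            TranscriptRecord(
                transcript_id=row.transcript_id,
                gene_id=row.gene_id,
                tss_id=row.tss_id,
                sequence=seqs[row.transcript_id],
                cds_start=cds_start,
            )
        )
    return records


def write_transcript_table(
    records: Sequence[TranscriptRecord], fasta: str | Path, table: str | Path
) -> None:
    with open(fasta, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.transcript_id}\n{rec.sequence}\n")
    rows = [
        {
            "transcript_id": r.transcript_id,
            "gene_id": r.gene_id,
            "tss_id": r.tss_id,
            "cds_start": r.cds_start,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(table, sep="\t", index=False, encoding="utf-8")


def read_abundance(path: str | Path) -> pd.DataFrame:
    """Read a transcript x sample abundance table (first column transcript ids)."""
    raw = _read_tsv(path)
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: need a transcript-id column plus sample columns")
    ids = raw.iloc[:, 0]
    dupes = _duplicates(ids.tolist())
    if dupes:
        raise FormatError(f"{path}: duplicate transcript id(s): {dupes}")
    body = raw.iloc[:, 1:].apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any():
        raise FormatError(f"{path}: non-numeric abundance value")
    if (body.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative abundance value")
    body.index = ids.tolist()
    body.index.name = "transcript_id"
    return body
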