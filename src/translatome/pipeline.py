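"""Orchestrated end-to-end runs with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

import translatome
from translatome.io import (
    read_abundance,
    read_counts,
    read_sample_sheet,
    read_transcript_table,
    write_counts,
)
from translatome.normalization import compute_rescale_factors, downsample_counts
from translatome.reports import tl_report
from translatome.te import run_te_analysis
from translatome.tl_features import annotate_transcript
from translatome.tss import compute_usage, usage_report

log = logging.getLogger("translatome")


@dataclass
class RunConfig:
    """All inputs and parameters of one pipeline run."""

    counts: str
    samples: str
    outdir: str
    fasta: Optional[str] = None
    transcript_table: Optional[str] = None
    abundance: Optional[str] = None
    grouping: str = "by-fraction"
    bin_size: int = 300
    z_threshold: float = 2.0
    min_count: float = 0.0
    pseudocount: float = 0.0
    cap_threshold: int = 15
    n_perm: int = 999
    seed: int = 0
    case_label: str = "case"
    control_label: str = "control"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def validate_paths(self) -> None:
        for name in ("counts", "samples", "fasta", "transcript_table", "abundance"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"config input {name}: no such file {value!r}")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """normalize -> te -> annotate-tl -> tss, with a run manifest.

    Each stage failure is re-raised with a stage label; nothing is written
    until the inputs validate.  Returns the output directory.
    """
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "translatome",
        "version": translatome.__version__,
        "parameters": asdict(config),
        "inputs": {},
        "stages": {},
    }
    for name in ("counts", "samples", "fasta", "transcript_table", "abundance"):
        value = getattr(config, name)
        if value is not None:
            manifest["inputs"][name] = {"path": str(value), "sha256": _sha256(value)}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            dt = time.perf_counter() - t0
            manifest["stages"][name] = {"seconds": round(dt, 3)}
            log.info("stage %s: done in %.2fs", name, dt)

        return wrap

    counts = read_counts(config.counts)
    sheet = read_sample_sheet(config.samples)
    state: dict = {}

    @stage("normalize")
    def _normalize():
        factors = compute_rescale_factors(counts, sheet, grouping=config.grouping)
        normalized = downsample_counts(counts, factors)
        factors.to_tsv(outdir / "rescale_factors.tsv")
        write_counts(normalized, outdir / "normalized.tsv")
        state["normalized"] = normalized

    @stage("te")
    def _te():
        result = run_te_analysis(
            state["normalized"],
            sheet,
            bin_size=config.bin_size,
            threshold=config.z_threshold,
            min_count=config.min_count,
            pseudocount=config.pseudocount,
        )
        result.to_csv(outdir / "te_report.tsv", sep="\t")

    if config.fasta and config.transcript_table:

        @stage("annotate-tl")
        def _annotate():
            records = read_transcript_table(config.fasta, config.transcript_table)
            anns = [annotate_transcript(r, cap_threshold=config.cap_threshold) for r in records]
            tl_report(anns).to_csv(outdir / "tl_report.tsv", sep="\t", index=False)
            state["records"] = records

    if config.abundance and config.fasta and config.transcript_table:

        @stage("tss")
        def _tss():
            abundances = read_abundance(config.abundance)
            profiles = compute_usage(abundances, state["records"], sheet)
            usage_report(profiles).to_csv(outdir / "tss_report.tsv", sep="\t", index=False)

    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
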