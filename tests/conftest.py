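import numpy as np
import pandas as pd
import pytest

from translatome.io import CountMatrix, SampleSheet


@pytest.fixture
def small_sheet() -> SampleSheet:
    rows = [
        {"sample_id": f"{c}_{f}_{r}", "condition": c, "fraction": f, "replicate": r}
        for c in ("case", "control")
        for f in ("total", "polysomal")
        for r in (1, 2, 3)
    ]
    return SampleSheet(pd.DataFrame(rows))


@pytest.fixture
def small_counts(small_sheet) -> CountMatrix:
    rng = np.random.default_rng(7)
    genes = [f"g{i}" for i in range(40)]
    counts = rng.integers(1, 500, size=(40, 12)).astype(float)
    return CountMatrix(genes, small_sheet.sample_ids, counts)


@pytest.fixture
def counts_tsv(tmp_path, small_counts):
    from translatome.io import write_counts

    path = tmp_path / "counts.tsv"
    write_counts(small_counts, path)
    return path


@pytest.fixture
def sheet_tsv(tmp_path, small_sheet):
    path = tmp_path / "samples.tsv"
    small_sheet.table.to_csv(path, sep="\t", index=False)
    return path
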