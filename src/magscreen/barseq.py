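"""BarSeq demultiplexing and barcode counting.

Reads are laid out index + flank + barcode. Counting is exact-match by
default; a Hamming-1 rescue for real data can be enabled on the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from magscreen.pool import _read_fastq_seqs

FRACTIONS = ("t0", "precolumn", "magnetic", "nonmagnetic")

INDEX_UNKNOWN = "index_unknown"
FLANK_MISSING = "flank_missing"
BARCODE_N = "barcode_N"


@dataclass(frozen=True)
class Sample:
    sample_id: str
    condition: str
    fraction: str
    replicate: int
    index_seq: str

    def __post_init__(self) -> None:
        if self.fraction not in FRACTIONS:
            raise ValueError(
                f"sample {self.sample_id}: fraction must be one of {FRACTIONS}, "
                f"got {self.fraction!r}"
            )
        if self.replicate < 1:
            raise ValueError(f"sample {self.sample_id}: replicate must be >= 1")


@dataclass
class SampleSheet:
    samples: list[Sample]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in sample sheet")
        idx = [s.index_seq for s in self.samples]
        if len(set(idx)) != len(idx):
            raise ValueError("duplicate index_seq in sample sheet")
        lens = {len(s.index_seq) for s in self.samples}
        if len(lens) > 1:
            raise ValueError("all index sequences must have equal length")
        # every non-t0 condition needs a precolumn sample for normalization
        conds = {(s.condition, s.replicate) for s in self.samples if s.fraction != "t0"}
        pre = {(s.condition, s.replicate) for s in self.samples if s.fraction == "precolumn"}
        missing = conds - pre
        if missing:
            raise ValueError(
                f"conditions without a precolumn sample: {sorted(missing)}"
            )

    @property
    def index_len(self) -> int:
        return len(self.samples[0].index_seq)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def by_index(self) -> dict[str, Sample]:
        return {s.index_seq: s for s in self.samples}

    def lookup(self, condition: str, fraction: str, replicate: int) -> Sample | None:
        for s in self.samples:
            if (s.condition, s.fraction, s.replicate) == (condition, fraction, replicate):
                return s
        return None


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sampleId", "condition", "fraction", "replicate", "index"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    samples = [
        Sample(
            sample_id=r.sampleId,
            condition=r.condition,
            fraction=r.fraction,
            replicate=int(r.replicate),
            index_seq=r.index,
        )
        for r in df.itertuples()
    ]
    return SampleSheet(samples)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    pd.DataFrame(
        {
            "sampleId": [s.sample_id for s in sheet.samples],
            "condition": [s.condition for s in sheet.samples],
            "fraction": [s.fraction for s in sheet.samples],
            "replicate": [s.replicate for s in sheet.samples],
            "index": [s.index_seq for s in sheet.samples],
        }
    ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class BarSeqReadModel:
    flank5: str = "CAGCGTACG"
    barcode_len: int = 20
    hamming1_rescue: bool = False


def parse_barseq_read(
    read: str, model: BarSeqReadModel, sheet: SampleSheet
) -> tuple[str, str] | tuple[None, str]:
    """Demultiplex one read to (sample_id, barcode), or (None, reason)."""
    read = read.upper()
    index = read[: sheet.index_len]
    sample = sheet.by_index().get(index)
    if sample is None:
        return None, INDEX_UNKNOWN
    rest = read[sheet.index_len :]
    if not rest.startswith(model.flank5):
        return None, FLANK_MISSING
    barcode = rest[len(model.flank5) : len(model.flank5) + model.barcode_len]
    if len(barcode) < model.barcode_len or "N" in barcode:
        return None, BARCODE_N
    return sample.sample_id, barcode


@dataclass
class CountMatrix:
    """Barcode x sample integer read counts plus per-sample unknown tallies."""

    counts: pd.DataFrame  # index: barcode, columns: sample_id
    unknown: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")

    @property
    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


def _hamming1_neighbors(barcode: str) -> Iterable[str]:
    for i, c in enumerate(barcode):
        for alt in "ACGT":
            if alt != c:
                yield barcode[:i] + alt + barcode[i + 1 :]


def count_barcodes(
    reads: Iterable[str] | str | Path,
    model: BarSeqReadModel,
    sheet: SampleSheet,
    pool: pd.DataFrame,
) -> CountMatrix:
    """Count pool barcodes per sample from BarSeq reads.

    Off-pool barcodes increment the per-sample unknown tally (optionally
    rescued to a unique Hamming-1 pool neighbor when the model enables
    it); every pool barcode is retained as a row even at zero counts.
    """
    if isinstance(reads, (str, Path)):
        reads = _read_fastq_seqs(reads)
    pool_barcodes = list(pool["barcode"])
    pool_set = set(pool_barcodes)
    sample_ids = sheet.sample_ids
    col_of = {s: j for j, s in enumerate(sample_ids)}
    row_of = {b: i for i, b in enumerate(pool_barcodes)}
    import numpy as np

    mat = np.zeros((len(pool_barcodes), len(sample_ids)), dtype=np.int64)
    unknown = {s: 0 for s in sample_ids}
    for read in reads:
        sample_id, barcode = parse_barseq_read(read, model, sheet)
        if sample_id is None:
            continue
        if barcode not in pool_set and model.hamming1_rescue:
            neighbors = [b for b in _hamming1_neighbors(barcode) if b in pool_set]
            if len(neighbors) == 1:
                barcode = neighbors[0]
        if barcode in pool_set:
            mat[row_of[barcode], col_of[sample_id]] += 1
        else:
            unknown[sample_id] += 1
    counts = pd.DataFrame(mat, index=pd.Index(pool_barcodes, name="barcode"),
                          columns=sample_ids)
    empty = [s for s in sample_ids if counts[s].sum() + unknown[s] == 0]
    if empty:
        warnings.warn(f"samples received zero reads: {empty}", stacklevel=2)
    return CountMatrix(counts=counts, unknown=unknown)


def write_counts_tsv(matrix: CountMatrix, path: str | Path) -> None:
    matrix.counts.to_csv(path, sep="\t")


def read_counts_tsv(path: str | Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="barcode")
    for col in df.columns:
        series = df[col]
        if not pd.api.types.is_integer_dtype(series):
            bad = series[series != series.round()]
            if not bad.empty:
                raise ValueError(
                    f"non-integer count at ({bad.index[0]}, {col}): {bad.iloc[0]}"
                )
            df[col] = series.astype(int)
        neg = df[df[col] < 0]
        if not neg.empty:
            raise ValueError(f"negative count at ({neg.index[0]}, {col})")
    return CountMatrix(counts=df)
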