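"""Input/output: dereplicated FASTA, sequence-by-sample count tables, results.

The two inputs are (a) a FASTA file of dereplicated sequences and (b) a
tab-separated count table whose rows are sequence IDs and whose columns are
samples; cell (s, i) is the number of times sequence s was observed in
sample i. Counts must be non-negative integers because the distribution
criterion models them as Poisson draws.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")


class InputError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclasses.dataclass(frozen=True)
class SequenceRecord:
    """A dereplicated sequence: a unique ID and an uppercase nucleotide string."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("sequence record has an empty ID")
        if not self.seq:
            raise InputError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise InputError(
                f"sequence {self.id!r} contains characters outside A/C/G/T/N: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


class CountTable:
    """Integer counts per (sequence, sample), with sample order preserved.

    Thin wrapper around a pandas DataFrame (index = sequence IDs, columns =
    sample IDs, int64 cells). Provides the per-sequence count vectors the
    distribution test consumes.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.empty:
            raise InputError("count table has no sequences")
        if (counts.values < 0).any():
            raise InputError("count table contains negative counts")
        self._df = counts.astype(np.int64)
        totals = self._df.sum(axis=1)
        zero = totals[totals == 0]
        if len(zero) > 0:
            raise InputError(
                "sequences with zero total counts: " + ", ".join(map(str, zero.index[:10]))
            )

    @classmethod
    def from_dict(
        cls, counts: Mapping[str, Iterable[int]], sample_ids: Iterable[str]
    ) -> "CountTable":
        samples = list(sample_ids)
        df = pd.DataFrame.from_dict(dict(counts), orient="index", columns=samples)
        return cls(df)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def seq_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def n_samples(self) -> int:
        return self._df.shape[1]

    def vector(self, seq_id: str) -> np.ndarray:
        """Per-sample count vector for one sequence, in input sample order."""
        return self._df.loc[seq_id].to_numpy()

    def total(self, seq_id: str) -> int:
        return int(self._df.loc[seq_id].sum())

    def totals(self) -> pd.Series:
        return self._df.sum(axis=1)

    def column_sums(self) -> np.ndarray:
        return self._df.sum(axis=0).to_numpy()

    def to_frame(self) -> pd.DataFrame:
        return self._df.copy()

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._df.index

    def __len__(self) -> int:
        return len(self._df)


@dataclasses.dataclass(frozen=True)
class Dataset:
    """Validated pairing of sequence records with their count table."""

    records: dict[str, SequenceRecord]
    table: CountTable


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read dereplicated sequences, uppercasing and checking ID uniqueness."""
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise InputError(f"duplicate sequence ID in {path}: {entry.id!r}")
        seen.add(entry.id)
        records.append(SequenceRecord(id=entry.id, seq=str(entry.seq).upper().strip()))
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    return records


def read_count_table(path: str | Path) -> CountTable:
    """Read a tab-separated count table.

    First row is a header whose first cell is an ignorable label followed by
    sample names; each subsequent row is a sequence ID followed by one
    integer count per sample. Rows whose counts sum to zero are rejected, as
    are non-integer or negative cells and ragged rows.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise InputError(f"count table {path} needs a header and at least one row")
    header = lines[0].split("\t")
    samples = header[1:]
    if not samples:
        raise InputError(f"count table {path} header names no samples")
    ids: list[str] = []
    rows: list[list[int]] = []
    for row_num, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(samples) + 1:
            raise InputError(
                f"{path} row {row_num}: expected {len(samples) + 1} columns, got {len(cells)}"
            )
        counts = []
        for col_num, cell in enumerate(cells[1:], start=2):
            try:
                value = int(cell)
            except ValueError:
                raise InputError(
                    f"{path} row {row_num} column {col_num}: non-integer count {cell!r}"
                ) from None
            if value < 0:
                raise InputError(
                    f"{path} row {row_num} column {col_num}: negative count {value}"
                )
            counts.append(value)
        ids.append(cells[0])
        rows.append(counts)
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InputError(f"{path}: duplicate sequence IDs {dupes[:10]}")
    df = pd.DataFrame(rows, index=ids, columns=samples)
    return CountTable(df)


def validate_inputs(records: list[SequenceRecord], table: CountTable) -> Dataset:
    """Check that FASTA and count-table sequence ID sets are identical."""
    fasta_ids = {r.id for r in records}
    table_ids = set(table.seq_ids)
    only_fasta = sorted(fasta_ids - table_ids)
    only_table = sorted(table_ids - fasta_ids)
    if only_fasta or only_table:
        parts = []
        if only_fasta:
            parts.append(f"in FASTA but not count table: {only_fasta[:10]}")
        if only_table:
            parts.append(f"in count table but not FASTA: {only_table[:10]}")
        raise InputError("sequence ID mismatch; " + "; ".join(parts))
    return Dataset(records={r.id: r for r in records}, table=table)


def write_outputs(result, out_prefix: str | Path) -> dict[str, Path]:
    """Write the OTU table, the membership map, and the merge log.

    Returns the paths written, keyed ``otu_table`` / ``membership`` / ``log``.
    OTU IDs are the representative (founding) sequence IDs; the OTU table's
    per-sample column sums equal those of the input table by construction.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)

    otu_path = out_prefix.with_suffix(".otus.tsv")
    table = pd.DataFrame(
        [otu.counts for otu in result.otus],
        index=[otu.rep_id for otu in result.otus],
        columns=result.sample_ids,
    )
    table.index.name = "OTU"
    table.to_csv(otu_path, sep="\t")

    member_path = out_prefix.with_suffix(".membership.tsv")
    with open(member_path, "w") as fh:
        fh.write("OTU\tmembers\n")
        for otu in result.otus:
            fh.write(f"{otu.rep_id}\t{','.join(otu.members)}\n")

    log_path = out_prefix.with_suffix(".log.tsv")
    with open(log_path, "w") as fh:
        fh.write(
            "candidate\totu\tstage\tdissimilarity\tp_value\tverdict\tx1\tx2\n"
        )
        for entry in result.merge_log:
            for row in entry.iter_log_rows():
                fh.write("\t".join(row) + "\n")
    return {"otu_table": otu_path, "membership": member_path, "log": log_path}
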