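import numpy as np
import pytest

from distotu.fixtures import FixtureConfig, make_community
from distotu.io import CountTable, SequenceRecord


# the OTU/candidate pair on which the likelihood-ratio test and the
# simulated chi-squared test disagree at p = 0.001 (6 mock-community samples)
X1_DISAGREEMENT = np.array([138, 129, 163, 92, 258, 14])
X2_DISAGREEMENT = np.array([15, 11, 28, 1, 13, 1])


@pytest.fixture
def disagreement_pair():
    return X1_DISAGREEMENT.copy(), X2_DISAGREEMENT.copy()


@pytest.fixture
def tiny_dataset():
    """Three short sequences over two samples; b and c are 1 edit from a."""
    records = [
        SequenceRecord(id="a", seq="ACGTACGTACGT"),
        SequenceRecord(id="b", seq="ACGTACGTACGA"),
        SequenceRecord(id="c", seq="ACGTACGTACGG"),
    ]
    table = CountTable.from_dict(
        {"a": [100, 200], "b": [10, 20], "c": [30, 0]}, ["s1", "s2"]
    )
    return records, table


@pytest.fixture
def synthetic_community():
    return make_community(FixtureConfig(seed=42))


def dp_edit_distance(a: str, b: str) -> int:
    """Independent full dynamic-programming Levenshtein oracle."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def write_fasta(path, records):
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")


def write_table(path, table: CountTable):
    df = table.to_frame()
    df.index.name = "sequence"
    df.to_csv(path, sep="\t")
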