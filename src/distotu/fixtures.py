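"""Synthetic mock communities with known OTU ground truth.

Emulates the structure of a dereplicated mock-community amplicon dataset:
a handful of mutually dissimilar "base" 16S fragments (default 187 nt, the
scale of trimmed V-region reads) observed across samples (default 6), each
accompanied by

* **error derivatives** — sequences one or two edits away whose per-sample
  counts are Poisson with rates proportional to the base's rates (rate
  ratio rho). These mimic sequencing error or intra-population variants and
  *should* be merged into the base's OTU; and
* an optional **ecological twin** — a sequence also one or two edits away
  but whose counts are concentrated in samples where the base is absent.
  These mimic sequence-similar but ecologically distinct populations and
  *should* be kept separate.

Counts are drawn from the same Poisson model the distribution criterion
assumes (base counts ~ Poisson(lambda_i), derivative counts ~
Poisson(rho * lambda_i)), so under the merge truth the likelihood-ratio
test's null holds exactly and recovery rates are interpretable as test
operating characteristics.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from distotu.genetic import genetic_dissimilarity
from distotu.io import CountTable, SequenceRecord

_BASES = np.array(list("ACGT"))


@dataclasses.dataclass
class FixtureConfig:
    """Generator settings; the seed is mandatory for reproducibility.

    error_rates: number of edits for each error derivative of a base (one
        derivative per entry). rho_values: Poisson rate ratio for each error
        derivative (cycled if shorter than error_rates). lambda_range: the
        per-sample base Poisson rates are drawn uniformly from this range.
    """

    n_base_seqs: int = 5
    seq_length: int = 187
    n_samples: int = 6
    error_rates: tuple[int, ...] = (1, 2)
    rho_values: tuple[float, ...] = (0.1,)
    lambda_range: tuple[float, float] = (50.0, 500.0)
    twins: bool = True
    twin_edits: int = 2
    min_base_dissimilarity: float = 0.2
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required")
        if self.n_base_seqs < 1:
            raise ValueError("n_base_seqs must be >= 1")
        if self.seq_length < 10 or self.n_samples < 1:
            raise ValueError("seq_length and n_samples must be positive")
        if any(k < 1 or k > 2 for k in self.error_rates):
            raise ValueError("error derivatives use 1 or 2 edits")
        if any(not 0 < r < 1 for r in self.rho_values):
            raise ValueError("rho values must be in (0, 1)")
        lo, hi = self.lambda_range
        if not 0 < lo <= hi:
            raise ValueError("lambda_range must be positive and ordered")


@dataclasses.dataclass(frozen=True)
class FixtureTruth:
    """Intended OTU membership: sequence ID -> founding sequence ID."""

    otu_of: dict[str, str]
    error_derivatives: list[str]
    twins: list[str]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, n_edits: int) -> str:
    """Apply n uniformly chosen substitutions/insertions/deletions."""
    s = list(seq)
    for _ in range(n_edits):
        op = rng.choice(["sub", "ins", "del"])
        pos = int(rng.integers(0, len(s)))
        if op == "sub":
            current = s[pos]
            choices = [b for b in "ACGT" if b != current]
            s[pos] = choices[int(rng.integers(0, 3))]
        elif op == "ins":
            s.insert(pos, str(rng.choice(_BASES)))
        else:
            del s[pos]
    return "".join(s)


def _poisson_at_least_one(rng: np.random.Generator, rates: np.ndarray) -> np.ndarray:
    """Poisson draw, redrawn in the rare case the whole vector is zero."""
    while True:
        x = rng.poisson(rates)
        if x.sum() > 0:
            return x


def make_community(config: FixtureConfig) -> tuple[list[SequenceRecord], CountTable, FixtureTruth]:
    """Generate (records, count table, truth) for one synthetic community."""
    rng = np.random.default_rng(config.seed)

    # mutually dissimilar base sequences (rejection sampling; random
    # sequences sit near 50% dissimilarity, so rejections are rare)
    bases: list[str] = []
    attempts = 0
    while len(bases) < config.n_base_seqs:
        attempts += 1
        if attempts > 100 * config.n_base_seqs:
            raise ValueError("cannot place this many mutually dissimilar bases")
        cand = _random_sequence(rng, config.seq_length)
        if all(
            genetic_dissimilarity(cand, b) > config.min_base_dissimilarity for b in bases
        ):
            bases.append(cand)

    records: list[SequenceRecord] = []
    counts: dict[str, np.ndarray] = {}
    otu_of: dict[str, str] = {}
    error_ids: list[str] = []
    twin_ids: list[str] = []

    lo, hi = config.lambda_range
    n = config.n_samples
    for b, base_seq in enumerate(bases):
        base_id = f"base{b}"
        lam = rng.uniform(lo, hi, size=n)
        records.append(SequenceRecord(id=base_id, seq=base_seq))
        counts[base_id] = _poisson_at_least_one(rng, lam)
        otu_of[base_id] = base_id

        for d, k in enumerate(config.error_rates):
            rho = config.rho_values[d % len(config.rho_values)]
            deriv_id = f"base{b}_err{d}"
            deriv_seq = _mutate(rng, base_seq, k)
            records.append(SequenceRecord(id=deriv_id, seq=deriv_seq))
            counts[deriv_id] = _poisson_at_least_one(rng, rho * lam)
            otu_of[deriv_id] = base_id
            error_ids.append(deriv_id)

        if config.twins:
            twin_id = f"base{b}_twin"
            twin_seq = _mutate(rng, base_seq, config.twin_edits)
            # occupy the half of the samples where we zero the base's rates:
            # disjoint occupancy is the ecological signal
            occupied = rng.permutation(n)[: max(1, n // 2)]
            twin_lam = np.zeros(n)
            twin_lam[occupied] = rng.uniform(lo, hi, size=occupied.size)
            records.append(SequenceRecord(id=twin_id, seq=twin_seq))
            counts[twin_id] = _poisson_at_least_one(rng, twin_lam)
            otu_of[twin_id] = twin_id
            twin_ids.append(twin_id)

    sample_ids = [f"sample{i + 1}" for i in range(n)]
    table = CountTable(
        pd.DataFrame.from_dict(
            {k: v.astype(np.int64) for k, v in counts.items()},
            orient="index",
            columns=sample_ids,
        )
    )
    truth = FixtureTruth(otu_of=otu_of, error_derivatives=error_ids, twins=twin_ids)
    return records, table, truth


def write_community(
    config: FixtureConfig, fasta_path: str | Path, table_path: str | Path
) -> FixtureTruth:
    """Generate a community and write FASTA + TSV count table to disk."""
    records, table, truth = make_community(config)
    fasta_path, table_path = Path(fasta_path), Path(table_path)
    with open(fasta_path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")
    df = table.to_frame()
    df.index.name = "sequence"
    df.to_csv(table_path, sep="\t")
    return truth
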