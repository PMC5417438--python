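"""The greedy OTU-calling loop.

Candidates are visited in order of decreasing total abundance (ties broken
by sequence ID). The most abundant sequence founds the first OTU. Each later
candidate is screened against existing OTUs with the three criteria applied
cheapest-first:

1. **abundance** — the OTU's current total (including prior merges) must be
   at least ``abundance_fold`` times the candidate's total;
2. **genetic** — normalized Levenshtein dissimilarity to the OTU's
   representative sequence must not exceed ``genetic_threshold``;
3. **distribution** — walking the surviving OTUs from most to least
   genetically similar, the candidate merges into the first one whose
   likelihood-ratio p-value is >= ``p_threshold``.

If no OTU accepts it, the candidate founds a new OTU. Merging adds the
candidate's per-sample counts to the OTU's counts; an OTU's representative
sequence never changes, so it is always the sequence of the OTU's most
abundant (founding) member.

The whole procedure is deterministic: no randomness, and every tie-break is
specified (candidate order by total then ID; equal dissimilarities by OTU
creation order).
"""

from __future__ import annotations

import dataclasses
from typing import Iterator, Optional

import numpy as np

from distotu.disttest import lrt_pvalue
from distotu.genetic import passes_genetic_criterion
from distotu.io import CountTable, Dataset, SequenceRecord


@dataclasses.dataclass
class CallerConfig:
    """Thresholds of the three merge criteria.

    genetic_threshold: maximum normalized edit distance 2E/(l1+l2), default 0.1.
    abundance_fold: minimum OTU:candidate total-count ratio, default 10.
    p_threshold: minimum LRT p-value for merging; below it the distributions
        are considered too distinct. Default 0.0005 — users migrating from a
        simulated chi-squared threshold of p should use roughly p/20, since
        the LRT reproduces that criterion best at an approximately
        twenty-fold smaller threshold.
    max_candidates: optional cap on distribution tests per candidate.
    """

    genetic_threshold: float = 0.1
    abundance_fold: float = 10.0
    p_threshold: float = 0.0005
    max_candidates: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 < self.genetic_threshold < 2:
            raise ValueError("genetic_threshold must be in (0, 2)")
        if self.abundance_fold < 0:
            raise ValueError("abundance_fold must be >= 0")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")


@dataclasses.dataclass
class OTU:
    """An OTU: founding representative plus accumulated per-sample counts."""

    rep_id: str
    rep_seq: str
    counts: np.ndarray
    members: list[str]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclasses.dataclass(frozen=True)
class TrailRecord:
    """One candidate-vs-OTU screening step, for the merge log."""

    otu_id: str
    abundance_pass: bool
    dissimilarity: Optional[float] = None  # None when genetic not evaluated
    genetic_pass: Optional[bool] = None
    p_value: Optional[float] = None  # set only if distribution-tested
    x1: Optional[tuple[int, ...]] = None  # OTU counts at test time
    x2: Optional[tuple[int, ...]] = None


@dataclasses.dataclass
class MergeLogEntry:
    candidate_id: str
    decision: str  # "new_otu" | "merged"
    target_otu: Optional[str]
    trail: list[TrailRecord]

    def iter_log_rows(self) -> Iterator[list[str]]:
        """Flatten to TSV rows: candidate, otu, stage, dissim, p, verdict, x1, x2."""

        def fmt(v) -> str:
            return "" if v is None else (f"{v:.6g}" if isinstance(v, float) else str(v))

        for rec in self.trail:
            if rec.p_value is not None:
                stage, verdict = "distribution", "tested"
            elif rec.dissimilarity is not None or rec.genetic_pass is not None:
                stage = "genetic"
                verdict = "pass" if rec.genetic_pass else "fail"
            else:
                stage, verdict = "abundance", "fail"
            yield [
                self.candidate_id,
                rec.otu_id,
                stage,
                fmt(rec.dissimilarity),
                fmt(rec.p_value),
                verdict,
                "" if rec.x1 is None else ",".join(map(str, rec.x1)),
                "" if rec.x2 is None else ",".join(map(str, rec.x2)),
            ]


@dataclasses.dataclass
class OTUResult:
    otus: list[OTU]
    sample_ids: list[str]
    merge_log: list[MergeLogEntry]

    @property
    def n_genetic_evaluations(self) -> int:
        return sum(
            1
            for e in self.merge_log
            for r in e.trail
            if r.abundance_pass and r.genetic_pass is not None and r.p_value is None
        )

    @property
    def n_distribution_tests(self) -> int:
        return sum(1 for e in self.merge_log for r in e.trail if r.p_value is not None)

    def membership(self) -> dict[str, str]:
        """Map each member sequence ID to its OTU's representative ID."""
        return {m: otu.rep_id for otu in self.otus for m in otu.members}


def sort_candidates(table: CountTable) -> list[str]:
    """Sequence IDs by decreasing total count; ties by ID, ascending."""
    totals = table.totals()
    return sorted(totals.index, key=lambda s: (-totals[s], s))


def eligible_otus(
    candidate: SequenceRecord,
    candidate_total: int,
    otus: list[OTU],
    config: CallerConfig,
) -> list[tuple[OTU, float]]:
    """OTUs passing abundance and genetic criteria, most similar first."""
    eligible, _ = _screen(candidate, candidate_total, otus, config)
    return eligible


def _screen(
    candidate: SequenceRecord,
    candidate_total: int,
    otus: list[OTU],
    config: CallerConfig,
) -> tuple[list[tuple[OTU, float]], list[TrailRecord]]:
    eligible: list[tuple[int, float, OTU]] = []
    trail: list[TrailRecord] = []
    for creation_order, otu in enumerate(otus):
        if otu.total < config.abundance_fold * candidate_total:
            trail.append(TrailRecord(otu_id=otu.rep_id, abundance_pass=False))
            continue
        passed, dissim = passes_genetic_criterion(
            candidate.seq, otu.rep_seq, config.genetic_threshold
        )
        trail.append(
            TrailRecord(
                otu_id=otu.rep_id,
                abundance_pass=True,
                dissimilarity=dissim,
                genetic_pass=passed,
            )
        )
        if passed:
            eligible.append((creation_order, dissim, otu))
    eligible.sort(key=lambda t: (t[1], t[0]))
    return [(otu, dissim) for _, dissim, otu in eligible], trail


def process_candidate(
    candidate: SequenceRecord,
    counts: np.ndarray,
    otus: list[OTU],
    config: CallerConfig,
) -> MergeLogEntry:
    """Screen one candidate against the current OTUs; merge or found anew.

    Mutates ``otus`` in place (appends a new OTU or adds counts to an
    existing one) and returns the log entry recording every evaluation.
    """
    candidate_total = int(counts.sum())
    eligible, trail = _screen(candidate, candidate_total, otus, config)
    if config.max_candidates is not None:
        eligible = eligible[: config.max_candidates]
    for otu, dissim in eligible:
        result = lrt_pvalue(otu.counts, counts)
        trail.append(
            TrailRecord(
                otu_id=otu.rep_id,
                abundance_pass=True,
                dissimilarity=dissim,
                genetic_pass=True,
                p_value=result.p_value,
                x1=tuple(int(v) for v in otu.counts),
                x2=tuple(int(v) for v in counts),
            )
        )
        if result.p_value >= config.p_threshold:
            otu.counts = otu.counts + counts
            otu.members.append(candidate.id)
            return MergeLogEntry(
                candidate_id=candidate.id,
                decision="merged",
                target_otu=otu.rep_id,
                trail=trail,
            )
    otus.append(
        OTU(rep_id=candidate.id, rep_seq=candidate.seq, counts=counts.copy(),
            members=[candidate.id])
    )
    return MergeLogEntry(
        candidate_id=candidate.id, decision="new_otu", target_otu=None, trail=trail
    )


def call_otus(
    records: list[SequenceRecord] | Dataset,
    table: CountTable | None = None,
    config: CallerConfig | None = None,
) -> OTUResult:
    """Run the full greedy loop over all sequences.

    Accepts either a validated :class:`~distotu.io.Dataset` or the raw
    (records, table) pair, which is validated first.
    """
    from distotu.io import validate_inputs

    if isinstance(records, Dataset):
        dataset = records
    else:
        if table is None:
            raise ValueError("table is required when records is a list")
        dataset = validate_inputs(records, table)
    config = config or CallerConfig()

    otus: list[OTU] = []
    log: list[MergeLogEntry] = []
    for seq_id in sort_candidates(dataset.table):
        candidate = dataset.records[seq_id]
        counts = dataset.table.vector(seq_id)
        log.append(process_candidate(candidate, counts, otus, config))
    return OTUResult(otus=otus, sample_ids=dataset.table.sample_ids, merge_log=log)
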