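"""The genetic criterion: normalized Levenshtein dissimilarity.

A candidate sequence may only be merged into an OTU whose representative
sequence is genetically close, measured as 2E/(l1 + l2) where E is the
Levenshtein edit distance (single-position insertions, deletions, or
substitutions) and l1, l2 are the two sequence lengths. The metric is a fast
approximation to the proportion of mismatched sites in a global pairwise
alignment; :func:`alignment_dissimilarity_oracle` provides that alignment
gold standard for evaluation.

Comparison is case-insensitive and ``N`` mismatches every base, including
another ``N`` — the conservative reading for an ambiguity code.
"""

from __future__ import annotations

import dataclasses
import math

import edlib
from Bio import Align

# edlib treats equal characters as matches, so to make N mismatch everything
# (itself included) we would need to rewrite Ns; instead we declare no extra
# equalities and substitute each N with a placeholder unique per side.
_N_SUB_A = "N"
_N_SUB_B = "n"


@dataclasses.dataclass(frozen=True)
class GeneticComparison:
    """Edit distance E between two sequences and the derived dissimilarity."""

    E: int
    len_a: int
    len_b: int

    @property
    def dissimilarity(self) -> float:
        return 2.0 * self.E / (self.len_a + self.len_b)


def _prepare(a: str, b: str) -> tuple[str, str]:
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    a = a.upper()
    b = b.upper()
    # distinct placeholders so N never matches anything, N vs N included
    return a.replace("N", _N_SUB_A), b.replace("N", _N_SUB_B)


def edit_distance(a: str, b: str) -> int:
    """Levenshtein edit distance between two nucleotide sequences."""
    a, b = _prepare(a, b)
    return edlib.align(a, b, task="distance")["editDistance"]


def bounded_edit_distance(a: str, b: str, max_distance: int) -> int | None:
    """Edit distance if it is <= max_distance, else None.

    Uses a banded computation that abandons the dynamic program once the
    distance provably exceeds the bound; the criterion decision is unchanged
    but far-apart pairs are rejected quickly.
    """
    a, b = _prepare(a, b)
    d = edlib.align(a, b, task="distance", k=max_distance)["editDistance"]
    return None if d == -1 else d


def compare(a: str, b: str) -> GeneticComparison:
    return GeneticComparison(E=edit_distance(a, b), len_a=len(a), len_b=len(b))


def genetic_dissimilarity(a: str, b: str) -> float:
    """2E/(l1 + l2): edit distance normalized by the summed lengths."""
    return compare(a, b).dissimilarity


def passes_genetic_criterion(a: str, b: str, threshold: float) -> tuple[bool, float | None]:
    """Decide the genetic criterion, inclusively (equality passes).

    Merging is blocked only when the dissimilarity strictly exceeds the
    threshold. Returns ``(passed, dissimilarity)``; the dissimilarity is
    None when the banded computation established only that it exceeds the
    threshold.
    """
    if not 0 < threshold < 2:
        raise ValueError(f"genetic threshold must be in (0, 2), got {threshold}")
    # E <= threshold*(l1+l2)/2  <=>  dissimilarity <= threshold
    max_e = math.floor(threshold * (len(a) + len(b)) / 2.0)
    d = bounded_edit_distance(a, b, max_e)
    if d is None:
        return False, None
    return True, 2.0 * d / (len(a) + len(b))


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _make_aligner()


def alignment_dissimilarity_oracle(a: str, b: str) -> float:
    """Proportion of mismatched sites in a global pairwise alignment.

    The evaluation gold standard: aligns the two sequences globally with a
    match-favoring score (match +1, mismatch -1, gap open -2, extend -0.5)
    and returns mismatched aligned sites divided by the number of aligned
    positions where neither sequence has a gap — gap columns are excluded
    from the denominator.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    a = a.upper()
    b = b.upper()
    if a == b:
        return 0.0
    alignment = _ALIGNER.align(a, b)[0]
    top, bottom = str(alignment[0]), str(alignment[1])
    mismatches = 0
    aligned = 0
    for ca, cb in zip(top, bottom):
        if ca == "-" or cb == "-":
            continue
        aligned += 1
        if ca != cb or ca == "N":
            mismatches += 1
    if aligned == 0:
        return 1.0
    return mismatches / aligned
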