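"""Evaluation statistics for the genetic and distribution criteria.

Two benchmark styles are supported. For the genetic criterion, pairs of
sequences are classified as "similar" (at or below a dissimilarity level,
hence candidates for merging) or "dissimilar" by a metric and by a
gold-standard alignment; the 2x2 confusion, sensitivity and specificity
summarize agreement, and the Pearson correlation (with a Fisher-z 95% CI)
quantifies how well the fast metric tracks the gold standard among similar
pairs. For the distribution criterion, "dissimilar" (p below threshold,
blocking a merge) is the positive class and accuracy is reported as F1.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
from scipy import stats


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    true_similars: int
    false_similars: int
    false_dissimilars: int
    true_dissimilars: int

    @property
    def n_pairs(self) -> int:
        return (
            self.true_similars
            + self.false_similars
            + self.false_dissimilars
            + self.true_dissimilars
        )


def confusion(predicted: Sequence[bool], gold: Sequence[bool]) -> ConfusionCounts:
    """2x2 tally of similar/dissimilar calls. True means "similar"."""
    if len(predicted) != len(gold):
        raise ValueError("predicted and gold label lists differ in length")
    pred = np.asarray(predicted, dtype=bool)
    gld = np.asarray(gold, dtype=bool)
    return ConfusionCounts(
        true_similars=int((pred & gld).sum()),
        false_similars=int((pred & ~gld).sum()),
        false_dissimilars=int((~pred & gld).sum()),
        true_dissimilars=int((~pred & ~gld).sum()),
    )


def sensitivity_specificity(c: ConfusionCounts) -> tuple[float, float]:
    """(sensitivity %, specificity %) with "similar" the positive class.

    sensitivity = TS/(TS+FD); specificity = TD/(TD+FS). Raises when a
    denominator is zero (the quantity is undefined).
    """
    pos = c.true_similars + c.false_dissimilars
    neg = c.true_dissimilars + c.false_similars
    if pos == 0 or neg == 0:
        raise ValueError("sensitivity/specificity undefined: empty class")
    return (
        100.0 * c.true_similars / pos,
        100.0 * c.true_dissimilars / neg,
    )


def f1(true_dissimilars: int, false_dissimilars: int, false_similars: int) -> float:
    """F1 (%) with "dissimilar" as the positive class.

    F1 = 2 TD / (2 TD + FD + FS); e.g. 16 true dissimilars with 1 false
    dissimilar gives 32/33 = 97.0%.
    """
    denom = 2 * true_dissimilars + false_dissimilars + false_similars
    if denom == 0:
        raise ValueError("F1 undefined: no positive calls or positives")
    return 100.0 * 2 * true_dissimilars / denom


def pearson_ci(xs, ys, confidence: float = 0.95) -> tuple[float, float, float]:
    """Pearson r with a Fisher-z confidence interval, all as percentages."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size != ys.size or xs.size < 4:
        raise ValueError("need at least 4 paired values")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(stats.pearsonr(xs, ys).statistic)
    z = math.atanh(min(max(r, -1 + 1e-15), 1 - 1e-15))
    se = 1.0 / math.sqrt(xs.size - 3)
    crit = stats.norm.ppf(0.5 + confidence / 2)
    lo, hi = math.tanh(z - crit * se), math.tanh(z + crit * se)
    return 100.0 * r, 100.0 * lo, 100.0 * hi


@dataclasses.dataclass(frozen=True)
class SweepRow:
    threshold: float
    true_dissimilars: int
    false_dissimilars: int
    false_similars: int
    f1: float


def threshold_sweep(
    p_values: Sequence[float],
    gold_dissimilar: Sequence[bool],
    thresholds: Iterable[float],
) -> list[SweepRow]:
    """Re-threshold the test's p-values against fixed gold labels.

    A pair is called dissimilar when its p-value falls below the threshold.
    Gold labels stay fixed, so as the threshold rises the number of true
    dissimilars is non-decreasing and false similars non-increasing.
    """
    p = np.asarray(p_values, dtype=float)
    gold = np.asarray(gold_dissimilar, dtype=bool)
    if p.size != gold.size:
        raise ValueError("p_values and gold labels differ in length")
    rows = []
    for t in thresholds:
        called = p < t
        td = int((called & gold).sum())
        fd = int((called & ~gold).sum())
        fs = int((~called & gold).sum())
        rows.append(
            SweepRow(threshold=t, true_dissimilars=td, false_dissimilars=fd,
                     false_similars=fs, f1=f1(td, fd, fs))
        )
    return rows


def midpoint_thresholds(p_values: Sequence[float]) -> list[float]:
    """Geometric midpoints between consecutive distinct observed p-values.

    Useful sweep thresholds: each one separates a different subset of the
    observed tests.
    """
    uniq = sorted(set(float(p) for p in p_values if p > 0))
    return [math.sqrt(a * b) for a, b in zip(uniq, uniq[1:])]
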