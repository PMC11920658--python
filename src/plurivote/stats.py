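"""Aggregation of per-message accuracies: K_m summaries, ratios, confusion
tables, misclassification flows, and Mann-Whitney rank comparisons."""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .engine import MessageAccuracy
from .errors import (
    EmptyCategoryError,
    MissingDecisionError,
    MixedMError,
    ZeroReferenceError,
)
from .model import LABELS, LABEL_INDEX, CorpusBundle, SentimentLabel

__all__ = [
    "AccuracySummary",
    "ConfusionTable",
    "RankTestResult",
    "aggregate_K",
    "ratio_to_reference",
    "confusion_table",
    "misclassification_flows",
    "mann_whitney_u",
]

#: Category value used for the pooled across-categories row.
ALL = "ALL"


@dataclass(frozen=True)
class AccuracySummary:
    """Category-level mean accuracy (K_m) with its standard error across messages."""

    platform: str
    category: str  # a SentimentLabel value or "ALL"
    m: int
    n: int
    k_m: float
    se: float
    ratio_to_ref: Optional[float] = None  # percentage K_m / K_ref

    def __post_init__(self) -> None:
        if not 0.0 <= self.k_m <= 1.0 + 1e-12:
            raise ValueError(f"k_m out of range: {self.k_m}")
        if self.se < 0:
            raise ValueError("se must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass(frozen=True)
class ConfusionTable:
    """Counts of (human label x machine decision) for one platform at one m."""

    platform: str
    m: int
    counts: np.ndarray  # 5x5, rows human, cols machine, canonical label order

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=np.int64)
        if arr.shape != (len(LABELS), len(LABELS)):
            raise ValueError("counts must be 5x5")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", arr)

    @property
    def row_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def row(self, category: SentimentLabel) -> np.ndarray:
        return self.counts[LABEL_INDEX[category]]


@dataclass(frozen=True)
class RankTestResult:
    """Mann-Whitney U for sample_a, with tie-corrected normal-approximation p."""

    u_statistic: float
    n1: int
    n2: int
    z_value: float
    p_value: float
    degenerate: bool = False  # all pooled values identical; p forced to 1


def aggregate_K(per_message: Sequence[MessageAccuracy], platform: str,
                category: str) -> AccuracySummary:
    """Mean accuracy across messages with its standard error.

    ``se`` is the sample standard deviation (n-1 denominator) over per-message
    accuracies divided by sqrt(n) — variability across messages, not across
    Monte Carlo iterations.  Requires n >= 2 so the SE is defined.
    """
    if not per_message:
        raise ValueError("no accuracies to aggregate")
    ms = {a.m for a in per_message}
    if len(ms) != 1:
        raise MixedMError(f"mixed m values: {sorted(ms)}")
    n = len(per_message)
    if n < 2:
        raise ValueError("need at least 2 messages for a standard error")
    vals = np.array([a.accuracy for a in per_message])
    return AccuracySummary(
        platform=platform,
        category=category,
        m=ms.pop(),
        n=n,
        k_m=float(vals.mean()),
        se=float(vals.std(ddof=1) / math.sqrt(n)),
    )


def ratio_to_reference(summary_m: AccuracySummary,
                       summary_ref: AccuracySummary) -> float:
    """100 * K_m / K_ref, for matching platform and category."""
    if (summary_m.platform, summary_m.category) != (summary_ref.platform,
                                                    summary_ref.category):
        raise ValueError("ratio requires matching platform and category")
    if summary_ref.k_m == 0:
        raise ZeroReferenceError("reference K is zero")
    return 100.0 * summary_m.k_m / summary_ref.k_m


def confusion_table(bundle: CorpusBundle,
                    decisions: Mapping[str, SentimentLabel],
                    platform: str, m: int = 0) -> ConfusionTable:
    """Tally human label x machine decision over one platform's messages."""
    counts = np.zeros((len(LABELS), len(LABELS)), dtype=np.int64)
    for msg in bundle.messages:
        if msg.platform != platform:
            continue
        if msg.message_id not in decisions:
            raise MissingDecisionError(f"no decision for message {msg.message_id!r}")
        g = decisions[msg.message_id]
        counts[LABEL_INDEX[msg.human_label], LABEL_INDEX[g]] += 1
    return ConfusionTable(platform, m, counts)


def misclassification_flows(
    table: ConfusionTable, category: SentimentLabel
) -> tuple[float, dict[SentimentLabel, float]]:
    """Misclassification rate (%) for a human category and flow shares (%)
    over the wrong machine labels.

    rate = 100 * (row total - diagonal) / row total; each flow share is
    100 * count / (row total - diagonal).  Shares sum to 100 whenever any
    misclassification exists; flows are empty at rate 0.
    """
    row = table.row(category)
    total = int(row.sum())
    if total == 0:
        raise EmptyCategoryError(f"no messages with human label {category}")
    diag = int(row[LABEL_INDEX[category]])
    wrong = total - diag
    rate = 100.0 * wrong / total
    flows: dict[SentimentLabel, float] = {}
    if wrong > 0:
        for j, lab in enumerate(LABELS):
            if lab is category or row[j] == 0:
                continue
            flows[lab] = 100.0 * row[j] / wrong
    return rate, flows


def mann_whitney_u(sample_a: Sequence[float],
                   sample_b: Sequence[float]) -> RankTestResult:
    """Mann-Whitney U from rank sums with midranks for ties.

    U is reported for ``sample_a`` (U_a + U_b = n1*n2).  The two-sided p-value
    uses the normal approximation with tie-corrected variance and a continuity
    correction.  If all pooled values are identical the test is degenerate:
    U = n1*n2/2 and p = 1, flagged.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 observations")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    u_a = r1 - n1 * (n1 + 1) / 2.0

    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    if tie_counts.size == 1:  # every pooled value identical
        return RankTestResult(u_a, n1, n2, 0.0, 1.0, degenerate=True)

    mu = n1 * n2 / 2.0
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    sigma = math.sqrt(sigma2)
    diff = u_a - mu
    cc = 0.5 * np.sign(diff)  # continuity correction toward the mean
    z = (diff - cc) / sigma if diff != 0 else 0.0
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return RankTestResult(u_a, n1, n2, float(z), float(p))
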