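"""Plurality machine decisions over resampled response instances.

The core procedure: draw ``m`` instances from a message's pool of ``N``
responses uniformly with replacement, take the plurality (mode) label, and
break ties by redrawing single instances from the pool until one lands in the
tied set — equivalently, picking among tied labels with probability
proportional to their pool counts.  Per-message accuracy is the probability
that this decision equals the human label, estimated either by Monte Carlo
(the 1000-iteration protocol) or computed exactly by enumerating count
compositions of the ``m`` draws.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterator, Sequence

import numpy as np
from scipy.stats import multinomial

from .model import LABELS, LABEL_INDEX, ResponsePool, SentimentLabel

__all__ = [
    "DecisionSpec",
    "DecisionRecord",
    "MessageAccuracy",
    "sample_instances",
    "plurality_decision",
    "monte_carlo_accuracy",
    "decision_distribution",
    "exact_accuracy",
    "full_pool_decision",
    "full_pool_distribution",
    "exact_full_pool_accuracy",
    "iterate_decisions",
]

TIE_POLICY = "pool-proportional-redraw"


@dataclass(frozen=True)
class DecisionSpec:
    """Resampling protocol: m draws per decision, Monte Carlo iteration count, seed."""

    m: int
    iterations: int = 1000
    tie_policy: str = TIE_POLICY
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.tie_policy != TIE_POLICY:
            raise ValueError(f"unsupported tie policy {self.tie_policy!r}")

    def rng_for(self, message_id: str) -> np.random.Generator:
        """Independent deterministic substream for one (message, m) pair.

        Keyed by a stable hash of the message id so message order never
        affects results.
        """
        key = zlib.crc32(message_id.encode("utf-8"))
        return np.random.default_rng(np.random.SeedSequence([self.seed, key, self.m]))


@dataclass(frozen=True)
class DecisionRecord:
    """One Monte Carlo round: the sampled labels, the decision, and concurrence."""

    iteration: int
    sampled_labels: tuple[SentimentLabel, ...]
    decision: SentimentLabel
    concurrence: int


@dataclass(frozen=True)
class MessageAccuracy:
    """Per-message probability that the machine decision matches the human label."""

    message_id: str
    m: int
    accuracy: float
    method: str  # "monte_carlo" or "exact"

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0 + 1e-12:
            raise ValueError(f"accuracy out of range: {self.accuracy}")


def sample_instances(pool: ResponsePool, m: int,
                     rng: np.random.Generator) -> list[SentimentLabel]:
    """Draw m instance labels i.i.d. uniformly over the pool, with replacement."""
    if m < 1:
        raise ValueError("m must be >= 1")
    idx = rng.integers(0, pool.n, size=m)
    return [pool.instances[i] for i in idx]


def plurality_decision(sampled_labels: Sequence[SentimentLabel], pool: ResponsePool,
                       rng: np.random.Generator) -> SentimentLabel:
    """Label with the maximal count among the sample; ties broken by pool redraw.

    On a tie, single instances are redrawn uniformly from the full pool until
    one belongs to the tied set.  Tied labels were sampled, hence present in
    the pool, so termination is guaranteed.
    """
    if not sampled_labels:
        raise ValueError("empty sample")
    counts = np.zeros(len(LABELS), dtype=np.int64)
    for lab in sampled_labels:
        counts[LABEL_INDEX[lab]] += 1
    top = counts.max()
    tied = np.flatnonzero(counts == top)
    if len(tied) == 1:
        return LABELS[tied[0]]
    tied_set = {LABELS[i] for i in tied}
    while True:
        extra = pool.instances[rng.integers(0, pool.n)]
        if extra in tied_set:
            return extra


def iterate_decisions(pool: ResponsePool, human_label: SentimentLabel,
                      spec: DecisionSpec) -> Iterator[DecisionRecord]:
    """Yield one :class:`DecisionRecord` per Monte Carlo iteration."""
    rng = spec.rng_for(pool.message_id)
    for it in range(spec.iterations):
        sample = sample_instances(pool, spec.m, rng)
        decision = plurality_decision(sample, pool, rng)
        yield DecisionRecord(it, tuple(sample), decision,
                             int(decision == human_label))


def monte_carlo_accuracy(pool: ResponsePool, human_label: SentimentLabel,
                         spec: DecisionSpec) -> MessageAccuracy:
    """Mean concurrence over ``spec.iterations`` independent decision rounds.

    Statistically identical to averaging :func:`iterate_decisions` but the
    rounds are drawn in a single batched pass.  Deterministic given the spec's
    seed; independent of every other message.
    """
    rng = spec.rng_for(pool.message_id)
    iters, m = spec.iterations, spec.m
    inst = pool.label_indices()
    pool_counts = pool.count_vector().astype(float)

    draws = rng.integers(0, pool.n, size=(iters, m))
    sampled = inst[draws]                                    # (iters, m)
    counts = np.zeros((iters, len(LABELS)), dtype=np.int64)
    for k in range(len(LABELS)):
        counts[:, k] = (sampled == k).sum(axis=1)
    top = counts.max(axis=1)
    is_max = counts == top[:, None]
    n_tied = is_max.sum(axis=1)

    decisions = counts.argmax(axis=1)
    tied_rows = np.flatnonzero(n_tied > 1)
    if tied_rows.size:
        # pool-proportional choice among tied labels
        w = is_max[tied_rows] * pool_counts
        cdf = np.cumsum(w, axis=1)
        cdf /= cdf[:, -1:]
        u = rng.random(tied_rows.size)
        decisions[tied_rows] = (cdf > u[:, None]).argmax(axis=1)

    acc = float(np.mean(decisions == LABEL_INDEX[human_label]))
    return MessageAccuracy(pool.message_id, m, acc, "monte_carlo")


def _compositions(m: int, k: int) -> Iterator[tuple[int, ...]]:
    """All k-tuples of non-negative integers summing to m (stars and bars)."""
    for bars in combinations(range(m + k - 1), k - 1):
        prev = -1
        parts = []
        for b in bars:
            parts.append(b - prev - 1)
            prev = b
        parts.append(m + k - 1 - prev - 1)
        yield tuple(parts)


def decision_distribution(pool: ResponsePool, m: int) -> np.ndarray:
    """Exact probability of each label being the machine decision at a given m.

    Enumerates count-compositions of the m draws over the labels present in
    the pool, weights each by its multinomial probability under
    p = counts / N, assigns each composition's mass to its plurality label,
    and splits tie compositions' mass across the tied labels proportionally
    to their pool counts.  Returns a length-5 vector in canonical label order
    summing to 1.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    pool_counts = pool.count_vector()
    present = np.flatnonzero(pool_counts)
    k = present.size
    p = pool_counts[present] / pool.n

    comps = np.array(list(_compositions(m, k)), dtype=np.int64)
    pmf = multinomial(m, p).pmf(comps)
    pmf = np.atleast_1d(pmf)

    out = np.zeros(len(LABELS))
    for comp, mass in zip(comps, pmf):
        top = comp.max()
        tied = present[comp == top]
        if tied.size == 1:
            out[tied[0]] += mass
        else:
            w = pool_counts[tied].astype(float)
            out[tied] += mass * w / w.sum()
    return out


def exact_accuracy(pool: ResponsePool, human_label: SentimentLabel,
                   m: int) -> MessageAccuracy:
    """Exact plurality-win probability of the human label — the analytic
    counterpart of :func:`monte_carlo_accuracy`."""
    dist = decision_distribution(pool, m)
    return MessageAccuracy(pool.message_id, m,
                           float(dist[LABEL_INDEX[human_label]]), "exact")


def full_pool_distribution(pool: ResponsePool) -> np.ndarray:
    """Decision distribution for the plurality over all N instances (no resampling)."""
    counts = pool.count_vector()
    top = counts.max()
    tied = np.flatnonzero(counts == top)
    out = np.zeros(len(LABELS))
    w = counts[tied].astype(float)
    out[tied] = w / w.sum()  # tied labels share the top count, so this is uniform
    return out


def full_pool_decision(pool: ResponsePool, rng: np.random.Generator) -> SentimentLabel:
    """Plurality over all N instances; ties broken by the pool-proportional rule."""
    counts = pool.count_vector()
    top = counts.max()
    tied = np.flatnonzero(counts == top)
    if tied.size == 1:
        return LABELS[tied[0]]
    tied_set = {LABELS[i] for i in tied}
    while True:
        extra = pool.instances[rng.integers(0, pool.n)]
        if extra in tied_set:
            return extra


def exact_full_pool_accuracy(pool: ResponsePool,
                             human_label: SentimentLabel) -> MessageAccuracy:
    """Exact concurrence probability of the full-pool (reference) decision."""
    dist = full_pool_distribution(pool)
    return MessageAccuracy(pool.message_id, pool.n,
                           float(dist[LABEL_INDEX[human_label]]), "exact")
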