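"""Domain types: sentiment labels, annotated messages, response pools, corpora.

The five-category sentiment vocabulary is closed: every label that enters the
system passes through :func:`parse_label`, which is strict by design — a token
that is not one of the five names (after trimming and upcasing) is an error,
never silently repaired.
"""
from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import IntegrityError, UnparseableLabel

__all__ = [
    "SentimentLabel",
    "LABELS",
    "PLATFORMS",
    "parse_label",
    "AnnotatedMessage",
    "ResponsePool",
    "CorpusBundle",
]


class SentimentLabel(str, enum.Enum):
    """One of the five admissible sentiment categories."""

    ANTI = "ANTI"
    PRO = "PRO"
    NEU = "NEU"
    MIX = "MIX"
    IR = "IR"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical label order used for every count vector and probability vector.
LABELS: tuple[SentimentLabel, ...] = (
    SentimentLabel.ANTI,
    SentimentLabel.PRO,
    SentimentLabel.NEU,
    SentimentLabel.MIX,
    SentimentLabel.IR,
)

#: Index of each label in the canonical order.
LABEL_INDEX: Mapping[SentimentLabel, int] = {lab: i for i, lab in enumerate(LABELS)}

PLATFORMS: tuple[str, str] = ("facebook", "twitter")

_STRIP_CHARS = " \t\r\n.,;:!?\"'`()[]{}"


def parse_label(raw: str) -> SentimentLabel:
    """Normalize a raw token to a :class:`SentimentLabel`.

    Trims whitespace and surrounding punctuation and upcases; no fuzzy
    matching.  Raises :class:`UnparseableLabel` for anything outside the
    five-name vocabulary.
    """
    if not isinstance(raw, str) or not raw:
        raise UnparseableLabel(str(raw))
    token = raw.strip(_STRIP_CHARS).upper()
    try:
        return SentimentLabel(token)
    except ValueError:
        raise UnparseableLabel(raw) from None


@dataclass(frozen=True)
class AnnotatedMessage:
    """A human-labeled social-media message."""

    message_id: str
    platform: str
    human_label: SentimentLabel
    text: Optional[str] = None

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}; expected one of {PLATFORMS}")


@dataclass(frozen=True)
class ResponsePool:
    """The ordered labels of the N response instances collected for one message."""

    message_id: str
    instances: tuple[SentimentLabel, ...]

    def __post_init__(self) -> None:
        if len(self.instances) < 1:
            raise ValueError("a response pool needs at least one instance")
        object.__setattr__(self, "instances", tuple(self.instances))

    @property
    def n(self) -> int:
        return len(self.instances)

    @property
    def counts(self) -> Counter:
        """Tally of instance labels; always sums to ``n``."""
        return Counter(self.instances)

    def count_vector(self) -> np.ndarray:
        """Integer counts in canonical :data:`LABELS` order."""
        vec = np.zeros(len(LABELS), dtype=np.int64)
        for lab in self.instances:
            vec[LABEL_INDEX[lab]] += 1
        return vec

    def label_indices(self) -> np.ndarray:
        """Instances as integer indices into :data:`LABELS`."""
        return np.array([LABEL_INDEX[lab] for lab in self.instances], dtype=np.int64)

    def share(self, label: SentimentLabel) -> float:
        """Fraction of instances carrying ``label``."""
        return self.counts.get(label, 0) / self.n


@dataclass
class CorpusBundle:
    """Messages plus their response pools, with a one-to-one correspondence."""

    messages: list[AnnotatedMessage] = field(default_factory=list)
    pools: dict[str, ResponsePool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [m.message_id for m in self.messages]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate message ids: {dupes[:5]}")
        missing = [i for i in ids if i not in self.pools]
        if missing:
            raise IntegrityError(f"messages without pools: {missing[:5]}")
        orphans = sorted(set(self.pools) - set(ids))
        if orphans:
            raise IntegrityError(f"pools without messages: {orphans[:5]}")

    def __len__(self) -> int:
        return len(self.messages)

    def pool_for(self, message: AnnotatedMessage) -> ResponsePool:
        return self.pools[message.message_id]

    def subset(self, platform: Optional[str] = None,
               category: Optional[SentimentLabel] = None) -> "CorpusBundle":
        """Messages (and their pools) restricted to a platform and/or category."""
        msgs = [
            m for m in self.messages
            if (platform is None or m.platform == platform)
            and (category is None or m.human_label == category)
        ]
        return CorpusBundle(msgs, {m.message_id: self.pools[m.message_id] for m in msgs})


def pool_from_sequence(message_id: str, labels: Sequence[SentimentLabel]) -> ResponsePool:
    """Convenience constructor from any label sequence."""
    return ResponsePool(message_id, tuple(labels))
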