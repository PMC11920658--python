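"""Prompt construction and response collection against a pluggable backend.

A backend is anything with ``complete(prompt, session) -> str`` where every
distinct ``session`` token is an independent, context-free exchange.  The
deterministic mock backends below make the whole collection layer testable
offline; a real network client can implement the same protocol.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

from .errors import BackendError, MissingTextError, RejectedMessage, UnparseableLabel
from .model import (
    LABELS,
    AnnotatedMessage,
    ResponsePool,
    SentimentLabel,
    parse_label,
)
from .synthetic import GeneratorProfile, Stratum, _message_id, pool_labels

__all__ = [
    "CodingScheme",
    "default_scheme",
    "Backend",
    "build_prompt",
    "collect_instances",
    "StaticBackend",
    "StochasticBackend",
    "ProfileBackend",
]


@dataclass(frozen=True)
class CodingScheme:
    """Instructions, per-label definitions, and output-formatting rules."""

    instructions: str
    label_definitions: dict[SentimentLabel, str]
    formatting_rules: str

    def __post_init__(self) -> None:
        missing = [lab.value for lab in LABELS
                   if not self.label_definitions.get(lab, "").strip()]
        if missing:
            raise ValueError(f"labels without definitions: {missing}")


def default_scheme() -> CodingScheme:
    """A generic five-category sentiment codebook for heated-tobacco messages."""
    return CodingScheme(
        instructions=(
            "You are annotating social media messages about heated tobacco "
            "products. Read the message and assign exactly one sentiment "
            "category from the coding scheme below."
        ),
        label_definitions={
            SentimentLabel.ANTI: "The message expresses opposition to or criticism of heated tobacco products.",
            SentimentLabel.PRO: "The message expresses support for or a favorable view of heated tobacco products.",
            SentimentLabel.NEU: "The message discusses heated tobacco products without a positive or negative stance.",
            SentimentLabel.MIX: "The message contains both positive and negative attitudes toward heated tobacco products.",
            SentimentLabel.IR: "The message is irrelevant to heated tobacco products.",
        },
        formatting_rules="Respond with the category name only: ANTI, PRO, NEU, MIX, or IR.",
    )


class Backend(Protocol):
    """One fresh-session completion per call; no context carries across calls."""

    def complete(self, prompt: str, session: str) -> str: ...


def build_prompt(message: AnnotatedMessage, scheme: CodingScheme) -> str:
    """Deterministic prompt: instructions, the message, the coding scheme,
    formatting rules.  Contains every label name via the definitions block."""
    if not message.text:
        raise MissingTextError(f"message {message.message_id!r} has no text")
    definitions = "\n".join(
        f"{lab.value}: {scheme.label_definitions[lab]}" for lab in LABELS
    )
    return (
        f"{scheme.instructions}\n\n"
        f"Message:\n{message.text}\n\n"
        f"Coding scheme:\n{definitions}\n\n"
        f"{scheme.formatting_rules}"
    )


def collect_instances(backend: Backend, message: AnnotatedMessage,
                      scheme: CodingScheme, n: int = 20,
                      max_retries: int = 3) -> ResponsePool:
    """Gather n parsed response instances for one message.

    Each instance is an independent fresh-session request.  An unparseable
    response is retried up to ``max_retries`` times (each retry a new
    session); if still unparseable the whole message is abandoned with
    :class:`RejectedMessage` carrying the failure count.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    prompt = build_prompt(message, scheme)
    labels: list[SentimentLabel] = []
    failures = 0
    for i in range(n):
        label = None
        for attempt in range(max_retries + 1):
            session = f"{message.message_id}#{i}#{attempt}"
            try:
                raw = backend.complete(prompt, session)
            except Exception as err:  # noqa: BLE001 - wrapped with context
                raise BackendError(message.message_id, err) from err
            try:
                label = parse_label(raw)
                break
            except UnparseableLabel:
                failures += 1
        if label is None:
            raise RejectedMessage(message.message_id, failures)
        labels.append(label)
    return ResponsePool(message.message_id, tuple(labels))


@dataclass
class StaticBackend:
    """Always returns the same raw string."""

    response: str

    def complete(self, prompt: str, session: str) -> str:
        return self.response


@dataclass
class StochasticBackend:
    """Emits labels with fixed probabilities, deterministically per session.

    The draw is keyed by (seed, session token), so collection order across
    messages never changes any response.
    """

    probs: tuple[float, ...]  # over LABELS order
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (len(LABELS),) or (p < 0).any() or abs(p.sum() - 1) > 1e-9:
            raise ValueError("probs must be a length-5 distribution")

    def complete(self, prompt: str, session: str) -> str:
        key = zlib.crc32(session.encode())
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, key]))
        return LABELS[rng.choice(len(LABELS), p=np.asarray(self.probs))].value


class ProfileBackend:
    """Replays a :class:`GeneratorProfile`'s pools as raw responses.

    Shares the substream contract of the synthetic generator: collecting n
    instances for a generated message id reproduces the generated pool
    exactly, regardless of collection order.
    """

    def __init__(self, profile: GeneratorProfile):
        self.profile = profile
        self._strata: dict[str, tuple[Stratum, int]] = {}
        for stratum in profile.strata:
            for i in range(stratum.n_messages):
                self._strata[_message_id(stratum.platform, stratum.human_label, i)] = (
                    stratum, i)
        self._cache: dict[str, list[SentimentLabel]] = {}

    def complete(self, prompt: str, session: str) -> str:
        mid, instance, _attempt = session.rsplit("#", 2)
        if mid not in self._strata:
            raise KeyError(f"message {mid!r} not in profile")
        if mid not in self._cache:
            stratum, index = self._strata[mid]
            self._cache[mid] = pool_labels(self.profile, stratum, index)
        return self._cache[mid][int(instance)].value
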