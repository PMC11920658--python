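"""Dirichlet-multinomial generator for synthetic response pools.

Each message in a stratum (platform x human label) gets a label-probability
vector drawn from a Dirichlet with that stratum's concentration vector; its N
response-instance labels are then i.i.d. draws from that vector.  This is the
minimal hierarchy producing between-message heterogeneity in instance
agreement.  The analytic expectation of the m=1 concurrence probability is
alpha_human / sum(alpha), which makes profiles easy to calibrate.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import yaml

from .model import (
    LABELS,
    LABEL_INDEX,
    AnnotatedMessage,
    CorpusBundle,
    ResponsePool,
    SentimentLabel,
    parse_label,
)

__all__ = [
    "Stratum",
    "GeneratorProfile",
    "default_profiles",
    "generate_corpus",
    "expected_K1",
    "load_profile",
    "save_profile",
    "pool_labels",
]

#: Default total Dirichlet concentration; lower values give more
#: between-message heterogeneity in instance agreement.
DEFAULT_CONCENTRATION = 8.0

# Mean single-instance concurrence each default stratum is calibrated to,
# per (model-like profile, platform, human label).
_K1_TARGETS = {
    "gpt35_like": {
        ("facebook", SentimentLabel.ANTI): 0.657,
        ("facebook", SentimentLabel.PRO): 0.452,
        ("facebook", SentimentLabel.NEU): 0.428,
        ("twitter", SentimentLabel.ANTI): 0.614,
        ("twitter", SentimentLabel.PRO): 0.411,
        ("twitter", SentimentLabel.NEU): 0.444,
    },
    "gpt4turbo_like": {
        ("facebook", SentimentLabel.ANTI): 0.856,
        ("facebook", SentimentLabel.PRO): 0.828,
        ("facebook", SentimentLabel.NEU): 0.661,
        ("twitter", SentimentLabel.ANTI): 0.789,
        ("twitter", SentimentLabel.PRO): 0.773,
        ("twitter", SentimentLabel.NEU): 0.704,
    },
}

_STRATUM_SIZES = {
    SentimentLabel.ANTI: 200,
    SentimentLabel.PRO: 200,
    SentimentLabel.NEU: 100,
}


@dataclass(frozen=True)
class Stratum:
    platform: str
    human_label: SentimentLabel
    n_messages: int
    alpha: tuple[float, ...]  # five strictly positive concentrations

    def __post_init__(self) -> None:
        if self.n_messages < 1:
            raise ValueError("n_messages must be >= 1")
        alpha = tuple(float(a) for a in self.alpha)
        if len(alpha) != len(LABELS) or any(a <= 0 for a in alpha):
            raise ValueError("alpha needs five strictly positive entries")
        object.__setattr__(self, "alpha", alpha)


@dataclass(frozen=True)
class GeneratorProfile:
    strata: tuple[Stratum, ...]
    pool_size: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        object.__setattr__(self, "strata", tuple(self.strata))

    def scaled(self, factor: float) -> "GeneratorProfile":
        """Same alphas, stratum sizes scaled by ``factor`` (min 1 message)."""
        return GeneratorProfile(
            tuple(Stratum(s.platform, s.human_label,
                          max(1, round(s.n_messages * factor)), s.alpha)
                  for s in self.strata),
            self.pool_size, self.seed)


def _calibrated_alpha(human_label: SentimentLabel, k1: float,
                      concentration: float = DEFAULT_CONCENTRATION) -> tuple[float, ...]:
    """Concentration vector whose expected m=1 concurrence equals ``k1`` exactly.

    The human label gets k1 * concentration; the remaining mass is split evenly
    over the other four labels.
    """
    if not 0 < k1 < 1:
        raise ValueError("k1 must be in (0, 1)")
    rest = (1.0 - k1) * concentration / (len(LABELS) - 1)
    return tuple(k1 * concentration if lab is human_label else rest for lab in LABELS)


def default_profiles(seed: int = 0) -> dict[str, GeneratorProfile]:
    """Two named profiles at the reference scale: 200 ANTI + 200 PRO + 100 NEU
    messages per platform, two platforms, pools of 20."""
    profiles = {}
    for name, targets in _K1_TARGETS.items():
        strata = tuple(
            Stratum(platform, label, _STRATUM_SIZES[label],
                    _calibrated_alpha(label, k1))
            for (platform, label), k1 in targets.items()
        )
        profiles[name] = GeneratorProfile(strata, pool_size=20, seed=seed)
    return profiles


def expected_K1(alpha: Sequence[float], human_label: SentimentLabel) -> float:
    """Analytic expectation of single-instance concurrence: alpha_h / sum(alpha)."""
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (len(LABELS),) or (alpha <= 0).any():
        raise ValueError("alpha needs five strictly positive entries")
    return float(alpha[LABEL_INDEX[human_label]] / alpha.sum())


def _message_rng(seed: int, platform: str, human_label: SentimentLabel,
                 index: int) -> np.random.Generator:
    """Deterministic substream for one generated message, independent of the
    order strata or messages are visited in."""
    key = zlib.crc32(f"{platform}:{human_label.value}".encode())
    return np.random.default_rng(np.random.SeedSequence([seed, key, index]))


def _message_id(platform: str, human_label: SentimentLabel, index: int) -> str:
    return f"{platform}-{human_label.value.lower()}-{index:04d}"


def pool_labels(profile: GeneratorProfile, stratum: Stratum,
                index: int) -> list[SentimentLabel]:
    """The full instance-label sequence for one message of a stratum.

    Shared by :func:`generate_corpus` and the profile-driven mock backend so
    both produce byte-identical pools for the same (profile, message).
    """
    rng = _message_rng(profile.seed, stratum.platform, stratum.human_label, index)
    p = rng.dirichlet(stratum.alpha)
    idx = rng.choice(len(LABELS), size=profile.pool_size, p=p)
    return [LABELS[i] for i in idx]


def generate_corpus(profile: GeneratorProfile) -> CorpusBundle:
    """Deterministically generate a corpus with the profile's strata."""
    messages: list[AnnotatedMessage] = []
    pools: dict[str, ResponsePool] = {}
    for stratum in profile.strata:
        for i in range(stratum.n_messages):
            mid = _message_id(stratum.platform, stratum.human_label, i)
            messages.append(AnnotatedMessage(mid, stratum.platform,
                                             stratum.human_label))
            pools[mid] = ResponsePool(mid, tuple(pool_labels(profile, stratum, i)))
    return CorpusBundle(messages, pools)


def save_profile(profile: GeneratorProfile, path: Union[str, Path]) -> None:
    doc = {
        "pool_size": profile.pool_size,
        "seed": profile.seed,
        "strata": [
            {"platform": s.platform, "label": s.human_label.value,
             "n": s.n_messages, "alpha": list(s.alpha)}
            for s in profile.strata
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_profile(path: Union[str, Path]) -> GeneratorProfile:
    doc = yaml.safe_load(Path(path).read_text())
    strata = tuple(
        Stratum(s["platform"], parse_label(s["label"]), int(s["n"]),
                tuple(float(a) for a in s["alpha"]))
        for s in doc["strata"]
    )
    return GeneratorProfile(strata, int(doc.get("pool_size", 20)),
                            int(doc.get("seed", 0)))
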