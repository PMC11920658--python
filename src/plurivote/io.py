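"""CSV readers and writers for corpora, summaries, and confusion tables.

Formats (UTF-8, comma-delimited, mandatory header):

* ``messages.csv``:  message_id,platform,human_label[,text]
* ``responses.csv``: message_id,instance_index,label (long format, one row
  per response instance so instance identity is auditable)
* ``summary.csv``:   platform,category,m,n,k_m,se,ratio_to_ref
* ``confusion.csv``: platform,human_label,machine_label,count
"""
from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import IntegrityError, SchemaError
from .model import (
    LABELS,
    LABEL_INDEX,
    AnnotatedMessage,
    CorpusBundle,
    ResponsePool,
    parse_label,
)
from .stats import AccuracySummary, ConfusionTable

__all__ = [
    "read_corpus",
    "write_corpus",
    "read_summary",
    "write_summary",
    "read_confusion",
    "write_confusion",
]

PathLike = Union[str, Path]

_MESSAGE_COLS = ["message_id", "platform", "human_label"]
_RESPONSE_COLS = ["message_id", "instance_index", "label"]
_SUMMARY_COLS = ["platform", "category", "m", "n", "k_m", "se", "ratio_to_ref"]
_CONFUSION_COLS = ["platform", "m", "human_label", "machine_label", "count"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: PathLike) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def read_corpus(messages_path: PathLike, pools_path: PathLike,
                pool_size: Optional[int] = None) -> CorpusBundle:
    """Read and cross-validate a message table and its response pools.

    ``pool_size`` declares the expected N; when None it is inferred from the
    first pool and every pool must match it.  Row order never affects the
    resulting bundle.
    """
    msg_df = pd.read_csv(messages_path, dtype={"message_id": str}, keep_default_na=False)
    _require_columns(msg_df, _MESSAGE_COLS, messages_path)
    resp_df = pd.read_csv(pools_path, dtype={"message_id": str}, keep_default_na=False)
    _require_columns(resp_df, _RESPONSE_COLS, pools_path)

    messages = []
    for rec in msg_df.to_dict("records"):
        text = rec.get("text")
        messages.append(AnnotatedMessage(
            message_id=rec["message_id"],
            platform=rec["platform"],
            human_label=parse_label(rec["human_label"]),
            text=text if isinstance(text, str) and text else None,
        ))

    pools: dict[str, ResponsePool] = {}
    resp_df = resp_df.sort_values("instance_index")
    for mid, grp in resp_df.groupby("message_id", sort=False):
        idx = grp["instance_index"].to_numpy()
        if sorted(idx) != list(range(len(idx))):
            raise IntegrityError(
                f"{pools_path}: instance_index for {mid!r} is not 0..{len(idx) - 1}")
        pools[mid] = ResponsePool(mid, tuple(parse_label(t) for t in grp["label"]))

    n_expected = pool_size
    for mid, pool in pools.items():
        if n_expected is None:
            n_expected = pool.n
        if pool.n != n_expected:
            raise IntegrityError(
                f"{pools_path}: pool for {mid!r} has {pool.n} rows, expected {n_expected}")

    try:
        return CorpusBundle(messages, pools)
    except IntegrityError as err:
        raise IntegrityError(f"{messages_path} / {pools_path}: {err}") from None


def write_corpus(bundle: CorpusBundle, messages_path: PathLike,
                 pools_path: PathLike) -> None:
    """Write a corpus bundle to the two-file CSV layout."""
    msg_rows = [
        {"message_id": m.message_id, "platform": m.platform,
         "human_label": m.human_label.value, "text": m.text or ""}
        for m in bundle.messages
    ]
    pd.DataFrame(msg_rows, columns=_MESSAGE_COLS + ["text"]).to_csv(
        messages_path, index=False)

    resp_rows = [
        {"message_id": m.message_id, "instance_index": i, "label": lab.value}
        for m in bundle.messages
        for i, lab in enumerate(bundle.pools[m.message_id].instances)
    ]
    pd.DataFrame(resp_rows, columns=_RESPONSE_COLS).to_csv(pools_path, index=False)


def write_summary(summaries: Sequence[AccuracySummary], path: PathLike) -> None:
    """One row per (platform, category, m); floats kept at full precision."""
    if not summaries:
        raise ValueError("no summaries to write")
    rows = [
        {"platform": s.platform, "category": s.category, "m": s.m, "n": s.n,
         "k_m": repr(s.k_m), "se": repr(s.se),
         "ratio_to_ref": "" if s.ratio_to_ref is None else repr(s.ratio_to_ref)}
        for s in summaries
    ]
    pd.DataFrame(rows, columns=_SUMMARY_COLS).to_csv(path, index=False)


def read_summary(path: PathLike) -> list[AccuracySummary]:
    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    _require_columns(df, _SUMMARY_COLS, path)
    out = []
    for rec in df.to_dict("records"):
        ratio = rec["ratio_to_ref"]
        out.append(AccuracySummary(
            platform=rec["platform"], category=rec["category"],
            m=int(rec["m"]), n=int(rec["n"]),
            k_m=float(rec["k_m"]), se=float(rec["se"]),
            ratio_to_ref=None if ratio in ("", None) or (
                isinstance(ratio, float) and math.isnan(ratio)) else float(ratio),
        ))
    return out


def write_confusion(tables: Sequence[ConfusionTable], path: PathLike) -> None:
    rows = [
        {"platform": t.platform, "m": t.m, "human_label": h.value,
         "machine_label": g.value, "count": int(t.counts[i, j])}
        for t in tables
        for i, h in enumerate(LABELS)
        for j, g in enumerate(LABELS)
    ]
    pd.DataFrame(rows, columns=_CONFUSION_COLS).to_csv(path, index=False)


def read_confusion(path: PathLike) -> list[ConfusionTable]:
    df = pd.read_csv(path, keep_default_na=False)
    _require_columns(df, _CONFUSION_COLS, path)
    tables = []
    for (platform, m), grp in df.groupby(["platform", "m"], sort=False):
        counts = np.zeros((len(LABELS), len(LABELS)), dtype=np.int64)
        for rec in grp.to_dict("records"):
            i = LABEL_INDEX[parse_label(rec["human_label"])]
            j = LABEL_INDEX[parse_label(rec["machine_label"])]
            counts[i, j] = int(rec["count"])
        tables.append(ConfusionTable(platform, int(m), counts))
    return tables
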