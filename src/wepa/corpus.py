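"""Corpus cleaning, tokenization, and user-week aggregation.

Raw posts are concatenated chronologically within 7-day windows anchored
at each user's registration date (week index = floor(days since
registration / 7)), then cleaned: URLs, @-mentions, nonlinguistic symbol
runs and one-character tokens are dropped.  The tokenizer is injected so
the same pipeline serves whitespace-delimited test fixtures and external
segmenters for languages without word boundaries.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Callable, Iterable

import pandas as pd

__all__ = [
    "RawPost",
    "UserWeekText",
    "whitespace_tokenize",
    "clean_and_tokenize",
    "aggregate_week",
    "filter_panel",
    "read_corpus",
]

Tokenizer = Callable[[str], list[str]]

_URL_RE = re.compile(r"://|^www\.", re.IGNORECASE)
# "letter" in any script; CJK ideographs are alphabetic under str.isalpha()
_HAS_LETTER_RE = re.compile(r"[^\W\d_]", re.UNICODE)


@dataclass
class RawPost:
    user_id: str
    timestamp: datetime
    text: str


@dataclass
class UserWeekText:
    """One user's concatenated, cleaned text for one week since registration."""

    user_id: str
    week_index: int
    raw_text: str
    tokens: list[str] = field(default_factory=list)
    str_len: int = 0
    valid_str_len: int = 0

    def __post_init__(self) -> None:
        if self.week_index < 0:
            raise ValueError("week_index must be nonnegative")


def whitespace_tokenize(text: str) -> list[str]:
    return text.split()


def clean_and_tokenize(text: str, tokenizer: Tokenizer = whitespace_tokenize) -> list[str]:
    """Tokenize then drop URL tokens, @-mentions, letterless symbol runs,
    and one-character tokens.  Relative order is preserved; the empty list
    is a valid result."""
    out = []
    for tok in tokenizer(text):
        if len(tok) < 2:
            continue
        if tok.startswith("@"):
            continue
        if _URL_RE.search(tok):
            continue
        if not _HAS_LETTER_RE.search(tok):
            continue
        out.append(tok)
    return out


def _as_datetime(ts: datetime | date | str) -> datetime:
    if isinstance(ts, datetime):
        return ts
    if isinstance(ts, date):
        return datetime(ts.year, ts.month, ts.day)
    return datetime.fromisoformat(str(ts))


def aggregate_week(
    posts: Iterable[RawPost],
    registration_date: datetime | date | str,
    tokenizer: Tokenizer = whitespace_tokenize,
) -> list[UserWeekText]:
    """Bucket one user's posts into registration-anchored 7-day weeks.

    Texts are concatenated in ascending timestamp order with a single
    separating space; weeks with no posts yield no record.  A post dated
    before registration is an error (identifies the offending post).
    """
    posts = list(posts)
    if not posts:
        return []
    users = {p.user_id for p in posts}
    if len(users) != 1:
        raise ValueError(f"posts span multiple users: {sorted(users)}")
    reg = _as_datetime(registration_date)
    buckets: dict[int, list[RawPost]] = {}
    for p in posts:
        ts = _as_datetime(p.timestamp)
        if ts < reg:
            raise ValueError(
                f"post by {p.user_id!r} at {ts.isoformat()} predates "
                f"registration {reg.isoformat()}"
            )
        week = int((ts - reg).days // 7)
        buckets.setdefault(week, []).append(p)
    records = []
    for week in sorted(buckets):
        ordered = sorted(buckets[week], key=lambda p: _as_datetime(p.timestamp))
        raw_text = " ".join(p.text for p in ordered)
        tokens = clean_and_tokenize(raw_text, tokenizer)
        records.append(
            UserWeekText(
                user_id=posts[0].user_id,
                week_index=week,
                raw_text=raw_text,
                tokens=tokens,
                str_len=len(raw_text),
                valid_str_len=len(tokens),
            )
        )
    return records


def filter_panel(
    records: Iterable[UserWeekText],
    user_info: dict[str, object] | pd.DataFrame,
    min_weeks: int = 2,
) -> tuple[list[UserWeekText], pd.DataFrame]:
    """Apply the panel inclusion rules and report removals by reason.

    Drops, in order: records whose cleaned text is empty; all records of
    users absent from the registration table; all records of users left
    with fewer than ``min_weeks`` valid weeks.  Idempotent.
    """
    if isinstance(user_info, pd.DataFrame):
        known_users = set(user_info["user_id"].astype(str))
    else:
        known_users = set(map(str, user_info))
    records = list(records)
    report: Counter[str] = Counter()

    kept = []
    for r in records:
        if not r.tokens:
            report["empty_text"] += 1
        else:
            kept.append(r)

    kept2 = []
    for r in kept:
        if str(r.user_id) not in known_users:
            report["missing_registration"] += 1
        else:
            kept2.append(r)

    weeks_per_user = Counter(r.user_id for r in kept2)
    retained = []
    for r in kept2:
        if weeks_per_user[r.user_id] < min_weeks:
            report["too_few_weeks"] += 1
        else:
            retained.append(r)

    report_df = pd.DataFrame(
        {"reason": list(report.keys()), "n_removed": list(report.values())}
    )
    return retained, report_df


def read_corpus(path: str | Path) -> list[RawPost]:
    """Read posts from TSV (user_id, timestamp, text header) or JSONL."""
    path = Path(path)
    posts = []
    if path.suffix.lower() in {".jsonl", ".ndjson"}:
        with path.open("r", encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                obj = json.loads(line)
                posts.append(
                    RawPost(
                        user_id=str(obj["user_id"]),
                        timestamp=_as_datetime(obj["timestamp"]),
                        text=str(obj.get("text", "")),
                    )
                )
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        for row in df.itertuples(index=False):
            posts.append(
                RawPost(
                    user_id=str(row.user_id),
                    timestamp=_as_datetime(row.timestamp),
                    text=str(row.text),
                )
            )
    return posts
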