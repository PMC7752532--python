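"""Post corpus I/O, de-identification, date filtering, and summaries.

A corpus is a UTF-8 line-delimited file, one JSON object per line with
keys ``post_id``, ``platform``, ``source_type`` (blog|community),
``date`` (ISO-8601 day) and ``text``. The post is the unit of analysis
throughout the package, so duplicate post ids abort ingestion: silent
deduplication (or double counting) would corrupt every downstream
frequency.
"""

from __future__ import annotations

import datetime as dt
import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

SOURCE_TYPES = ("blog", "community")


class CorpusError(Exception):
    """A corpus file violates the record format."""


@dataclass(frozen=True)
class PostRecord:
    post_id: str
    platform: str
    source_type: str
    date: dt.date
    text: str


@dataclass
class CorpusSummary:
    """Post counts overall and by year / platform / source type."""

    total: int
    by_year: dict[int, int] = field(default_factory=dict)
    by_platform: dict[str, int] = field(default_factory=dict)
    by_source: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_year_counts(cls, by_year: dict[int, int]) -> "CorpusSummary":
        """Build a summary from yearly counts alone (total = their sum)."""
        return cls(total=sum(by_year.values()), by_year=dict(by_year))

    def to_frame(self) -> pd.DataFrame:
        rows = [("total", "all", self.total)]
        rows += [("year", str(y), n) for y, n in sorted(self.by_year.items())]
        rows += [("platform", p, n) for p, n in sorted(self.by_platform.items())]
        rows += [("source", s, n) for s, n in sorted(self.by_source.items())]
        return pd.DataFrame(rows, columns=["stratum_kind", "stratum", "n_posts"])


_MANDATORY = ("post_id", "platform", "source_type", "date", "text")


def read_corpus(path: str | Path) -> list[PostRecord]:
    """Read a line-delimited corpus; malformed lines are reported with
    their line number, duplicate post ids abort the read."""
    records: list[PostRecord] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as e:
                raise CorpusError(f"{path}:{lineno}: invalid JSON ({e})") from None
            missing = [k for k in _MANDATORY if k not in obj]
            if missing:
                raise CorpusError(
                    f"{path}:{lineno}: record missing field(s) {missing}"
                )
            if obj["source_type"] not in SOURCE_TYPES:
                raise CorpusError(
                    f"{path}:{lineno}: source_type must be one of {SOURCE_TYPES}"
                )
            try:
                date = dt.date.fromisoformat(obj["date"])
            except ValueError:
                raise CorpusError(
                    f"{path}:{lineno}: unparseable date {obj['date']!r}"
                ) from None
            pid = str(obj["post_id"])
            if pid in seen:
                raise CorpusError(f"{path}:{lineno}: duplicate post_id {pid!r}")
            seen.add(pid)
            records.append(PostRecord(pid, str(obj["platform"]),
                                      obj["source_type"], date, str(obj["text"])))
    return records


def write_corpus(records: Iterable[PostRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(json.dumps({
                "post_id": r.post_id,
                "platform": r.platform,
                "source_type": r.source_type,
                "date": r.date.isoformat(),
                "text": r.text,
            }, ensure_ascii=False) + "\n")


# -- de-identification -----------------------------------------------------
# Pattern-based masking of phone numbers, e-mails, URLs (which embed
# account names) and @handles. Personal names require NER and are a
# documented limitation. Placeholders contain no digits and no '@', so
# the operation is idempotent.

_DEID_PATTERNS = [
    (re.compile(r"https?://\S+|www\.\S+"), "[URL]"),
    (re.compile(r"[A-Za-z0-9._%+-]+@[A-Za-z0-9-]+(?:\.[A-Za-z0-9-]+)+"), "[EMAIL]"),
    (re.compile(r"\b0\d{1,2}[- ]?\d{3,4}[- ]\d{4}\b"), "[PHONE]"),
    (re.compile(r"@\w+"), "[HANDLE]"),
]


def deidentify(text: str) -> str:
    """Replace identifying substrings with fixed per-category placeholders."""
    for pattern, placeholder in _DEID_PATTERNS:
        text = pattern.sub(placeholder, text)
    return text


# -- filtering and summarising --------------------------------------------

def filter_by_date(corpus: Sequence[PostRecord], start: dt.date,
                   end: dt.date) -> list[PostRecord]:
    """Retain records with start <= date <= end (closed interval)."""
    if start > end:
        raise ValueError(f"start {start} is after end {end}")
    return [r for r in corpus if start <= r.date <= end]


def summarize_corpus(corpus: Sequence[PostRecord]) -> CorpusSummary:
    by_year = Counter(r.date.year for r in corpus)
    by_platform = Counter(r.platform for r in corpus)
    by_source = Counter(r.source_type for r in corpus)
    return CorpusSummary(
        total=len(corpus),
        by_year=dict(sorted(by_year.items())),
        by_platform=dict(sorted(by_platform.items())),
        by_source=dict(sorted(by_source.items())),
    )
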