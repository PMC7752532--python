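"""Post-level frequency analysis.

Counting is binary per post: a post contributes at most one count to a
concept however often its terms occur, and one count to a superclass S
iff it mentions any concept in S's subtree (including S's own surface
forms — "unspecified treatment" style mentions). Relative frequencies
are percentages of the stratum total N, reported rounded half-up to one
decimal with the raw fraction retained.

Strata overlap: a post mentioning two cancer types belongs to both
strata, and each stratum's denominator is its own post total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import pandas as pd

from .annotate import PostAnnotation
from .ontology import Ontology

ALL_STRATA = "ALL"
LEVELS = ("superclass", "class", "end_node")


class FrequencyError(Exception):
    pass


@dataclass(frozen=True)
class FrequencyRow:
    concept_id: str
    n_posts: int
    pct_raw: float
    pct: float


@dataclass
class FrequencyTable:
    """Counts n_c and percentages p_c per concept within one stratum of
    total N. Rows may sum above N — a post can carry many concepts."""

    stratum: str
    level: str
    rows: list[FrequencyRow] = field(default_factory=list)
    total: int = 0

    def to_frame(self, ont: Ontology | None = None) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "stratum": self.stratum,
                "level": self.level,
                "concept_id": r.concept_id,
                "label": (ont.node(r.concept_id).preferred_label
                          if ont is not None else r.concept_id),
                "n_posts": r.n_posts,
                "total": self.total,
                "pct_raw": r.pct_raw,
                "pct_rounded": r.pct,
            }
            for r in self.rows
        ])

    def get(self, concept_id: str) -> FrequencyRow | None:
        for r in self.rows:
            if r.concept_id == concept_id:
                return r
        return None


@dataclass
class RankComparison:
    social_top: list[str]
    registry_top: list[str]
    shared: set[str]
    social_only: set[str]
    registry_only: set[str]
    #: concept -> (social rank or None, registry rank or None), 1-based
    rank_pairs: dict[str, tuple[int | None, int | None]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"type": t, "social_rank": s, "registry_rank": r}
            for t, (s, r) in sorted(
                self.rank_pairs.items(),
                key=lambda kv: (kv[1][0] is None, kv[1][0] or 0, kv[0]),
            )
        ])


# -- primitives ------------------------------------------------------------

def relative_frequency(n: int, total: int) -> float:
    """100·n/total rounded half-up to one decimal (the raw value is what
    FrequencyTable rows retain alongside)."""
    if total <= 0:
        raise FrequencyError("relative frequency undefined for total <= 0")
    if not 0 <= n <= total:
        raise FrequencyError(f"count {n} outside [0, {total}]")
    return float(
        (Decimal(n) * 100 / Decimal(total)).quantize(Decimal("0.1"), ROUND_HALF_UP)
    )


def _qualifying(annotations: Sequence[PostAnnotation]) -> list[PostAnnotation]:
    """The analysis corpus: cancer posts that are not advertisements."""
    return [a for a in annotations if a.is_cancer_post and not a.is_ad]


def _concepts_at_level(a: PostAnnotation, ont: Ontology, level: str) -> set[str]:
    for c in a.concepts:
        if c not in ont.nodes:
            raise FrequencyError(f"annotation of {a.post_id!r} carries concept "
                                 f"{c!r} absent from the ontology")
    if level == "class":
        return set(a.concepts)
    if level == "end_node":
        return {c for c in a.concepts if not ont.children(c)}
    if level == "superclass":
        return {ont.superclass_of(c) for c in a.concepts}
    raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")


def _table(annotations: Sequence[PostAnnotation], ont: Ontology, level: str,
           stratum: str) -> FrequencyTable:
    counts: dict[str, int] = {}
    for a in annotations:
        for c in _concepts_at_level(a, ont, level):
            counts[c] = counts.get(c, 0) + 1
    total = len(annotations)
    rows = [
        FrequencyRow(c, n, 100.0 * n / total, relative_frequency(n, total))
        for c, n in counts.items()
    ] if total > 0 else []
    rows.sort(key=lambda r: (-r.n_posts, r.concept_id))
    return FrequencyTable(stratum=stratum, level=level, rows=rows, total=total)


# -- operations ------------------------------------------------------------

def count_posts_by_concept(
    annotations: Sequence[PostAnnotation], ont: Ontology, level: str = "class"
) -> FrequencyTable:
    """Frequency table over the whole analysis corpus (stratum ALL)."""
    return _table(_qualifying(annotations), ont, level, ALL_STRATA)


def rollup_to_superclass(
    annotations: Sequence[PostAnnotation], ont: Ontology
) -> FrequencyTable:
    """Superclass table: a post counts once toward S iff it mentions any
    concept in subtree(S)."""
    return count_posts_by_concept(annotations, ont, level="superclass")


def stratify_by_cancer_type(
    annotations: Sequence[PostAnnotation],
    ont: Ontology,
    types: Sequence[str],
    level: str = "superclass",
) -> dict[str, FrequencyTable]:
    """Per-cancer-type tables. The stratum for type t is the set of
    qualifying posts whose concepts include t; counts and percentages
    are against that stratum's own N (reported even when N = 0)."""
    qualifying = _qualifying(annotations)
    out: dict[str, FrequencyTable] = {}
    for t in types:
        ont.node(t)  # raises UnknownConceptError for unknown ids
        members = ont.subtree(t)
        stratum = [a for a in qualifying if a.concepts & members]
        out[t] = _table(stratum, ont, level, stratum=t)
    return out


def rank_top_n(table: FrequencyTable, n: int) -> list[str]:
    """Concept ids of the top *n* rows by post count, ties broken by
    lexicographic concept_id."""
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    ordered = sorted(table.rows, key=lambda r: (-r.n_posts, r.concept_id))
    return [r.concept_id for r in ordered[:n]]


def compare_rankings(
    social_top: Sequence[str], registry_top: Sequence[str]
) -> RankComparison:
    """Set algebra between two deduplicated ranked lists."""
    for name, lst in (("social_top", social_top), ("registry_top", registry_top)):
        if len(set(lst)) != len(lst):
            raise ValueError(f"{name} contains duplicates")
    social, registry = set(social_top), set(registry_top)
    pairs: dict[str, tuple[int | None, int | None]] = {}
    for i, t in enumerate(social_top, start=1):
        pairs[t] = (i, None)
    for i, t in enumerate(registry_top, start=1):
        pairs[t] = (pairs.get(t, (None, None))[0], i)
    return RankComparison(
        social_top=list(social_top),
        registry_top=list(registry_top),
        shared=social & registry,
        social_only=social - registry,
        registry_only=registry - social,
        rank_pairs=pairs,
    )


# -- registry statistics ---------------------------------------------------

def read_registry(path: str | Path) -> pd.DataFrame:
    """Registry incidence table: cancer_type_label, concept_id,
    incidence_rank (1-based), sorted by rank."""
    df = pd.read_csv(path)
    required = {"cancer_type_label", "concept_id", "incidence_rank"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"registry file missing column(s) {sorted(missing)}")
    return df.sort_values("incidence_rank").reset_index(drop=True)


def registry_top_n(df: pd.DataFrame, n: int) -> list[str]:
    return list(df.sort_values("incidence_rank")["concept_id"].head(n))
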