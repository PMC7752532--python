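"""Ontology-driven post annotation.

The pipeline per post is fixed: normalize → de-identify → advertising
check → stop-phrase masking → dictionary matching. Advertising posts
are dropped whole (their concept set stays empty); stop phrases, by
contrast, mask only the offending region — "agseong virus" (computer
virus) is overwritten in place so the embedded cancer keyword "agseong"
(malignant) cannot fire, while the rest of the post still matches.

Matching is normalized substring search: Korean is agglutinative
("jaegeomsa" contains "jaegeom"), so token-boundary matching would miss
exactly the consumer abbreviations the terminology exists for.
Overlapping candidates are resolved longest-first, then leftmost-first;
the accepted spans never overlap each other or a masked region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import PostRecord, deidentify
from .ontology import Ontology
from .textnorm import MASK_CHAR, normalize

logger = logging.getLogger(__name__)


class AmbiguousTermError(Exception):
    """An ambiguous surface form (two concepts) matched; the terminology
    must be disambiguated (usually with a stop phrase) before use."""


@dataclass(frozen=True)
class StopPhrase:
    phrase: str
    note: str = ""


@dataclass(frozen=True)
class MatchSpan:
    """Character span [start, end) in the processed (normalized, masked)
    text, with the surface form that matched and its concept."""

    start: int
    end: int
    surface_form: str
    concept_id: str


@dataclass
class PostAnnotation:
    post_id: str
    concepts: set[str] = field(default_factory=set)
    spans: list[MatchSpan] = field(default_factory=list)
    is_ad: bool = False
    is_cancer_post: bool = False


@dataclass
class AnnotationConfig:
    ad_keywords: list[str] = field(default_factory=list)
    stop_phrases: list[StopPhrase] = field(default_factory=list)
    cancer_type_root: str = "cancer_type"
    apply_deidentify: bool = True
    apply_stop_phrases: bool = True

    def __post_init__(self) -> None:
        # deduplicate after normalization, preserving first occurrence
        self.ad_keywords = list(dict.fromkeys(
            k for k in (normalize(k) for k in self.ad_keywords) if k))
        seen: dict[str, StopPhrase] = {}
        for sp in self.stop_phrases:
            key = normalize(sp.phrase)
            if key and key not in seen:
                seen[key] = StopPhrase(key, sp.note)
        self.stop_phrases = list(seen.values())


# -- keyword list files ----------------------------------------------------

def load_keywords(path: str | Path) -> list[str]:
    """One entry per line; '#' starts a comment; blanks ignored."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        entry = line.split("#", 1)[0].strip()
        if entry:
            out.append(entry)
    return out


def load_stop_phrases(path: str | Path) -> list[StopPhrase]:
    """Stop phrase file: phrase TAB note, '#' comments allowed."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        entry = line.split("#", 1)[0].rstrip()
        if not entry.strip():
            continue
        phrase, _, note = entry.partition("\t")
        out.append(StopPhrase(phrase.strip(), note.strip()))
    return out


def default_config(**overrides) -> AnnotationConfig:
    """AnnotationConfig built from the packaged ad-keyword and
    stop-phrase lists."""
    data = resources.files("oncolex").joinpath("data")
    cfg = AnnotationConfig(
        ad_keywords=load_keywords(Path(data / "ad_keywords.txt")),
        stop_phrases=load_stop_phrases(Path(data / "stop_phrases.txt")),
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


# -- span selection --------------------------------------------------------

def _occurrences(text: str, needle: str) -> Iterable[int]:
    start = 0
    while True:
        i = text.find(needle, start)
        if i < 0:
            return
        yield i
        start = i + 1


def _select_spans(candidates: list[tuple[int, int, str]]) -> list[tuple[int, int, str]]:
    """Greedy non-overlapping selection: longest first, then leftmost,
    then lexicographic on the needle for full determinism."""
    chosen: list[tuple[int, int, str]] = []
    for start, end, needle in sorted(
        candidates, key=lambda c: (-(c[1] - c[0]), c[0], c[2])
    ):
        if all(end <= s or start >= e for s, e, _ in chosen):
            chosen.append((start, end, needle))
    return sorted(chosen)


# -- operations ------------------------------------------------------------

def mask_stop_phrases(
    text: str, stop_phrases: Sequence[StopPhrase]
) -> tuple[str, list[tuple[int, int]]]:
    """Overwrite every stop-phrase occurrence with a same-length run of
    the mask character; returns the masked text and the masked spans."""
    candidates = [
        (i, i + len(key), key)
        for sp in stop_phrases
        for key in [normalize(sp.phrase)]
        if key
        for i in _occurrences(text, key)
    ]
    spans = [(s, e) for s, e, _ in _select_spans(candidates)]
    if not spans:
        return text, []
    chars = list(text)
    for s, e in spans:
        chars[s:e] = MASK_CHAR * (e - s)
    return "".join(chars), spans


def is_advertisement(post: PostRecord | str, ad_keywords: Sequence[str]) -> bool:
    """True iff the normalized text contains any ad keyword as a substring."""
    text = normalize(post.text if isinstance(post, PostRecord) else post)
    return any(normalize(k) in text for k in ad_keywords if normalize(k))


class ConceptMatcher:
    """Dictionary matcher over an ontology's terminology.

    Built once per corpus; raises AmbiguousTermError if an ambiguous
    surface form (validator warning AMBIGUOUS_TERM) actually occurs in
    a text rather than silently picking a concept.
    """

    def __init__(self, ont: Ontology):
        self.ontology = ont
        index = ont.term_index()
        self._unambiguous = {k: next(iter(v)) for k, v in index.items() if len(v) == 1}
        self._ambiguous = {k for k, v in index.items() if len(v) > 1}

    def match(self, text: str) -> list[MatchSpan]:
        candidates: list[tuple[int, int, str]] = []
        for key in self._ambiguous:
            for i in _occurrences(text, key):
                raise AmbiguousTermError(
                    f"ambiguous term {key!r} at offset {i}; resolve it in the "
                    f"terminology or mask it with a stop phrase"
                )
        for key in self._unambiguous:
            for i in _occurrences(text, key):
                candidates.append((i, i + len(key), key))
        return [
            MatchSpan(s, e, k, self._unambiguous[k])
            for s, e, k in _select_spans(candidates)
        ]


def match_terms(text: str, ont: Ontology) -> list[MatchSpan]:
    """All non-overlapping term matches in *text* (already normalized
    and stop-masked), longest-first then leftmost."""
    return ConceptMatcher(ont).match(text)


def annotate_post(
    post: PostRecord,
    ont: Ontology,
    cfg: AnnotationConfig,
    matcher: ConceptMatcher | None = None,
) -> PostAnnotation:
    """Run the full per-post pipeline and return its annotation."""
    if matcher is None:
        matcher = ConceptMatcher(ont)
    text = normalize(post.text)
    if cfg.apply_deidentify:
        text = deidentify(text)
    if is_advertisement(text, cfg.ad_keywords):
        return PostAnnotation(post.post_id, is_ad=True)
    if cfg.apply_stop_phrases:
        text, _ = mask_stop_phrases(text, cfg.stop_phrases)
    spans = matcher.match(text)
    concepts = {s.concept_id for s in spans}
    cancer_members = ont.subtree(cfg.cancer_type_root)
    return PostAnnotation(
        post_id=post.post_id,
        concepts=concepts,
        spans=spans,
        is_ad=False,
        is_cancer_post=bool(concepts & cancer_members),
    )


def annotate_corpus(
    corpus: Sequence[PostRecord], ont: Ontology, cfg: AnnotationConfig
) -> list[PostAnnotation]:
    """Annotate every post, preserving order; logs ad / cancer-post counts."""
    matcher = ConceptMatcher(ont)
    annotations = [annotate_post(p, ont, cfg, matcher) for p in corpus]
    n_ad = sum(a.is_ad for a in annotations)
    n_cancer = sum(a.is_cancer_post for a in annotations)
    logger.info(
        "annotated %d posts: %d advertising (removed), %d cancer posts",
        len(annotations), n_ad, n_cancer,
    )
    return annotations
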