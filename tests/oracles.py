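"""Independent brute-force reference implementations used as oracles.

Deliberately naive: position-by-position scans and explicit arg-max
loops, sharing no code with the package's matcher or hierarchy walks.
"""

from __future__ import annotations


def all_occurrences(text: str, needle: str) -> list[int]:
    if not needle:
        return []
    return [
        i
        for i in range(len(text) - len(needle) + 1)
        if text[i:i + len(needle)] == needle
    ]


def select_spans(candidates: list[tuple[int, int, str]]) -> list[tuple[int, int, str]]:
    """Maximal non-overlapping span set under the (length desc, start
    asc, needle asc) priority, picked one at a time by explicit scan."""
    remaining = list(candidates)
    chosen: list[tuple[int, int, str]] = []
    while remaining:
        best = None
        for cand in remaining:
            if best is None:
                best = cand
                continue
            key_c = (-(cand[1] - cand[0]), cand[0], cand[2])
            key_b = (-(best[1] - best[0]), best[0], best[2])
            if key_c < key_b:
                best = cand
        chosen.append(best)
        remaining = [
            c for c in remaining
            if c[1] <= best[0] or c[0] >= best[1]
        ]
    return sorted(chosen)


def brute_match(text: str, index: dict[str, str]) -> list[tuple[int, int, str, str]]:
    """All-position scan matcher: index maps surface form -> concept_id."""
    candidates = [
        (i, i + len(surface), surface)
        for surface in index
        for i in all_occurrences(text, surface)
    ]
    return [(s, e, k, index[k]) for s, e, k in select_spans(candidates)]


def brute_mask(text: str, phrases: list[str], mask_char: str) -> str:
    spans = select_spans([
        (i, i + len(p), p) for p in phrases for i in all_occurrences(text, p)
    ])
    chars = list(text)
    for s, e, _ in spans:
        for j in range(s, e):
            chars[j] = mask_char
    return "".join(chars)


def ancestor_chain(parents: dict[str, str | None], cid: str) -> list[str]:
    chain = []
    cur = parents[cid]
    while cur is not None:
        chain.append(cur)
        cur = parents[cur]
    return chain


def brute_descendants(parents: dict[str, str | None], cid: str) -> set[str]:
    """v is a descendant of cid iff cid lies on v's ancestor chain."""
    return {v for v in parents if cid in ancestor_chain(parents, v)}
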