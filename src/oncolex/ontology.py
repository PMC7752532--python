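"""Cancer ontology and consumer terminology.

The ontology is a forest: nine root concepts (superclasses) — cancer
type, prevention, diagnosis, treatment, prognosis, risk factor, symptom,
dealing with cancer, emotion — each carrying a shallow subtree of class
concepts (3–4 hierarchy levels in total). A terminology maps consumer
surface forms (preferred terms, synonyms, abbreviations, heteronyms such
as "jol-eob" = graduation = complete cure) onto those concepts.

Canonical on-disk form is a UTF-8 tab-separated table with one row per
term (columns ``concept_id``, ``parent_id``, ``preferred_label``,
``term_type``, ``surface_form``); an OBO-like stanza format is supported
as an interchange export. A packaged skeleton covers the named portion
of the hierarchy and ships with the package.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .textnorm import normalize

TERM_TYPES = ("preferred", "synonym", "abbreviation", "heteronym")

DEFAULT_MAX_DEPTH = 4


class OntologyError(Exception):
    """Base class for ontology loading/validation failures."""


class OntologyParseError(OntologyError):
    """A line of an ontology file could not be parsed."""


class OntologyStructureError(OntologyError):
    """The parsed rows do not form a valid forest."""


class UnknownConceptError(OntologyError, KeyError):
    """A concept_id was requested that the ontology does not contain."""


@dataclass(frozen=True)
class ConceptNode:
    """One class concept. ``parent_id is None`` iff the node is a
    superclass root; ``level`` is the number of parent hops to its root."""

    concept_id: str
    preferred_label: str
    parent_id: str | None = None
    level: int = 0


@dataclass(frozen=True)
class TermEntry:
    """One terminology row: a surface form naming a concept."""

    surface_form: str
    concept_id: str
    term_type: str = "synonym"


@dataclass
class Counts:
    n_superclasses: int = 0
    n_classes: int = 0
    n_terms: int = 0
    max_depth: int = 0


@dataclass
class ValidationReport:
    errors: list[tuple[str, str, tuple[str, ...]]] = field(default_factory=list)
    warnings: list[tuple[str, str, tuple[str, ...]]] = field(default_factory=list)
    counts: Counts = field(default_factory=Counts)

    @property
    def ok(self) -> bool:
        return not self.errors

    def error_codes(self) -> set[str]:
        return {code for code, _, _ in self.errors}

    def warning_codes(self) -> set[str]:
        return {code for code, _, _ in self.warnings}


class Ontology:
    """Concept forest plus terminology.

    ``roots`` preserves file order; node and term iteration order is the
    insertion order, so a load→save round trip is byte-stable.
    """

    def __init__(
        self,
        nodes: Iterable[ConceptNode],
        terms: Iterable[TermEntry],
        roots: Iterable[str] | None = None,
        max_depth_limit: int = DEFAULT_MAX_DEPTH,
    ):
        self.nodes: dict[str, ConceptNode] = {}
        for node in nodes:
            if node.concept_id in self.nodes:
                raise OntologyStructureError(
                    f"duplicate concept_id {node.concept_id!r}"
                )
            self.nodes[node.concept_id] = node
        self.terms: list[TermEntry] = list(terms)
        if roots is None:
            roots = [c for c, n in self.nodes.items() if n.parent_id is None]
        self.roots: list[str] = list(roots)
        self.max_depth_limit = max_depth_limit
        self._children: dict[str, list[str]] = defaultdict(list)
        for node in self.nodes.values():
            if node.parent_id is not None:
                self._children[node.parent_id].append(node.concept_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Ontology):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and sorted(self.terms, key=lambda t: (t.concept_id, t.surface_form))
            == sorted(other.terms, key=lambda t: (t.concept_id, t.surface_form))
            and self.roots == other.roots
        )

    # -- hierarchy queries -------------------------------------------------

    def node(self, concept_id: str) -> ConceptNode:
        try:
            return self.nodes[concept_id]
        except KeyError:
            raise UnknownConceptError(concept_id) from None

    def children(self, concept_id: str) -> list[str]:
        self.node(concept_id)
        return list(self._children.get(concept_id, ()))

    def descendants(self, concept_id: str) -> set[str]:
        """Transitive closure of children, excluding the node itself."""
        self.node(concept_id)
        out: set[str] = set()
        stack = list(self._children.get(concept_id, ()))
        while stack:
            c = stack.pop()
            if c not in out:
                out.add(c)
                stack.extend(self._children.get(c, ()))
        return out

    def superclass_of(self, concept_id: str) -> str:
        """Root ancestor of *concept_id* (identity for roots)."""
        node = self.node(concept_id)
        seen = {concept_id}
        while node.parent_id is not None:
            if node.parent_id in seen:  # defensive: cycles are load errors
                raise OntologyStructureError(f"cycle through {concept_id!r}")
            seen.add(node.parent_id)
            node = self.node(node.parent_id)
        return node.concept_id

    def subtree(self, concept_id: str) -> set[str]:
        """descendants ∪ {self} — the rollup membership set."""
        return self.descendants(concept_id) | {concept_id}

    def term_index(self) -> dict[str, set[str]]:
        """Normalized surface form → set of concept_ids carrying it."""
        index: dict[str, set[str]] = defaultdict(set)
        for term in self.terms:
            key = normalize(term.surface_form)
            if key:
                index[key].add(term.concept_id)
        return dict(index)

    def terms_of(self, concept_id: str) -> list[str]:
        self.node(concept_id)
        return [t.surface_form for t in self.terms if t.concept_id == concept_id]


# -- loading ---------------------------------------------------------------

_TABULAR_COLUMNS = ["concept_id", "parent_id", "preferred_label", "term_type", "surface_form"]


def _build(rows: list[tuple[str, str | None, str, str, str]],
           max_depth_limit: int) -> Ontology:
    """Assemble an Ontology from parsed term rows, computing levels.

    Structural defects that make levels uncomputable (conflicting
    duplicate definitions, dangling parents, cycles) raise
    OntologyStructureError; everything else is left to the validator.
    """
    spec: dict[str, tuple[str | None, str]] = {}
    order: list[str] = []
    for concept_id, parent_id, label, _, _ in rows:
        if concept_id in spec:
            if spec[concept_id] != (parent_id, label):
                raise OntologyStructureError(
                    f"conflicting duplicate definition of concept {concept_id!r}"
                )
        else:
            spec[concept_id] = (parent_id, label)
            order.append(concept_id)

    for concept_id, (parent_id, _) in spec.items():
        if parent_id is not None and parent_id not in spec:
            raise OntologyStructureError(
                f"concept {concept_id!r} has dangling parent {parent_id!r}"
            )

    levels: dict[str, int] = {}

    def level_of(cid: str, trail: tuple[str, ...]) -> int:
        if cid in levels:
            return levels[cid]
        if cid in trail:
            raise OntologyStructureError(
                f"cycle in hierarchy through {' -> '.join(trail + (cid,))}"
            )
        parent = spec[cid][0]
        lv = 0 if parent is None else level_of(parent, trail + (cid,)) + 1
        levels[cid] = lv
        return lv

    for cid in order:
        level_of(cid, ())

    nodes = [
        ConceptNode(cid, spec[cid][1], spec[cid][0], levels[cid]) for cid in order
    ]
    roots = [cid for cid in order if spec[cid][0] is None]
    terms = [TermEntry(surface, cid, ttype) for cid, _, _, ttype, surface in rows]
    return Ontology(nodes, terms, roots, max_depth_limit)


def load_ontology(path: str | Path, format: str = "tabular",
                  max_depth_limit: int = DEFAULT_MAX_DEPTH) -> Ontology:
    """Read an ontology file in the ``tabular`` or ``obo`` dialect."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if format == "tabular":
        return _load_tabular(text, str(path), max_depth_limit)
    if format in ("obo", "obo-like"):
        return _load_obo(text, str(path), max_depth_limit)
    raise ValueError(f"unknown ontology format {format!r}")


def _load_tabular(text: str, name: str, max_depth_limit: int) -> Ontology:
    lines = text.splitlines()
    if not lines or not lines[0].strip():
        raise OntologyParseError(f"{name}: empty ontology file")
    header = lines[0].rstrip("\n").split("\t")
    if header != _TABULAR_COLUMNS:
        raise OntologyParseError(
            f"{name}:1: expected header {_TABULAR_COLUMNS}, got {header}"
        )
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise OntologyParseError(
                f"{name}:{lineno}: expected 5 tab-separated fields, got {len(fields)}"
            )
        concept_id, parent_id, label, term_type, surface = fields
        if not concept_id:
            raise OntologyParseError(f"{name}:{lineno}: empty concept_id")
        if term_type not in TERM_TYPES:
            raise OntologyParseError(
                f"{name}:{lineno}: unknown term_type {term_type!r}"
            )
        rows.append((concept_id, parent_id or None, label, term_type, surface))
    if not rows:
        raise OntologyParseError(f"{name}: no term rows")
    return _build(rows, max_depth_limit)


_OBO_SYN = re.compile(r'^synonym:\s*"([^"]*)"')


def _load_obo(text: str, name: str, max_depth_limit: int) -> Ontology:
    rows: list[tuple[str, str | None, str, str, str]] = []
    stanza: dict[str, object] | None = None

    def flush() -> None:
        if stanza is None:
            return
        cid = stanza.get("id")
        if not cid:
            raise OntologyParseError(f"{name}: [Term] stanza without id")
        label = stanza.get("name", cid)
        parent = stanza.get("is_a")
        rows.append((cid, parent, label, "preferred", label))
        for syn in stanza.get("synonyms", []):
            rows.append((cid, parent, label, "synonym", syn))

    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if line == "[Term]":
            flush()
            stanza = {"synonyms": []}
        elif stanza is not None and line.startswith("id:"):
            stanza["id"] = line[3:].strip()
        elif stanza is not None and line.startswith("name:"):
            stanza["name"] = line[5:].strip()
        elif stanza is not None and line.startswith("is_a:"):
            stanza["is_a"] = line[5:].strip().split("!")[0].strip()
        elif stanza is not None and line.startswith("synonym:"):
            m = _OBO_SYN.match(line)
            if not m:
                raise OntologyParseError(f"{name}:{lineno}: bad synonym line")
            stanza["synonyms"].append(m.group(1))
    flush()
    if not rows:
        raise OntologyParseError(f"{name}: no [Term] stanzas")
    return _build(rows, max_depth_limit)


# -- saving ----------------------------------------------------------------

def save_ontology(ont: Ontology, path: str | Path, format: str = "tabular") -> None:
    """Write *ont* in the tabular (canonical) or OBO-like dialect.

    The OBO export is lossy for ``term_type`` (every non-preferred term
    is written as a plain EXACT synonym); the tabular form round-trips.
    """
    path = Path(path)
    if format == "tabular":
        lines = ["\t".join(_TABULAR_COLUMNS)]
        for term in ont.terms:
            node = ont.node(term.concept_id)
            lines.append("\t".join([
                node.concept_id, node.parent_id or "", node.preferred_label,
                term.term_type, term.surface_form,
            ]))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format in ("obo", "obo-like"):
        chunks = ["format-version: 1.2\n"]
        for node in ont.nodes.values():
            lines = [f"[Term]", f"id: {node.concept_id}", f"name: {node.preferred_label}"]
            if node.parent_id is not None:
                lines.append(f"is_a: {node.parent_id} ! "
                             f"{ont.node(node.parent_id).preferred_label}")
            for term in ont.terms:
                if term.concept_id == node.concept_id and term.term_type != "preferred":
                    lines.append(f'synonym: "{term.surface_form}" EXACT []')
            chunks.append("\n".join(lines) + "\n")
        path.write_text("\n".join(chunks), encoding="utf-8")
    else:
        raise ValueError(f"unknown ontology format {format!r}")


# -- validation ------------------------------------------------------------

def validate_ontology(ont: Ontology) -> ValidationReport:
    """Check every structural and terminological invariant.

    All problems are reported, never raised; counts are filled in
    regardless. ``AMBIGUOUS_TERM`` (one normalized surface form under
    two concepts) is a warning — the matcher refuses such terms rather
    than guessing.
    """
    report = ValidationReport()
    err = report.errors.append
    warn = report.warnings.append

    root_set = set(ont.roots)
    for cid, node in ont.nodes.items():
        if node.parent_id is None and cid not in root_set:
            err(("ROOT_MISMATCH", f"parentless node {cid!r} not listed as root", (cid,)))
        if node.parent_id is not None:
            if cid in root_set:
                err(("ROOT_MISMATCH", f"root {cid!r} has a parent", (cid,)))
            if node.parent_id not in ont.nodes:
                err(("DANGLING_PARENT",
                     f"{cid!r} points at missing parent {node.parent_id!r}",
                     (cid, node.parent_id)))

    # level correctness + acyclicity by explicit parent-chain walk
    max_depth = 0
    for cid, node in ont.nodes.items():
        hops, cur, seen = 0, node, {cid}
        broken = False
        while cur.parent_id is not None:
            if cur.parent_id in seen or cur.parent_id not in ont.nodes:
                if cur.parent_id in seen:
                    err(("CYCLE", f"cycle through {cid!r}", tuple(sorted(seen))))
                broken = True
                break
            seen.add(cur.parent_id)
            cur = ont.nodes[cur.parent_id]
            hops += 1
        if broken:
            continue
        if node.level != hops:
            err(("BAD_LEVEL",
                 f"{cid!r} has level {node.level}, expected {hops}", (cid,)))
        max_depth = max(max_depth, hops)
    if max_depth > ont.max_depth_limit:
        err(("DEPTH_EXCEEDED",
             f"max depth {max_depth} exceeds limit {ont.max_depth_limit}", ()))

    by_key: dict[str, set[str]] = defaultdict(set)
    for term in ont.terms:
        if term.concept_id not in ont.nodes:
            err(("MISSING_CONCEPT",
                 f"term {term.surface_form!r} names missing concept "
                 f"{term.concept_id!r}", (term.concept_id,)))
        key = normalize(term.surface_form)
        if not key:
            err(("EMPTY_SURFACE",
                 f"term of {term.concept_id!r} is empty after normalization",
                 (term.concept_id,)))
        else:
            by_key[key].add(term.concept_id)
    for key, cids in sorted(by_key.items()):
        if len(cids) > 1:
            warn(("AMBIGUOUS_TERM",
                  f"surface form {key!r} maps to {len(cids)} concepts",
                  tuple(sorted(cids))))

    n_roots = sum(1 for n in ont.nodes.values() if n.parent_id is None)
    report.counts = Counts(
        n_superclasses=n_roots,
        n_classes=len(ont.nodes) - n_roots,
        n_terms=len(ont.terms),
        max_depth=max_depth,
    )
    return report


# -- packaged skeleton -----------------------------------------------------

def skeleton_path() -> Path:
    """Filesystem path of the packaged skeleton terminology."""
    return Path(resources.files("oncolex").joinpath("data/skeleton.tsv"))


def load_skeleton() -> Ontology:
    """The packaged skeleton: the 9 superclasses and every named class."""
    return load_ontology(skeleton_path(), format="tabular")
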