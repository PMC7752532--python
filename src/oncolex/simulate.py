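"""Synthetic corpus and ontology-fixture generation with ground truth.

The study's raw posts were never deposited, so every stage of the
pipeline is exercised against generated corpora whose planted labels
are known exactly. A synthetic post is a bag of terminology surface
forms plus nonsense filler, shuffled — the matcher is purely lexical,
so lexical structure is the only structure that matters for testing.

Filler words and synthetic synonyms are built from strictly alternating
consonant-vowel syllables over the restricted alphabet {b d k m n p r s
t} x {a i o u}. Every packaged surface form contains a character or a
cluster impossible under that scheme, and all synthetic synonyms share
one fixed length, so no surface form can ever arise by accident inside
filler or inside another synthetic term: the planted concept set IS the
exhaustive truth of what a correct annotator can find.

Default rates mirror the study conditions: per-cancer-type mention
probabilities headed by colon cancer at 0.064, per-superclass
conditional rates from 0.425 (risk factor) down to 0.094 (prognosis),
a blog share of 0.587, and the two dominant platforms carrying 0.977
of the posts. Every genuine post carries a generic cancer-type surface
form — the crawled corpus was keyword-extracted, so by construction
every real post mentioned cancer.
"""

from __future__ import annotations

import datetime as dt
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .annotate import PostAnnotation
from .corpus import PostRecord
from .ontology import ConceptNode, Ontology, TermEntry, load_skeleton

_CONSONANTS = "bdkmnprst"
_VOWELS = "aiou"
_SYN_SYLLABLES = 4  # synthetic synonyms all 8 chars -> none nests in another

DEFAULT_TYPE_PROBS: dict[str, float] = {
    "colon_cancer": 0.064,
    "breast_cancer": 0.063,
    "stomach_cancer": 0.050,
    "cervical_cancer": 0.045,
    "lung_cancer": 0.042,
    "liver_cancer": 0.038,
    "prostate_cancer": 0.030,
    "pancreatic_cancer": 0.025,
    "brain_tumor": 0.022,
    "leukemia": 0.020,
    "thyroid_cancer": 0.008,
}

DEFAULT_SUPERCLASS_RATES: dict[str, float] = {
    "risk_factor": 0.425,
    "emotion": 0.338,
    "symptom": 0.322,
    "treatment": 0.302,
    "dealing_with_cancer": 0.294,
    "diagnosis": 0.237,
    "prevention": 0.144,
    "prognosis": 0.094,
}

DEFAULT_PLATFORM_WEIGHTS = {"naver": 0.600, "daum": 0.377, "tistory": 0.015,
                            "egloos": 0.008}
DEFAULT_SOURCE_WEIGHTS = {"blog": 0.587, "community": 0.413}

DEFAULT_AD_KEYWORDS = ["detoxification", "antioxidant therapy", "enzyme therapy"]
DEFAULT_CONFUSABLE_PHRASES = ["agseong virus"]


class SimulationError(Exception):
    pass


@dataclass
class CorpusSpec:
    """Generation parameters; the defaults are the study conditions."""

    n_posts: int = 1000
    date_range: tuple[dt.date, dt.date] = (dt.date(2014, 1, 1), dt.date(2017, 6, 30))
    platform_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PLATFORM_WEIGHTS))
    source_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SOURCE_WEIGHTS))
    type_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_PROBS))
    #: superclass_id -> rate, optionally overridden per type with a
    #: "type_id|superclass_id" key
    superclass_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUPERCLASS_RATES))
    ad_fraction: float = 0.05
    confusable_fraction: float = 0.05
    ad_keywords: list[str] = field(default_factory=lambda: list(DEFAULT_AD_KEYWORDS))
    confusable_phrases: list[str] = field(
        default_factory=lambda: list(DEFAULT_CONFUSABLE_PHRASES))
    n_filler: tuple[int, int] = (3, 10)
    seed: int = 0

    def validate(self) -> None:
        if self.n_posts < 0:
            raise SimulationError("n_posts must be >= 0")
        if self.date_range[0] > self.date_range[1]:
            raise SimulationError("date_range start is after end")
        for name, probs in (("type_probs", self.type_probs),
                            ("superclass_rates", self.superclass_rates)):
            for key, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise SimulationError(f"{name}[{key!r}] = {p} not in [0, 1]")
        for name, p in (("ad_fraction", self.ad_fraction),
                        ("confusable_fraction", self.confusable_fraction)):
            if not 0.0 <= p <= 1.0:
                raise SimulationError(f"{name} = {p} not in [0, 1]")
        if self.ad_fraction + self.confusable_fraction > 1.0:
            raise SimulationError("ad_fraction + confusable_fraction > 1")
        for name, weights in (("platform_weights", self.platform_weights),
                              ("source_weights", self.source_weights)):
            if weights and abs(sum(weights.values()) - 1.0) > 1e-9:
                raise SimulationError(f"{name} must sum to 1")

    def rate(self, type_id: str, superclass_id: str) -> float:
        key = f"{type_id}|{superclass_id}"
        if key in self.superclass_rates:
            return self.superclass_rates[key]
        return self.superclass_rates.get(superclass_id, 0.0)


@dataclass
class PostTruth:
    post_id: str
    concepts: set[str] = field(default_factory=set)
    is_ad: bool = False
    is_confusable: bool = False
    strata: set[str] = field(default_factory=set)


@dataclass
class GroundTruth:
    posts: dict[str, PostTruth] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.posts)


# -- word generation -------------------------------------------------------

def _cv_word(rng: random.Random, n_syllables: int) -> str:
    return "".join(rng.choice(_CONSONANTS) + rng.choice(_VOWELS)
                   for _ in range(n_syllables))


def _fresh_cv_word(rng: random.Random, used: set[str],
                   n_syllables: int = _SYN_SYLLABLES) -> str:
    while True:
        w = _cv_word(rng, n_syllables)
        if w not in used:
            used.add(w)
            return w


# -- ontology fixture ------------------------------------------------------

def generate_ontology_fixture(n_extra_classes: int, n_synonyms_per_class: int,
                              seed: int) -> Ontology:
    """The packaged skeleton, re-terminologised and optionally extended.

    Every class keeps its preferred label as its sole preferred term;
    synthetic pronounceable synonyms are added until each class carries
    ``n_synonyms_per_class`` terms (1 means the preferred term only).
    ``n_extra_classes`` synthetic leaf classes are attached under random
    existing classes at depth <= 2. Same seed, same ontology.
    """
    if n_extra_classes < 0 or n_synonyms_per_class < 0:
        raise SimulationError("counts must be >= 0")
    rng = random.Random(seed)
    skeleton = load_skeleton()
    nodes = list(skeleton.nodes.values())
    used: set[str] = set()

    eligible_parents = sorted(
        cid for cid, n in skeleton.nodes.items() if n.level <= 2
    )
    for k in range(n_extra_classes):
        label = _fresh_cv_word(rng, used)
        parent = rng.choice(eligible_parents)
        nodes.append(ConceptNode(
            concept_id=f"syn_{k:04d}",
            preferred_label=label,
            parent_id=parent,
            level=skeleton.nodes[parent].level + 1,
        ))

    terms: list[TermEntry] = []
    for node in nodes:
        terms.append(TermEntry(node.preferred_label, node.concept_id, "preferred"))
        for _ in range(max(n_synonyms_per_class, 1) - 1):
            terms.append(TermEntry(_fresh_cv_word(rng, used),
                                   node.concept_id, "synonym"))
    roots = skeleton.roots
    return Ontology(nodes, terms, roots, skeleton.max_depth_limit)


# -- corpus generation -----------------------------------------------------

def _weighted_choice(rng: random.Random, weights: Mapping[str, float]) -> str:
    labels = list(weights)
    return rng.choices(labels, weights=[weights[k] for k in labels], k=1)[0]


def generate_corpus(spec: CorpusSpec, ont: Ontology) -> tuple[list[PostRecord], GroundTruth]:
    """Generate a corpus and its exact planted labels.

    One pseudo-random stream per post, derived from (seed, post index),
    so the output is reproducible and order-independent. Advertising
    posts carry an ad keyword (plus a cancer keyword — real ads were in
    the keyword-extracted corpus too); confusable posts carry a stop
    phrase embedding a cancer keyword but no genuine mention; genuine
    posts always carry one generic cancer-type surface form plus
    Bernoulli-drawn type and superclass mentions.
    """
    spec.validate()
    for cid in spec.type_probs:
        ont.node(cid)  # raises UnknownConceptError for unknown ids

    surfaces: dict[str, list[str]] = {}
    for term in ont.terms:
        surfaces.setdefault(term.concept_id, []).append(term.surface_form)

    cancer_root = "cancer_type"
    ont.node(cancer_root)
    other_roots = [r for r in ont.roots if r != cancer_root]
    subtree_members = {r: sorted(ont.subtree(r)) for r in other_roots}

    start, end = spec.date_range
    n_days = (end - start).days

    records: list[PostRecord] = []
    truth = GroundTruth()
    for i in range(spec.n_posts):
        rng = random.Random(f"{spec.seed}|{i}")
        post_id = f"p{i:07d}"
        platform = _weighted_choice(rng, spec.platform_weights)
        source = _weighted_choice(rng, spec.source_weights)
        date = start + dt.timedelta(days=rng.randint(0, n_days))

        tokens: list[str] = []
        pt = PostTruth(post_id)
        roll = rng.random()
        if spec.ad_keywords and roll < spec.ad_fraction:
            pt.is_ad = True
            tokens.append(rng.choice(sorted(surfaces[cancer_root])))
            tokens.append(rng.choice(sorted(spec.ad_keywords)))
        elif (spec.confusable_phrases
              and roll < spec.ad_fraction + spec.confusable_fraction):
            pt.is_confusable = True
            tokens.append(rng.choice(sorted(spec.confusable_phrases)))
        else:
            tokens.append(rng.choice(sorted(surfaces[cancer_root])))
            pt.concepts.add(cancer_root)
            drawn = [t for t in sorted(spec.type_probs)
                     if rng.random() < spec.type_probs[t]]
            for t in drawn:
                tokens.append(rng.choice(sorted(surfaces[t])))
                pt.concepts.add(t)
                pt.strata.add(t)
            hit_superclasses = set()
            for t in drawn:
                for s in other_roots:
                    if s not in hit_superclasses and rng.random() < spec.rate(t, s):
                        hit_superclasses.add(s)
                        concept = rng.choice(subtree_members[s])
                        tokens.append(rng.choice(sorted(surfaces[concept])))
                        pt.concepts.add(concept)

        lo, hi = spec.n_filler
        tokens.extend(_cv_word(rng, rng.randint(2, 3))
                      for _ in range(rng.randint(lo, hi)))
        rng.shuffle(tokens)
        records.append(PostRecord(post_id, platform, source, date, " ".join(tokens)))
        truth.posts[post_id] = pt
    return records, truth


# -- recovery evaluation ---------------------------------------------------

@dataclass(frozen=True)
class ConceptRecovery:
    concept_id: str
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 1.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 1.0


@dataclass
class RecoveryReport:
    per_concept: dict[str, ConceptRecovery]
    micro_precision: float
    micro_recall: float
    n_posts: int


def recovery_report(annotations: Sequence[PostAnnotation],
                    truth: GroundTruth) -> RecoveryReport:
    """Post-level presence precision/recall of an annotation run against
    the planted labels. Advertising posts (per ground truth) are skipped
    — removal, not annotation, is the correct behaviour for them."""
    ann_ids = {a.post_id for a in annotations}
    if ann_ids != set(truth.posts):
        raise SimulationError(
            f"annotations and ground truth cover different posts "
            f"({len(ann_ids ^ set(truth.posts))} mismatched ids)"
        )
    tp: dict[str, int] = {}
    fp: dict[str, int] = {}
    fn: dict[str, int] = {}
    n = 0
    for a in annotations:
        pt = truth.posts[a.post_id]
        if pt.is_ad:
            continue
        n += 1
        for c in a.concepts & pt.concepts:
            tp[c] = tp.get(c, 0) + 1
        for c in a.concepts - pt.concepts:
            fp[c] = fp.get(c, 0) + 1
        for c in pt.concepts - a.concepts:
            fn[c] = fn.get(c, 0) + 1
    concepts = sorted(set(tp) | set(fp) | set(fn))
    per_concept = {
        c: ConceptRecovery(c, tp.get(c, 0), fp.get(c, 0), fn.get(c, 0))
        for c in concepts
    }
    total_tp = sum(tp.values())
    total_fp = sum(fp.values())
    total_fn = sum(fn.values())
    micro_p = total_tp / (total_tp + total_fp) if (total_tp + total_fp) else 1.0
    micro_r = total_tp / (total_tp + total_fn) if (total_tp + total_fn) else 1.0
    return RecoveryReport(per_concept, micro_p, micro_r, n)


# -- spec / ground truth files ---------------------------------------------

def save_corpus_spec(spec: CorpusSpec, path: str | Path) -> None:
    obj = {
        "n_posts": spec.n_posts,
        "date_range": [d.isoformat() for d in spec.date_range],
        "platform_weights": spec.platform_weights,
        "source_weights": spec.source_weights,
        "type_probs": spec.type_probs,
        "superclass_rates": spec.superclass_rates,
        "ad_fraction": spec.ad_fraction,
        "confusable_fraction": spec.confusable_fraction,
        "ad_keywords": spec.ad_keywords,
        "confusable_phrases": spec.confusable_phrases,
        "n_filler": list(spec.n_filler),
        "seed": spec.seed,
    }
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False), encoding="utf-8")


def load_corpus_spec(path: str | Path) -> CorpusSpec:
    obj = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if "date_range" in obj:
        obj["date_range"] = tuple(dt.date.fromisoformat(d) for d in obj["date_range"])
    if "n_filler" in obj:
        obj["n_filler"] = tuple(obj["n_filler"])
    spec = CorpusSpec(**obj)
    spec.validate()
    return spec


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid, pt in truth.posts.items():
            fh.write(json.dumps({
                "post_id": pid,
                "concepts": sorted(pt.concepts),
                "is_ad": pt.is_ad,
                "is_confusable": pt.is_confusable,
                "strata": sorted(pt.strata),
            }) + "\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    truth = GroundTruth()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            truth.posts[obj["post_id"]] = PostTruth(
                post_id=obj["post_id"],
                concepts=set(obj["concepts"]),
                is_ad=obj["is_ad"],
                is_confusable=obj["is_confusable"],
                strata=set(obj["strata"]),
            )
    return truth
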