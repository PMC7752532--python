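"""End-to-end pipeline: read → de-identify → date-filter → annotate →
count → stratify → rank → compare, with every product written as a tidy
CSV (plus line-delimited annotations) under one output directory.

The run report carries every count needed to recompute every percentage
the pipeline writes: posts read, posts in the date window, ads removed,
cancer posts, and per-stage timings.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import annotate as ann
from . import corpus as cio
from . import frequency as freq
from .ontology import load_ontology, load_skeleton, validate_ontology

logger = logging.getLogger(__name__)


class PipelineError(Exception):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    corpus_path: str | Path
    out_dir: str | Path
    ontology_path: str | Path | None = None  # None -> packaged skeleton
    ad_keywords_path: str | Path | None = None
    stop_phrases_path: str | Path | None = None
    registry_path: str | Path | None = None
    start_date: dt.date = dt.date(2014, 1, 1)
    end_date: dt.date = dt.date(2017, 6, 30)
    strata: list[str] | None = None  # None -> social-media top-N types
    top_n: int = 10
    cancer_type_root: str = "cancer_type"

    def validate(self) -> None:
        for name in ("corpus_path", "ontology_path", "ad_keywords_path",
                     "stop_phrases_path", "registry_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError("config", f"{name} does not exist: {p}")
        if self.start_date > self.end_date:
            raise PipelineError("config", "start_date is after end_date")
        if self.top_n <= 0:
            raise PipelineError("config", "top_n must be positive")


def _annotations_frame(annotations) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "post_id": a.post_id,
            "is_ad": a.is_ad,
            "is_cancer_post": a.is_cancer_post,
            "concepts": ",".join(sorted(a.concepts)),
        }
        for a in annotations
    ])


def write_annotations(annotations, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a in annotations:
            fh.write(json.dumps({
                "post_id": a.post_id,
                "is_ad": a.is_ad,
                "is_cancer_post": a.is_cancer_post,
                "concepts": sorted(a.concepts),
            }) + "\n")


def read_annotations(path: str | Path) -> list[ann.PostAnnotation]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                obj = json.loads(line)
                out.append(ann.PostAnnotation(
                    post_id=obj["post_id"],
                    concepts=set(obj["concepts"]),
                    is_ad=obj["is_ad"],
                    is_cancer_post=obj["is_cancer_post"],
                ))
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage; returns the run report (also written as
    run_report.json in the output directory)."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}

    def stage(name: str):
        t0 = time.perf_counter()

        def done(**counts):
            report["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3), **counts}
            logger.info("stage %s: %s", name, counts)

        return done

    try:
        done = stage("ontology")
        ont = (load_ontology(cfg.ontology_path) if cfg.ontology_path
               else load_skeleton())
        vr = validate_ontology(ont)
        if not vr.ok:
            raise PipelineError("ontology", f"{len(vr.errors)} validation errors")
        done(n_superclasses=vr.counts.n_superclasses, n_classes=vr.counts.n_classes,
             n_terms=vr.counts.n_terms)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("ontology", str(e)) from e

    try:
        done = stage("read")
        corpus = cio.read_corpus(cfg.corpus_path)
        done(n_posts=len(corpus))

        done = stage("date_filter")
        corpus = cio.filter_by_date(corpus, cfg.start_date, cfg.end_date)
        done(n_posts=len(corpus))
        summary = cio.summarize_corpus(corpus)
        summary.to_frame().to_csv(out / "corpus_summary.csv", index=False)
    except cio.CorpusError as e:
        raise PipelineError("read", str(e)) from e

    try:
        done = stage("annotate")
        defaults = ann.default_config()
        cfg_ann = ann.AnnotationConfig(
            ad_keywords=(ann.load_keywords(cfg.ad_keywords_path)
                         if cfg.ad_keywords_path else defaults.ad_keywords),
            stop_phrases=(ann.load_stop_phrases(cfg.stop_phrases_path)
                          if cfg.stop_phrases_path else defaults.stop_phrases),
            cancer_type_root=cfg.cancer_type_root,
        )
        annotations = ann.annotate_corpus(corpus, ont, cfg_ann)
        n_ad = sum(a.is_ad for a in annotations)
        n_cancer = sum(a.is_cancer_post and not a.is_ad for a in annotations)
        write_annotations(annotations, out / "annotations.jsonl")
        done(n_posts=len(annotations), n_ad_removed=n_ad, n_cancer_posts=n_cancer)
    except ann.AmbiguousTermError as e:
        raise PipelineError("annotate", str(e)) from e

    try:
        done = stage("count")
        class_table = freq.count_posts_by_concept(annotations, ont, level="class")
        super_table = freq.rollup_to_superclass(annotations, ont)
        frames = [class_table.to_frame(ont), super_table.to_frame(ont)]
        done(n_qualifying=class_table.total)

        done = stage("stratify")
        type_table = freq.FrequencyTable(
            stratum=freq.ALL_STRATA, level="class",
            rows=[r for r in class_table.rows
                  if r.concept_id in ont.descendants(cfg.cancer_type_root)],
            total=class_table.total)
        strata = cfg.strata or freq.rank_top_n(type_table, cfg.top_n)
        per_type = freq.stratify_by_cancer_type(annotations, ont, strata,
                                                level="superclass")
        frames += [t.to_frame(ont) for t in per_type.values()]
        pd.concat(frames, ignore_index=True).to_csv(
            out / "frequencies.csv", index=False)
        done(n_strata=len(strata))

        done = stage("rank_compare")
        social_top = strata
        if cfg.registry_path:
            registry = freq.read_registry(cfg.registry_path)
            comparison = freq.compare_rankings(
                social_top, freq.registry_top_n(registry, cfg.top_n))
            comparison.to_frame().to_csv(out / "rank_comparison.csv", index=False)
            report["rank_comparison"] = {
                "shared": sorted(comparison.shared),
                "social_only": sorted(comparison.social_only),
                "registry_only": sorted(comparison.registry_only),
            }
        done(n_social_top=len(social_top))
    except (freq.FrequencyError, ValueError) as e:
        raise PipelineError("analysis", str(e)) from e

    report["social_top"] = social_top
    (out / "run_report.json").write_text(
        json.dumps(report, indent=2), encoding="utf-8")
    return report
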