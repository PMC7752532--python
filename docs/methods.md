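# Methods

## The problem

Health consumers write about cancer on blogs and community boards in lay
language — synonyms, abbreviations ("jaegeom" for re-test, "chompa" for
ultrasound) and heteronyms ("jol-eob", literally *graduation*, meaning
complete cure). `oncolex` measures what such a corpus talks about: it
annotates each post with the concepts of a consumer-term cancer
ontology, then reports post-level relative frequencies per concept,
rolled up to nine superclasses and stratified by cancer type.

## The ontology model

The ontology is a single-parent forest of concept classes, 3–4 levels
deep, with nine superclass roots: *cancer type, prevention, diagnosis,
treatment, prognosis, risk factor, symptom, dealing with cancer,
emotion*. A terminology maps surface forms (preferred term, synonym,
abbreviation, heteronym) onto classes. The forest (rather than a DAG)
is a deliberate choice: rolling a post up to a unique superclass
requires every class to have exactly one root ancestor.

The packaged skeleton (`src/oncolex/data/skeleton.tsv`) encodes the
nine superclasses, the eleven cancer types the analyses discuss, the
risk-factor, symptom, dealing-with-cancer, treatment and prognosis
subtrees, and the nine emotion classes — 59 concepts and 116 surface
forms. The original full terminology (hundreds of classes, thousands of
synonyms) was never published; the synthetic fixture generator
(`generate_ontology_fixture`) extends the skeleton with pronounceable
synthetic classes and synonyms to reach arbitrary sizes while staying
validator-clean.

Terminology normalization is Unicode NFC + case folding + whitespace
collapse. Case folding is a no-op for Hangul; it exists because
consumer posts mix scripts. A normalized surface form mapping to two
different concepts is a validation *warning* (`AMBIGUOUS_TERM`), not an
error, and the matcher raises rather than guessing if such a form
actually occurs in a text: the pipeline's only disambiguation mechanism
is the stop-phrase list, so silent tie-breaking would be unsound.

*Prognosis* keeps *recurrence* and *cure* as subclasses; frequency
tables can be produced at superclass, class, or end-node level, so both
the aggregated and the split view are available.

## Filtering and annotation

Per post, in fixed order:

1. **normalize** the text (as above);
2. **de-identify**: phone numbers, e-mails, URLs and @handles are
   replaced by fixed placeholders. This is pattern-based only; personal
   names would need NER and are a known limitation;
3. **advertising check**: if any of the ad keywords (e.g.
   *detoxification*, *antioxidant therapy*, *enzyme therapy*) occurs as
   a normalized substring, the post is flagged `is_ad` and excluded
   whole from all counting, before any matching;
4. **stop-phrase masking**: every occurrence of a stop phrase — a
   longer phrase in which a cancer keyword loses its cancer meaning,
   e.g. "agseong virus" (computer virus) embedding "agseong"
   (malignant) — is overwritten in place by a same-length run of a
   placeholder character that can never match a term. Ads remove posts;
   stop phrases remove only false-positive *regions*;
5. **dictionary matching**: normalized substring search over all
   terminology surface forms. All candidate occurrences are collected
   and resolved greedily longest-first, then leftmost, then
   lexicographically — so "dietary risk factor" matches the *dietary
   risk factor* class and not its embedded "diet" or "risk factor".
   Accepted spans never overlap each other or a masked region.

A post is a **cancer post** iff at least one matched concept lies in
the *cancer type* subtree (including the superclass's own surface
forms). Only cancer posts that are not ads enter the analysis corpus.

Substring (not token-boundary) matching is an explicit assumption: the
original NLP vendor's matching granularity is unknown, and subword hits
are exactly how agglutinative Korean consumer abbreviations surface.

## Frequency analysis

Counting is binary per post ("the post is the unit of analysis"): n_c =
number of qualifying posts mentioning concept c at least once, p_c =
100·n_c/N with N the stratum's post total. A post counts once toward
superclass S iff it mentions any concept in subtree(S). Percentages are
rounded **half-up to one decimal** to match conventional reporting
(`decimal.Decimal`, not banker's rounding: 6.25 → 6.3); the raw
fraction is retained in every output row. Rows may sum above N — a
post can carry many concepts — so no sum-to-100 constraint exists.

Strata overlap: a post mentioning colon and stomach cancer belongs to
both strata, each with its own denominator. Ranking ties are broken by
lexicographic concept id; a deterministic rule is required and no
substantive one is available. Rank comparison against a registry
incidence table is plain set algebra plus per-type rank pairs.

## The synthetic corpus generator

No corpus of this kind is publicly deposited, so the generator *is* the
test bed. A synthetic post is a shuffled bag of terminology surface
forms plus nonsense filler — the matcher is purely lexical, so lexical
structure is the only structure that matters. Per post:

- metadata: platform ~ {naver 0.600, daum 0.377, tistory 0.015, egloos
  0.008} (the two major platforms carry 97.7%), source ~ {blog 0.587,
  community 0.413}, date uniform over 2014-01-01..2017-06-30;
- with probability `ad_fraction` (default 0.05) the post is an ad: one
  ad keyword plus one cancer keyword (real ads passed the keyword
  crawl too);
- else with probability `confusable_fraction` (default 0.05) it is a
  confusable: a stop phrase ("agseong virus") containing a cancer
  keyword but no genuine mention;
- otherwise it is genuine: one generic cancer-type surface form always
  (the real corpus was keyword-extracted, so every post mentioned
  cancer); each specific cancer type independently with its
  `type_probs` probability (defaults headed by colon 0.064, breast
  0.063, stomach 0.050 — mirroring the reported shares); and for each
  drawn type and superclass, one concept drawn uniformly from that
  superclass's subtree with the `superclass_rates` conditional
  probability (defaults 0.425 risk factor … 0.094 prognosis).

Independent Bernoulli draws per type (not single-label multinomial) are
deliberate: real strata overlap. One pseudo-random stream per post is
derived from `(seed, post index)`, so corpora are byte-reproducible.

**Why ground truth is exact.** Filler words and synthetic synonyms are
strictly alternating consonant-vowel strings over {b d k m n p r s t} ×
{a i o u}; every packaged surface form contains a letter or a cluster
impossible under that scheme, all synthetic synonyms share one length,
and no multiword surface form can assemble across token boundaries.
Hence a term occurs in a synthetic text *iff* it was planted, and the
planted concept set equals exactly what a correct annotator can
recover — which is why the recovery tests can demand precision =
recall = 1.0 rather than approximate agreement. This is also what the
generator does **not** emulate: fluent discourse, morphology, spelling
noise, emotion co-occurrence. Passing recovery tests certify the
pipeline's mechanics, not robustness to linguistic variation.

The packaged stop-phrase list carries only phrases whose embedded
keyword exists in the skeleton terminology ("agseong …"); a stop phrase
containing no known keyword can never mask anything and fails the
`StopPhrase` intent.

## Numerical and degenerate-input choices

- Date filtering is a closed interval on both ends.
- Duplicate post ids abort ingestion (no silent deduplication).
- Empty stratum: reported with N = 0 and no rows; `relative_frequency`
  raises for N = 0 rather than returning NaN.
- `rank_top_n` with fewer rows than n returns all rows.
- Masking placeholder is U+FFFD, absent from every surface form.
- Determinism everywhere: annotation is a pure function of (corpus,
  ontology, config); generation is a pure function of (spec, seed).

## Problem sizes

The recovery suite uses a 50,000-post corpus for the headline
colon-rate check (binomial 3σ ≈ ±0.33 points around 6.4%), 2,000-20,000
posts for the remaining stochastic checks, and 1,000 randomized short
texts per lexical-oracle comparison; these sizes put the whole suite in
the tens of seconds while keeping the binomial bounds tight enough to
be meaningful.

## Known limitations

- The skeleton is a faithful but small subset of the original
  unpublished terminology; absolute class counts are not comparable to
  the original study's 213 classes / 4061 synonyms.
- De-identification is regex-only.
- No morphological analysis: substring matching over-matches in
  principle (any term embedded in an unrelated longer word); the
  stop-phrase list is the only counter-measure, exactly as in the
  modelled workflow.
- Descriptive statistics only; no inference on frequency differences.
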