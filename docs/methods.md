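# Methods

This note documents the models and procedures implemented in `litmine`, the
parameter defaults and why they were chosen, the design decisions taken where
the design was genuinely open, and the limits of what the synthetic-corpus
validation demonstrates.

## Corpus model and sentence splitting

A corpus is an ordered list of publication records (unique PMID-like
`doc_id`, title, abstract, optional full text, publication year in
[1800, 2100], journal name, SCImago Journal Rank, and the set of query tags
that retrieved the record), serialized as a UTF-8 JSON list.  All downstream
analysis operates on **one text field per document** — the abstract when
non-empty, else the full text.  Mixing abstract and body sentences in one
analysis would double-count entities for records that carry both, and
abstract-level statistics are the ones practitioners usually report.

Sentence splitting is rule-based and fully deterministic, so the pipeline
needs no model download and its outputs are reproducible bit-for-bit.  A
sentence boundary is a `.`, `!` or `?` followed by whitespace and an
uppercase letter or digit, except when the period (i) sits directly between
digits (decimals such as "4.9"), (ii) closes a protected abbreviation
("e.g.", "i.e.", "et al.", "vs.", "Fig.", "ca."), or (iii) closes a single
capital initial as in author names ("J. Kaput").  Spans are 0-based,
half-open, whitespace-trimmed, ordered and disjoint; the text between spans
is whitespace only.  A rule-based splitter will mis-handle exotic
abbreviations; for the statistics computed here (sentence-level
co-occurrence) an occasional merged sentence slightly over-links and an
occasional split sentence slightly under-links entities, without bias toward
any particular pair.

## Dictionary tagging and normalization

Entity recognition is dictionary-based: a lexicon entry carries a preferred
label (`preflabel`), a type (`protein` or `disease` — genes and proteins are
deliberately not distinguished, matching common gene-normalizer behaviour),
synonyms, and an external identifier (NCBI gene or MeSH style).  Matching is
per sentence, aligned to token boundaries (a token character is a letter,
digit or hyphen), and resolves overlaps leftmost-first, then longest-span,
then by lexicon order — so "milk fat globule membrane" beats "milk" at the
same start.  Synonyms of ≥ 4 characters match case-insensitively; shorter
synonyms (gene symbols such as "INS", "TF") require exact case, because
otherwise common English words ("ins", "tf") would flood the mention list
with false positives.  The threshold of 4 is a judgment call: 3-character
gene symbols are the overwhelming source of such collisions, while
4-character synonyms are already rarely ambiguous.

Normalization is the collapse of every matched surface form onto its
`preflabel`; tagging the preflabel string itself always yields that
preflabel (idempotence).  No abbreviation detection, coreference or
context-dependent disambiguation is attempted.

## Comention analysis

A comention is the undirected co-occurrence of two distinct preflabels in
one sentence; it carries no semantic direction or polarity.  Records keep
the canonical vertex order (v1 ≤ v2 by preflabel) and are deduplicated per
sentence: a pair co-occurring twice in one sentence is one comention event,
and the earliest occurrence of each entity supplies the reported surface
form, making extraction invariant to mention input order.  Network edge
support is counted at the **distinct-document** level, not the sentence
level, because repeated phrasing within one publication is one piece of
evidence; the default support threshold of 5 documents matches the
convention of displaying only robustly co-reported pairs.  Node weight is
the number of distinct documents in which the entity participates in any
record.  Exports: GraphML (node attributes preflabel/type/weight, edge
attribute weight), an edge-list TSV, and the per-record table with columns
pmid / sentence / date / gene-protein / disease.

## tf-idf vectorization

Tokens are lowercase maximal runs of letters, digits and hyphens of length
≥ 2; stopwords are removed before n-grams of adjacent surviving tokens are
added, up to `ngram_max = 4` — long enough to keep multi-word domain terms
such as "milk fat globule membrane" as single vocabulary entries.  The
bundled stop list contains function words only: generic content words
("study", "human") are intentionally kept, because they are part of how a
corpus talks about itself and routinely appear in human-readable themes.
Terms with document frequency below `min_df = 2` are dropped.

The tf-idf variant is fixed: raw term counts,
idf(t) = ln((1 + N)/(1 + df(t))) + 1 (smoothed, never zero), and L2
(unit-Euclidean) row normalization.  This is the de-facto standard variant
in the Python ecosystem; sublinear tf is not used.  The vectorizer is backed
by scikit-learn and is verified in the test suite against an independent
brute-force implementation of the same formula to 1e-9.

## K-means clustering and choosing K

Clustering runs Lloyd's algorithm with k-means++ initialization on the
normalized tf-idf rows (scikit-learn backend), `n_restarts = 10` with the
lowest within-cluster sum of squares (WSS) winning, `max_iter = 300`,
`tol = 1e-6`, fully determined by the seed.  Clusters are always non-empty
(empty clusters are repaired by the backend's relocation step).  Euclidean
distance on L2-normalized rows is monotone in cosine similarity, so this is
effectively cosine clustering.

K is the analyst's choice and defaults to 7.  The WSS curve over a K range
(default 2–10) carries an **advisory** elbow suggestion: the interior K
maximizing the second forward difference of WSS, i.e. the sharpest bend of
the curve.  On corpora with 7 well-separated planted topics the suggestion
is 7, but on real corpora the elbow can be shallow and the choice should be
reviewed against the themes themselves.

Each cluster is summarized by its top-10 terms by **mean tf-idf weight**
over the cluster's documents (ties broken alphabetically), the cluster size
in documents, and median SJR / median year / earliest / latest over member
documents with known metadata.  Cluster size is reported as a document
count.  Cluster letters in the exported theme table are positional labels
(A, B, C, … by cluster index) with no meaning beyond identification.

## 2-D embedding

The document map is t-SNE on the tf-idf rows, initialized from the
2-component truncated SVD rescaled to small norm (the standard small-norm
init), deterministic given the seed.  Gradients are computed exactly for
corpora up to 2000 documents: the Barnes–Hut tree approximation can assign
coincident points to different cells and separate exact duplicates, while
the exact gradient keeps identical documents exactly co-located; at corpus
scale the O(n²) cost is a few seconds.  Perplexity defaults to 30 and must
be below the number of documents; the pipeline clamps it to (n−1)/3 for
small corpora.  The embedding is for visual inspection only — no statistic
in the package is computed from the coordinates, beyond the sanity property
that within-topic distances are smaller than between-topic distances on
planted-topic data.

## Overrepresentation statistics

Both enrichment families use the upper-tail hypergeometric probability

P(X ≥ k), X ~ Hypergeometric(N_bg, K_bg, n),

equivalent to a one-sided Fisher exact test; k = 0 returns exactly 1, and
the implementation (scipy backend) is verified against exhaustive subset
enumeration for all parameter sets with N_bg ≤ 12 at 1e-12.

- **Entity enrichment** (per cluster, document level): k = documents of the
  cluster mentioning the entity, n = cluster size, K_bg = documents in the
  whole analyzed corpus mentioning it, N_bg = corpus size.  Entities
  observed in fewer than 2 cluster documents are not tested (a single
  occurrence cannot meaningfully exceed background), and rows with
  p ≥ alpha (default 0.1) are dropped from the report.
- **Category enrichment** (per cluster, entity level): cluster entities are
  mapped through an entity→category table (e.g. disease-ontology terms);
  entities without any mapping are counted out of both cluster (n) and
  background (N_bg).

False discovery rates are Benjamini–Hochberg step-up values,
q_(i) = min_{j ≥ i} (m·p_(j)/j) clipped at 1, computed **within each
cluster's family of performed tests**; raw p and FDR are reported side by
side rather than silently replacing one with the other.  Because the
hypergeometric is discrete, the attainable levels sit below the nominal
level; with the background counts used in validation (hundreds of documents
per entity) the empirical type-I rate at p < 0.05 sits close to, and
slightly under, 0.05.

## Synthetic corpus generator

The generator is the package's instrument for validation and defines the
reference study conditions.  Each document draws a topic (uniformly by
default), a length ~ Poisson(`doc_length_mean`) truncated at ≥ 20 tokens,
and tokens i.i.d.: with probability `keyword_weight` a uniform draw from the
topic's keyword vocabulary, else a uniform draw from the shared background
vocabulary.  Keyword vocabularies of distinct topics are disjoint and
disjoint from the background, so the expected between-topic document cosine
similarity on keyword terms is zero — the structural assumption that makes
topic recovery by tf-idf + K-means a fair test.  Sentences are chunks of
8–15 tokens (uniform), rendered with a capitalized first token and a
terminal period so the rule-based sentencizer recovers exactly the generated
boundaries.  Entity mentions are planted per document with count ~
Poisson(`mention_rate`), entity uniform over the lexicon, surface form a
non-preferred synonym with probability `synonym_prob`, inserted as whole
token units never at a sentence start and never across sentence boundaries;
exact character spans and sentence indices are recorded as ground truth.
Years are uniform over `year_range`; journals and SJR values are synthetic
metadata.  Randomness is a per-document substream keyed by (seed, document
index), so corpora are prefix-stable when only `n_docs` changes.

Reference defaults: 7 topics × 15 keywords, `keyword_weight = 0.6`,
`n_docs = 700`, `doc_length_mean = 120`, years 2000–2022, `synonym_prob =
0.5`, `mention_rate = 8` planted mentions per document.  The mention rate
emulates the annotated-entity density of real abstracts processed by
gene/disease taggers (several entity mentions per abstract); with the
bundled 23-entity lexicon it yields on the order of 1.5 protein–disease
comention records per document and a non-degenerate network at the
5-document support threshold.  The bundled default lexicon (13 proteins, 10
diseases) is constructed so that no synonym collides with any topic keyword
or background word, and no multi-word synonym can arise by chance adjacency
of pool words — this is what makes *exact* precision/recall validation of
the tagger possible.

**What the generator does not emulate** — and therefore what passing tests
do *not* show about real corpora: English syntax and discourse, Zipfian
vocabulary, topic mixtures within a document (each document has exactly one
topic), correlated entity mentions (entities are planted independently of
topic and of each other), ambiguous or overlapping entity names, and OCR or
encoding noise.  Recovery results on this generator are a correctness check
of the machinery under its own assumptions, not an accuracy claim for live
literature; on real text, tagging quality is bounded by lexicon coverage
and clustering quality by how well word usage separates themes.

## Validation problem sizes

The bundled checks run at deliberate desk scale: topic-recovery studies use
five seeded corpora of 700 documents (ARI vs planted labels, elbow
suggestion, theme-keyword recovery); tagger exactness uses synonym-varied
corpora of 80–200 documents; the type-I calibration pools 2000
(cluster, entity) tests from four 2000-document corpora with a 100-entity
lexicon, short documents (the text content is irrelevant to the calibration)
and mentions planted independently of topic; hypergeometric enumeration
covers every parameter set with a universe of ≤ 12.  These sizes give the
statistics enough granularity to be meaningful (e.g. discrete p-values fine
enough to approach the nominal 0.05) while the whole suite runs in about a
minute.

## Pipeline and determinism

`run_pipeline` executes simulate/load → sentencize → tag → comention →
vectorize → cluster → themes → embed → year trends → enrichment, writing
every artifact as TSV/JSON/GraphML plus a manifest with per-stage row counts
and SHA-256 content hashes.  One global seed is fanned out to independent
per-stage substreams (generator, K-means, embedding) via a seed sequence;
every table header records the config hash (analysis settings only — the
output directory is excluded) and seed.  Two runs with the same config and
seed are byte-identical.  A stage failure raises an error naming the stage
and removes the partial outputs of that run.

## Known limitations

- Dictionary tagging cannot find entities absent from the lexicon and does
  not disambiguate polysemous names; it is a transparent, reproducible
  stand-in for learned taggers, not a replacement at their accuracy.
- The comention network records co-occurrence only; an edge is not a claim
  of mechanism or direction.
- K-means with cosine-equivalent geometry assumes roughly balanced, convex
  clusters in tf-idf space; strongly imbalanced or nested themes will be
  split or merged.
- The elbow heuristic is a second-difference argmax and is advisory; flat
  WSS curves yield weak suggestions.
- BH-FDR assumes independence or positive dependence within each cluster's
  test family; entity tests within a cluster are weakly negatively
  correlated through the fixed cluster size, which in practice makes the
  procedure mildly conservative here.
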