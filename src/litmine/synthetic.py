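"""Synthetic corpus generator with planted topic structure and entity mentions.

Every downstream stage of the pipeline is exercised against corpora produced
here, because each generated document carries a recoverable ground truth: its
latent topic and the exact character spans of every planted entity mention.

The generative model is token-level (no syntax): each document draws a topic,
then draws tokens i.i.d. from the topic's keyword vocabulary with probability
``keyword_weight`` and from a shared background vocabulary otherwise.  Entity
mentions are inserted as whole token units (possibly multi-word surfaces),
never at a sentence start and never split across sentence boundaries, so the
annotation and comention ground truth is exact.  Topic keyword sets are
mutually disjoint, which makes the expected between-topic document similarity
on keyword terms zero and justifies the clustering-recovery checks.

Defaults encode the reference study conditions: 7 topics with 15 disjoint
keywords each, 700 documents, keyword_weight 0.6, mean document length 120
tokens, publication years uniform on 2000-2022.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotate import EntityLexicon, LexiconEntry
from .corpus import Corpus, Document
from .errors import ValidationError

__all__ = [
    "TopicSpec",
    "GeneratorConfig",
    "PlantedMention",
    "GroundTruth",
    "default_topics",
    "default_background_vocab",
    "default_entity_lexicon",
    "generate",
    "truth_entity_doc_counts",
    "write_ground_truth",
    "read_ground_truth",
]


@dataclass(frozen=True)
class TopicSpec:
    """A latent topic: an id, its keyword vocabulary, and the probability that
    a generated token is a keyword rather than a background word."""

    topic_id: int
    keywords: tuple[str, ...]
    keyword_weight: float = 0.6


@dataclass(frozen=True)
class PlantedMention:
    preflabel: str
    type: str
    start: int
    end: int
    surface: str
    sentence_index: int


@dataclass
class GroundTruth:
    """Per-document truth: latent topic and planted mentions with spans."""

    topic_of: dict[str, int] = field(default_factory=dict)
    mentions: dict[str, list[PlantedMention]] = field(default_factory=dict)


# --- default study conditions ----------------------------------------------

_TOPIC_KEYWORDS: tuple[tuple[str, ...], ...] = (
    # liver / metabolic animal studies
    ("liver", "diet", "mouse", "fatty", "rat", "plasma", "muscle", "hepatic",
     "lipid", "metabolic", "cholesterol", "adipose", "glucose", "triglyceride",
     "mitochondrial"),
    # milk and lactation
    ("milk", "peptide", "infant", "colostrum", "lactation", "bovine", "membrane",
     "globule", "dairy", "whey", "formula", "breastfeeding", "maternal",
     "neonatal", "glycoprotein"),
    # plant and food allergens
    ("plant", "seed", "allergen", "gluten", "wheat", "soybean", "crop", "fruit",
     "grain", "flour", "cultivar", "harvest", "germination", "legume", "cereal"),
    # gut microbiota
    ("gut", "probiotic", "microbiota", "intestinal", "microbiome", "bacterial",
     "host", "mucosa", "fermentation", "bowel", "colon", "microbial",
     "commensal", "barrier", "epithelial"),
    # nutrition science at large
    ("nutrition", "nutritional", "research", "nutrigenomics", "health",
     "metabolomics", "genomics", "science", "policy", "education", "technology",
     "personalized", "translational", "interdisciplinary", "framework"),
    # cancer and meat quality
    ("cell", "cancer", "meat", "colorectal", "quality", "fish", "tumor", "beef",
     "pork", "tenderness", "apoptosis", "proliferation", "postmortem",
     "carcass", "signaling"),
    # saliva / egg / pediatric biomarkers
    ("egg", "salivary", "child", "saliva", "proteome", "yolk", "albumen",
     "oral", "pediatric", "cohort", "urinary", "urine", "serum", "secretion",
     "gland"),
)

_BACKGROUND: tuple[str, ...] = (
    "protein", "proteins", "proteomic", "proteomics", "study", "human",
    "analysis", "sample", "samples", "level", "levels", "expression",
    "identified", "associated", "results", "data", "method", "methods",
    "approach", "significant", "increased", "decreased", "observed", "measured",
    "compared", "control", "group", "groups", "effect", "effects", "response",
    "profile", "profiling", "pathway", "pathways", "function", "functional",
    "process", "processes", "role", "potential", "novel", "specific",
    "different", "total", "using", "based", "related", "important",
    "development", "changes", "change", "higher", "lower", "present", "found",
    "showed", "performed", "evaluated", "determined", "investigated",
    "examined", "conducted", "obtained", "collected", "treatment", "condition",
    "conditions", "model", "models", "mechanism", "mechanisms", "factor",
    "factors", "component", "components", "content", "concentration",
    "concentrations", "quantitative", "spectrometry", "chromatography",
    "electrophoresis", "assay", "antibody", "gel", "mass", "liquid", "tandem",
    "label", "labeling", "relative", "absolute", "abundance", "abundant",
    "differential", "differentially", "regulation", "regulated", "upregulated",
    "downregulated", "biological", "clinical", "molecular", "cellular",
    "tissue", "tissues", "blood", "subjects", "participants", "patients",
    "individuals", "healthy", "adult", "adults", "women", "men", "age",
    "years", "daily", "intake", "consumption", "supplementation",
    "intervention", "baseline", "outcome", "outcomes", "risk", "association",
    "correlation", "regression", "statistical", "database", "software",
    "workflow", "experiment", "experimental", "replicate", "validation",
    "candidate", "target", "targets", "interaction", "interactions",
)

_JOURNALS: tuple[str, ...] = (
    "Journal of Proteome Research",
    "Nutrients",
    "Proteomics",
    "Molecular Nutrition and Food Research",
    "Clinical Proteomics",
    "Food Chemistry",
)

_PROTEINS: tuple[tuple[str, tuple[str, ...], str], ...] = (
    ("LEP", ("leptin",), "gene:3952"),
    ("ADIPOQ", ("adiponectin",), "gene:9370"),
    ("INS", ("insulin",), "gene:3630"),
    ("ALB", ("albumin",), "gene:213"),
    ("CRP", ("c-reactive protein",), "gene:1401"),
    ("IL6", ("interleukin-6",), "gene:3569"),
    ("TNF", ("tumor necrosis factor",), "gene:7124"),
    ("LTF", ("lactoferrin", "lactotransferrin"), "gene:4057"),
    ("MFGE8", ("lactadherin",), "gene:4240"),
    ("GDF15", ("growth differentiation factor-15",), "gene:9518"),
    ("TF", ("transferrin",), "gene:7018"),
    ("APOE", ("apolipoprotein e",), "gene:348"),
    ("PON1", ("paraoxonase-1",), "gene:5444"),
)

_DISEASES: tuple[tuple[str, tuple[str, ...], str], ...] = (
    ("obesity", (), "MESH:D009765"),
    ("diabetes mellitus", ("diabetes",), "MESH:D003920"),
    ("celiac disease", ("coeliac disease",), "MESH:D002446"),
    ("inflammatory bowel disease", ("IBD",), "MESH:D015212"),
    ("NAFLD", ("fatty liver disease",), "MESH:D065626"),
    ("anemia", ("anaemia",), "MESH:D000740"),
    ("hypertension", (), "MESH:D006973"),
    ("atherosclerosis", (), "MESH:D050197"),
    ("asthma", (), "MESH:D001249"),
    ("osteoporosis", (), "MESH:D010024"),
)


def default_topics(keyword_weight: float = 0.6) -> list[TopicSpec]:
    """The seven reference topics (disjoint 15-keyword vocabularies)."""
    return [
        TopicSpec(topic_id=i, keywords=kw, keyword_weight=keyword_weight)
        for i, kw in enumerate(_TOPIC_KEYWORDS)
    ]


def default_background_vocab() -> tuple[str, ...]:
    return _BACKGROUND


def default_entity_lexicon() -> EntityLexicon:
    """A small protein/disease lexicon whose synonyms never collide with the
    default topic keywords or background vocabulary (so dictionary tagging on
    generated corpora is exact)."""
    entries = [
        LexiconEntry(pl, "protein", (pl,) + syns, xid) for pl, syns, xid in _PROTEINS
    ] + [
        LexiconEntry(pl, "disease", (pl,) + syns, xid) for pl, syns, xid in _DISEASES
    ]
    return EntityLexicon(entries)


@dataclass
class GeneratorConfig:
    """Generator settings; the defaults are the reference study conditions."""

    n_docs: int = 700
    topics: list[TopicSpec] = field(default_factory=default_topics)
    background_vocab: tuple[str, ...] = field(default_factory=default_background_vocab)
    doc_length_mean: int = 120
    lexicon: EntityLexicon = field(default_factory=default_entity_lexicon)
    mention_rate: float = 8.0
    synonym_prob: float = 0.5
    year_range: tuple[int, int] = (2000, 2022)
    seed: int = 0
    topic_weights: tuple[float, ...] | None = None

    def validate(self) -> None:
        if self.n_docs < len(self.topics):
            raise ValidationError("n_docs must be >= number of topics")
        if self.doc_length_mean < 20:
            raise ValidationError("doc_length_mean must be >= 20")
        if not self.topics:
            raise ValidationError("at least one topic required")
        seen: set[str] = set()
        for t in self.topics:
            if len(t.keywords) < 10 or len(set(t.keywords)) != len(t.keywords):
                raise ValidationError(f"topic {t.topic_id}: needs >= 10 distinct keywords")
            if not (0.0 < t.keyword_weight < 1.0):
                raise ValidationError(f"topic {t.topic_id}: keyword_weight outside (0,1)")
            overlap = seen.intersection(t.keywords)
            if overlap:
                raise ValidationError(f"topic keyword sets overlap: {sorted(overlap)}")
            seen.update(t.keywords)
        if seen.intersection(self.background_vocab):
            raise ValidationError("background vocabulary overlaps topic keywords")
        if self.mention_rate < 0:
            raise ValidationError("mention_rate must be non-negative")
        if not (0.0 <= self.synonym_prob <= 1.0):
            raise ValidationError("synonym_prob outside [0,1]")
        lo, hi = self.year_range
        if lo > hi:
            raise ValidationError("invalid year_range")
        if self.topic_weights is not None and len(self.topic_weights) != len(self.topics):
            raise ValidationError("topic_weights length mismatch")


def _doc_rng(seed: int, index: int) -> np.random.Generator:
    # per-document substream: corpora are prefix-stable under n_docs changes
    return np.random.default_rng([seed, index])


def _render(
    sentence_units: list[list[tuple[str, object]]]
) -> tuple[str, list[PlantedMention]]:
    """Join sentence token units into an abstract, recording mention spans.

    Each unit is (surface, entry-or-None); the first unit of a sentence is
    capitalized (it is never a mention) so the rule-based sentencizer splits
    generated text exactly at the generated sentence boundaries.
    """
    parts: list[str] = []
    planted: list[PlantedMention] = []
    offset = 0
    for s_idx, units in enumerate(sentence_units):
        for u_idx, (surface, entry) in enumerate(units):
            if u_idx == 0:
                surface = surface[0].upper() + surface[1:]
            if parts:
                parts.append(" ")
                offset += 1
            if entry is not None:
                planted.append(
                    PlantedMention(
                        preflabel=entry.preflabel,
                        type=entry.type,
                        start=offset,
                        end=offset + len(surface),
                        surface=surface,
                        sentence_index=s_idx,
                    )
                )
            parts.append(surface)
            offset += len(surface)
            if u_idx == len(units) - 1:
                parts.append(".")
                offset += 1
    return "".join(parts), planted


def generate(config: GeneratorConfig) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus and its ground truth; fully determined by the seed."""
    config.validate()
    truth = GroundTruth()
    docs: list[Document] = []
    n_topics = len(config.topics)
    weights = None
    if config.topic_weights is not None:
        w = np.asarray(config.topic_weights, dtype=float)
        weights = w / w.sum()
    lex_entries = config.lexicon.entries
    for i in range(config.n_docs):
        rng = _doc_rng(config.seed, i)
        doc_id = str(10_000_000 + i)
        topic = config.topics[int(rng.choice(n_topics, p=weights))]
        length = max(20, int(rng.poisson(config.doc_length_mean)))
        is_kw = rng.random(length) < topic.keyword_weight
        kw_idx = rng.integers(0, len(topic.keywords), size=length)
        bg_idx = rng.integers(0, len(config.background_vocab), size=length)
        tokens = [
            topic.keywords[kw_idx[j]] if is_kw[j] else config.background_vocab[bg_idx[j]]
            for j in range(length)
        ]
        # chunk into sentences of 8-15 tokens
        sentence_units: list[list[tuple[str, object]]] = []
        pos = 0
        while pos < length:
            n = int(rng.integers(8, 16))
            chunk = tokens[pos : pos + n]
            sentence_units.append([(tok, None) for tok in chunk])
            pos += n
        # plant mentions as whole units, never at a sentence start
        n_mentions = int(rng.poisson(config.mention_rate)) if lex_entries else 0
        for _ in range(n_mentions):
            entry = lex_entries[int(rng.integers(len(lex_entries)))]
            non_pref = [s for s in entry.synonyms if s != entry.preflabel]
            if non_pref and rng.random() < config.synonym_prob:
                surface = non_pref[int(rng.integers(len(non_pref)))]
            else:
                surface = entry.preflabel
            s_idx = int(rng.integers(len(sentence_units)))
            units = sentence_units[s_idx]
            at = int(rng.integers(1, len(units) + 1))
            units.insert(at, (surface, entry))
        abstract, planted = _render(sentence_units)
        year = int(rng.integers(config.year_range[0], config.year_range[1] + 1))
        journal = str(rng.choice(_JOURNALS))
        sjr = round(float(rng.uniform(0.3, 3.5)), 3)
        title = f"Synthetic abstract {doc_id} (topic {topic.topic_id})"
        docs.append(
            Document(
                doc_id=doc_id,
                title=title,
                abstract=abstract,
                year=year,
                journal=journal,
                sjr=sjr,
                query_tags=frozenset({"synthetic"}),
            )
        )
        truth.topic_of[doc_id] = topic.topic_id
        truth.mentions[doc_id] = planted
    return Corpus(documents=docs), truth


def truth_entity_doc_counts(truth: GroundTruth) -> dict[str, int]:
    """Document-level planted-mention counts per preflabel (each document
    counts once however many times the entity was planted in it)."""
    counts: dict[str, int] = {}
    for doc_id, planted in truth.mentions.items():
        for pl in {p.preflabel for p in planted}:
            counts[pl] = counts.get(pl, 0) + 1
    return counts


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "topic_of": truth.topic_of,
        "mentions": {
            doc_id: [
                {
                    "preflabel": p.preflabel,
                    "type": p.type,
                    "start": p.start,
                    "end": p.end,
                    "surface": p.surface,
                    "sentence_index": p.sentence_index,
                }
                for p in planted
            ]
            for doc_id, planted in truth.mentions.items()
        },
    }
    Path(path).write_text(
        json.dumps(payload, ensure_ascii=False, indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    truth = GroundTruth(topic_of={k: int(v) for k, v in payload["topic_of"].items()})
    for doc_id, planted in payload["mentions"].items():
        truth.mentions[doc_id] = [PlantedMention(**p) for p in planted]
    return truth
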