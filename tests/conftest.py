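"""Shared fixtures: small lexica, tiny corpora, and generated corpora."""

from __future__ import annotations

import pytest

from litmine import Corpus, Document, sentencize
from litmine.annotate import EntityLexicon, LexiconEntry
from litmine.synthetic import GeneratorConfig, generate


@pytest.fixture(scope="session")
def small_lexicon() -> EntityLexicon:
    return EntityLexicon(
        [
            LexiconEntry("LEP", "protein", ("LEP", "leptin"), "gene:3952"),
            LexiconEntry("ADIPOQ", "protein", ("ADIPOQ", "adiponectin"), "gene:9370"),
            LexiconEntry("INS", "protein", ("INS", "insulin"), "gene:3630"),
            LexiconEntry("obesity", "disease", ("obesity",), "MESH:D009765"),
            LexiconEntry(
                "diabetes mellitus", "disease", ("diabetes mellitus", "diabetes"), "MESH:D003920"
            ),
        ]
    )


@pytest.fixture()
def tiny_corpus() -> Corpus:
    docs = [
        Document(
            doc_id="111",
            title="Leptin and obesity",
            abstract="Leptin is linked to obesity. Adiponectin was also measured.",
            year=2015,
            journal="Nutrients",
            sjr=1.2,
            query_tags=frozenset({"q1"}),
        ),
        Document(
            doc_id="222",
            title="Insulin study",
            abstract="Insulin correlates with diabetes. Plasma leptin rose in obesity.",
            year=2018,
            journal="Proteomics",
            sjr=0.9,
            query_tags=frozenset({"q1", "q2"}),
        ),
    ]
    return Corpus(documents=docs)


@pytest.fixture(scope="session")
def planted_corpus():
    """A mid-sized generated corpus with ground truth, sentencized."""
    cfg = GeneratorConfig(n_docs=100, seed=7)
    corpus, truth = generate(cfg)
    return sentencize(corpus), truth, cfg


def global_mention_spans(corpus, mentions):
    """Map tagger mentions (sentence-local spans) to document-global spans."""
    out = set()
    for m in mentions:
        sent = corpus.sentences[m.doc_id][m.sentence_index]
        out.add((m.doc_id, sent.start + m.start, sent.start + m.end, m.preflabel))
    return out


def planted_spans(truth):
    return {
        (doc_id, p.start, p.end, p.preflabel)
        for doc_id, planted in truth.mentions.items()
        for p in planted
    }
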