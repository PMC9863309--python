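"""Sentence-level entity comention records and the undirected comention network.

A comention is the undirected co-occurrence of two distinct normalized
entities within one sentence; it carries no semantic direction.  Records are
stored in canonical vertex order (v1 <= v2 by preflabel) and deduplicated per
sentence: a pair mentioned twice in a sentence is one comention event.  Edge
support in the network is counted at the distinct-document level — the number
of unique publications comentioning the two entities.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from .annotate import Mention
from .corpus import Corpus
from .errors import ContractError, StateError

__all__ = [
    "EntityRef",
    "ComentionRecord",
    "ComentionNetwork",
    "extract_comentions",
    "build_network",
    "comention_table",
    "records_to_frame",
]


@dataclass(frozen=True)
class EntityRef:
    preflabel: str
    type: str
    text_found: str


@dataclass(frozen=True)
class ComentionRecord:
    """One sentence-level comention of two distinct entities, with v1 <= v2
    lexicographically by preflabel."""

    doc_id: str
    sentence_index: int
    sentence_text: str
    v1: EntityRef
    v2: EntityRef
    pub_year: int | None


def extract_comentions(
    mentions: Sequence[Mention],
    corpus: Corpus,
    type_pair: tuple[str, str] | None = None,
) -> list[ComentionRecord]:
    """All unordered pairs of distinct preflabels comentioned in a sentence.

    Repeated mentions of one preflabel in a sentence are deduplicated (the
    earliest occurrence in the sentence supplies ``text_found``, so extraction
    is invariant to the input order of the mentions).  With ``type_pair``
    given, only pairs carrying those two types (in either order) are kept.
    """
    if not corpus.is_sentencized:
        raise StateError("extract_comentions requires a sentencized corpus")
    years = {d.doc_id: d.year for d in corpus.documents}
    by_sentence: dict[tuple[str, int], dict[tuple[str, str], tuple[int, EntityRef]]] = {}
    for m in mentions:
        key = (m.doc_id, m.sentence_index)
        ents = by_sentence.setdefault(key, {})
        ekey = (m.preflabel, m.type)
        if ekey not in ents or m.start < ents[ekey][0]:
            ents[ekey] = (m.start, EntityRef(m.preflabel, m.type, m.text_found))
    records: list[ComentionRecord] = []
    for (doc_id, s_idx) in sorted(by_sentence):
        ents = by_sentence[(doc_id, s_idx)]
        refs = [ents[k][1] for k in sorted(ents)]
        for a, b in combinations(refs, 2):
            if a.preflabel == b.preflabel:
                continue
            if type_pair is not None:
                ta, tb = type_pair
                if (a.type, b.type) not in ((ta, tb), (tb, ta)):
                    continue
            v1, v2 = (a, b) if a.preflabel <= b.preflabel else (b, a)
            records.append(
                ComentionRecord(
                    doc_id=doc_id,
                    sentence_index=s_idx,
                    sentence_text=corpus.sentences[doc_id][s_idx].text,
                    v1=v1,
                    v2=v2,
                    pub_year=years.get(doc_id),
                )
            )
    return records


@dataclass
class ComentionNetwork:
    """Undirected network over (preflabel, type) nodes.

    Node weight is the number of distinct documents mentioning the entity in
    the supporting records; edge weight is the number of distinct documents
    comentioning the pair, so an edge never outweighs its endpoints.
    """

    graph: nx.Graph
    records_by_edge: dict[tuple[tuple[str, str], tuple[str, str]], list[ComentionRecord]]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def to_graphml(self, path: str | Path) -> None:
        g = nx.Graph()
        for (pl, t), data in self.graph.nodes(data=True):
            g.add_node(f"{pl}|{t}", preflabel=pl, type=t, weight=data["weight"])
        for (u, v, data) in self.graph.edges(data=True):
            g.add_edge(f"{u[0]}|{u[1]}", f"{v[0]}|{v[1]}", weight=data["weight"])
        nx.write_graphml(g, str(path))

    def to_edgelist_tsv(self, path: str | Path) -> None:
        rows = []
        for u, v, data in self.graph.edges(data=True):
            a, b = sorted((u, v))
            rows.append(
                {
                    "v1_preflabel": a[0],
                    "v1_type": a[1],
                    "v2_preflabel": b[0],
                    "v2_type": b[1],
                    "n_documents": data["weight"],
                }
            )
        frame = pd.DataFrame(
            rows,
            columns=["v1_preflabel", "v1_type", "v2_preflabel", "v2_type", "n_documents"],
        )
        if len(frame):
            frame = frame.sort_values(
                ["v1_preflabel", "v2_preflabel"], kind="stable"
            ).reset_index(drop=True)
        frame.to_csv(path, sep="\t", index=False)


def build_network(
    records: Sequence[ComentionRecord], min_support: int = 0
) -> ComentionNetwork:
    """Aggregate records into a network, keeping edges whose distinct-document
    support is at least ``min_support``; isolated nodes are dropped."""
    node_docs: dict[tuple[str, str], set[str]] = {}
    edge_docs: dict[tuple, set[str]] = {}
    edge_records: dict[tuple, list[ComentionRecord]] = {}
    for r in records:
        k1, k2 = (r.v1.preflabel, r.v1.type), (r.v2.preflabel, r.v2.type)
        node_docs.setdefault(k1, set()).add(r.doc_id)
        node_docs.setdefault(k2, set()).add(r.doc_id)
        ekey = (k1, k2) if k1 <= k2 else (k2, k1)
        edge_docs.setdefault(ekey, set()).add(r.doc_id)
        edge_records.setdefault(ekey, []).append(r)
    g = nx.Graph()
    kept: dict[tuple, list[ComentionRecord]] = {}
    for ekey, docs in edge_docs.items():
        if len(docs) < min_support:
            continue
        k1, k2 = ekey
        for k in (k1, k2):
            if k not in g:
                g.add_node(k, weight=len(node_docs[k]))
        g.add_edge(k1, k2, weight=len(docs))
        kept[ekey] = edge_records[ekey]
    return ComentionNetwork(graph=g, records_by_edge=kept)


def comention_table(records: Sequence[ComentionRecord]) -> pd.DataFrame:
    """Tabular form of protein–disease records: one row per record with
    columns pmid, sentence, date, gene/protein, disease.  Any column can be
    sorted stably (pandas ``sort_values(kind="stable")``)."""
    rows = []
    for r in records:
        types = {r.v1.type, r.v2.type}
        if types != {"protein", "disease"}:
            raise ContractError(
                "comention_table requires protein-disease records; got types "
                f"{sorted(types)} in document {r.doc_id}"
            )
        prot = r.v1 if r.v1.type == "protein" else r.v2
        dis = r.v2 if prot is r.v1 else r.v1
        rows.append(
            {
                "pmid": r.doc_id,
                "sentence": r.sentence_text,
                "date": r.pub_year,
                "gene/protein": prot.preflabel,
                "disease": dis.preflabel,
            }
        )
    return pd.DataFrame(rows, columns=["pmid", "sentence", "date", "gene/protein", "disease"])


def records_to_frame(records: Sequence[ComentionRecord]) -> pd.DataFrame:
    """Generic record export (any type pair), one row per record."""
    rows = [
        {
            "doc_id": r.doc_id,
            "sentence_index": r.sentence_index,
            "sentence": r.sentence_text,
            "pub_year": r.pub_year,
            "v1_preflabel": r.v1.preflabel,
            "v1_type": r.v1.type,
            "v1_text_found": r.v1.text_found,
            "v2_preflabel": r.v2.preflabel,
            "v2_type": r.v2.type,
            "v2_text_found": r.v2.text_found,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "doc_id",
            "sentence_index",
            "sentence",
            "pub_year",
            "v1_preflabel",
            "v1_type",
            "v1_text_found",
            "v2_preflabel",
            "v2_type",
            "v2_text_found",
        ],
    )
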