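"""End-to-end pipeline: simulate/load -> sentencize -> tag -> comention ->
vectorize -> cluster -> themes -> embedding -> year trends -> enrichment.

One config and one seed drive the whole run; the seed is fanned out to
per-stage substreams (generator, K-means, embedding).  Every report table is
written as TSV with a header comment recording the config hash and seed, and a
JSON manifest records inputs, per-stage row counts and content hashes — two
runs with the same config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import string
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import annotate, comention, enrichment, synthetic, themes
from .corpus import read_corpus, sentencize, write_corpus
from .errors import PipelineStageError, ValidationError

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Settings for one pipeline run; exactly one of ``corpus_path`` /
    ``simulate`` must be set."""

    out_dir: str = "litmine_out"
    corpus_path: str | None = None
    simulate: synthetic.GeneratorConfig | None = None
    lexicon_path: str | None = None
    category_map_path: str | None = None
    type_pair: tuple[str, str] = ("protein", "disease")
    min_support: int = 5
    min_doc_count: int = 1
    ngram_max: int = 4
    min_df: int = 2
    stopwords_path: str | None = None
    k: int = 7
    wss_k_min: int = 2
    wss_k_max: int = 10
    n_restarts: int = 10
    alpha: float = 0.1
    perplexity: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        if (self.corpus_path is None) == (self.simulate is None):
            raise ValidationError("exactly one of corpus_path / simulate must be set")
        if self.k < 2:
            raise ValidationError("k must be >= 2")

    @classmethod
    def from_file(cls, path: str | Path, seed: int | None = None) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            topics = sim.pop("topics", None)
            gen = synthetic.GeneratorConfig(**sim)
            if topics is not None:
                gen.topics = [synthetic.TopicSpec(**t) for t in topics]
            cfg.simulate = gen
        if isinstance(cfg.type_pair, list):
            cfg.type_pair = tuple(cfg.type_pair)
        if seed is not None:
            cfg.seed = seed
        return cfg

    def to_jsonable(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            sim = d["simulate"]
            sim["lexicon"] = [
                dataclasses.asdict(e) for e in self.simulate.lexicon.entries
            ]
        return d


def _config_hash(config: PipelineConfig) -> str:
    # identifies the analysis settings; the output destination is excluded
    d = config.to_jsonable()
    d.pop("out_dir", None)
    blob = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode("utf-8")).hexdigest()[:12]


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(3)
    names = ("generator", "kmeans", "embedding")
    return {
        name: int(c.generate_state(1)[0] % (2**31)) for name, c in zip(names, children)
    }


def _cluster_letter(c: int) -> str:
    letters = string.ascii_uppercase
    return letters[c] if c < 26 else f"C{c}"


class _Run:
    """Tracks written files so a failed stage can clean up after itself."""

    def __init__(self, out_dir: Path, header: str):
        self.out_dir = out_dir
        self.header = header
        self.files: list[Path] = []

    def write_frame(self, name: str, frame) -> Path:
        path = self.out_dir / name
        body = frame.to_csv(sep="\t", index=False, float_format="%.6g", lineterminator="\n")
        path.write_text(self.header + body, encoding="utf-8")
        self.files.append(path)
        return path

    def track(self, path: Path) -> Path:
        self.files.append(path)
        return path

    def cleanup(self) -> None:
        for p in self.files:
            try:
                p.unlink()
            except OSError:
                pass


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage and write all report artifacts.

    Returns the manifest (also written as ``manifest.json``).  On a stage
    failure, a :class:`PipelineStageError` naming the stage is raised and the
    partial outputs of this run are removed.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    header = f"# litmine config={_config_hash(config)} seed={config.seed}\n"
    run = _Run(out_dir, header)
    stages: dict[str, dict[str, int]] = {}
    log: list[str] = []
    current = "setup"

    def stage(name: str, **counts: int) -> None:
        stages[name] = counts
        log.append(f"stage={name} " + " ".join(f"{k}={v}" for k, v in counts.items()))

    try:
        # --- corpus -------------------------------------------------------
        current = "corpus"
        truth = None
        if config.simulate is not None:
            gen = dataclasses.replace(config.simulate, seed=seeds["generator"])
            corpus, truth = synthetic.generate(gen)
            write_corpus(corpus, run.track(out_dir / "corpus.json"))
            synthetic.write_ground_truth(truth, run.track(out_dir / "ground_truth.json"))
        else:
            corpus = read_corpus(config.corpus_path)
        stage("corpus", n_documents=len(corpus))

        # --- sentencize ---------------------------------------------------
        current = "sentencize"
        corpus = sentencize(corpus)
        n_sent = sum(len(s) for s in corpus.sentences.values())
        stage("sentencize", n_documents=len(corpus), n_sentences=n_sent)

        # --- tag ----------------------------------------------------------
        current = "tag"
        if config.lexicon_path is not None:
            lexicon = annotate.read_lexicon_tsv(config.lexicon_path)
        elif config.simulate is not None:
            lexicon = config.simulate.lexicon
        else:
            raise ValidationError("no lexicon available (set lexicon_path)")
        mentions = annotate.tag(corpus, lexicon)
        counts = annotate.entity_document_counts(mentions, min_count=config.min_doc_count)
        run.write_frame("entity_doc_counts.tsv", counts)
        run.write_frame(
            "mentions.tsv",
            pd.DataFrame(
                [dataclasses.asdict(m) for m in mentions],
                columns=[
                    "doc_id", "sentence_index", "start", "end",
                    "text_found", "preflabel", "type",
                ],
            ),
        )
        stage("tag", n_mentions=len(mentions), n_entities=len(counts))

        # --- comention ----------------------------------------------------
        current = "comention"
        records = comention.extract_comentions(mentions, corpus, config.type_pair)
        table = comention.comention_table(records)
        run.write_frame("comention_records.tsv", table)
        network = comention.build_network(records, min_support=config.min_support)
        network.to_graphml(run.track(out_dir / "comention_network.graphml"))
        network.to_edgelist_tsv(run.track(out_dir / "comention_edges.tsv"))
        stage(
            "comention",
            n_records=len(records),
            n_nodes=network.n_nodes,
            n_edges=network.n_edges,
        )

        # --- vectorize ----------------------------------------------------
        current = "vectorize"
        if config.stopwords_path is not None:
            stop = frozenset(
                w.strip()
                for w in Path(config.stopwords_path).read_text("utf-8").splitlines()
                if w.strip() and not w.startswith("#")
            )
        else:
            stop = themes.load_default_stopwords()
        matrix = themes.vectorize_corpus(
            corpus, ngram_max=config.ngram_max, stopwords=stop, min_df=config.min_df
        )
        stage("vectorize", n_documents=matrix.shape[0], n_terms=matrix.shape[1])

        # --- cluster ------------------------------------------------------
        current = "cluster"
        curve = themes.wss_curve(
            matrix,
            range(config.wss_k_min, min(config.wss_k_max, len(corpus)) + 1),
            seed=seeds["kmeans"],
            n_restarts=config.n_restarts,
        )
        result = themes.kmeans(
            matrix, config.k, seed=seeds["kmeans"], n_restarts=config.n_restarts
        )
        run.write_frame(
            "wss_curve.tsv",
            pd.DataFrame(curve.points, columns=["k", "wss"]),
        )
        run.write_frame(
            "assignments.tsv",
            pd.DataFrame(
                {"doc_id": result.doc_ids, "cluster": result.label_array}
            ),
        )
        stage("cluster", k=result.k, elbow_suggestion=curve.elbow or -1)

        # --- themes -------------------------------------------------------
        current = "themes"
        theme_list = themes.cluster_themes(matrix, result, corpus)
        run.write_frame(
            "themes.tsv",
            pd.DataFrame(
                [
                    {
                        "cluster": _cluster_letter(t.cluster),
                        "theme": ", ".join(term for term, _ in t.top_terms),
                        "cluster_size": t.size,
                        "median_sjr": t.median_sjr,
                        "median_year": t.median_year,
                        "earliest": t.earliest,
                        "latest": t.latest,
                    }
                    for t in theme_list
                ]
            ),
        )
        stage("themes", n_clusters=len(theme_list))

        # --- embedding ----------------------------------------------------
        current = "embedding"
        perplexity = min(config.perplexity, max(2.0, (len(corpus) - 1) / 3))
        coords = themes.embed_2d(matrix, seed=seeds["embedding"], perplexity=perplexity)
        sjr = {d.doc_id: d.sjr for d in corpus.documents}
        run.write_frame(
            "embedding.tsv",
            pd.DataFrame(
                [
                    {
                        "doc_id": d,
                        "x": coords[d][0],
                        "y": coords[d][1],
                        "cluster": result.labels[d],
                        "sjr": sjr.get(d),
                    }
                    for d in result.doc_ids
                ]
            ),
        )
        stage("embedding", n_documents=len(coords))

        # --- year trend ---------------------------------------------------
        current = "year_trend"
        trend = themes.cluster_year_trend(result, corpus)
        run.write_frame("year_trend.tsv", trend)
        stage("year_trend", n_rows=len(trend))

        # --- enrichment ---------------------------------------------------
        current = "enrichment"
        ent = enrichment.cluster_entity_enrichment(
            mentions, result, type_filter=None, alpha=config.alpha
        )
        run.write_frame("entity_enrichment.tsv", enrichment.results_to_frame(ent))
        n_cat = 0
        if config.category_map_path is not None:
            catmap = enrichment.read_category_map_tsv(config.category_map_path)
            cluster_entities = {
                c: {
                    m.preflabel
                    for m in mentions
                    if result.labels.get(m.doc_id) == c and m.type == "protein"
                }
                for c in range(result.k)
            }
            background = {e.preflabel for e in lexicon.entries if e.type == "protein"}
            cat = enrichment.category_enrichment(cluster_entities, catmap, background)
            run.write_frame("category_enrichment.tsv", enrichment.results_to_frame(cat))
            n_cat = len(cat)
        stage("enrichment", n_entity_rows=len(ent), n_category_rows=n_cat)

        # --- manifest -----------------------------------------------------
        current = "manifest"
        log_path = out_dir / "pipeline.log"
        log_path.write_text("\n".join(log) + "\n", encoding="utf-8")
        run.track(log_path)
        files = {}
        for p in sorted(run.files):
            if p.name == "manifest.json":
                continue
            data = p.read_bytes()
            files[p.name] = {
                "sha256": hashlib.sha256(data).hexdigest(),
                "n_rows": max(0, data.count(b"\n") - 2) if p.suffix == ".tsv" else None,
            }
        manifest = {
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "stage_seeds": seeds,
            "stages": stages,
            "files": files,
        }
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        return manifest
    except Exception as exc:
        run.cleanup()
        if isinstance(exc, PipelineStageError):
            raise
        raise PipelineStageError(current, str(exc)) from exc
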