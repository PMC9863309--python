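"""Thematic clustering: tf-idf vectorization, K-means with WSS diagnostics,
per-cluster theme keywords, 2-D embedding, and cluster-by-year trends.

The tf-idf variant is fixed: raw term counts, smoothed inverse document
frequency idf(t) = ln((1+N)/(1+df(t))) + 1, and L2 (unit Euclidean) row
normalization — the de-facto standard of the scikit-learn ecosystem, which
backs the vectorizer, the K-means clustering (k-means++ initialization,
restart with the lowest within-cluster sum of squares wins) and the t-SNE
embedding here.

Tokenization keeps multi-word themes recoverable: terms are lowercase runs of
letters/digits/hyphens of length >= 2, with n-grams of adjacent surviving
tokens up to ``ngram_max`` (default 4, enough to admit a theme term like
"milk fat globule membrane" as a single vocabulary entry).
"""

from __future__ import annotations

import re
import statistics
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.cluster import KMeans
from sklearn.decomposition import TruncatedSVD
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.manifold import TSNE

from .corpus import Corpus
from .errors import ValidationError

__all__ = [
    "TfidfMatrix",
    "ClusteringResult",
    "ClusterTheme",
    "WssCurve",
    "load_default_stopwords",
    "tokenize",
    "tfidf",
    "vectorize_corpus",
    "kmeans",
    "wss_curve",
    "cluster_themes",
    "embed_2d",
    "cluster_year_trend",
]

_TOKEN_RE = re.compile(r"[^\W_]+(?:-[^\W_]+)*", re.UNICODE)


def load_default_stopwords() -> frozenset[str]:
    """The bundled minimal function-word stop list."""
    text = (resources.files("litmine") / "data" / "stopwords_en.txt").read_text("utf-8")
    return frozenset(
        w.strip() for w in text.splitlines() if w.strip() and not w.startswith("#")
    )


def tokenize(
    text: str, ngram_max: int = 4, stopwords: Iterable[str] | None = None
) -> list[str]:
    """Term sequence for one document: lowercased unigrams (length >= 2 runs of
    letters/digits/hyphen, stopwords removed) followed by n-grams of adjacent
    surviving tokens up to ``ngram_max`` (joined with single spaces)."""
    if not 1 <= ngram_max <= 4:
        raise ValidationError("ngram_max must be in 1..4")
    stop = frozenset(stopwords) if stopwords is not None else frozenset()
    unigrams = [
        tok for tok in _TOKEN_RE.findall(text.lower()) if len(tok) >= 2 and tok not in stop
    ]
    terms = list(unigrams)
    for n in range(2, ngram_max + 1):
        terms.extend(
            " ".join(unigrams[i : i + n]) for i in range(len(unigrams) - n + 1)
        )
    return terms


@dataclass
class TfidfMatrix:
    """Documents x terms tf-idf weights with unit-norm rows.

    ``vocabulary`` is sorted lexicographically; ``idf`` is per-term."""

    doc_ids: list[str]
    vocabulary: list[str]
    weights: sp.csr_matrix
    idf: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape

    def term_index(self, term: str) -> int:
        return self.vocabulary.index(term)


def tfidf(
    token_lists: Sequence[Sequence[str]],
    doc_ids: Sequence[str] | None = None,
    min_df: int = 1,
) -> TfidfMatrix:
    """tf-idf matrix over pre-tokenized documents.

    tf is the raw count, idf(t) = ln((1+N)/(1+df(t))) + 1, and every document
    row is scaled to unit Euclidean norm.  Terms with document frequency below
    ``min_df`` are dropped from the vocabulary.  Documents that end up with no
    vocabulary terms are an error (their doc_ids are listed).
    """
    if doc_ids is None:
        doc_ids = [str(i) for i in range(len(token_lists))]
    if len(doc_ids) != len(token_lists):
        raise ValidationError("doc_ids and token_lists length mismatch")
    vec = TfidfVectorizer(
        analyzer=lambda toks: toks,
        min_df=min_df,
        norm="l2",
        smooth_idf=True,
        sublinear_tf=False,
        lowercase=False,
    )
    try:
        weights = vec.fit_transform(token_lists)
    except ValueError as exc:  # empty vocabulary
        raise ValidationError(f"no terms survive vectorization: {exc}") from exc
    empty = [doc_ids[i] for i in range(weights.shape[0]) if weights.indptr[i] == weights.indptr[i + 1]]
    if empty:
        raise ValidationError(f"documents with no vocabulary terms: {empty}")
    vocab = vec.get_feature_names_out().tolist()
    return TfidfMatrix(
        doc_ids=list(doc_ids),
        vocabulary=vocab,
        weights=sp.csr_matrix(weights),
        idf=np.asarray(vec.idf_, dtype=float),
    )


def vectorize_corpus(
    corpus: Corpus,
    ngram_max: int = 4,
    stopwords: Iterable[str] | None = None,
    min_df: int = 2,
) -> TfidfMatrix:
    """Tokenize every document's analysis text field and build the tf-idf matrix."""
    if stopwords is None:
        stopwords = load_default_stopwords()
    token_lists = [tokenize(d.text, ngram_max, stopwords) for d in corpus.documents]
    return tfidf(token_lists, [d.doc_id for d in corpus.documents], min_df=min_df)


@dataclass
class ClusteringResult:
    k: int
    doc_ids: list[str]
    label_array: np.ndarray
    centroids: np.ndarray
    wss: float
    seed: int
    n_restarts: int

    @property
    def labels(self) -> dict[str, int]:
        return {d: int(l) for d, l in zip(self.doc_ids, self.label_array)}

    def cluster_members(self, c: int) -> list[str]:
        return [d for d, l in zip(self.doc_ids, self.label_array) if l == c]


def kmeans(
    matrix: TfidfMatrix,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> ClusteringResult:
    """K-means (Lloyd, k-means++ init) on the tf-idf rows; the restart with the
    lowest within-cluster sum of squares wins.  Deterministic given ``seed``."""
    n = matrix.weights.shape[0]
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} outside [1, n={n}]")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_restarts,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
        algorithm="lloyd",
    ).fit(matrix.weights)
    return ClusteringResult(
        k=k,
        doc_ids=list(matrix.doc_ids),
        label_array=km.labels_.astype(int),
        centroids=km.cluster_centers_,
        wss=float(km.inertia_),
        seed=seed,
        n_restarts=n_restarts,
    )


@dataclass
class WssCurve:
    """Within-cluster sum of squares for each K, with the elbow suggestion:
    the interior K maximizing the second forward difference of WSS.  The
    suggestion is advisory; K remains user-selectable."""

    points: list[tuple[int, float]]
    elbow: int | None


def wss_curve(
    matrix: TfidfMatrix,
    k_range: Iterable[int],
    seed: int = 0,
    n_restarts: int = 10,
) -> WssCurve:
    ks = sorted(set(int(k) for k in k_range))
    n = matrix.weights.shape[0]
    if not ks or ks[0] < 1 or ks[-1] > n:
        raise ValidationError(f"k_range must lie within [1, n={n}]")
    points = [(k, kmeans(matrix, k, seed=seed, n_restarts=n_restarts).wss) for k in ks]
    elbow = None
    if len(points) >= 3:
        w = [p[1] for p in points]
        second = [w[i - 1] - 2 * w[i] + w[i + 1] for i in range(1, len(w) - 1)]
        elbow = points[1 + int(np.argmax(second))][0]
    return WssCurve(points=points, elbow=elbow)


@dataclass
class ClusterTheme:
    """Human-readable cluster summary: top terms by mean tf-idf, plus size and
    year/journal-rank summaries of the member documents."""

    cluster: int
    top_terms: list[tuple[str, float]]
    size: int
    median_sjr: float | None
    median_year: float | None
    earliest: int | None
    latest: int | None


def cluster_themes(
    matrix: TfidfMatrix,
    result: ClusteringResult,
    corpus: Corpus,
    top_n: int = 10,
) -> list[ClusterTheme]:
    """Theme extraction: for each cluster, the ``top_n`` terms by mean
    normalized tf-idf weight over the cluster's documents (ties alphabetical),
    with document-count, median SJR and publication-year summaries."""
    if list(matrix.doc_ids) != list(result.doc_ids):
        raise ValidationError("matrix and clustering have inconsistent doc ordering")
    docs = {d.doc_id: d for d in corpus.documents}
    themes: list[ClusterTheme] = []
    vocab = np.asarray(matrix.vocabulary, dtype=object)
    for c in range(result.k):
        mask = result.label_array == c
        mean = np.asarray(matrix.weights[mask].mean(axis=0)).ravel()
        # sort by mean desc, ties alphabetical
        order = np.lexsort((vocab, -mean))[:top_n]
        top = [(str(vocab[i]), float(mean[i])) for i in order]
        members = [docs[d] for d, m in zip(result.doc_ids, mask) if m]
        years = [d.year for d in members if d.year is not None]
        sjrs = [d.sjr for d in members if d.sjr is not None]
        themes.append(
            ClusterTheme(
                cluster=c,
                top_terms=top,
                size=int(mask.sum()),
                median_sjr=float(statistics.median(sjrs)) if sjrs else None,
                median_year=float(statistics.median(years)) if years else None,
                earliest=min(years) if years else None,
                latest=max(years) if years else None,
            )
        )
    return themes


def embed_2d(
    matrix: TfidfMatrix, seed: int = 0, perplexity: float = 30.0
) -> dict[str, tuple[float, float]]:
    """t-SNE 2-D embedding of the tf-idf rows, deterministic given ``seed``.

    Initialization is the (deterministic) 2-component truncated SVD of the
    matrix, rescaled to small norm as usual for t-SNE, so identical documents
    stay co-located.
    """
    X = matrix.weights
    n = X.shape[0]
    if n < 4:
        raise ValidationError("embedding requires at least 4 documents")
    if perplexity >= n:
        raise ValidationError(f"perplexity ({perplexity}) must be < n ({n})")
    if X.shape[1] > 2:
        init = TruncatedSVD(n_components=2, random_state=seed).fit_transform(X)
    else:
        init = np.asarray(X.todense(), dtype=float)[:, :2]
    scale = init.std()
    if scale > 0:
        init = init / scale * 1e-4
    # exact gradients keep duplicate documents exactly co-located (the
    # Barnes-Hut tree approximation can split coincident points); the O(n^2)
    # cost is immaterial at corpus scale, so fall back to Barnes-Hut only for
    # very large corpora
    method = "exact" if n <= 2000 else "barnes_hut"
    coords = TSNE(
        n_components=2,
        perplexity=perplexity,
        init=init,
        random_state=seed,
        method=method,
    ).fit_transform(X)
    return {d: (float(x), float(y)) for d, (x, y) in zip(matrix.doc_ids, coords)}


def cluster_year_trend(result: ClusteringResult, corpus: Corpus) -> pd.DataFrame:
    """Counts per (year, cluster) over documents with a known year; years
    without publications inside the observed range are reported as zero."""
    years = {d.doc_id: d.year for d in corpus.documents}
    labels = result.labels
    pairs = [
        (years[d], labels[d]) for d in result.doc_ids if years.get(d) is not None
    ]
    if not pairs:
        return pd.DataFrame(columns=["year", "cluster", "n_docs"])
    counts: dict[tuple[int, int], int] = {}
    for y, c in pairs:
        counts[(y, c)] = counts.get((y, c), 0) + 1
    y_min = min(y for y, _ in pairs)
    y_max = max(y for y, _ in pairs)
    rows = [
        {"year": y, "cluster": c, "n_docs": counts.get((y, c), 0)}
        for y in range(y_min, y_max + 1)
        for c in range(result.k)
    ]
    return pd.DataFrame(rows, columns=["year", "cluster", "n_docs"])
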