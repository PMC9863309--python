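"""Vectorization, K-means, theme extraction, embedding and year trends."""

import math

import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from litmine import Corpus, Document
from litmine.errors import ValidationError
from litmine.synthetic import GeneratorConfig, generate
from litmine.themes import (
    TfidfMatrix,
    cluster_themes,
    cluster_year_trend,
    embed_2d,
    kmeans,
    tfidf,
    tokenize,
    vectorize_corpus,
    wss_curve,
)


def bruteforce_tfidf(token_lists, min_df=1):
    """Independent implementation of the fixed tf-idf variant: raw counts,
    idf = ln((1+N)/(1+df)) + 1, L2 row normalization."""
    N = len(token_lists)
    df: dict[str, int] = {}
    for toks in token_lists:
        for t in set(toks):
            df[t] = df.get(t, 0) + 1
    vocab = sorted(t for t, d in df.items() if d >= min_df)
    idx = {t: i for i, t in enumerate(vocab)}
    W = np.zeros((N, len(vocab)))
    for r, toks in enumerate(token_lists):
        for t in toks:
            if t in idx:
                W[r, idx[t]] += 1.0
        for t in set(toks):
            if t in idx:
                W[r, idx[t]] *= math.log((1 + N) / (1 + df[t])) + 1
        norm = np.linalg.norm(W[r])
        if norm > 0:
            W[r] /= norm
    return vocab, W


class TestTokenize:
    def test_lowercase_and_punctuation_stripping(self):
        assert tokenize("Milk protein, milk!", ngram_max=1) == ["milk", "protein", "milk"]

    def test_single_character_tokens_dropped(self):
        assert tokenize("A 4-gram of n words", ngram_max=1) == ["4-gram", "of", "words"]

    def test_stopwords_removed_before_ngrams(self):
        terms = tokenize("milk of the cow", ngram_max=2, stopwords={"of", "the"})
        assert terms == ["milk", "cow", "milk cow"]

    def test_four_gram_admitted(self):
        terms = tokenize("the milk fat globule membrane fraction", ngram_max=4,
                         stopwords={"the"})
        assert "milk fat globule membrane" in terms

    def test_ngram_max_bounds(self):
        with pytest.raises(ValidationError):
            tokenize("x y", ngram_max=5)


class TestTfidf:
    def test_hand_computed_weights(self):
        # d1="milk protein milk", d2="liver protein"
        mat = tfidf([["milk", "protein", "milk"], ["liver", "protein"]], ["d1", "d2"])
        i_milk = mat.vocabulary.index("milk")
        i_prot = mat.vocabulary.index("protein")
        assert mat.idf[i_prot] == pytest.approx(1.0)
        assert mat.idf[i_milk] == pytest.approx(math.log(3 / 2) + 1, abs=1e-9)
        w = mat.weights.toarray()
        assert w[0, i_milk] == pytest.approx(0.94216, abs=1e-5)
        assert w[0, i_prot] == pytest.approx(0.33517, abs=1e-5)

    def test_vocabulary_sorted_and_rows_unit_norm(self):
        mat = tfidf([["b", "a", "c"], ["c", "a"], ["d", "a"]])
        assert mat.vocabulary == sorted(mat.vocabulary)
        norms = np.asarray(sp.linalg.norm(mat.weights, axis=1)).ravel()
        assert np.allclose(norms, 1.0)

    def test_uniform_term_has_equal_weight_everywhere(self):
        token_lists = [["shared", f"u{i}"] for i in range(4)]
        mat = tfidf(token_lists)
        col = mat.weights.toarray()[:, mat.vocabulary.index("shared")]
        assert np.allclose(col, col[0])

    def test_min_df_drops_rare_terms(self):
        mat = tfidf([["spelt", "wheat"], ["wheat", "grain"], ["grain", "wheat"]], min_df=2)
        assert "spelt" not in mat.vocabulary

    def test_empty_document_error_lists_ids(self):
        with pytest.raises(ValidationError, match="d2"):
            tfidf([["milk"], []], ["d1", "d2"])

    def test_matches_bruteforce_on_random_corpora(self):
        rng = np.random.default_rng(37)
        vocab_pool = [f"w{i}" for i in range(12)]
        for trial in range(10):
            n_docs = int(rng.integers(2, 11))
            token_lists = [
                [vocab_pool[j] for j in rng.integers(0, 12, size=rng.integers(3, 15))]
                for _ in range(n_docs)
            ]
            mat = tfidf(token_lists)
            vocab, W = bruteforce_tfidf(token_lists)
            assert mat.vocabulary == vocab
            assert np.abs(mat.weights.toarray() - W).max() < 1e-9


class TestKmeans:
    def _matrix(self, X):
        return TfidfMatrix(
            doc_ids=[str(i) for i in range(X.shape[0])],
            vocabulary=[f"t{j}" for j in range(X.shape[1])],
            weights=sp.csr_matrix(X),
            idf=np.ones(X.shape[1]),
        )

    def test_k1_centroid_is_mean_and_wss_is_total_deviation(self):
        rng = np.random.default_rng(0)
        X = rng.random((12, 3))
        res = kmeans(self._matrix(X), 1)
        assert np.allclose(res.centroids[0], X.mean(axis=0))
        assert res.wss == pytest.approx(((X - X.mean(axis=0)) ** 2).sum(), rel=1e-9)

    def test_orthogonal_rows_separate_with_zero_wss(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        res = kmeans(self._matrix(X), 2)
        assert res.wss == pytest.approx(0.0, abs=1e-12)
        assert len(set(res.label_array)) == 2

    def test_recovers_three_planted_gaussians(self):
        rng = np.random.default_rng(41)
        centers = np.array([[0.0, 0.0], [1.5, 0.0], [0.0, 1.5]])
        labels = np.repeat([0, 1, 2], 20)
        X = centers[labels] + rng.normal(scale=0.05, size=(60, 2))
        res = kmeans(self._matrix(X), 3, seed=0)
        assert adjusted_rand_score(labels, res.label_array) == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        X = rng.random((30, 4))
        r1 = kmeans(self._matrix(X), 3, seed=9)
        r2 = kmeans(self._matrix(X), 3, seed=9)
        assert (r1.label_array == r2.label_array).all()
        assert r1.wss == r2.wss

    def test_k_out_of_range_rejected(self):
        X = np.eye(3)
        with pytest.raises(ValidationError):
            kmeans(self._matrix(X), 4)

    def test_wss_curve_endpoints_and_elbow(self):
        rng = np.random.default_rng(43)
        centers = np.array([[0, 0], [2, 0], [0, 2]])
        labels = np.repeat([0, 1, 2], 10)
        X = centers[labels] + rng.normal(scale=0.05, size=(30, 2))
        mat = self._matrix(X)
        curve = wss_curve(mat, range(1, 7), seed=0, n_restarts=5)
        ks = [k for k, _ in curve.points]
        ws = [w for _, w in curve.points]
        assert ks == [1, 2, 3, 4, 5, 6]
        total = ((X - X.mean(axis=0)) ** 2).sum()
        assert ws[0] == pytest.approx(total, rel=1e-9)
        assert curve.elbow == 3
        # WSS at k = n is zero
        full = wss_curve(mat, [30], seed=0, n_restarts=1)
        assert full.points[0][1] == pytest.approx(0.0, abs=1e-12)


class TestThemesAndTrends:
    def test_one_document_cluster_theme_is_its_top_terms(self):
        corpus = Corpus(
            documents=[
                Document(doc_id="a", abstract="milk milk whey", year=2010, sjr=1.0),
                Document(doc_id="b", abstract="liver diet rat", year=2012, sjr=2.0),
            ]
        )
        mat = vectorize_corpus(corpus, ngram_max=1, stopwords=set(), min_df=1)
        res = kmeans(mat, 2, seed=0)
        themes = cluster_themes(mat, res, corpus, top_n=2)
        for t in themes:
            (doc_id,) = res.cluster_members(t.cluster)
            row = mat.weights.toarray()[mat.doc_ids.index(doc_id)]
            best = mat.vocabulary[int(np.argmax(row))]
            assert t.top_terms[0][0] == best
            assert t.size == 1

    def test_theme_metadata_summaries(self):
        corpus = Corpus(
            documents=[
                Document(doc_id=str(i), abstract=f"term{i % 2} filler", year=2000 + i,
                         sjr=float(i))
                for i in range(6)
            ]
        )
        mat = vectorize_corpus(corpus, ngram_max=1, stopwords=set(), min_df=1)
        res = kmeans(mat, 2, seed=0)
        for t in cluster_themes(mat, res, corpus):
            members = res.cluster_members(t.cluster)
            years = sorted(2000 + int(d) for d in members)
            assert t.earliest == years[0] and t.latest == years[-1]
            assert t.median_year == pytest.approx(float(np.median(years)))

    def test_planted_topic_keywords_dominate_themes(self):
        cfg = GeneratorConfig(n_docs=210, seed=2)
        corpus, truth = generate(cfg)
        mat = vectorize_corpus(corpus)
        res = kmeans(mat, 7, seed=2)
        kw = {t.topic_id: set(t.keywords) for t in cfg.topics}
        from collections import Counter

        for t in cluster_themes(mat, res, corpus):
            members = res.cluster_members(t.cluster)
            topic = Counter(truth.topic_of[d] for d in members).most_common(1)[0][0]
            hits = sum(1 for term, _ in t.top_terms if term in kw[topic])
            assert hits >= 8

    def test_year_trend_counts_and_zero_fill(self):
        corpus, truth = generate(GeneratorConfig(n_docs=80, year_range=(2010, 2014), seed=3))
        mat = vectorize_corpus(corpus)
        res = kmeans(mat, 7, seed=0)
        trend = cluster_year_trend(res, corpus)
        assert trend["n_docs"].sum() == 80
        assert len(trend) == 5 * 7  # full year x cluster grid
        # brute-force tally
        for _, row in trend.iterrows():
            expected = sum(
                1
                for d in corpus.documents
                if d.year == row["year"] and res.labels[d.doc_id] == row["cluster"]
            )
            assert row["n_docs"] == expected

    def test_single_year_two_clusters(self):
        corpus = Corpus(
            documents=[
                Document(doc_id=str(i), abstract=f"term{i % 2} filler", year=2020)
                for i in range(6)
            ]
        )
        mat = vectorize_corpus(corpus, ngram_max=1, stopwords=set(), min_df=1)
        res = kmeans(mat, 2, seed=0)
        trend = cluster_year_trend(res, corpus)
        assert list(trend["year"].unique()) == [2020]
        assert trend["n_docs"].sum() == 6


class TestEmbedding:
    def test_one_coordinate_pair_per_document(self):
        corpus, _ = generate(GeneratorConfig(n_docs=40, seed=4))
        mat = vectorize_corpus(corpus)
        coords = embed_2d(mat, seed=0, perplexity=10)
        assert set(coords) == set(mat.doc_ids)
        assert all(len(v) == 2 for v in coords.values())

    def test_duplicate_rows_land_together(self):
        corpus, _ = generate(GeneratorConfig(n_docs=20, seed=5))
        mat = vectorize_corpus(corpus)
        dup = TfidfMatrix(
            doc_ids=mat.doc_ids + ["dup"],
            vocabulary=mat.vocabulary,
            weights=sp.csr_matrix(sp.vstack([mat.weights, mat.weights[0]])),
            idf=mat.idf,
        )
        coords = embed_2d(dup, seed=0, perplexity=5)
        xy = np.array(list(coords.values()))
        span = np.linalg.norm(xy.max(axis=0) - xy.min(axis=0))
        d = np.linalg.norm(np.array(coords["dup"]) - np.array(coords[mat.doc_ids[0]]))
        assert d < 0.01 * span

    def test_within_topic_tighter_than_between(self):
        cfg = GeneratorConfig(n_docs=140, seed=6)
        corpus, truth = generate(cfg)
        mat = vectorize_corpus(corpus)
        coords = embed_2d(mat, seed=0, perplexity=20)
        xy = np.array([coords[d] for d in mat.doc_ids])
        lab = np.array([truth.topic_of[d] for d in mat.doc_ids])
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(xy))
        iu = np.triu_indices(len(lab), 1)
        same = (lab[:, None] == lab[None, :])[iu]
        assert D[iu][same].mean() < D[iu][~same].mean()

    def test_perplexity_must_be_below_n(self):
        corpus, _ = generate(GeneratorConfig(n_docs=10, seed=7))
        mat = vectorize_corpus(corpus)
        with pytest.raises(ValidationError):
            embed_2d(mat, seed=0, perplexity=10)
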