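"""Weighting-model formulas, search behaviour and their oracles.

The oracle below recomputes every model score directly from raw token
lists (its own tf/df/F counting, its own formula transcription with
``math.log(x, 2)``), independent of the index and scorer under test.
"""

import math
from collections import Counter

import numpy as np
import pytest

from datasetir.index import InvertedIndex
from datasetir.ranking import (CORE_MODELS, CollectionStats, ModelParams,
                               WeightedTerm, merge_terms, score_term, search,
                               tfn)

# ---------------------------------------------------------------------------
# independent oracle
# ---------------------------------------------------------------------------


def oracle_scores(corpus, query_weights, model, c=1.0, k1=1.2, b=0.75):
    """Brute-force document scores from raw ``(docno, tokens)`` pairs."""
    N = len(corpus)
    lengths = {d: len(toks) for d, toks in corpus}
    avg = sum(lengths.values()) / N
    df = Counter()
    F = Counter()
    for d, toks in corpus:
        for t in set(toks):
            df[t] += 1
        for t in toks:
            F[t] += 1

    def one(model, tf, dl, nt, tF):
        T = tf * math.log(1 + c * avg / dl, 2)
        if model == "lgd":
            lam = nt / N
            return math.log((lam + T) / lam, 2)
        if model == "inl2":
            return T / (T + 1) * math.log((N + 1) / (nt + 0.5), 2)
        if model == "pl2":
            lamF = tF / N
            if lamF >= 1:
                return T / (T + 1)
            return (1 / (T + 1)) * (T * math.log(T / lamF, 2)
                                    + (lamF - T) * math.log(math.e, 2)
                                    + 0.5 * math.log(2 * math.pi * T, 2))
        if model == "dph":
            f = tf / dl
            if f >= 1:
                return 0.0
            return ((1 - f) ** 2 / (tf + 1)) * (
                tf * math.log((tf * avg / dl) * (N / tF), 2)
                + 0.5 * math.log(2 * math.pi * tf * (1 - f), 2))
        if model == "bm25":
            idf = math.log((N - nt + 0.5) / (nt + 0.5), 2)
            return idf * ((k1 + 1) * tf) / (tf + k1 * (1 - b + b * dl / avg))
        if model == "tfidf":
            return ((k1 + 1) * tf / (tf + k1 * (1 - b + b * dl / avg))) \
                * math.log(1 + N / nt, 2)
        raise ValueError(model)

    scores = {}
    for d, toks in corpus:
        counts = Counter(toks)
        s = 0.0
        matched = False
        for term, qtw in query_weights.items():
            if term in counts:
                matched = True
                s += qtw * one(model, counts[term], lengths[d], df[term], F[term])
        if matched:
            scores[d] = s
    return scores


def random_corpus(seed, n_docs, vocab=("a", "b", "c", "d", "e", "f")):
    rng = np.random.default_rng(seed)
    corpus = []
    for i in range(n_docs):
        n = int(rng.integers(1, 12))
        corpus.append((f"d{i}", [vocab[int(j)] for j in rng.integers(0, len(vocab), n)]))
    return corpus


# ---------------------------------------------------------------------------
# formula spot values
# ---------------------------------------------------------------------------


class TestTfn:
    def test_average_length_doc(self):
        assert tfn(2, 10, 10, 1.0) == pytest.approx(2.0)

    def test_long_doc_hand_value(self):
        assert tfn(1, 20, 10, 1.0) == pytest.approx(math.log2(1.5), abs=1e-9)
        assert tfn(1, 20, 10, 1.0) == pytest.approx(0.58496, abs=1e-5)

    def test_vanishes_as_c_goes_to_zero(self):
        values = [tfn(1, 10, 10, c) for c in (1.0, 0.1, 0.01, 0.001)]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert values[-1] < 0.002

    def test_zero_length_doc_is_domain_error(self):
        with pytest.raises(ValueError):
            tfn(1, 0, 10, 1.0)


def stats(N, avg_dl, df, F, total=None):
    return CollectionStats(N=N, avg_dl=avg_dl,
                           total_tokens=total or int(N * avg_dl), df=df, F=F)


class TestScoreTermSpotValues:
    def test_inl2_printed_value(self):
        s = score_term("inl2", tf=2, dl=10, index_stats=stats(2, 10.0, 1, 2))
        assert s == pytest.approx(2.0 / 3.0, abs=1e-5)
        assert s == pytest.approx(0.66667, abs=1e-5)

    def test_lgd_printed_value(self):
        s = score_term("lgd", tf=2, dl=10, index_stats=stats(2, 10.0, 1, 2))
        assert s == pytest.approx(math.log2(5.0), abs=1e-9)
        assert s == pytest.approx(2.32193, abs=1e-5)

    def test_bm25_zero_idf(self):
        for tf in (1, 2, 5):
            assert score_term("bm25", tf=tf, dl=10,
                              index_stats=stats(2, 10.0, 1, 5)) == pytest.approx(0.0)

    def test_qtw_is_multiplicative(self):
        base = score_term("lgd", 2, 10, stats(4, 10.0, 1, 2), qtw=1.0)
        assert score_term("lgd", 2, 10, stats(4, 10.0, 1, 2), qtw=7.5) == \
            pytest.approx(7.5 * base)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            score_term("nosuch", 1, 1, stats(2, 1.0, 1, 1))

    def test_extended_models_are_config_gated(self):
        with pytest.raises(ValueError, match="allow_extended"):
            score_term("bb2", 1, 10, stats(5, 10.0, 1, 2))
        s = score_term("bb2", 1, 10, stats(5, 10.0, 1, 2),
                       params=ModelParams(allow_extended=True))
        assert math.isfinite(s)

    def test_pl2_falls_back_when_term_saturates_collection(self):
        # F >= N breaks the Poisson rarity assumption
        s = score_term("pl2", tf=2, dl=10, index_stats=stats(2, 10.0, 2, 4))
        assert s == pytest.approx(2.0 / 3.0)

    def test_extended_models_finite_on_toy_stats(self):
        p = ModelParams(allow_extended=True)
        for model in ("bb2", "ifb2", "in_expb2", "in_expc2", "dlh", "dlh13",
                      "dfree", "dfr_bm25"):
            s = score_term(model, tf=2, dl=12, index_stats=stats(20, 10.0, 4, 9),
                           params=p)
            assert math.isfinite(s), model


class TestModelParams:
    @pytest.mark.parametrize("kwargs", [{"c": 0.0}, {"c": -1.0}, {"b": 1.5},
                                        {"k1": 0.0}])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------


class TestSearch:
    @pytest.mark.parametrize("model", CORE_MODELS)
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_oracle_equivalence_on_small_corpora(self, model, seed):
        corpus = random_corpus(seed, n_docs=int(np.random.default_rng(seed).integers(2, 11)))
        idx = InvertedIndex.from_texts((d, " ".join(t)) for d, t in corpus)
        qw = {"a": 100.0, "c": 20.0, "f": 1.0}
        query = [WeightedTerm(t, w) for t, w in qw.items()]
        ranked = search(query, idx, model, cutoff=1000)
        expected = oracle_scores(corpus, qw, model)
        got = dict(ranked.rows)
        assert set(got) == set(expected)
        for d in expected:
            assert got[d] == pytest.approx(expected[d], abs=1e-9)

    @pytest.mark.parametrize("model", ["bm25", "tfidf", "inl2", "lgd"])
    def test_tf_monotonicity(self, model):
        idx = InvertedIndex.from_texts([
            ("low", "x y y y"), ("high", "x x y y"), ("pad", "z z z z"),
            ("pad2", "z y w w"),
        ])
        ranked = search([WeightedTerm("x")], idx, model)
        assert ranked.docnos()[0] == "high"

    def test_absent_term_gives_empty_ranking(self):
        idx = InvertedIndex.from_texts([("d1", "a b")])
        assert search([WeightedTerm("zz")], idx, "lgd").rows == ()

    def test_uniform_weight_scaling_preserves_order(self):
        corpus = random_corpus(9, 8)
        idx = InvertedIndex.from_texts((d, " ".join(t)) for d, t in corpus)
        q1 = [WeightedTerm("a", 1.0), WeightedTerm("b", 2.0)]
        q10 = [WeightedTerm("a", 10.0), WeightedTerm("b", 20.0)]
        r1 = search(q1, idx, "lgd")
        r10 = search(q10, idx, "lgd")
        assert r1.docnos() == r10.docnos()
        for (_, s1), (_, s10) in zip(r1.rows, r10.rows):
            assert s10 == pytest.approx(10 * s1, rel=1e-12)

    def test_ties_break_by_ascending_docno_and_repeat_identically(self):
        idx = InvertedIndex.from_texts([("b", "x"), ("a", "x"), ("c", "x")])
        r1 = search([WeightedTerm("x")], idx, "bm25")  # zero-idf ties... use tfidf
        r2 = search([WeightedTerm("x")], idx, "bm25")
        assert r1 == r2
        r = search([WeightedTerm("x")], idx, "tfidf")
        assert r.docnos() == ["a", "b", "c"]

    def test_cutoff_truncates(self):
        idx = InvertedIndex.from_texts([(f"d{i}", "x") for i in range(30)])
        assert len(search([WeightedTerm("x")], idx, "tfidf", cutoff=5)) == 5

    def test_empty_query_warns_and_returns_empty(self):
        idx = InvertedIndex.from_texts([("d1", "a")])
        assert search([], idx, "lgd").rows == ()

    def test_duplicate_query_terms_sum_weights(self):
        merged = merge_terms([WeightedTerm("a", 2.0), WeightedTerm("a", 3.0)])
        assert len(merged) == 1
        assert merged[0].qtw == 5.0

    def test_scores_nonincreasing(self):
        corpus = random_corpus(21, 10)
        idx = InvertedIndex.from_texts((d, " ".join(t)) for d, t in corpus)
        r = search([WeightedTerm("a"), WeightedTerm("b")], idx, "lgd")
        scores = [s for _, s in r.rows]
        assert scores == sorted(scores, reverse=True)
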