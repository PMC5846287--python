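"""Query cleaning, embedding-neighbour expansion and PRF."""

import math

import numpy as np
import pytest

from datasetir.expansion import (EmbeddingSpace, ExpansionConfig, PRFParams,
                                 bo1_weight, clean_query, cosine,
                                 expand_with_embeddings, format_weighted_query,
                                 load_word2vec_text, parse_weighted_query,
                                 prf_expand, write_word2vec_text)
from datasetir.index import InvertedIndex
from datasetir.ranking import WeightedTerm, search


class TestCleanQuery:
    def test_noise_phrases_then_stopwords(self):
        terms = clean_query("Find data related to diabetes in mice",
                            stoplist={"to", "in"},
                            noise_phrases=["find", "data", "related to"])
        assert terms == ["diabetes", "mice"]

    def test_empty_input(self):
        assert clean_query("") == []

    def test_pure_noise_topic_reduces_to_nothing(self):
        assert clean_query("find all data", stoplist={"all"},
                           noise_phrases=["find", "data"]) == []

    def test_phrase_match_respects_word_boundaries(self):
        # "data" must not eat the substring inside "database"
        terms = clean_query("database of mice", stoplist={"of"},
                            noise_phrases=["data"])
        assert terms == ["database", "mice"]

    def test_default_lists_strip_common_noise(self):
        assert clean_query("Find data related to diabetes in mice") == \
            ["diabetes", "mice"]


class TestCosine:
    def test_identical(self):
        assert cosine([1.0, 2.0], [1.0, 2.0]) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert cosine([1.0, 0.0], [0.0, 3.0]) == pytest.approx(0.0)

    def test_hand_value(self):
        assert cosine([1.0, 0.0], [1.0, 1.0]) == pytest.approx(0.70711, abs=1e-5)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine([0.0, 0.0], [1.0, 0.0])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cosine([1.0], [1.0, 2.0])


def space_from(vectors):
    return EmbeddingSpace({k: np.array(v, float) for k, v in vectors.items()})


class TestEmbeddingSpace:
    def test_neighbors_threshold_and_cap(self):
        sp = space_from({
            "gene": [1.0, 0.0], "near": [0.95, 0.3122499], "far": [0.0, 1.0],
        })
        assert [t for t, _ in sp.neighbors("gene", 0.9, 10)] == ["near"]
        assert sp.neighbors("gene", 0.99, 10) == []
        assert sp.neighbors("absent", 0.5, 10) == []

    def test_zero_vector_dropped_on_load(self):
        sp = space_from({"a": [1.0, 0.0], "z": [0.0, 0.0]})
        assert "z" not in sp

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            EmbeddingSpace({"a": np.ones(3), "b": np.ones(4)})

    def test_word2vec_text_round_trip(self, tmp_path):
        vecs = {"alpha": [0.1, 0.2, 0.3], "beta": [1.0, -1.0, 0.5]}
        path = tmp_path / "v.txt"
        write_word2vec_text(vecs, path)
        sp = load_word2vec_text(path)
        assert len(sp) == 2
        assert sp.dimension == 3
        assert cosine(sp.vector("alpha"), vecs["alpha"]) == pytest.approx(1.0)

    def test_malformed_header_rejected(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("just one line\nalpha 1 2\n")
        with pytest.raises(ValueError):
            load_word2vec_text(p)


class TestExpandWithEmbeddings:
    def pubmed_space(self):
        # controlled similarities to "gene": high=0.92, low=0.85
        def at_cos(c):
            return [c, math.sqrt(1 - c * c)]
        return space_from({"gene": [1.0, 0.0], "high": at_cos(0.92),
                           "low": at_cos(0.85), "unrelated": [0.0, 1.0]})

    def test_threshold_admits_and_excludes(self):
        out = expand_with_embeddings(["gene"], {"pubmed": self.pubmed_space()})
        by_term = {t.term: t for t in out}
        assert by_term["gene"].qtw == 100.0
        assert by_term["gene"].source == "original"
        assert by_term["high"].qtw == 20.0
        assert by_term["high"].source == "pubmed_emb"
        assert "low" not in by_term
        assert "unrelated" not in by_term

    def test_collection_space_weight_is_one(self):
        out = expand_with_embeddings(
            ["gene"], {"collection": self.pubmed_space()},
            ExpansionConfig(thresholds={"collection": 0.8},
                            weights={"original": 100.0, "collection": 1.0}))
        by_term = {t.term: t for t in out}
        assert by_term["high"].qtw == 1.0
        assert by_term["low"].qtw == 1.0   # 0.85 >= the 0.8 threshold

    def test_duplicate_across_spaces_keeps_max_weight(self):
        sp = self.pubmed_space()
        out = expand_with_embeddings(
            ["gene"], {"pubmed": sp, "collection": sp},
            ExpansionConfig(thresholds={"pubmed": 0.9, "collection": 0.8},
                            weights={"original": 100.0, "pubmed": 20.0,
                                     "collection": 1.0}))
        by_term = {t.term: t for t in out}
        assert by_term["high"].qtw == 20.0     # max(20, 1), not 21
        assert by_term["low"].qtw == 1.0       # only the collection space

    def test_thresholds_above_one_are_a_no_op(self):
        out = expand_with_embeddings(
            ["gene"], {"pubmed": self.pubmed_space()},
            ExpansionConfig(thresholds={"pubmed": 1.1},
                            weights={"original": 100.0, "pubmed": 20.0}))
        assert [(t.term, t.qtw) for t in out] == [("gene", 100.0)]

    def test_originals_never_displaced(self):
        sp = space_from({"gene": [1.0, 0.0], "dna": [0.99, 0.1410674]})
        out = expand_with_embeddings(["gene", "dna"], {"pubmed": sp})
        by_term = {t.term: t for t in out}
        assert by_term["dna"].qtw == 100.0
        assert by_term["dna"].source == "original"

    def test_planted_cluster_matches_brute_force_all_pairs(self, fixture_dir):
        import json
        sp = load_word2vec_text(fixture_dir["vectors_pubmed"], "pubmed")
        truth = json.loads(fixture_dir["truth"].read_text())
        clusters = truth["clusters"]["pubmed"]
        terms = [sp._terms[i] for i in range(len(sp))]
        for seed_term, members in clusters.items():
            brute = {t for t in terms
                     if t != seed_term
                     and cosine(sp.vector(seed_term), sp.vector(t)) >= 0.9}
            got = {t for t, _ in sp.neighbors(seed_term, 0.9, 100)}
            assert got == brute
            assert set(members) <= brute

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            expand_with_embeddings([], {})

    def test_output_size_bound(self):
        sp = self.pubmed_space()
        cfg = ExpansionConfig(thresholds={"pubmed": 0.5},
                              weights={"original": 100.0, "pubmed": 20.0},
                              max_neighbors=2)
        out = expand_with_embeddings(["gene"], {"pubmed": sp}, cfg)
        assert len(out) <= 1 * (1 + 2)


class TestPRF:
    def toy_index(self):
        # "shared" dominates the two top documents and co-occurs with "x"
        return InvertedIndex.from_texts([
            ("top1", "x x shared shared shared"),
            ("top2", "x x shared shared extra2"),
            ("mid", "x filler filler"),
            ("other", "y filler noise noise"),
            ("other2", "z noise filler pad pad"),
        ])

    def query(self):
        return [WeightedTerm("x", 100.0, "original")]

    def test_beta_zero_rocchio_is_identity(self):
        idx = self.toy_index()
        first = search(self.query(), idx, "lgd")
        out = prf_expand(self.query(), idx, first, PRFParams(beta=0.0))
        assert out == self.query()
        again = search(out, idx, "lgd")
        assert again == first

    def test_at_most_topdocs_times_terms_new_terms(self):
        idx = self.toy_index()
        first = search(self.query(), idx, "lgd")
        params = PRFParams(top_docs=2, terms_per_doc=2, beta=0.5)
        out = prf_expand(self.query(), idx, first, params)
        new = [t for t in out if t.source == "prf"]
        assert len(new) <= params.top_docs * params.terms_per_doc

    def test_dominant_cooccurring_term_has_max_bo1(self):
        idx = self.toy_index()
        first = search(self.query(), idx, "lgd")
        top2 = [d for d, _ in first.rows[:2]]
        assert top2 == ["top1", "top2"]
        # brute-force Bo1 over the candidate vocabulary of the top docs
        pool = {}
        for d in top2:
            for t, tf in idx.doc_term_freqs([d])[d].items():
                pool[t] = pool.get(t, 0) + tf
        brute = {t: bo1_weight(tf, idx.term_stats(t).F, idx.N)
                 for t, tf in pool.items()}
        best = max(brute, key=brute.get)
        assert best == "shared"
        out = prf_expand(self.query(), idx, first, PRFParams(beta=0.5))
        new = {t.term: t for t in out if t.source == "prf"}
        assert "shared" in new
        # the top-scoring candidate carries the full beta weight
        assert new["shared"].qtw == pytest.approx(0.5)

    def test_originals_always_retained(self):
        idx = self.toy_index()
        first = search(self.query(), idx, "lgd")
        for method in ("rocchio", "bo1"):
            out = prf_expand(self.query(), idx, first,
                             PRFParams(method=method, beta=0.5))
            assert "x" in {t.term for t in out}

    def test_bo1_leaves_original_weights_untouched(self):
        idx = self.toy_index()
        first = search(self.query(), idx, "lgd")
        out = prf_expand(self.query(), idx, first, PRFParams(method="bo1"))
        by_term = {t.term: t for t in out}
        assert by_term["x"].qtw == 100.0

    def test_empty_first_pass_rejected(self):
        idx = self.toy_index()
        from datasetir.ranking import RankedList
        with pytest.raises(ValueError):
            prf_expand(self.query(), idx, RankedList("1", ()), PRFParams())

    @pytest.mark.parametrize("kwargs", [{"method": "nosuch"}, {"top_docs": 0},
                                        {"beta": -0.1}])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PRFParams(**kwargs)


class TestWeightedQueryFormat:
    def test_round_trip(self):
        terms = [WeightedTerm("diabetes", 100.0), WeightedTerm("mouse", 20.0)]
        line = format_weighted_query("7", terms)
        qid, parsed = parse_weighted_query(line)
        assert qid == "7"
        assert [(t.term, t.qtw) for t in parsed] == \
            [("diabetes", 100.0), ("mouse", 20.0)]
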