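"""Retrieval weighting models and search.

Documents are scored against weighted queries with models from the
Divergence-From-Randomness (DFR) family plus Okapi BM25 and TF-IDF.  A
DFR model scores a term by how far its within-document distribution
diverges from a random (non-informative) model, combining a basic
randomness model, an after-effect (first normalization) and a
document-length normalization of the term frequency.  Length
normalization here is "Normalization 2",

    tfn = tf * log2(1 + c * avg_dl / dl),

with hyper-parameter ``c`` (default 1).  All logarithms are base 2.

Query terms carry multiplicative weights (``qtw``), which is how the
original/expanded term weighting scheme (e.g. 100 for original terms, 20
and 1 for embedding neighbours) enters the score: a document's score is
the sum over matching query terms of ``qtw * model(term, doc)``.

The core model set is {LGD, InL2, PL2, DPH, BM25, TFIDF}; an extended
set following the same framework's conventions (BB2, IFB2, In_expB2,
In_expC2, DLH, DLH13, DFRee, DFR_BM25) is available behind
``ModelParams.allow_extended``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .index import InvertedIndex, TermStats

logger = logging.getLogger(__name__)

LOG2_E = math.log2(math.e)
_2PI = 2.0 * math.pi

CORE_MODELS = ("lgd", "inl2", "pl2", "dph", "bm25", "tfidf")
EXTENDED_MODELS = ("bb2", "ifb2", "in_expb2", "in_expc2",
                   "dlh", "dlh13", "dfree", "dfr_bm25")
ALL_MODELS = CORE_MODELS + EXTENDED_MODELS


@dataclass(frozen=True)
class ModelParams:
    """Hyper-parameters shared across the model family.

    ``c``    Normalization-2 constant (c > 0).
    ``k1``   BM25/TFIDF saturation (k1 > 0).
    ``b``    BM25/TFIDF length-normalization slope (0 <= b <= 1).
    """

    c: float = 1.0
    k1: float = 1.2
    b: float = 0.75
    allow_extended: bool = False

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("c must be > 0")
        if not (0 <= self.b <= 1):
            raise ValueError("b must be in [0, 1]")
        if self.k1 <= 0:
            raise ValueError("k1 must be > 0")


@dataclass(frozen=True)
class WeightedTerm:
    """A query term with its multiplicative weight and provenance tag."""

    term: str
    qtw: float = 1.0
    source: str = "original"   # original | pubmed_emb | collection_emb | prf

    def __post_init__(self):
        if self.qtw <= 0:
            raise ValueError(f"qtw must be > 0 (term {self.term!r})")


@dataclass(frozen=True)
class RankedList:
    """Descending-score ranking for one topic; ties break by docno."""

    topic: str
    rows: tuple[tuple[str, float], ...]
    tag: str = "run"

    def docnos(self) -> list[str]:
        return [d for d, _ in self.rows]

    def __len__(self) -> int:
        return len(self.rows)


def merge_terms(terms: Iterable[WeightedTerm]) -> list[WeightedTerm]:
    """Deduplicate query terms, summing the weights of exact duplicates."""
    merged: dict[str, WeightedTerm] = {}
    for wt in terms:
        if wt.term in merged:
            prev = merged[wt.term]
            merged[wt.term] = replace(prev, qtw=prev.qtw + wt.qtw)
        else:
            merged[wt.term] = wt
    return list(merged.values())


# ---------------------------------------------------------------------------
# term scoring
# ---------------------------------------------------------------------------

def tfn(tf: float, dl: float, avg_dl: float, c: float) -> float:
    """Normalization-2 term frequency: ``tf * log2(1 + c*avg_dl/dl)``."""
    if dl <= 0:
        raise ValueError("document length must be positive")
    return tf * math.log2(1.0 + c * avg_dl / dl)


_pl2_warned = False


def _bm25_tf_part(tf: float, dl: float, avg_dl: float, k1: float, b: float) -> float:
    return ((k1 + 1.0) * tf) / (tf + k1 * (1.0 - b + b * dl / avg_dl))


def score_term(model_id: str, tf: int, dl: int, index_stats: "CollectionStats",
               qtw: float = 1.0, params: ModelParams = ModelParams()) -> float:
    """Score a single (term, document) match under ``model_id``.

    ``index_stats`` bundles N, avg_dl, total token count and the term's
    df and F.  The returned value is already multiplied by ``qtw``.
    """
    model = model_id.lower()
    if model not in ALL_MODELS:
        raise ValueError(f"unknown model {model_id!r}")
    if model not in CORE_MODELS and not params.allow_extended:
        raise ValueError(f"model {model_id!r} requires ModelParams(allow_extended=True)")
    if tf < 1:
        raise ValueError("tf must be >= 1")

    N, avg_dl = index_stats.N, index_stats.avg_dl
    df, F = index_stats.df, index_stats.F
    w = _MODELS[model](tf, dl, N, avg_dl, df, F, index_stats.total_tokens, params)
    return qtw * w


def _w_lgd(tf, dl, N, avg_dl, df, F, total, p):
    lam = df / N
    t = tfn(tf, dl, avg_dl, p.c)
    return math.log2((lam + t) / lam)


def _w_inl2(tf, dl, N, avg_dl, df, F, total, p):
    t = tfn(tf, dl, avg_dl, p.c)
    return (t / (t + 1.0)) * math.log2((N + 1.0) / (df + 0.5))


def _w_pl2(tf, dl, N, avg_dl, df, F, total, p):
    global _pl2_warned
    lamF = F / N
    t = tfn(tf, dl, avg_dl, p.c)
    if lamF >= 1.0:
        # Poisson rate >= 1 breaks the model's rare-term assumption;
        # fall back to the after-effect-only branch.
        if not _pl2_warned:
            logger.warning("PL2: collection frequency >= N for some term; "
                           "using tf-only fallback")
            _pl2_warned = True
        return t / (t + 1.0)
    return (1.0 / (t + 1.0)) * (
        t * math.log2(t / lamF)
        + (lamF - t) * LOG2_E
        + 0.5 * math.log2(_2PI * t)
    )


def _w_dph(tf, dl, N, avg_dl, df, F, total, p):
    f = tf / dl
    if f >= 1.0:
        return 0.0
    norm = (1.0 - f) ** 2 / (tf + 1.0)
    return norm * (
        tf * math.log2((tf * avg_dl / dl) * (N / F))
        + 0.5 * math.log2(_2PI * tf * (1.0 - f))
    )


def _w_bm25(tf, dl, N, avg_dl, df, F, total, p):
    idf = math.log2((N - df + 0.5) / (df + 0.5))
    return idf * _bm25_tf_part(tf, dl, avg_dl, p.k1, p.b)


def _w_tfidf(tf, dl, N, avg_dl, df, F, total, p):
    return _bm25_tf_part(tf, dl, avg_dl, p.k1, p.b) * math.log2(1.0 + N / df)


# -- extended set (framework conventions; additive constants may differ
#    between implementations, which never affects the ordering) ------------

def _stirling(n: float, m: float) -> float:
    return (m + 0.5) * math.log2(n / m) + (n - m) * math.log2(n)


def _w_bb2(tf, dl, N, avg_dl, df, F, total, p):
    t = tfn(tf, dl, avg_dl, p.c)
    if N <= 1 or F - t <= 0 or N + F - t - 2 <= 0:
        return 0.0
    norm = (F + 1.0) / (df * (t + 1.0))
    return norm * (
        -math.log2(N - 1.0) - LOG2_E
        + _stirling(N + F - 1.0, N + F - t - 2.0)
        - _stirling(F, F - t)
    )


def _w_ifb2(tf, dl, N, avg_dl, df, F, total, p):
    t = tfn(tf, dl, avg_dl, p.c)
    norm = (F + 1.0) / (df * (t + 1.0))
    return norm * t * math.log2((N + 1.0) / (df + 0.5))


def _n_exp(N: float, F: float) -> float:
    return N * (1.0 - ((N - 1.0) / N) ** F)


def _w_in_expb2(tf, dl, N, avg_dl, df, F, total, p):
    t = tfn(tf, dl, avg_dl, p.c)
    ne = _n_exp(N, F)
    norm = (F + 1.0) / (df * (t + 1.0))
    return norm * t * math.log2((N + 1.0) / (ne + 0.5))


def _w_in_expc2(tf, dl, N, avg_dl, df, F, total, p):
    t = tf * math.log(1.0 + p.c * avg_dl / dl)   # natural-log normalization
    ne = _n_exp(N, F)
    norm = (F + 1.0) / (df * (t + 1.0))
    return norm * t * math.log((N + 1.0) / (ne + 0.5)) * LOG2_E


def _w_dlh(tf, dl, N, avg_dl, df, F, total, p):
    f = tf / dl
    if f >= 1.0:
        return 0.0
    return (
        tf * math.log2((tf * avg_dl / dl) * (N / F))
        + (dl - tf) * math.log2(1.0 - f)
        + 0.5 * math.log2(_2PI * tf * (1.0 - f))
    ) / (tf + 0.5)


def _w_dlh13(tf, dl, N, avg_dl, df, F, total, p):
    f = tf / dl
    if f >= 1.0:
        return 0.0
    return (
        tf * math.log2((tf * avg_dl / dl) * (N / F))
        + 0.5 * math.log2(_2PI * tf * (1.0 - f))
    ) / (tf + 0.5)


def _w_dfree(tf, dl, N, avg_dl, df, F, total, p):
    prior = tf / dl
    posterior = (tf + 1.0) / (dl + 1.0)
    inv_prior_coll = total / F
    norm = tf * math.log2(posterior / prior)
    return norm * (
        tf * (-math.log2(prior * inv_prior_coll))
        + (tf + 1.0) * math.log2(posterior * inv_prior_coll)
        + 0.5 * math.log2(posterior / prior)
    )


def _w_dfr_bm25(tf, dl, N, avg_dl, df, F, total, p):
    t = tfn(tf, dl, avg_dl, p.c)
    return ((p.k1 + 1.0) * t / (p.k1 + t)) * math.log2((N - df + 0.5) / (df + 0.5))


_MODELS = {
    "lgd": _w_lgd, "inl2": _w_inl2, "pl2": _w_pl2, "dph": _w_dph,
    "bm25": _w_bm25, "tfidf": _w_tfidf,
    "bb2": _w_bb2, "ifb2": _w_ifb2, "in_expb2": _w_in_expb2,
    "in_expc2": _w_in_expc2, "dlh": _w_dlh, "dlh13": _w_dlh13,
    "dfree": _w_dfree, "dfr_bm25": _w_dfr_bm25,
}


@dataclass(frozen=True)
class CollectionStats:
    """The statistics bundle a model sees for one term."""

    N: int
    avg_dl: float
    total_tokens: int
    df: int
    F: int


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------

def search(query: Sequence[WeightedTerm], index: InvertedIndex, model_id: str,
           params: ModelParams = ModelParams(), cutoff: int = 1000,
           topic: str = "0", tag: str = "run") -> RankedList:
    """Rank documents for a weighted query.

    Only documents matching at least one query term are scored; a
    document's score is the sum of its per-term scores.  At most
    ``cutoff`` rows are returned, descending by score with ties broken
    by ascending docno (so repeated searches are byte-identical).
    """
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    query = merge_terms(query)
    if not query:
        logger.warning("empty query for topic %s; returning empty ranking", topic)
        return RankedList(topic=topic, rows=(), tag=tag)

    N, avg_dl, total = index.N, index.avg_dl, index.total_tokens
    scores: dict[str, float] = {}
    for wt in query:
        plist = index.postings.get(wt.term)
        if not plist:
            continue
        ts = index.term_stats(wt.term)
        stats = CollectionStats(N=N, avg_dl=avg_dl, total_tokens=total,
                                df=ts.df, F=ts.F)
        for docno, tf in plist:
            s = score_term(model_id, tf, index.doc_length[docno], stats,
                           qtw=wt.qtw, params=params)
            scores[docno] = scores.get(docno, 0.0) + s

    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))[:cutoff]
    return RankedList(topic=topic, rows=tuple(ranked), tag=tag)
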