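"""Query preprocessing and expansion.

Raw topics are natural-language sentences ("Find data related to …");
:func:`clean_query` strips common non-informative phrases, then
stopwords, leaving the informative original terms.

Two expansion stages follow:

1. *Embedding-neighbour expansion.*  For every original term, nearest
   neighbours by cosine similarity are looked up in one or more word
   embedding spaces (word2vec text format).  Each space has its own
   admission threshold (defaults: 0.9 for the large PubMed-trained
   space, 0.8 for the collection-trained space) and its own query-term
   weight (defaults: original 100, PubMed neighbours 20, collection
   neighbours 1): expansion terms must weigh far less than original
   terms or they drift the query.

2. *Pseudo-relevance feedback (PRF).*  After a first retrieval pass,
   candidate terms from the top-ranked documents are scored with the
   Bose-Einstein Bo1 informativeness statistic and folded in either by
   the Rocchio rule (``alpha``/``beta`` mix of normalized original and
   feedback weights) or directly (plain Bo1).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .index import InvertedIndex, tokenize
from .ranking import RankedList, WeightedTerm

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# embedding spaces (word2vec text format)
# ---------------------------------------------------------------------------

class EmbeddingSpace:
    """An in-memory word-embedding vocabulary with cosine neighbourhoods."""

    def __init__(self, vectors: Mapping[str, np.ndarray], source: str = "space",
                 metadata: Mapping[str, object] | None = None):
        dims = {len(v) for v in vectors.values()}
        if len(dims) > 1:
            raise ValueError(f"inconsistent vector dimensions: {sorted(dims)}")
        self.dimension = dims.pop() if dims else 0
        self.source = source
        self.metadata = dict(metadata or {})
        self._terms: list[str] = []
        rows = []
        for term, vec in vectors.items():
            arr = np.asarray(vec, dtype=np.float64)
            norm = float(np.linalg.norm(arr))
            if norm == 0.0:
                logger.warning("%s: dropping zero vector for %r", source, term)
                continue
            self._terms.append(term)
            rows.append(arr / norm)
        self._matrix = np.vstack(rows) if rows else np.zeros((0, self.dimension))
        self._lookup = {t: i for i, t in enumerate(self._terms)}

    def __contains__(self, term: str) -> bool:
        return term in self._lookup

    def __len__(self) -> int:
        return len(self._terms)

    def vector(self, term: str) -> np.ndarray:
        return self._matrix[self._lookup[term]]

    def neighbors(self, term: str, threshold: float, cap: int) -> list[tuple[str, float]]:
        """Terms with cosine >= threshold, best first, at most ``cap``."""
        i = self._lookup.get(term)
        if i is None:
            return []
        sims = self._matrix @ self._matrix[i]
        order = np.argsort(-sims, kind="stable")
        out = []
        for j in order:
            if j == i:
                continue
            if sims[j] < threshold:
                break
            out.append((self._terms[j], float(sims[j])))
            if len(out) >= cap:
                break
        return out


def load_word2vec_text(path: str | Path, source: str = "space") -> EmbeddingSpace:
    """Read the standard word2vec text format (``count dim`` header)."""
    vectors: dict[str, np.ndarray] = {}
    dim = None
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: expected 'count dim' header")
        n_decl, dim = int(header[0]), int(header[1])
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(" ")
            if len(parts) < dim + 1:
                raise ValueError(f"{path}:{lineno}: expected {dim} components")
            vectors[parts[0]] = np.array(parts[1: dim + 1], dtype=np.float64)
    if len(vectors) != n_decl:
        logger.warning("%s: header declared %d terms, read %d", path, n_decl, len(vectors))
    return EmbeddingSpace(vectors, source=source, metadata={"path": str(path), "dims": dim})


def write_word2vec_text(space_vectors: Mapping[str, Sequence[float]],
                        path: str | Path) -> None:
    items = list(space_vectors.items())
    dim = len(items[0][1]) if items else 0
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(items)} {dim}\n")
        for term, vec in items:
            fh.write(term + " " + " ".join(f"{x:.6f}" for x in vec) + "\n")


def cosine(u: Sequence[float], v: Sequence[float]) -> float:
    """Standard cosine similarity; zero vectors are a domain error."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError("dimension mismatch")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine undefined for zero vectors")
    return float(np.dot(u, v) / (nu * nv))


# ---------------------------------------------------------------------------
# topic cleaning
# ---------------------------------------------------------------------------

def _load_list(name: str) -> list[str]:
    text = resources.files("datasetir.data").joinpath(name).read_text("utf-8")
    return [l.strip().lower() for l in text.splitlines()
            if l.strip() and not l.startswith("#")]


def default_stoplist() -> frozenset[str]:
    return frozenset(_load_list("stopwords.txt"))


def default_noise_phrases() -> tuple[str, ...]:
    return tuple(_load_list("noise_phrases.txt"))


def clean_query(raw: str, stoplist: Iterable[str] | None = None,
                noise_phrases: Iterable[str] | None = None) -> list[str]:
    """Strip noise phrases (as phrases, longest first), then stopwords.

    The survivors are lowercased through the index tokenizer so query
    and index vocabularies agree.
    """
    stoplist = frozenset(s.lower() for s in stoplist) if stoplist is not None \
        else default_stoplist()
    phrases = tuple(noise_phrases) if noise_phrases is not None \
        else default_noise_phrases()

    text = raw.lower()
    for phrase in sorted(phrases, key=len, reverse=True):
        text = re.sub(r"\b" + re.escape(phrase.lower()) + r"\b", " ", text)
    terms = [t for t in tokenize(text) if t not in stoplist]
    if not terms and raw.strip():
        logger.warning("query %r reduced to nothing after cleaning", raw)
    return terms


# ---------------------------------------------------------------------------
# embedding expansion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpansionConfig:
    """Thresholds, per-source weights and the per-term neighbour cap."""

    thresholds: Mapping[str, float] = field(
        default_factory=lambda: {"pubmed": 0.9, "collection": 0.8})
    weights: Mapping[str, float] = field(
        default_factory=lambda: {"original": 100.0, "pubmed": 20.0, "collection": 1.0})
    max_neighbors: int = 10

    def __post_init__(self):
        for k, v in self.thresholds.items():
            if not (0.0 < v):
                raise ValueError(f"threshold for {k!r} must be positive")
        for k, v in self.weights.items():
            if v <= 0:
                raise ValueError(f"weight for {k!r} must be > 0")


def expand_with_embeddings(original_terms: Sequence[str],
                           spaces: Mapping[str, EmbeddingSpace],
                           config: ExpansionConfig = ExpansionConfig(),
                           ) -> list[WeightedTerm]:
    """Attach embedding neighbours to the original terms.

    Originals keep their configured weight and are never displaced.  A
    candidate appearing via several spaces (or several originals) keeps
    the maximum weight it earned.  Multi-word candidates are split by the
    tokenizer with each token inheriting the candidate weight.  The
    result is an already-weighted query: it must not be re-tokenized
    downstream or the weights would be lost.
    """
    if not original_terms:
        raise ValueError("cannot expand an empty query")
    w_orig = config.weights.get("original", 100.0)
    originals = set(original_terms)
    out: dict[str, WeightedTerm] = {
        t: WeightedTerm(t, w_orig, "original") for t in original_terms
    }
    for label, space in spaces.items():
        threshold = config.thresholds.get(label)
        weight = config.weights.get(label)
        if threshold is None or weight is None:
            raise ValueError(f"no threshold/weight configured for space {label!r}")
        source = f"{label}_emb"
        for term in original_terms:
            for cand, sim in space.neighbors(term, threshold, config.max_neighbors):
                for token in tokenize(cand.replace("_", " ")):
                    if token in originals:
                        continue   # originals are never displaced
                    prev = out.get(token)
                    if prev is not None and prev.qtw >= weight:
                        continue   # duplicate across sources keeps max weight
                    out[token] = WeightedTerm(token, weight, source)
    return list(out.values())


# ---------------------------------------------------------------------------
# pseudo-relevance feedback
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PRFParams:
    """PRF configuration: Rocchio (``alpha``/``beta``) or plain Bo1."""

    method: str = "rocchio"        # rocchio | bo1
    top_docs: int = 2
    terms_per_doc: int = 2
    alpha: float = 1.0
    beta: float = 0.5
    per_document: bool = True      # select terms_per_doc per document

    def __post_init__(self):
        if self.method not in ("rocchio", "bo1"):
            raise ValueError(f"unknown PRF method {self.method!r}")
        if self.top_docs < 1:
            raise ValueError("top_docs must be >= 1")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


def bo1_weight(tf_x: int, F: int, N: int) -> float:
    """Bo1 informativeness of a candidate term.

    ``tf_x`` is the term's frequency within the pseudo-relevant set and
    ``Pn = F/N`` its mean collection rate:
    ``w = tf_x * log2((1+Pn)/Pn) + log2(1+Pn)``.
    """
    pn = F / N
    return tf_x * math.log2((1.0 + pn) / pn) + math.log2(1.0 + pn)


def prf_expand(query: Sequence[WeightedTerm], index: InvertedIndex,
               first_pass: RankedList, params: PRFParams = PRFParams(),
               ) -> list[WeightedTerm]:
    """Augment a weighted query from the top of a first-pass ranking.

    Candidates are the terms of the ``top_docs`` highest-ranked
    documents; per document (or overall, with ``per_document=False``)
    the ``terms_per_doc`` best candidates by Bo1 weight are selected.

    * ``rocchio``: every term's final weight is
      ``alpha * qtw_orig/max(qtw_orig) + beta * w/max(w)`` (the second
      term only for selected candidates).  With ``beta == 0`` this is a
      no-op: the original query is returned unchanged, since the rescale
      would not alter the ranking.
    * ``bo1``: selected new terms are appended with weight ``w/max(w)``;
      original weights are untouched.
    """
    if not first_pass.rows:
        raise ValueError("first-pass ranking is empty")
    if params.method == "rocchio" and params.beta == 0.0:
        logger.info("rocchio with beta=0 is a no-op; query unchanged")
        return list(query)

    top = [d for d, _ in first_pass.rows[: params.top_docs]]
    doc_vecs = index.doc_term_freqs(top)
    pool: dict[str, int] = {}
    for vec in doc_vecs.values():
        for term, tf in vec.items():
            pool[term] = pool.get(term, 0) + tf

    N = index.N
    weights = {t: bo1_weight(tf_x, index.term_stats(t).F, N)
               for t, tf_x in pool.items()}

    selected: set[str] = set()
    if params.per_document:
        for docno in top:
            cands = sorted(doc_vecs[docno],
                           key=lambda t: (-weights[t], t))[: params.terms_per_doc]
            selected.update(cands)
    else:
        budget = params.top_docs * params.terms_per_doc
        selected.update(sorted(pool, key=lambda t: (-weights[t], t))[:budget])

    if not selected:
        return list(query)
    max_w = max(weights[t] for t in selected)

    orig = {wt.term: wt for wt in query}
    out: list[WeightedTerm] = []
    if params.method == "bo1":
        out.extend(query)
        for term in sorted(selected):
            if term not in orig:
                out.append(WeightedTerm(term, weights[term] / max_w, "prf"))
        return out

    # rocchio
    max_orig = max(wt.qtw for wt in query)
    for wt in query:
        w = params.alpha * wt.qtw / max_orig
        if wt.term in selected:
            w += params.beta * weights[wt.term] / max_w
        out.append(WeightedTerm(wt.term, w, wt.source))
    for term in sorted(selected):
        if term not in orig:
            out.append(WeightedTerm(term, params.beta * weights[term] / max_w, "prf"))
    return out


# ---------------------------------------------------------------------------
# weighted-query exchange format
# ---------------------------------------------------------------------------

def format_weighted_query(qid: str, terms: Sequence[WeightedTerm]) -> str:
    """One line: ``qid term^weight term^weight …``.

    Weights print with ``repr`` (shortest exact form) so a parsed query
    reproduces scores bit for bit.
    """
    return qid + " " + " ".join(f"{t.term}^{t.qtw!r}" for t in terms)


def parse_weighted_query(line: str) -> tuple[str, list[WeightedTerm]]:
    parts = line.split()
    if not parts:
        raise ValueError("empty weighted-query line")
    qid, terms = parts[0], []
    for tok in parts[1:]:
        term, sep, w = tok.partition("^")
        terms.append(WeightedTerm(term, float(w) if sep else 1.0, "original"))
    return qid, terms
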