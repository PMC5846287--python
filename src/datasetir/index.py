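"""Tokenization and the inverted index.

The index keeps exactly the statistics the ranking models consume:
per-term postings with within-document frequencies, document lengths,
the collection size ``N``, the mean document length and per-term
document/collection frequencies.  All three kept categories of a record
are indexed as one flat bag of words.  Stopwords are not removed at
indexing time (query preprocessing handles them), and stemming is off by
default.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

#: tokens longer than this are dropped (junk strings, accession blobs)
DEFAULT_MAX_TOKEN_LEN = 20

_SPLIT = re.compile(r"[^0-9a-z]+")

INDEX_FORMAT_VERSION = 1


def tokenize(text: str, max_token_len: int = DEFAULT_MAX_TOKEN_LEN) -> list[str]:
    """Lowercase and split on any non-alphanumeric character.

    Empty fragments and tokens longer than ``max_token_len`` are dropped,
    so ``"Diabetes, type-2"`` becomes ``["diabetes", "type", "2"]``.
    """
    return [t for t in _SPLIT.split(text.lower()) if t and len(t) <= max_token_len]


def porter_light_stem(token: str) -> str:
    """A small Porter-style suffix stripper, used only when enabled."""
    for suf in ("ational", "izations", "ization", "ations", "ation",
                "ingly", "edly", "ies", "ing", "ed", "es", "s"):
        if token.endswith(suf) and len(token) - len(suf) >= 3:
            if suf == "ies":
                return token[:-3] + "y"
            if suf in ("ational", "ization", "ation"):
                return token[: -len(suf)] + "ate" if suf != "ization" else token[: -len(suf)] + "ize"
            return token[: -len(suf)]
    return token


@dataclass(frozen=True)
class TermStats:
    df: int   # number of documents containing the term
    F: int    # total occurrences across the collection


@dataclass
class InvertedIndex:
    """Postings plus the collection statistics used by ranking models."""

    postings: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    doc_length: dict[str, int] = field(default_factory=dict)

    @property
    def N(self) -> int:
        return len(self.doc_length)

    @property
    def total_tokens(self) -> int:
        return sum(self.doc_length.values())

    @property
    def avg_dl(self) -> float:
        return self.total_tokens / self.N if self.N else 0.0

    def term_stats(self, term: str) -> TermStats:
        plist = self.postings.get(term, [])
        return TermStats(df=len(plist), F=sum(tf for _, tf in plist))

    def __contains__(self, term: str) -> bool:
        return term in self.postings

    @property
    def vocabulary(self) -> list[str]:
        return sorted(self.postings)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_texts(cls, texts: Iterable[tuple[str, str]],
                   max_token_len: int = DEFAULT_MAX_TOKEN_LEN,
                   stem: bool = False) -> "InvertedIndex":
        """Build from ``(docno, text)`` pairs.  Duplicate docnos are fatal."""
        idx = cls()
        for docno, text in texts:
            if docno in idx.doc_length:
                raise ValueError(f"duplicate docno {docno!r}")
            tokens = tokenize(text, max_token_len)
            if stem:
                tokens = [porter_light_stem(t) for t in tokens]
            idx.doc_length[docno] = len(tokens)
            counts: dict[str, int] = {}
            for t in tokens:
                counts[t] = counts.get(t, 0) + 1
            for t in sorted(counts):
                idx.postings.setdefault(t, []).append((docno, counts[t]))
        logger.info("indexed %d documents, %d terms, %d tokens",
                    idx.N, len(idx.postings), idx.total_tokens)
        return idx

    def doc_term_freqs(self, docnos: Iterable[str]) -> dict[str, dict[str, int]]:
        """Forward vectors ``docno -> {term: tf}`` for a small set of docs."""
        wanted = set(docnos)
        out: dict[str, dict[str, int]] = {d: {} for d in wanted}
        for term, plist in self.postings.items():
            for docno, tf in plist:
                if docno in wanted:
                    out[docno][term] = tf
        return out

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "datasetir-index",
            "version": INDEX_FORMAT_VERSION,
            "doc_length": self.doc_length,
            "postings": {t: [[d, tf] for d, tf in pl]
                         for t, pl in sorted(self.postings.items())},
        }
        Path(path).write_text(json.dumps(payload), "utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "InvertedIndex":
        payload = json.loads(Path(path).read_text("utf-8"))
        if payload.get("format") != "datasetir-index":
            raise ValueError(f"{path}: not a datasetir index file")
        if payload.get("version") != INDEX_FORMAT_VERSION:
            raise ValueError(f"{path}: unsupported index version {payload.get('version')}")
        idx = cls(doc_length=dict(payload["doc_length"]))
        idx.postings = {t: [(d, int(tf)) for d, tf in pl]
                        for t, pl in payload["postings"].items()}
        return idx


def build_index(records, decisions: Mapping[str, Mapping[str, bool]] | None = None,
                **kwargs) -> InvertedIndex:
    """Index normalized records, honouring per-category keep flags.

    ``decisions`` maps docno to keep flags as produced by the filter; a
    record with no kept non-empty category is omitted entirely.  With
    ``decisions=None`` every non-empty category is indexed.
    """
    def texts():
        for rec in records:
            flags = decisions.get(rec.docno, {}) if decisions is not None else None
            kept = [rec.category(c) for c in ("title", "keywords", "description")
                    if (flags is None or flags.get(c)) and rec.category(c)]
            if kept:
                yield rec.docno, " ".join(kept)

    return InvertedIndex.from_texts(texts(), **kwargs)
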