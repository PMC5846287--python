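"""Metadata informativeness filtering.

Many dataset records carry category texts that are useless for retrieval
("chr19", bare replicate labels, empty keyword lists).  Before indexing,
each category text of each record is scored against a two-part lexicon:

* ``english_words`` — an ordinary English wordlist (a compact list ships
  with the package; any one-word-per-line file can replace it), and
* ``mesh_words`` — the flat set of words harvested from the MeSH
  (Medical Subject Headings) XML vocabulary files, so that domain tokens
  like ``MIP-2`` or ``CD69`` that no English dictionary knows still count
  as informative.

For a category text with ``X`` whitespace tokens, of which ``Y1`` are
recognized English words and ``Y2`` are MeSH words *not* already counted
as English, the score is ``(Y1 + Y2) / X``; an empty text scores the
sentinel ``-1``.  Title and description are kept when ``score > 0`` and
``X > 2``; keywords when ``score > 0``.  A record whose three categories
all fail is dropped from indexing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from lxml import etree

from .collection import NormalizedRecord

logger = logging.getLogger(__name__)

CATEGORIES = ("title", "keywords", "description")

#: characters stripped from MeSH names and scored text before word-splitting
_STRIP_CHARS = ",()"
_STRIP_TABLE = str.maketrans({c: " " for c in _STRIP_CHARS})


def filter_tokenize(text: str) -> list[str]:
    """Whitespace word-split after stripping ``, ( )``; hyphens survive.

    This deliberately differs from the index tokenizer: the filter must
    see ``MIP-2`` as a single (non-English) word.
    """
    return text.translate(_STRIP_TABLE).lower().split()


# ---------------------------------------------------------------------------
# lexicon
# ---------------------------------------------------------------------------

@dataclass
class TermLexicon:
    """English + MeSH word sets with case-insensitive membership."""

    english_words: frozenset[str]
    mesh_words: frozenset[str]
    source_manifest: tuple[str, ...] = ()

    def is_english(self, word: str) -> bool:
        return word.lower() in self.english_words

    def is_mesh(self, word: str) -> bool:
        return word.lower() in self.mesh_words


# MeSH 2017 file schemas: root tag -> subtree tags harvested for names.
_MESH_HARVEST: dict[str, tuple[str, ...]] = {
    "DescriptorRecordSet": ("DescriptorName", "ConceptList"),
    "PharmacologicalActionSet": ("DescriptorName", "PharmacologicalActionSubstanceList"),
    "QualifierRecordSet": ("QualifierName", "ConceptList"),
    "SupplementalRecordSet": ("SupplementalRecordName", "ConceptList"),
}


def _mesh_words_from_text(name: str) -> list[str]:
    return filter_tokenize(name)


def build_mesh_lexicon(mesh_files: Iterable[str | Path]) -> set[str]:
    """Harvest the flat MeSH word set from vocabulary XML files.

    Per file schema, term strings (descriptor/qualifier/supplemental
    names, concept terms and their synonyms, pharmacological substances)
    are collected from the designated subtrees; ``, ( )`` characters are
    removed, names are whitespace-split and the union is deduplicated.
    Files with an unrecognized root are skipped with a warning.
    """
    words: set[str] = set()
    n_files = 0
    for path in mesh_files:
        path = Path(path)
        try:
            root = etree.parse(str(path)).getroot()
        except (etree.XMLSyntaxError, OSError) as exc:
            logger.warning("skipping MeSH file %s: %s", path, exc)
            continue
        harvest = _MESH_HARVEST.get(root.tag)
        if harvest is None:
            logger.warning("skipping %s: unrecognized MeSH root <%s>", path, root.tag)
            continue
        n_files += 1
        for tag in harvest:
            for subtree in root.iter(tag):
                strings = subtree.iter("String")
                found = False
                for s in strings:
                    if s.text:
                        words.update(_mesh_words_from_text(s.text))
                        found = True
                if not found and subtree.text and subtree.text.strip():
                    words.update(_mesh_words_from_text(subtree.text))
    if not n_files:
        logger.warning("no usable MeSH files; lexicon is empty")
    return words


def load_wordlist(path: str | Path | None = None) -> frozenset[str]:
    """Load a one-word-per-line list (``#`` comment lines ignored)."""
    if path is None:
        text = resources.files("datasetir.data").joinpath(
            "english_words.txt").read_text("utf-8")
        name = "packaged:english_words.txt"
    else:
        text = Path(path).read_text("utf-8")
        name = str(path)
    words = {line.strip().lower() for line in text.splitlines()
             if line.strip() and not line.startswith("#")}
    logger.debug("loaded %d words from %s", len(words), name)
    return frozenset(words)


def save_word_set(words: Iterable[str], path: str | Path) -> None:
    """Write a word set as a sorted one-word-per-line cache file."""
    Path(path).write_text("\n".join(sorted(set(words))) + "\n", "utf-8")


def build_lexicon(mesh_files: Iterable[str | Path] = (),
                  english_wordlist: str | Path | None = None,
                  mesh_cache: str | Path | None = None) -> TermLexicon:
    """Assemble the filter lexicon from MeSH XML and/or cached word files."""
    manifest = []
    if mesh_cache is not None:
        mesh = set(load_wordlist(mesh_cache))
        manifest.append(f"mesh-cache:{mesh_cache}")
    else:
        mesh_files = list(mesh_files)
        mesh = build_mesh_lexicon(mesh_files)
        manifest.extend(f"mesh-xml:{p}" for p in mesh_files)
    english = load_wordlist(english_wordlist)
    manifest.append(f"english:{english_wordlist or 'packaged'}")
    return TermLexicon(english_words=english, mesh_words=frozenset(mesh),
                       source_manifest=tuple(manifest))


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldScore:
    """Informativeness score for one category text.

    ``X`` counts all whitespace tokens, ``Y1`` the recognized English
    words, ``Y2`` the remaining MeSH words; ``score = (Y1+Y2)/X`` or the
    sentinel ``-1`` when the text is empty.
    """

    category: str
    X: int
    Y1: int
    Y2: int
    score: float
    keep: bool


def score_field(text: str, lexicon: TermLexicon, category: str) -> FieldScore:
    """Score one category text and decide whether it is worth indexing."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    tokens = filter_tokenize(text)
    x = len(tokens)
    if x == 0:
        return FieldScore(category, 0, 0, 0, -1.0, False)
    y1 = sum(1 for t in tokens if lexicon.is_english(t))
    y2 = sum(1 for t in tokens if not lexicon.is_english(t) and lexicon.is_mesh(t))
    score = (y1 + y2) / x
    if category == "keywords":
        keep = score > 0
    else:
        keep = score > 0 and x > 2
    return FieldScore(category, x, y1, y2, score, keep)


@dataclass(frozen=True)
class FilterDecision:
    docno: str
    scores: Mapping[str, FieldScore]
    drop: bool

    @property
    def keep_flags(self) -> dict[str, bool]:
        return {c: s.keep for c, s in self.scores.items()}


def filter_record(record: NormalizedRecord, lexicon: TermLexicon) -> FilterDecision:
    """Score all three categories; drop iff none is kept."""
    scores = {c: score_field(record.category(c), lexicon, c) for c in CATEGORIES}
    return FilterDecision(record.docno, scores,
                          drop=not any(s.keep for s in scores.values()))


def filter_collection(records: Iterable[NormalizedRecord],
                      lexicon: TermLexicon) -> dict[str, FilterDecision]:
    """Filter every record; log drop counts per repository."""
    decisions: dict[str, FilterDecision] = {}
    drops_by_repo: dict[str, int] = {}
    for rec in records:
        d = filter_record(rec, lexicon)
        if rec.docno in decisions:
            raise ValueError(f"duplicate docno {rec.docno!r}")
        decisions[rec.docno] = d
        if d.drop:
            drops_by_repo[rec.repository] = drops_by_repo.get(rec.repository, 0) + 1
    for repo, n in sorted(drops_by_repo.items()):
        logger.info("filter: dropped %d records from %s", n, repo)
    return decisions
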