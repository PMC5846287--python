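"""Reading, writing and normalizing dataset-metadata collections.

A collection is a TREC-style XML file with one ``<DOC>`` element per
dataset record.  Each record carries four tags:

``<DOCNO>``
    opaque document identifier,
``<TITLE>``
    free-text title (possibly empty or absent),
``<REPOSITORY>``
    name of the source repository,
``<METADATA>``
    repository-specific metadata as a JSON object.

Because every repository uses its own JSON schema, records are reduced to
three common text categories — *title*, *keywords* and *description* — by
per-repository :class:`CategoryMapping` rules.  A mapping lists, per
category, the metadata keys whose values are concatenated into that
category's text.  Keys are matched as case-insensitive suffixes of the
flattened (dot-joined) JSON key paths, so nested payloads and flat ones
are treated uniformly.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import yaml
from lxml import etree

logger = logging.getLogger(__name__)

_WS = re.compile(r"\s+")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DatasetDocument:
    """One raw dataset record as found in the collection XML."""

    docno: str
    title: str = ""
    repository: str = "unknown"
    metadata: Mapping[str, Any] = field(default_factory=dict)


@dataclass(frozen=True)
class CategoryMapping:
    """Per-repository rules mapping metadata keys into the three categories."""

    repository: str
    title_keys: tuple[str, ...] = ()
    keyword_keys: tuple[str, ...] = ()
    description_keys: tuple[str, ...] = ()


@dataclass(frozen=True)
class NormalizedRecord:
    """A dataset record reduced to the three category texts."""

    docno: str
    repository: str
    title_text: str = ""
    keywords_text: str = ""
    description_text: str = ""

    def category(self, name: str) -> str:
        return {
            "title": self.title_text,
            "keywords": self.keywords_text,
            "description": self.description_text,
        }[name]


@dataclass
class ParseStats:
    """Per-parse bookkeeping: how many records were read, skipped or noisy."""

    n_documents: int = 0
    n_skipped_missing_docno: int = 0
    n_metadata_json_warnings: int = 0


class CollectionParseError(RuntimeError):
    """Fatal, unrecoverable defect in a collection stream."""


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _read_source(source) -> bytes:
    if isinstance(source, bytes):
        return source
    if isinstance(source, str):
        # heuristics: a string without markup naming a file is a path
        if source and "<" not in source and Path(source).is_file():
            return Path(source).read_bytes()
        return source.encode("utf-8")
    if isinstance(source, Path):
        return source.read_bytes()
    data = source.read()
    return data if isinstance(data, bytes) else data.encode("utf-8")


def parse_collection(source, stats: ParseStats | None = None) -> list[DatasetDocument]:
    """Parse a collection stream into :class:`DatasetDocument` records.

    ``source`` may be XML text/bytes, a path, or an open file.  The stream
    holds zero or more ``<DOC>`` elements; a surrounding root element is
    optional (TREC collections traditionally have none).

    Malformed JSON inside ``<METADATA>`` yields an empty metadata tree and
    a counted warning.  A ``<DOC>`` without a ``<DOCNO>`` is skipped and
    counted.  Truncated or non-well-formed XML raises
    :class:`CollectionParseError` naming the approximate byte offset.
    """
    raw = _read_source(source)
    stats = stats if stats is not None else ParseStats()
    wrapped = b"<collection>" + raw + b"</collection>"
    try:
        root = etree.fromstring(wrapped, parser=etree.XMLParser(huge_tree=True))
    except etree.XMLSyntaxError as exc:
        line, col = exc.position
        # offset relative to the original stream, not the synthetic wrapper
        lines = raw.split(b"\n")
        offset = sum(len(l) + 1 for l in lines[: line - 1]) + col
        offset = max(0, offset - len(b"<collection>"))
        raise CollectionParseError(
            f"collection XML is not well-formed near byte offset {offset}: {exc}"
        ) from exc

    docs: list[DatasetDocument] = []
    for el in root.iter("DOC"):
        docno_el = el.find("DOCNO")
        docno = (docno_el.text or "").strip() if docno_el is not None else ""
        if not docno:
            stats.n_skipped_missing_docno += 1
            logger.warning("skipping DOC without DOCNO (record %d)", len(docs) + 1)
            continue
        title_el = el.find("TITLE")
        title = _WS.sub(" ", title_el.text or "").strip() if title_el is not None else ""
        repo_el = el.find("REPOSITORY")
        repository = (repo_el.text or "").strip() if repo_el is not None else "unknown"
        meta_el = el.find("METADATA")
        metadata: Mapping[str, Any] = {}
        meta_text = (meta_el.text or "").strip() if meta_el is not None else ""
        if meta_text:
            try:
                parsed = json.loads(meta_text)
                metadata = parsed if isinstance(parsed, dict) else {"value": parsed}
            except json.JSONDecodeError:
                stats.n_metadata_json_warnings += 1
                logger.warning("invalid METADATA JSON in %s; using empty metadata", docno)
        docs.append(DatasetDocument(docno=docno, title=title,
                                    repository=repository or "unknown",
                                    metadata=metadata))
        stats.n_documents += 1
    return docs


def write_collection(docs: Iterable[DatasetDocument]) -> str:
    """Serialize records back to the collection dialect (UTF-8, escaped)."""
    root = etree.Element("collection")
    for doc in docs:
        el = etree.SubElement(root, "DOC")
        etree.SubElement(el, "DOCNO").text = doc.docno
        etree.SubElement(el, "TITLE").text = doc.title
        etree.SubElement(el, "REPOSITORY").text = doc.repository
        etree.SubElement(el, "METADATA").text = (
            json.dumps(doc.metadata, sort_keys=True) if doc.metadata else ""
        )
    inner = b"\n".join(
        etree.tostring(child, encoding="utf-8", pretty_print=True).rstrip()
        for child in root
    )
    return inner.decode("utf-8") + "\n"


# ---------------------------------------------------------------------------
# category normalization
# ---------------------------------------------------------------------------

def flatten_metadata(tree: Mapping[str, Any] | Sequence | Any,
                     prefix: str = "") -> list[tuple[str, str]]:
    """Flatten a JSON tree to ordered ``(dot.joined.path, value)`` pairs.

    List elements are indexed positionally; scalar values are stringified.
    Order follows document order, so concatenation is reproducible.
    """
    out: list[tuple[str, str]] = []
    if isinstance(tree, Mapping):
        for key, value in tree.items():
            path = f"{prefix}.{key}" if prefix else str(key)
            out.extend(flatten_metadata(value, path))
    elif isinstance(tree, (list, tuple)):
        for i, value in enumerate(tree):
            path = f"{prefix}.{i}" if prefix else str(i)
            out.extend(flatten_metadata(value, path))
    elif tree is None:
        pass
    else:
        text = tree if isinstance(tree, str) else json.dumps(tree)
        if text.strip():
            out.append((prefix, text))
    return out


def _key_matches(path: str, key: str) -> bool:
    """Case-insensitive suffix match of a mapping key against a flat path.

    Mapping keys come from flattened staging-column names, so both the
    dotted path and its dot-stripped form are tried: ``dataItemkeywords``
    matches paths ``dataItem.keywords`` and ``dataItemkeywords`` alike.
    Positional list indices are ignored for matching.
    """
    p = re.sub(r"\.\d+(?=\.|$)", "", path).lower()
    k = key.lower()
    last = p.rsplit(".", 1)[-1]
    if last == k or p == k or p.endswith("." + k):
        return True
    return p.replace(".", "").endswith(k.replace(".", ""))


def _collect(flat: list[tuple[str, str]], keys: Sequence[str]) -> str:
    parts: list[str] = []
    for key in keys:
        for path, value in flat:
            if _key_matches(path, key):
                parts.append(value)
    return _WS.sub(" ", " ".join(parts)).strip()


def normalize(doc: DatasetDocument, mapping: CategoryMapping) -> NormalizedRecord:
    """Reduce one record to its three category texts under ``mapping``.

    The record's own ``<TITLE>`` tag backs the ``title`` key; all other
    keys are resolved against the flattened metadata in mapping order.
    """
    flat = flatten_metadata(doc.metadata)
    if doc.title:
        flat = [("title", doc.title)] + flat

    return NormalizedRecord(
        docno=doc.docno,
        repository=doc.repository,
        title_text=_collect(flat, mapping.title_keys),
        keywords_text=_collect(flat, mapping.keyword_keys),
        description_text=_collect(flat, mapping.description_keys),
    )


_FALLBACK = CategoryMapping("unknown", ("title",), (), ("description",))


def load_mappings(path: str | Path | None = None) -> dict[str, CategoryMapping]:
    """Load category mappings from YAML; defaults ship with the package."""
    if path is None:
        text = resources.files("datasetir.data").joinpath(
            "category_mappings.yaml").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    raw = yaml.safe_load(text) or {}
    out: dict[str, CategoryMapping] = {}
    for repo, cats in raw.items():
        out[repo.lower()] = CategoryMapping(
            repository=repo.lower(),
            title_keys=tuple(cats.get("title") or ()),
            keyword_keys=tuple(cats.get("keywords") or ()),
            description_keys=tuple(cats.get("description") or ()),
        )
    return out


def mapping_for(repository: str,
                mappings: Mapping[str, CategoryMapping]) -> CategoryMapping:
    """Mapping for ``repository``; unknown repositories get the fallback."""
    return mappings.get(repository.lower(), mappings.get("unknown", _FALLBACK))


def normalize_collection(docs: Iterable[DatasetDocument],
                         mappings: Mapping[str, CategoryMapping] | None = None,
                         ) -> list[NormalizedRecord]:
    mappings = mappings if mappings is not None else load_mappings()
    return [normalize(d, mapping_for(d.repository, mappings)) for d in docs]


# ---------------------------------------------------------------------------
# indexable-corpus output
# ---------------------------------------------------------------------------

def write_indexable_corpus(records: Iterable[NormalizedRecord],
                           decisions: Mapping[str, Mapping[str, bool]]) -> str:
    """Emit the filtered corpus as TREC DOC/DOCNO/TEXT XML.

    ``decisions`` maps docno to per-category keep flags (the filter
    module's output).  A record with no kept category is omitted; kept
    category texts are concatenated in title/keywords/description order.
    """
    root = etree.Element("collection")
    n_out = 0
    for rec in records:
        flags = decisions.get(rec.docno, {})
        kept = [rec.category(c) for c in ("title", "keywords", "description")
                if flags.get(c) and rec.category(c)]
        if not kept:
            continue
        el = etree.SubElement(root, "DOC")
        etree.SubElement(el, "DOCNO").text = rec.docno
        etree.SubElement(el, "TEXT").text = " ".join(kept)
        n_out += 1
    logger.info("indexable corpus: %d documents emitted", n_out)
    if not n_out:
        return "\n"
    inner = b"\n".join(
        etree.tostring(child, encoding="utf-8", pretty_print=True).rstrip()
        for child in root
    )
    return inner.decode("utf-8") + "\n"
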