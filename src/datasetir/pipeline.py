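"""End-to-end orchestration of one retrieval run.

Stage order: lexicon build -> parse -> normalize -> filter -> index ->
query cleaning -> embedding expansion -> first-pass retrieval -> PRF ->
second-pass retrieval -> evaluation.  A run is fully described by a
:class:`RunConfig`; rerunning the same config reproduces the run file
byte for byte, and a provenance record (SHA-256 of every input and
output, plus the effective config) is written next to the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .collection import ParseStats, load_mappings, normalize_collection, parse_collection
from .evaluation import EvalReport, SampledQrels, evaluate_run, parse_qrels, write_run
from .expansion import (ExpansionConfig, PRFParams, clean_query,
                        expand_with_embeddings, format_weighted_query,
                        load_word2vec_text, prf_expand)
from .filtering import build_lexicon, filter_collection
from .index import build_index
from .ranking import ModelParams, RankedList, WeightedTerm, search

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    collection: str
    topics: str
    outdir: str
    mesh_dir: str | None = None
    mesh_cache: str | None = None
    english_wordlist: str | None = None
    mappings: str | None = None
    vectors: dict[str, str] = field(default_factory=dict)   # label -> path
    qrels: str | None = None
    qrels_rates: str | None = None        # JSON {topic: p}
    model_id: str = "lgd"
    model: ModelParams = field(default_factory=ModelParams)
    expansion: ExpansionConfig = field(default_factory=ExpansionConfig)
    prf: PRFParams | None = field(default_factory=PRFParams)
    cutoff: int = 1000
    tag: str = "datasetir"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text("utf-8")) or {}
        for key, typ in (("model", ModelParams), ("expansion", ExpansionConfig)):
            if isinstance(raw.get(key), dict):
                raw[key] = typ(**raw[key])
        if isinstance(raw.get("prf"), dict):
            raw["prf"] = PRFParams(**raw["prf"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def read_topics(path: str | Path) -> list[tuple[str, str]]:
    """Topics file: one ``qid<TAB>text`` (or ``qid text``) line each."""
    out = []
    for line in Path(path).read_text("utf-8").splitlines():
        if not line.strip():
            continue
        if "\t" in line:
            qid, text = line.split("\t", 1)
        else:
            qid, _, text = line.partition(" ")
        out.append((qid.strip(), text.strip()))
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; return paths, the report and provenance."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, str] = {}

    def track(label: str, path) -> Path:
        p = Path(path)
        inputs[label] = _sha256(p)
        return p

    # 1. lexicon
    mesh_files: list[Path] = []
    if config.mesh_dir:
        mesh_files = sorted(Path(config.mesh_dir).glob("*.xml"))
        for p in mesh_files:
            track(f"mesh:{p.name}", p)
    if config.mesh_cache:
        track("mesh_cache", config.mesh_cache)
    if config.english_wordlist:
        track("english_wordlist", config.english_wordlist)
    lexicon = build_lexicon(mesh_files, config.english_wordlist, config.mesh_cache)

    # 2-3. parse + normalize
    stats = ParseStats()
    docs = parse_collection(track("collection", config.collection), stats=stats)
    mappings = load_mappings(config.mappings)
    if config.mappings:
        track("mappings", config.mappings)
    records = normalize_collection(docs, mappings)
    logger.info("parsed %d documents (%d skipped, %d metadata warnings)",
                stats.n_documents, stats.n_skipped_missing_docno,
                stats.n_metadata_json_warnings)

    # 4-5. filter + index
    decisions = filter_collection(records, lexicon)
    keep_flags = {d: dec.keep_flags for d, dec in decisions.items()}
    n_dropped = sum(1 for dec in decisions.values() if dec.drop)
    index = build_index(records, keep_flags)
    logger.info("filter dropped %d of %d records; indexed %d",
                n_dropped, len(records), index.N)

    # 6. embedding spaces
    spaces = {}
    for label, path in sorted(config.vectors.items()):
        spaces[label] = load_word2vec_text(track(f"vectors:{label}", path),
                                           source=label)

    # 7. topics -> queries -> rankings
    topics = read_topics(track("topics", config.topics))
    rankings: list[RankedList] = []
    query_lines: list[str] = []
    for qid, raw in topics:
        terms = clean_query(raw)
        if not terms:
            rankings.append(RankedList(topic=qid, rows=(), tag=config.tag))
            continue
        if spaces:
            query = expand_with_embeddings(terms, spaces, config.expansion)
        else:
            w = config.expansion.weights.get("original", 100.0)
            query = [WeightedTerm(t, w, "original") for t in terms]
        first = search(query, index, config.model_id, config.model,
                       config.cutoff, topic=qid, tag=config.tag)
        if config.prf is not None and first.rows:
            query = prf_expand(query, index, first, config.prf)
            final = search(query, index, config.model_id, config.model,
                           config.cutoff, topic=qid, tag=config.tag)
        else:
            final = first
        query_lines.append(format_weighted_query(qid, query))
        rankings.append(final)

    run_path = outdir / "run.txt"
    write_run(rankings, run_path)
    (outdir / "queries.txt").write_text("\n".join(query_lines) + "\n", "utf-8")

    # 8. evaluation
    report: EvalReport | None = None
    report_path = None
    if config.qrels:
        qrels = parse_qrels(str(track("qrels", config.qrels)))
        if config.qrels_rates:
            rates = json.loads(Path(track("qrels_rates", config.qrels_rates))
                               .read_text("utf-8"))
            for topic, p in rates.items():
                qrels.set_rate(topic, float(p))
        report = evaluate_run(rankings, qrels)
        report_path = outdir / "report.tsv"
        report_path.write_text(report.to_tsv(), "utf-8")

    # 9. provenance + effective config
    config_path = outdir / "config.yaml"
    config_path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True), "utf-8")
    outputs = {"run.txt": _sha256(run_path)}
    if report_path is not None:
        outputs["report.tsv"] = _sha256(report_path)
    provenance = {
        "inputs": inputs,
        "outputs": outputs,
        "counts": {
            "documents_parsed": stats.n_documents,
            "records_skipped": stats.n_skipped_missing_docno,
            "metadata_warnings": stats.n_metadata_json_warnings,
            "records_dropped_by_filter": n_dropped,
            "documents_indexed": index.N,
            "topics": len(topics),
        },
    }
    (outdir / "provenance.json").write_text(
        json.dumps(provenance, indent=1, sort_keys=True), "utf-8")

    return {"run_path": run_path, "report": report, "report_path": report_path,
            "provenance": provenance, "rankings": rankings}


# ---------------------------------------------------------------------------
# run comparison
# ---------------------------------------------------------------------------

def compare_runs(reports: Mapping[str, EvalReport]) -> pd.DataFrame:
    """Model x measure grid of mean values over a common topic set.

    Raises when the reports cover different topics, listing the
    symmetric difference.
    """
    if len(reports) < 1:
        raise ValueError("no reports to compare")
    topic_sets = {label: set(r.per_topic) for label, r in reports.items()}
    reference = next(iter(topic_sets.values()))
    for label, ts in topic_sets.items():
        if ts != reference:
            diff = sorted(ts ^ reference)
            raise ValueError(f"topic mismatch for {label!r}: {diff}")
    rows = {label: r.means for label, r in reports.items()}
    return pd.DataFrame.from_dict(rows, orient="index")


def format_comparison(table: pd.DataFrame) -> str:
    """Render the grid with the per-column maxima flagged by ``*``."""
    out = table.copy().astype(object)
    for col in table.columns:
        best = table[col].max()
        out[col] = [f"{v:.4f}*" if v == best else f"{v:.4f}"
                    for v in table[col]]
    return out.to_string()
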