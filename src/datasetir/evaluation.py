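"""Retrieval evaluation over graded, possibly sampled judgments.

Judgments (qrels) are graded ``{0, 1, 2}`` (non-relevant, partially
relevant, relevant) with the extra class ``-1`` for documents that were
pooled but never judged.  When only a random sample of the pool was
judged, each judged document belongs to a stratum with a known sampling
rate ``p``; the *inferred* measures infAP and infNDCG estimate the exact
AP and NDCG by inverse-probability weighting of the sampled judgments.

Exact measures:

* ``precision_at_k`` — P@k, counting grades {1,2} as relevant
  (``+partial``) or only grade 2 (``-partial``); unjudged ranks count
  against the denominator.
* ``ndcg_at_k`` — linear gain (= grade) with ``log2(rank+1)`` discount;
  ideal DCG from the topic's judged grades sorted descending.
* ``average_precision`` — classic AP with binary relevance (grade >= 1).

Inferred measures follow the sampled-pool estimator family: the expected
precision above a relevant rank is reconstructed from the judged sample
(with Lidstone smoothing ``eps`` when ``p < 1``), and DCG/ideal-DCG are
scaled by ``1/p`` per stratum.  At ``p = 1`` with no ``-1`` entries both
collapse exactly to their exact counterparts.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .ranking import RankedList

logger = logging.getLogger(__name__)

VALID_GRADES = (-1, 0, 1, 2)
DEFAULT_EPS = 1e-5

MEASURES = ("infAP", "infNDCG", "NDCG@10", "P@10(+partial)", "P@10(-partial)")


@dataclass
class SampledQrels:
    """Graded judgments with optional per-(topic, stratum) sampling rates.

    ``judgments[(topic, docno)] = (grade, stratum)``; stratum 0 with rate
    1.0 is the fully-judged default.  Grade ``-1`` marks pooled-but-
    unjudged documents: they belong to the pool but to no sample.
    """

    judgments: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)
    rates: dict[tuple[str, int], float] = field(default_factory=dict)

    def add(self, topic: str, docno: str, grade: int, stratum: int = 0) -> None:
        if grade not in VALID_GRADES:
            raise ValueError(f"invalid grade {grade} for ({topic}, {docno})")
        key = (topic, docno)
        if key in self.judgments:
            raise ValueError(f"duplicate judgment for ({topic}, {docno})")
        self.judgments[key] = (grade, stratum)

    def set_rate(self, topic: str, p: float, stratum: int = 0) -> None:
        if not (0.0 < p <= 1.0):
            raise ValueError("sampling rate must be in (0, 1]")
        self.rates[(topic, stratum)] = p

    def rate(self, topic: str, stratum: int) -> float:
        return self.rates.get((topic, stratum), 1.0)

    def topics(self) -> list[str]:
        return sorted({t for t, _ in self.judgments})

    def grade(self, topic: str, docno: str) -> int | None:
        """Judged grade, ``-1`` for pooled-unjudged, None if unpooled."""
        entry = self.judgments.get((topic, docno))
        return entry[0] if entry is not None else None

    def stratum(self, topic: str, docno: str) -> int | None:
        entry = self.judgments.get((topic, docno))
        return entry[1] if entry is not None else None

    def topic_entries(self, topic: str) -> list[tuple[str, int, int]]:
        return [(d, g, s) for (t, d), (g, s) in self.judgments.items() if t == topic]


# ---------------------------------------------------------------------------
# TREC-format I/O
# ---------------------------------------------------------------------------

def parse_qrels(source) -> SampledQrels:
    """Parse 4-column qrels ``topic iter docno grade`` (optional 5th
    column ``stratum``).  Malformed lines raise with their line number."""
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text("utf-8")
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    qrels = SampledQrels()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) not in (4, 5):
            raise ValueError(f"qrels line {lineno}: expected 4 or 5 columns")
        topic, _, docno = parts[0], parts[1], parts[2]
        try:
            grade = int(parts[3])
            stratum = int(parts[4]) if len(parts) == 5 else 0
        except ValueError as exc:
            raise ValueError(f"qrels line {lineno}: non-integer field") from exc
        if grade not in VALID_GRADES:
            raise ValueError(f"qrels line {lineno}: invalid grade {grade}")
        try:
            qrels.add(topic, docno, grade, stratum)
        except ValueError as exc:
            raise ValueError(f"qrels line {lineno}: {exc}") from exc
    return qrels


def write_qrels(qrels: SampledQrels) -> str:
    lines = []
    for (topic, docno), (grade, stratum) in sorted(qrels.judgments.items()):
        cols = [topic, "0", docno, str(grade)]
        if stratum != 0:
            cols.append(str(stratum))
        lines.append(" ".join(cols))
    return "\n".join(lines) + "\n"


def write_run(rankings: Iterable[RankedList], dest=None) -> str:
    """Serialize rankings in the 6-column TREC run format.

    ``qid Q0 docno rank score tag`` with the score printed to 6 decimal
    places.  Returns the text; also writes it to ``dest`` if given.
    """
    buf = io.StringIO()
    for rl in rankings:
        for rank, (docno, score) in enumerate(rl.rows, start=1):
            buf.write(f"{rl.topic} Q0 {docno} {rank} {score:.6f} {rl.tag}\n")
    text = buf.getvalue()
    if dest is not None:
        Path(dest).write_text(text, "utf-8")
    return text


def parse_run(source) -> list[RankedList]:
    """Parse a TREC run file back into per-topic rankings."""
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text("utf-8")
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    by_topic: dict[str, list[tuple[int, str, float, str]]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6:
            raise ValueError(f"run line {lineno}: expected 6 columns")
        topic, _, docno, rank, score, tag = parts
        by_topic.setdefault(topic, []).append((int(rank), docno, float(score), tag))
    out = []
    for topic in sorted(by_topic, key=lambda t: (len(t), t)):
        rows = sorted(by_topic[topic])
        tag = rows[0][3] if rows else "run"
        out.append(RankedList(topic=topic,
                              rows=tuple((d, s) for _, d, s, _ in rows), tag=tag))
    return out


# ---------------------------------------------------------------------------
# exact measures
# ---------------------------------------------------------------------------

def precision_at_k(ranked: RankedList, qrels: SampledQrels, k: int = 10,
                   partial: bool = True) -> float:
    """P@k; ``partial=True`` counts grades {1,2}, else only grade 2.

    Unjudged and pooled-unjudged ranks count as non-relevant; the
    denominator is ``k`` even when fewer documents were retrieved.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    hits = 0
    for docno, _ in ranked.rows[:k]:
        g = qrels.grade(ranked.topic, docno)
        if g is not None and (g >= 1 if partial else g == 2):
            hits += 1
    return hits / k


def _dcg(grades: Sequence[float], k: int | None = None) -> float:
    if k is not None:
        grades = grades[:k]
    return sum(g / math.log2(i + 2) for i, g in enumerate(grades))


def ndcg_at_k(ranked: RankedList, qrels: SampledQrels, k: int = 10) -> float | None:
    """NDCG@k with linear gain; None when the topic has no relevant doc."""
    entries = qrels.topic_entries(ranked.topic)
    ideal = sorted((g for _, g, _ in entries if g > 0), reverse=True)
    if not ideal:
        logger.warning("topic %s has no relevant documents; excluded", ranked.topic)
        return None
    gains = [max(qrels.grade(ranked.topic, d) or 0, 0) for d, _ in ranked.rows]
    return _dcg(gains, k) / _dcg(ideal, k)


def average_precision(ranked: RankedList, qrels: SampledQrels) -> float | None:
    """Classic AP (binary relevance: grade >= 1); None without relevant."""
    entries = qrels.topic_entries(ranked.topic)
    n_rel = sum(1 for _, g, _ in entries if g >= 1)
    if n_rel == 0:
        return None
    hits = 0
    total = 0.0
    for rank, (docno, _) in enumerate(ranked.rows, start=1):
        g = qrels.grade(ranked.topic, docno)
        if g is not None and g >= 1:
            hits += 1
            total += hits / rank
    return total / n_rel


# ---------------------------------------------------------------------------
# inferred measures
# ---------------------------------------------------------------------------

def inf_ap(ranked: RankedList, qrels: SampledQrels,
           eps: float = DEFAULT_EPS) -> float | None:
    """Inferred average precision over a sampled judgment pool.

    For each retrieved sampled-relevant document at rank ``k`` the
    expected precision is

        1/k + ((k-1)/k) * (d/(k-1)) * (r^ + eps) / (r^ + n^ + 2*eps)

    where ``d`` counts pooled documents above rank ``k`` and ``r^``,
    ``n^`` are the judged relevant/non-relevant counts above, scaled by
    ``1/p`` of their stratum.  The estimates are averaged with weight
    ``1/p`` and divided by the estimated number of relevant documents,
    so unretrieved relevant documents dilute the mean exactly as in AP.
    With every rate at 1 the unsmoothed ratio is used and the value
    equals classic AP.
    """
    topic = ranked.topic
    entries = qrels.topic_entries(topic)
    rel_total = sum(1.0 / qrels.rate(topic, s) for _, g, s in entries if g >= 1)
    if rel_total == 0:
        logger.warning("topic %s has no sampled relevant documents; excluded", topic)
        return None
    fully_judged = all(qrels.rate(topic, s) == 1.0 for _, _, s in entries)

    total = 0.0
    d_above = 0            # pooled docs above current rank
    rn_above: dict[int, list[float]] = {}   # stratum -> [rel, nonrel]
    for rank, (docno, _) in enumerate(ranked.rows, start=1):
        g = qrels.grade(topic, docno)
        s = qrels.stratum(topic, docno)
        if g is not None and g >= 1:
            p = qrels.rate(topic, s)
            if rank == 1:
                e_p = 1.0
            else:
                r_hat = sum(c[0] / qrels.rate(topic, st) for st, c in rn_above.items())
                n_hat = sum(c[1] / qrels.rate(topic, st) for st, c in rn_above.items())
                if fully_judged:
                    ratio = r_hat / (r_hat + n_hat) if (r_hat + n_hat) > 0 else 0.0
                else:
                    ratio = (r_hat + eps) / (r_hat + n_hat + 2.0 * eps)
                e_p = 1.0 / rank + (d_above / rank) * ratio
            total += e_p / p
        # update the above-rank tallies for the next positions
        if g is not None:
            d_above += 1
            if g >= 0:
                counts = rn_above.setdefault(s, [0.0, 0.0])
                counts[0 if g >= 1 else 1] += 1.0
    return total / rel_total


def inf_ndcg(ranked: RankedList, qrels: SampledQrels,
             k: int | None = None) -> float | None:
    """Inferred NDCG: 1/p-weighted DCG over an inverse-probability ideal.

    The ideal gain multiset estimates, per grade, how many relevant
    documents the full pool holds (observed count / p, rounded, never
    below the observed count).  The ratio is capped at 1.
    """
    topic = ranked.topic
    entries = qrels.topic_entries(topic)
    if not any(g >= 1 for _, g, _ in entries):
        logger.warning("topic %s has no sampled relevant documents; excluded", topic)
        return None

    dcg = 0.0
    for rank, (docno, _) in enumerate(ranked.rows, start=1):
        if k is not None and rank > k:
            break
        g = qrels.grade(topic, docno)
        if g is not None and g >= 1:
            s = qrels.stratum(topic, docno)
            dcg += (g / qrels.rate(topic, s)) / math.log2(rank + 1)

    # inverse-probability estimate of the relevant-grade multiset
    grade_counts: dict[int, dict[int, int]] = {}
    for _, g, s in entries:
        if g >= 1:
            grade_counts.setdefault(g, {})
            grade_counts[g][s] = grade_counts[g].get(s, 0) + 1
    ideal_gains: list[int] = []
    for g, by_stratum in grade_counts.items():
        observed = sum(by_stratum.values())
        estimated = sum(c / qrels.rate(topic, s) for s, c in by_stratum.items())
        ideal_gains.extend([g] * max(int(round(estimated)), observed))
    ideal_gains.sort(reverse=True)
    idcg = _dcg(ideal_gains, k)
    if idcg == 0.0:
        return None
    return min(dcg / idcg, 1.0)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Per-topic measure values and their arithmetic means.

    Topics without any sampled relevant document are excluded from the
    means (and listed in ``excluded_topics``).
    """

    per_topic: dict[str, dict[str, float]]
    means: dict[str, float]
    excluded_topics: tuple[str, ...] = ()

    def to_tsv(self) -> str:
        cols = list(self.means)
        lines = ["topic\t" + "\t".join(cols)]
        for topic in sorted(self.per_topic, key=lambda t: (len(t), t)):
            row = self.per_topic[topic]
            lines.append(topic + "\t" + "\t".join(f"{row[c]:.4f}" for c in cols))
        lines.append("mean\t" + "\t".join(f"{self.means[c]:.4f}" for c in cols))
        return "\n".join(lines) + "\n"


def evaluate_run(rankings: Sequence[RankedList], qrels: SampledQrels,
                 k: int = 10, eps: float = DEFAULT_EPS) -> EvalReport:
    """Score every topic with the five reported measures and average."""
    per_topic: dict[str, dict[str, float]] = {}
    excluded: list[str] = []
    for rl in rankings:
        iap = inf_ap(rl, qrels, eps=eps)
        indcg = inf_ndcg(rl, qrels)
        ndcg = ndcg_at_k(rl, qrels, k=k)
        if iap is None or indcg is None or ndcg is None:
            excluded.append(rl.topic)
            continue
        per_topic[rl.topic] = {
            "infAP": iap,
            "infNDCG": indcg,
            f"NDCG@{k}": ndcg,
            f"P@{k}(+partial)": precision_at_k(rl, qrels, k, partial=True),
            f"P@{k}(-partial)": precision_at_k(rl, qrels, k, partial=False),
        }
    if excluded:
        logger.info("excluded topics without relevant documents: %s",
                    ", ".join(excluded))
    if not per_topic:
        return EvalReport({}, {}, tuple(excluded))
    cols = next(iter(per_topic.values())).keys()
    means = {c: sum(r[c] for r in per_topic.values()) / len(per_topic) for c in cols}
    return EvalReport(per_topic, means, tuple(excluded))
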