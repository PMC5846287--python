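"""Seeded synthetic fixtures with known ground truth.

Every stage of the pipeline is testable offline: this module generates
toy collections in the challenge XML dialect (including a declared
fraction of degenerate, uninformative records), miniature MeSH
vocabulary files, embedding spaces with planted neighbour clusters,
natural-language topics, and graded qrels together with p-subsampled
variants for the inferred-measure estimators.

Everything is driven by a :class:`FixtureSpec` and a single seed; a
repeated seed reproduces every artifact byte for byte.  Truth tables
(which records the filter must drop, which documents are relevant to
which topic) accompany the data so tests never re-derive expectations
from the code under test.

The fixtures emulate the *shape* of real dataset metadata — repository
mixes, missing fields, domain tokens no dictionary knows — not its
statistical texture; they pin contracts, not retrieval quality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .collection import (DatasetDocument, load_mappings, mapping_for,
                         write_collection)
from .evaluation import SampledQrels
from .expansion import write_word2vec_text
from .filtering import load_wordlist
from .ranking import RankedList

#: degenerate-record templates: verbatim real-world shapes of useless
#: metadata (bare chromosome labels, taxon names, replicate identifiers)
DEGENERATE_TEMPLATES: tuple[tuple[str, str, str], ...] = (
    ("chr19", "", ""),
    ("Chr8", "", ""),
    ("Sobemovirus", "", ""),
    ("Alphaflexiviridae", "", ""),
    ("A375R_RPL10a_vivo__Ronly_vem10d_rep2", "", "melanoma"),
    ("A375_vitro_vehicle_rep3", "", "melanoma"),
)

_DEFAULT_MIX = {
    "clinicaltrials": 0.24, "bioproject": 0.20, "pdb": 0.14, "geo": 0.13,
    "dryad": 0.09, "arrayexpress": 0.08, "dataverse": 0.07, "neuromorpho": 0.05,
}


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs of the synthetic world; the seed determines everything."""

    seed: int = 0
    n_docs: int = 200
    repo_mix: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_MIX))
    degenerate_fraction: float = 0.1
    n_topics: int = 5
    embedding_dim: int = 100
    cluster_size: int = 4
    cluster_noise: float = 0.2
    n_domain_tokens: int = 60
    qrels_p: float = 0.5

    def __post_init__(self):
        total = sum(self.repo_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"repository mix must sum to 1 (got {total})")
        if not (0.0 <= self.degenerate_fraction < 1.0):
            raise ValueError("degenerate_fraction must be in [0, 1)")
        if self.embedding_dim < 2 * self.n_topics + 2:
            raise ValueError("embedding_dim too small for the planted clusters")


def _rng(spec: FixtureSpec, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, salt]))


def _english_vocab() -> list[str]:
    return sorted(w for w in load_wordlist() if len(w) >= 3 and w.isalpha())


def make_domain_tokens(spec: FixtureSpec) -> list[str]:
    """Synthetic domain tokens (gene/protein-symbol shaped, non-English)."""
    rng = _rng(spec, 1)
    letters = "bcdfgjklmnpqrstvwz"
    tokens: set[str] = set()
    while len(tokens) < spec.n_domain_tokens:
        stem = "".join(rng.choice(list(letters), size=int(rng.integers(2, 5))))
        tok = f"{stem}-{int(rng.integers(1, 100))}"
        tokens.add(tok)
    return sorted(tokens)


# ---------------------------------------------------------------------------
# MeSH vocabulary fixtures
# ---------------------------------------------------------------------------

def make_mesh_files(terms: Sequence[str]) -> dict[str, str]:
    """Tiny MeSH-schema XML files spreading ``terms`` across the four
    vocabulary file types (synthetic stand-ins for the real files)."""
    quarters = [list(terms[i::4]) for i in range(4)]

    def strings(ts):
        return "".join(f"<Term><String>{t}</String></Term>" for t in ts)

    desc = "<DescriptorRecordSet>" + "".join(
        f"<DescriptorRecord><DescriptorName><String>{t}</String></DescriptorName>"
        f"<ConceptList><Concept><ConceptName><String>{t}</String></ConceptName>"
        f"<TermList>{strings([t])}</TermList></Concept></ConceptList>"
        f"</DescriptorRecord>" for t in quarters[0]) + "</DescriptorRecordSet>"
    pa = "<PharmacologicalActionSet>" + "".join(
        f"<PharmacologicalAction><DescriptorReferredTo><DescriptorName>"
        f"<String>{t}</String></DescriptorName></DescriptorReferredTo>"
        f"<PharmacologicalActionSubstanceList><Substance><RecordName>"
        f"<String>{t}</String></RecordName></Substance>"
        f"</PharmacologicalActionSubstanceList></PharmacologicalAction>"
        for t in quarters[1]) + "</PharmacologicalActionSet>"
    qual = "<QualifierRecordSet>" + "".join(
        f"<QualifierRecord><QualifierName><String>{t}</String></QualifierName>"
        f"<ConceptList><Concept><ConceptName><String>{t}</String></ConceptName>"
        f"</Concept></ConceptList></QualifierRecord>" for t in quarters[2]
    ) + "</QualifierRecordSet>"
    suppl = "<SupplementalRecordSet>" + "".join(
        f"<SupplementalRecord><SupplementalRecordName><String>{t}</String>"
        f"</SupplementalRecordName><ConceptList><Concept><ConceptName>"
        f"<String>{t}</String></ConceptName></Concept></ConceptList>"
        f"</SupplementalRecord>" for t in quarters[3]
    ) + "</SupplementalRecordSet>"
    return {"desc2017.xml": desc, "pa2017.xml": pa,
            "qual2017.xml": qual, "suppl2017.xml": suppl}


# ---------------------------------------------------------------------------
# topics and planted relevance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Topic:
    qid: str
    raw_text: str
    concept_terms: tuple[str, ...]   # the informative terms after cleaning


def make_topics(spec: FixtureSpec) -> list[Topic]:
    """Topics pairing one English word with one domain token, wrapped in
    the noisy phrasing real information needs arrive in."""
    from .expansion import default_noise_phrases, default_stoplist

    rng = _rng(spec, 2)
    english = _english_vocab()
    domain = make_domain_tokens(spec)
    reserved = set(default_stoplist()) | set(default_noise_phrases())
    topics = []
    used: set[str] = set()
    for i in range(spec.n_topics):
        while True:
            w1 = english[int(rng.integers(0, len(english)))]
            if w1 not in used and w1 not in reserved:
                used.add(w1)
                break
        w2 = domain[i % len(domain)]
        raw = f"Find data related to {w1} and {w2} studies"
        # the domain token splits into stem+number under the tokenizer
        cleaned = tuple([w1] + w2.replace("-", " ").split())
        topics.append(Topic(qid=str(i + 1), raw_text=raw, concept_terms=cleaned))
    return topics


# ---------------------------------------------------------------------------
# collection
# ---------------------------------------------------------------------------

def _metadata_for(repo: str, mappings, keywords: str, description: str) -> dict:
    """Build a metadata payload whose keys the repository mapping resolves."""
    m = mapping_for(repo, mappings)
    meta: dict[str, str] = {}
    if keywords and m.keyword_keys:
        meta[m.keyword_keys[0]] = keywords
    if description and m.description_keys:
        meta[m.description_keys[0]] = description
    return meta


def make_collection(spec: FixtureSpec, topics: Sequence[Topic] | None = None,
                    ) -> tuple[list[DatasetDocument], dict]:
    """Generate the document set plus its truth table.

    The truth table records, per docno: the repository, whether the
    record is degenerate (must be dropped by the filter) and, when
    topics are given, its planted relevance grade per topic.
    """
    rng = _rng(spec, 3)
    english = _english_vocab()
    domain = make_domain_tokens(spec)
    mappings = load_mappings()
    repos = sorted(spec.repo_mix)
    probs = np.array([spec.repo_mix[r] for r in repos])
    probs = probs / probs.sum()

    n_degenerate = int(round(spec.degenerate_fraction * spec.n_docs))
    degenerate_idx = set(
        int(i) for i in rng.choice(spec.n_docs, size=n_degenerate, replace=False))

    relevance: dict[str, dict[str, int]] = {t.qid: {} for t in (topics or [])}
    docs: list[DatasetDocument] = []
    truth_docs: dict[str, dict] = {}

    def words(n):
        return " ".join(english[int(j)] for j in rng.integers(0, len(english), n))

    for i in range(spec.n_docs):
        docno = f"d{i:05d}"
        repo = repos[int(rng.choice(len(repos), p=probs))]
        if i in degenerate_idx:
            title, kw, desc = DEGENERATE_TEMPLATES[i % len(DEGENERATE_TEMPLATES)]
            docs.append(DatasetDocument(
                docno=docno, title=title, repository=repo,
                metadata=_metadata_for(repo, mappings, kw, desc)))
            truth_docs[docno] = {"repository": repo, "degenerate": True}
            continue

        title = words(int(rng.integers(3, 7)))
        kw = " ".join([english[int(rng.integers(0, len(english)))],
                       domain[int(rng.integers(0, len(domain)))]])
        desc = words(int(rng.integers(4, 12)))

        grades: dict[str, int] = {}
        if topics:
            for t in topics:
                u = rng.random()
                if u < 0.06:        # highly relevant: concepts, repeated
                    reps = int(rng.integers(2, 5))
                    desc += (" " + " ".join(t.concept_terms)) * reps
                    grades[t.qid] = 2
                elif u < 0.14:      # partially relevant: one mention
                    desc += " " + " ".join(t.concept_terms)
                    grades[t.qid] = 1
        for qid, g in grades.items():
            relevance[qid][docno] = g

        docs.append(DatasetDocument(
            docno=docno, title=title, repository=repo,
            metadata=_metadata_for(repo, mappings, kw, desc)))
        truth_docs[docno] = {"repository": repo, "degenerate": False,
                             "grades": grades}

    truth = {"documents": truth_docs, "relevance": relevance}
    return docs, truth


# ---------------------------------------------------------------------------
# embeddings with planted neighbour clusters
# ---------------------------------------------------------------------------

def make_embeddings(spec: FixtureSpec, cluster_seeds: Sequence[str],
                    extra_vocab: Sequence[str] = (), salt: int = 4,
                    dim: int | None = None,
                    ) -> tuple[dict[str, np.ndarray], dict[str, list[str]]]:
    """Vectors with one tight cluster per seed term.

    Cluster members share a base direction perturbed by bounded noise,
    so within-cluster cosines sit in a high band (≈ 1 - noise²) and
    cross-cluster cosines near 0.  Returns the vectors and the planted
    cluster membership (seed term -> its neighbour terms).
    """
    dim = dim if dim is not None else spec.embedding_dim
    n_clusters = len(cluster_seeds)
    if dim < n_clusters:
        raise ValueError(f"dimension {dim} < {n_clusters} clusters")
    rng = _rng(spec, salt)
    english = _english_vocab()

    vectors: dict[str, np.ndarray] = {}
    clusters: dict[str, list[str]] = {}
    taken = set(cluster_seeds) | set(extra_vocab)

    def perturbed(base: np.ndarray) -> np.ndarray:
        noise = rng.standard_normal(dim)
        noise -= (noise @ base) * base           # keep noise orthogonal
        noise /= np.linalg.norm(noise)
        v = base + spec.cluster_noise * noise
        return v / np.linalg.norm(v)

    for ci, seed_term in enumerate(cluster_seeds):
        base = np.zeros(dim)
        base[ci] = 1.0
        vectors[seed_term] = perturbed(base)
        members = []
        for _ in range(spec.cluster_size - 1):
            while True:
                cand = english[int(rng.integers(0, len(english)))] + "like"
                if cand not in taken and cand not in vectors:
                    break
            vectors[cand] = perturbed(base)
            members.append(cand)
        clusters[seed_term] = members

    # background vocabulary far from every cluster
    for term in extra_vocab:
        if term in vectors:
            continue
        v = rng.standard_normal(dim)
        v[: n_clusters] = 0.0                     # orthogonal to all bases
        norm = np.linalg.norm(v)
        vectors[term] = v / norm if norm > 0 else np.eye(dim)[-1]
    return vectors, clusters


# ---------------------------------------------------------------------------
# qrels
# ---------------------------------------------------------------------------

def make_qrels(relevance: Mapping[str, Mapping[str, int]],
               pool: Mapping[str, Sequence[str]]) -> SampledQrels:
    """Full qrels: planted grades plus grade-0 entries for pooled docs."""
    qrels = SampledQrels()
    for qid in sorted(relevance):
        graded = relevance[qid]
        for docno in sorted(pool.get(qid, ())):
            qrels.add(qid, docno, int(graded.get(docno, 0)))
    return qrels


def subsample_qrels(qrels: SampledQrels, p: float,
                    seed: int) -> SampledQrels:
    """Keep each judged entry with probability ``p``; the rest become
    pooled-but-unjudged (-1).  Rates are recorded per topic."""
    if not (0.0 < p <= 1.0):
        raise ValueError("p must be in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    out = SampledQrels()
    for (topic, docno), (grade, stratum) in sorted(qrels.judgments.items()):
        if grade >= 0 and (p == 1.0 or rng.random() < p):
            out.add(topic, docno, grade, stratum)
        else:
            out.add(topic, docno, -1, stratum)
    for topic in qrels.topics():
        out.set_rate(topic, p)
    return out


def make_estimator_fixture(seed: int, n_pool: int = 400,
                           frac_rel: float = 0.15, frac_partial: float = 0.10,
                           score_noise: float = 2.0,
                           ) -> tuple[RankedList, SampledQrels]:
    """A single-topic ranking plus fully-judged qrels for estimator tests.

    The ranking is quality-correlated but noisy (relevant documents tend
    to rank high without being perfectly sorted), putting AP and NDCG in
    the mid-range regime the sampled-judgment estimators are designed
    for: near-perfect rankings saturate the NDCG cap at 1 and are not a
    meaningful test of an estimator of retrieval *quality under
    uncertainty*.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    docnos = [f"e{i:04d}" for i in range(n_pool)]
    grades = np.zeros(n_pool, dtype=int)
    n_rel = int(frac_rel * n_pool)
    n_part = int(frac_partial * n_pool)
    grades[:n_rel] = 2
    grades[n_rel: n_rel + n_part] = 1
    rng.shuffle(grades)

    qrels = SampledQrels()
    for d, g in zip(docnos, grades):
        qrels.add("1", d, int(g))

    score = grades * 1.0 + rng.normal(0.0, score_noise, size=n_pool)
    order = np.argsort(-score, kind="stable")
    rows = tuple((docnos[int(i)], float(score[int(i)])) for i in order)
    return RankedList(topic="1", rows=rows, tag="synthetic"), qrels


# ---------------------------------------------------------------------------
# one-stop fixture directory
# ---------------------------------------------------------------------------

def make_fixture_dir(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Write a complete fixture set: collection, MeSH files, two vector
    files, topics, full and subsampled qrels, and the truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    topics = make_topics(spec)
    docs, truth = make_collection(spec, topics)
    domain = make_domain_tokens(spec)

    paths["collection"] = outdir / "collection.xml"
    paths["collection"].write_text(write_collection(docs), "utf-8")

    mesh_dir = outdir / "mesh"
    mesh_dir.mkdir(exist_ok=True)
    for name, xml in make_mesh_files(domain).items():
        (mesh_dir / name).write_text(xml, "utf-8")
    paths["mesh_dir"] = mesh_dir

    seeds = sorted({t.concept_terms[0] for t in topics})
    extra = [t for topic in topics for t in topic.concept_terms[1:]]
    for label, salt in (("pubmed", 4), ("collection", 5)):
        vectors, clusters = make_embeddings(spec, seeds, extra_vocab=extra,
                                            salt=salt)
        path = outdir / f"vectors_{label}.txt"
        write_word2vec_text(vectors, path)
        paths[f"vectors_{label}"] = path
        truth.setdefault("clusters", {})[label] = clusters

    paths["topics"] = outdir / "topics.txt"
    paths["topics"].write_text(
        "".join(f"{t.qid}\t{t.raw_text}\n" for t in topics), "utf-8")

    pool = {t.qid: [d.docno for d in docs] for t in topics}
    full = make_qrels(truth["relevance"], pool)
    from .evaluation import write_qrels
    paths["qrels_full"] = outdir / "qrels_full.txt"
    paths["qrels_full"].write_text(write_qrels(full), "utf-8")
    sampled = subsample_qrels(full, spec.qrels_p, spec.seed)
    paths["qrels_sampled"] = outdir / "qrels_sampled.txt"
    paths["qrels_sampled"].write_text(write_qrels(sampled), "utf-8")
    (outdir / "qrels_rates.json").write_text(
        json.dumps({t: spec.qrels_p for t in full.topics()}), "utf-8")

    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True), "utf-8")
    return paths
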