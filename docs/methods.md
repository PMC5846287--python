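# Methods and design notes

This note records the models implemented, the defaults and why they are
set where they are, what the synthetic fixtures do and do not emulate,
and the choices made where the design was genuinely open.

## The retrieval problem

The collection is a set of dataset *metadata* records, not articles:
each record is an XML `DOC` with an identifier, an optional title, a
repository name, and a repository-specific JSON payload.  Two properties
dominate the engineering: the payload schemas differ per repository (and
sometimes within one), and a non-trivial share of records carry no
retrievable content at all (a bare chromosome label as title, empty
keywords, no description).  The pipeline therefore normalizes first,
filters second, and only then indexes.

## Category normalization

Per repository, an ordered list of metadata keys feeds each of the three
categories (title / keywords / description).  Keys are matched as
case-insensitive suffixes of the flattened, dot-joined JSON paths; list
elements are indexed positionally and ignored during matching.  The
shipped defaults (one YAML file, user-replaceable) cover the twenty
repository names of the benchmark collection; unknown repositories fall
back to `{title: [title], description: [description]}`.  Suffix matching
is a best-effort choice: the canonical key lists circulate as flattened
staging-column names (`dataItemkeywords`), not JSON paths, so both
`dataItemkeywords` and `dataItem.keywords` must resolve.  The
over-matching this can cause (a `subtitle` key would satisfy a `title`
suffix) is accepted and documented rather than guessed away.

One repository (geo) historically augments its description with text
fetched online by accession; this package never performs network I/O, so
the geo mapping uses only in-record keys.

## Informativeness filter

For one category text with `X` whitespace tokens (after stripping the
characters `,`, `(`, `)`; hyphens are kept, so `MIP-2` is one word),
`Y1` counts tokens found in an English wordlist and `Y2` tokens found in
the MeSH word set *but not* counted in `Y1`:

    score = (Y1 + Y2) / X        (score = −1 when X = 0)
    keep(title, description)  iff  score > 0  and  X > 2
    keep(keywords)            iff  score > 0

A record is dropped when no category is kept.  The `X > 2` guard is
deliberately absent for keywords: a single recognized keyword is
informative, a single-token title ("chr19") is not.  Both threshold
comparisons are strict.

The MeSH side of the lexicon is harvested flat — descriptor, qualifier
and supplemental-record names, concept names, term synonyms and
pharmacological substances — with no use of the tree-number hierarchy.
The English side is a wordlist: the packaged one is compact (~900 common
and biomedical English words), sufficient for the synthetic fixtures and
for demonstration; production use should point `build_lexicon` at a full
spell-check list (any one-word-per-line file).  Whether bare numerals
count as words is unspecified in the source procedure; here every
whitespace token counts toward `X`.

## Indexing

Lowercase, split on any non-alphanumeric, drop tokens longer than 20
characters (junk accession blobs).  No stemming by default (a light
Porter-style stemmer sits behind a flag); stopwords are *not* removed at
indexing time — query cleaning handles them — and the three kept
categories are indexed as one flat field.  Positional/bigram features
are out of scope: proximity models have not helped on this kind of
collection.

## Ranking models

All logarithms are base 2.  Term-frequency normalization is
Normalization 2, `tfn = tf·log2(1 + c·avg_dl/dl)` with `c = 1` by
default.  Query-term weights are multiplicative key frequencies — *not*
normalized probabilities — which is exactly what makes the 100/20/1
expansion weighting behave as intended: an original term contributes one
hundred times the evidence of a collection-space neighbour, all else
equal.  The six core models (LGD, InL2, PL2, DPH, BM25, TFIDF) follow
the standard formulas; LGD's log-logistic rate uses the
document-frequency variant `λ = df/N` (configurable reading; the
reference formulation is df-based).  Degenerate cases are pinned: DPH
returns 0 when `tf = dl`; PL2 falls back to the after-effect-only branch
`tfn/(tfn+1)` with a logged warning when `F ≥ N` (the Poisson rarity
assumption is void); BM25's idf can legitimately be ≤ 0 on tiny
collections.  The extended set (BB2, IFB2, In_expB2, In_expC2, DLH,
DLH13, DFRee, DFR_BM25) follows the conventions of the DFR framework's
reference implementation; additive constants in that family differ
between published variants, which never affects ranking order, and the
extended set is config-gated so the tested contract is the core six.

Ties in the ranked list break by ascending docno, making every search
byte-reproducible.

## Query expansion

Cleaning removes non-informative phrases first (as whole phrases,
longest first: "related to", "find", "data", …), then stopwords, then
tokenizes.  Embedding expansion looks up each original term in each
space and admits neighbours at or above that space's cosine threshold —
0.9 for the PubMed space, 0.8 for the collection space (the collection
corpus being smaller, its neighbourhoods are noisier and its terms get
weight 1 rather than 20).  A per-term neighbour cap (default 10) bounds
query drift; the threshold alone gives no size guarantee.  A candidate
reached from several sources keeps the *maximum* weight, not the sum —
over-weighting expansion terms is precisely the failure mode the 100/20/1
scheme exists to avoid.  Originals are never displaced and their weights
never change.  The expanded query is already weighted and is not passed
through the tokenizer again (multi-word candidates are split once, each
token inheriting the candidate weight).

PRF runs after a first retrieval pass: candidates are the terms of the
top `m = 2` documents; per document the `n = 2` best by the Bo1
informativeness score

    w(t) = tf_x · log2((1 + Pn)/Pn) + log2(1 + Pn),   Pn = F(t)/N

are selected ("per document" is one reading of the printed parameters; a
`per_document=False` switch selects the top `m·n` overall).  Rocchio
sets every term's final weight to `α·qtw/max(qtw) + β·w/max(w)` (`α` is
fixed at 1 and not exposed; only `β`, default 0.5, is a parameter), new
terms carrying only the `β` component.  With `β = 0` the feedback
component vanishes and the uniform `α/max(qtw)` rescale cannot change
any ordering, so the implementation short-circuits to the identity —
this keeps a disabled-PRF run bitwise equal to the baseline, which the
regression tests rely on.  Plain Bo1 appends the selected new terms with
weight `w/max(w)` and leaves original weights untouched; at original
weight 100 its additive effect is deliberately small.

## Evaluation

Grades are `{0, 1, 2}` with `−1` for pooled-but-unjudged.  P@10 counts
grades `{1,2}` (+partial) or `{2}` (−partial) with denominator 10
regardless of retrieval depth.  NDCG uses linear gain (= grade) and
`log2(rank+1)` discount — the common trec-family convention; an
exponential-gain flag exists because the challenge scorer's convention
is not printed anywhere authoritative.  Topics with no (sampled)
relevant document are excluded from means, with the exclusion logged,
rather than scored zero.

The inferred measures follow the sampled-pool estimator family.  For a
sampled-relevant document at rank `k`,

    êP@k = 1/k + (d/k) · (r̂ + ε)/(r̂ + n̂ + 2ε)

with `d` the pooled documents above `k` and `r̂`, `n̂` the judged
relevant/non-relevant counts above, inverse-probability scaled by their
stratum rate; êP@1 = 1.  infAP averages `êP@k` (weighted `1/p`) over
retrieved sampled-relevant documents and divides by the estimated total
relevant count, so unretrieved relevant documents dilute the value
exactly as in classic AP.  The Lidstone smoothing `ε = 1e−5` exists to
stabilize subsampled estimates; under full judgment (every rate 1) the
unsmoothed ratio is used, so infAP collapses to AP *exactly* (to 1e−10
in the tests), not merely to O(ε).  infNDCG scales each retrieved
relevant gain by `1/p`, builds the ideal gain multiset from
inverse-probability grade counts (`round(observed/p)`, never below the
observed count), and caps the ratio at 1.

Qrels carry an optional 5th `stratum` column with per-(topic, stratum)
rates supplied as a JSON sidecar; the single-stratum, rate-1 default
reproduces fully-judged evaluation.  The official stratified layout of
the benchmark's qrels is not publicly specified, so cross-checking
against the official scorer on real data is recommended where available
but is not part of this package's test surface.

## Synthetic fixtures

The generator emulates the *shape* of the real data: a repository mix
over eight of the benchmark's repository names, metadata payloads whose
keys the shipped mappings resolve, a declared fraction (default 10%) of
degenerate records built from verbatim real-world templates ("chr19",
"Sobemovirus", `A375_vitro_vehicle_rep3`, a one-word "melanoma"
description), domain tokens shaped like gene symbols (`qkr-31`) that
appear in the fixture MeSH files but in no English list, embedding
spaces with planted clusters (orthogonal base directions plus bounded
orthogonal noise at 0.2, giving within-cluster cosines ≈ 0.92–0.96 and
cross-cluster ≈ 0), and graded qrels with known full-judgment truth plus
`p`-subsampled variants.  It does **not** emulate biomedical language
statistics, realistic term burstiness, or judgment noise — passing tests
demonstrate that the contracts hold, not that retrieval quality on real
repositories would match.

The estimator fixture (pool 400, relevant fraction 0.25, ranking scores
= grade + Gaussian noise with σ = 2.0) deliberately produces mid-range
quality (AP ≈ 0.45, NDCG ≈ 0.8).  That is the regime the inferred
estimators are designed for: on near-perfect rankings the infNDCG cap at
1 truncates the replicate distribution and the êP smoothing's 1/2
fallback at sparsely-judged early ranks biases infAP — known behaviour
of this estimator family near saturation, not an implementation defect.

## Problem sizes

Defaults throughout are desk-scale by design: 200–1000 document
collections, 5 topics, 100-dimensional vectors, 200 Monte-Carlo
replicates for the estimator checks.  The full pipeline is linear in
collection size and runs the 1000-document regression in seconds; the
same code paths take a real multi-hundred-thousand-record collection,
just slower, with the inverted index held in memory (a few GB at
benchmark scale).

## Known limitations

- The packaged English wordlist is intentionally small; filter recall on
  real free text depends on supplying a full dictionary.
- Exact JSON paths behind the flattened mapping names are best-effort
  suffix matches; repository schema drift requires editing the mapping
  YAML.
- The extended DFR models are provided for completeness and parity
  studies; their absolute scores may differ from other implementations
  by model-specific constants.
- No significance testing between runs; comparison is descriptive.
- Embedding spaces are consumed, never trained; vector quality is the
  caller's responsibility.
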