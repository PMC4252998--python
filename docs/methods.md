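# Methods

This note documents the model, the defaults and the numerical choices
behind `polsa`, and what the synthetic benchmark does and does not show.

## Semantic model

The corpus is reduced to a term × heading count matrix: every abstract's
title and abstract text is tokenized (lowercase; punctuation and symbol
characters split tokens, intra-token hyphens survive) and scanned with a
greedy leftmost-longest gazetteer matcher over the multi-gram dictionary.
At each position the longest known surface (up to 6 tokens) is consumed;
spans never overlap. Greedy matching is linear-time and is the standard
behaviour of dictionary taggers; the test suite pins its semantics against
an exhaustive tiling oracle, so the choice is load-bearing only in the
rare ambiguous tilings ("a b" vs "b c"), where leftmost wins.

An abstract annotated with k selected headings contributes its full term
counts to all k columns. No down-weighting by 1/k is applied; pooling is
the simplest reading of heading-grouped columns and keeps counting
additive (tested). Heading annotation strings are never injected as text —
that would make the model circular.

Weighting is the textbook raw-tf × log-idf form, `w = c · ln(H/df)`, with
no sublinear tf and no column normalization. Terms present in every
column get idf 0 and thus an all-zero row; queries consisting only of such
terms carry no signal and are reported as all-"unknown" rather than
rejected.

"Energy" for the SVD cutoff is squared singular values (Frobenius
energy). The retained rank k is the smallest with cumulative energy
fraction ≥ the threshold (default 0.95); minimality is asserted on every
fit. The factorization uses LAPACK's deterministic divide-and-conquer
driver on the dense matrix — heading spaces have at most a few thousand
columns, so an iterative sparse solver would buy nothing and cost
reproducibility. Singular values below `σ₁ · max(T,H) · ε` are treated as
numerical zeros.

Queries fold in as idf-weighted pseudo-documents, `q̂ = qᵀU_k` (the
Deerwester convention), compared against heading coordinates `V_kΣ_k` by
cosine. Two details matter:

- The cosine denominator uses the *original* pseudo-document norm ‖q‖,
  not ‖q̂‖. Folding-in discards any query component orthogonal to the
  factor span; keeping the original norm makes full-rank latent cosines
  agree with raw-TF-IDF-space cosines to machine precision (the
  equivalence the test suite checks at 1e−8) instead of being uniformly
  inflated.
- Cosines with magnitude below 1e−12 are snapped to exactly 0 before
  sorting. Headings orthogonal to the query in the raw space pick up
  ~1e−16 rotation noise in the latent space; without snapping, their
  relative order would be noise-driven rather than resolved by the
  heading-id tie-break.

Query idf weighting (vs raw 0/1 indicators) is a config toggle
(`query_idf_weighting`, default on): idf-weighted entries put queries on
the same scale as matrix rows, and for single-term queries the choice
does not affect ranking at all (cosine is scale-invariant).

## Heading selection

Inclusive count window [1 000, 50 000]: the endpoints pass, since
exclusion is stated strictly ("fewer than"/"greater than"). The
Disease-category constraint is a floor: at least half the selected set
must carry category C. It is enforced by dropping non-C headings, lowest
abstract count first — never by admitting out-of-window C headings,
because the count window is a hard filter. A heading carrying C alongside
other letters counts toward the floor. The greedy drop rule provably
reaches the maximal feasible selection (all C headings kept, as many
non-C as the floor allows, highest counts first); tests verify it against
brute-force subset enumeration.

## Dictionary

One term per selected heading; its variants are all comma-segment
*rotations* of the preferred name and of each entry term ("Fever, Yellow,
Virus" → "yellow virus fever" among others). Rotations, not full
permutations: MeSH inverted display forms are rotations, and rotations
keep variant counts linear in segment count. Gene symbols are added as
single terms, matched case-insensitively like everything else. Surface
collisions resolve by priority heading > entry term > gene symbol, then
earlier term id; ontology concepts anchor the column space, symbols are a
layer on top. Entry terms of non-selected headings contribute nothing.
Surfaces longer than 6 tokens are dropped (logged) to bound the matcher
window.

## Relevance model

Standard Bezdek fuzzy c-means on the 1-D cosine-score distribution:
c = 3 clusters (highly / possibly / unknown), fuzzifier m = 2, convergence
when centers move < 1e−6, cap 300 iterations. Centers are initialized at
the 10th/50th/90th percentiles, which makes every run deterministic with
no seed; duplicate initial centers (heavily skewed scores) are nudged
apart by 1e−9. A point coinciding with a center gets membership exactly 1
there (the FCM singularity rule). Final group labels come from cutoff
*intervals* — midpoints between adjacent sorted centers — not raw argmax,
so groups are contiguous in score and a pair of cutoff values fully
describes each query's partition. Fewer than three distinct scores is a
degenerate distribution: an error by default, all-"unknown" in the
pipeline's lenient mode. The implementation is validated against an
independent plain-loop FCM to 1e−4 on the centers.

## Association networks

Headings in the included groups (default highly + possibly) are attached
under their full tree-number ancestor chains; ancestors that are not
themselves relevant appear as structural nodes without scores, because a
collapsible view needs complete paths. A heading with several tree
numbers appears once per position while `n_relevant` counts distinct
headings. Children sort by best descendant cosine so the strongest
associations read top-down. JSON serialization is key-ordered and
deterministic (byte-identical across runs); positions whose tree number
has no owning heading in the ontology are named by the tree number
itself.

## Synthetic benchmark

The generator emulates the study conditions at desk scale: a two-level
ontology over category roots C, D and J with the Disease share at the
configured floor; a dictionary of heading-name terms (50 of 100 heading
names are 2–3-token phrases in the reference spec) plus gene-symbol-like
single tokens, totalling 500 terms; 2 000 records, each annotated with
exactly one heading; 10 planted term–heading pairs.

Occurrences are Poisson *per (term, heading pool)*: the total count of a
term across the record pool of one heading is Poisson(background_rate =
0.2), or Poisson(planted_rate = 5) for a planted pair in its target pool,
scattered uniformly over the pool's records and padded with
out-of-dictionary filler to 50 tokens per abstract. The pool-level rate
is the deliberate reading of the occurrence model: it keeps column
document frequencies realistic (a background term occupies ~18 % of
heading columns, idf ≈ 1.7). A per-record rate of 0.2 would put nearly
every term in nearly every column, driving ln(H/df) to ≈ 0 and often to
exactly 0 — under that regime no weighting scheme of this family can
separate planted from background signal, so it would test the formula's
degenerate limit rather than the method. Single-annotation records keep
the planted column attribution unambiguous; multi-annotation pooling is
covered separately by hand-built fixtures.

What passing the recovery benchmark shows: the TF-IDF/SVD/FCM chain
concentrates a 25× occurrence-rate excess into the "highly associated"
group for ≥ 90 % of planted pairs in ≥ 8 of 10 seeds. What it does not
show: behaviour on real English text (no word-frequency law, no syntax,
no synonymy beyond entry terms), temporal drift, multi-annotation
abstracts at scale, or the ambiguity of real gene symbols against common
words — the generator's vocabulary is collision-free by construction.

## Problem sizes and determinism

Test and acceptance runs use the reference synthetic spec (100 × 500 ×
2 000) for recovery, 20 × 10 random matrices for ranking fidelity, 500
random cases for the matcher oracle, and 12-heading corpora for the
CLI round-trips — sizes chosen so the full validation completes in
seconds while keeping every statistical check comfortably powered. All
randomness flows from explicit integer seeds; builds, queries and the
precompute cache are byte-reproducible, and the cache invalidates on the
model digest.

## Known limitations

- MEDLINE parsing covers the PMID/TI/AB/MH/DP fields with continuation
  unfolding; other fields are ignored.
- MH values resolve through exact (case-insensitive) preferred-name and
  entry-term lookup; unmatched values are logged and skipped, not fuzzily
  matched.
- Disambiguation of a surface claimed by several sources is purely the
  static priority rule; no context-sensitive sense resolution.
- The relevance model always uses three clusters; no model-order
  selection.
- Networks contain only the ontology hierarchy — no cross-links between
  headings beyond shared ancestry.
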