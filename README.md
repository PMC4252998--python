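# polsa

Phrase-ontology latent semantic analysis for literature-based knowledge
discovery.

Biomedical researchers routinely miss associations that are present in the
literature but never stated in any single abstract — a drug whose lung
toxicity is scattered across decades-old case reports, or two diseases
linked only through a shared gene family. `polsa` implements the
engine behind this kind of discovery: it compresses a large annotated
abstract corpus into a semantic space whose columns are
controlled-vocabulary headings (MeSH-style descriptors) and whose rows are
ontology-derived multi-word phrases plus gene symbols, then answers free
queries with a ranked, grouped, browsable network of associated headings.

## Method

Let `C` be the term × heading count matrix: `C[t, h]` counts occurrences of
dictionary term *t* (matched greedily, leftmost-longest, so the phrase
"yellow virus fever" is one unit, not three words) in abstracts annotated
with heading *h*. The pipeline is:

1. **Ontology mapping.** Headings are selected when their abstract count
   lies in the inclusive window [1 000, 50 000] and at least half of the
   selected set comes from the Disease category (C); heading names, their
   comma-inverted entry-term variants ("Scleroderma, Systemic" ≡ "Systemic
   Scleroderma"), and gene symbols form the multi-gram dictionary.
2. **TF-IDF + truncated SVD.** `W[t,h] = C[t,h] · ln(H/df_t)` with
   `df_t = |{h : C[t,h] > 0}|`; `W = UΣVᵀ` is truncated at the smallest
   rank *k* whose cumulative squared-singular-value energy
   `Σ_{i≤k} σ_i² / Σ σ_i²` reaches 95 %. Headings live at `V_kΣ_k`.
3. **Query folding-in.** A query becomes an idf-weighted pseudo-document
   `q`, projected as `q̂ = qᵀU_k`, and every heading is scored by cosine
   similarity (the original ‖q‖ is kept as the denominator so full-rank
   scores equal raw-space scores exactly).
4. **Relevance model.** Fuzzy c-means (Bezdek iteration, m = 2, three
   clusters, percentile initialization) partitions each query's score
   distribution into *highly associated*, *possibly associated* and
   *unknown*; the cutoffs are midpoints between cluster centers, so they
   adapt to every query rather than being fixed globally.
5. **Reverse ontology mapping.** Relevant headings are re-attached to their
   full ancestor chains ("Proteostasis Deficiencies > Amyloidosis") and
   exported as collapsible D3-flare hierarchy JSON and edge-list TSV.

A synthetic-data generator produces miniature ontologies and corpora with
*planted* term–heading associations so the whole pipeline is testable
without any external download.

## Worked example

Generate a small corpus with 4 planted associations, build the model, and
query one of the planted surfaces (`h6a h6b`, planted on heading
`SH0016`, whose name is `h16`):

```sh
polsa synth --seed 11 --out fixtures --n-headings 20 --n-terms 80 \
    --n-records 400 --n-topics 4 --n-multigrams 8 --tokens-per-abstract 30
polsa build --ontology fixtures/ontology.tsv \
    --gene-symbols fixtures/gene_symbols.txt \
    --corpus fixtures/corpus.jsonl --out model
polsa query model "h6a h6b" --top 5 --json net.json
```

which prints:

```
model archive written to model: 20 headings, 80 terms, 400 records, k=17 (energy 0.9585)
rank    name    cosine  group
1       h16     0.868157        highly
2       h18     0.369156        possibly
3       h10     0.260418        possibly
4       h1a h1b h1c     0.211297        possibly
5       h15     0.209426        possibly
```

The planted target `h16` is recovered at rank 1 with cosine 0.87 and lands
in the *highly associated* group; the remaining headings are background
noise whose scores the relevance model correctly separates into weaker
groups. `net.json` holds the association network: the query at the root,
category roots below it, and score-bearing heading leaves sorted by best
descendant cosine. `polsa precompute model cache/` materializes every
dictionary query so later lookups are served byte-identically from disk.

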