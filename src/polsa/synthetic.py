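"""Synthetic ontologies and corpora with planted term-heading associations.

Real deployments of this pipeline run over millions of annotated abstracts;
for testing, this module generates miniature inputs with *known* structure:
a two-level ontology (category roots C, D, J), a dictionary of heading
names (a configurable share of them multi-token phrases) plus single-token
gene-symbol-like terms, and a corpus in which each record is annotated with
exactly one heading.

Occurrences follow a Poisson model per (term, heading-pool): within the
record pool of each heading, a term's total occurrence count is drawn
Poisson(background_rate), except for planted (term, heading) pairs, whose
count in the target heading's pool is drawn Poisson(planted_rate);
occurrences are then scattered uniformly over the pool's records and padded
with out-of-dictionary filler tokens.  Because planted_rate > background_rate
the planted term concentrates in its target column, which TF-IDF + SVD
should recover as a top-ranked, highly-associated heading.

Everything is driven by one integer seed; identical seeds give
byte-identical fixture files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus import AbstractRecord
from .dictionary import MultiGramDictionary, build_dictionary
from .ontology import Heading, OntologyTree, SelectionConfig, select_headings

logger = logging.getLogger(__name__)

__all__ = ["SyntheticSpec", "PlantedAssociation", "generate_ontology", "generate_corpus", "write_fixture_files"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the generated study.

    Defaults are the reference recovery conditions used throughout the test
    suite: 100 headings, 500 dictionary terms of which 50 are multi-grams,
    2,000 single-annotation records, 10 planted pairs with a 25x
    planted-to-background rate ratio.
    """

    n_headings: int = 100
    n_terms: int = 500
    n_records: int = 2000
    n_topics: int = 10
    planted_pairs: tuple[tuple[int, int], ...] = ()
    background_rate: float = 0.2
    planted_rate: float = 5.0
    tokens_per_abstract: int = 50
    disease_fraction_target: float = 0.5
    n_multigrams: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_headings < 4:
            raise ValueError("need at least 4 headings")
        if self.n_terms < self.n_headings:
            raise ValueError("n_terms must be >= n_headings (one term per heading)")
        if self.planted_rate <= self.background_rate:
            raise ValueError("planted_rate must exceed background_rate")
        if self.n_multigrams > self.n_headings:
            raise ValueError("n_multigrams cannot exceed n_headings")
        for t, h in self.planted_pairs:
            if not (0 <= t < self.n_terms and 0 <= h < self.n_headings):
                raise ValueError(f"planted pair ({t}, {h}) out of range")

    @property
    def n_gene_symbols(self) -> int:
        return self.n_terms - self.n_headings


@dataclass(frozen=True)
class PlantedAssociation:
    query_surface: str
    target_heading_id: str
    strength: float  # planted_rate / background_rate

    def __post_init__(self) -> None:
        if not self.strength > 1:
            raise ValueError("planted association must be stronger than background")


_CATEGORY_ROOTS = (("C", "C01", "synthetic diseases root"),
                   ("D", "D01", "synthetic chemicals root"),
                   ("J", "J01", "synthetic technology root"))


def _heading_name(i: int, n_multigrams: int) -> str:
    """Unique heading name; the first ``n_multigrams`` are 2- or 3-grams."""
    if i < n_multigrams:
        toks = [f"h{i}a", f"h{i}b"] if i % 2 == 0 else [f"h{i}a", f"h{i}b", f"h{i}c"]
        return " ".join(toks)
    return f"h{i}"


def generate_ontology(spec: SyntheticSpec) -> tuple[OntologyTree, list[str]]:
    """Build the synthetic two-level ontology and its heading selection.

    Headings are assigned to category C at the ``disease_fraction_target``
    rate (rounded up) and the remainder alternates between D and J; abstract
    counts are drawn uniformly inside the default selection window so every
    generated heading is selectable.
    """
    rng = np.random.default_rng(spec.seed)
    sel_cfg = SelectionConfig()
    n_c = int(np.ceil(spec.n_headings * spec.disease_fraction_target))
    headings = [
        Heading(
            heading_id=f"ROOT_{letter}",
            preferred_name=root_name,
            tree_numbers=[tn],
        )
        for letter, tn, root_name in _CATEGORY_ROOTS
    ]
    roots = {letter: tn for letter, tn, _ in _CATEGORY_ROOTS}
    counts = rng.integers(sel_cfg.min_abstracts, sel_cfg.max_abstracts + 1, size=spec.n_headings)
    for i in range(spec.n_headings):
        if i < n_c:
            letter = "C"
        else:
            letter = "D" if (i - n_c) % 2 == 0 else "J"
        name = _heading_name(i, spec.n_multigrams)
        # every 5th multi-gram heading also carries a comma-inverted entry term
        entry_terms = []
        if i < spec.n_multigrams and i % 5 == 0:
            toks = name.split()
            entry_terms = [f"{toks[-1]}, {' '.join(toks[:-1])}"]
        headings.append(
            Heading(
                heading_id=f"SH{i:04d}",
                preferred_name=name,
                entry_terms=entry_terms,
                tree_numbers=[f"{roots[letter]}.{i:03d}"],
                abstract_count=int(counts[i]),
            )
        )
    tree = OntologyTree(headings)
    selection = select_headings(tree, sel_cfg)
    return tree, selection


def gene_symbols_for(spec: SyntheticSpec) -> list[str]:
    return [f"gs{i:04d}" for i in range(spec.n_gene_symbols)]


def default_planted_pairs(
    spec: SyntheticSpec, dictionary: MultiGramDictionary, selection: list[str]
) -> list[tuple[int, int]]:
    """Deterministic planted pairs when the spec leaves them empty.

    Half the pairs use gene-symbol terms, half multi-gram heading terms
    (planted on a heading other than their own), each targeting a distinct
    heading.
    """
    rng = np.random.default_rng(spec.seed + 1)
    gene_ids = [t.term_id for t in dictionary.terms if t.source == "gene_symbol"]
    multi_ids = [t.term_id for t in dictionary.terms if t.n_tokens > 1]
    targets = rng.choice(len(selection), size=spec.n_topics, replace=False)
    pairs = []
    for j, h in enumerate(targets):
        pool = multi_ids if (j % 2 == 0 and multi_ids) else gene_ids or multi_ids
        t = int(pool[int(rng.integers(len(pool)))])
        # avoid planting a heading's own name term on itself
        if dictionary.terms[t].linked_heading == selection[int(h)]:
            t = int(pool[(pool.index(t) + 1) % len(pool)])
        pairs.append((t, int(h)))
    return pairs


def generate_corpus(
    spec: SyntheticSpec,
    tree: OntologyTree,
    dictionary: MultiGramDictionary,
    selection: list[str] | None = None,
) -> tuple[list[AbstractRecord], list[PlantedAssociation]]:
    """Generate records with planted term-heading co-occurrence structure."""
    selection = selection or select_headings(tree)
    rng = np.random.default_rng(spec.seed + 2)
    H = len(selection)
    pairs = list(spec.planted_pairs) or default_planted_pairs(spec, dictionary, selection)

    # records round-robin over headings: heading j owns records j, j+H, ...
    pools: list[list[int]] = [list(range(j, spec.n_records, H)) for j in range(H)]
    record_surfaces: list[list[str]] = [[] for _ in range(spec.n_records)]
    planted_lookup = {(t, h) for t, h in pairs}
    for j in range(H):
        pool = pools[j]
        if not pool:
            continue
        for term in dictionary.terms:
            rate = spec.planted_rate if (term.term_id, j) in planted_lookup else spec.background_rate
            if rate <= 0:
                continue
            total = int(rng.poisson(rate))
            for _ in range(total):
                rec = pool[int(rng.integers(len(pool)))]
                record_surfaces[rec].append(term.canonical)

    records = []
    for r in range(spec.n_records):
        surfaces = record_surfaces[r]
        n_tokens = sum(len(s.split()) for s in surfaces)
        n_filler = max(0, spec.tokens_per_abstract - n_tokens)
        tokens = surfaces + [f"xf{int(rng.integers(50)):02d}" for _ in range(n_filler)]
        rng.shuffle(tokens)
        records.append(
            AbstractRecord(
                record_id=f"S{r:06d}",
                year=1960 + r % 50,
                title=f"synthetic record {r}",
                abstract=" ".join(tokens),
                annotations=[selection[r % H]],
            )
        )
    strength = (
        spec.planted_rate / spec.background_rate if spec.background_rate > 0 else float("inf")
    )
    truth = [
        PlantedAssociation(
            query_surface=dictionary.terms[t].canonical,
            target_heading_id=selection[h],
            strength=strength,
        )
        for t, h in pairs
    ]
    return records, truth


def write_fixture_files(spec: SyntheticSpec, outdir) -> dict[str, Path]:
    """Emit the fixture files the real readers consume.

    Writes the ontology TSV, gene-symbol list, JSONL corpus, and a
    planted-truth TSV into ``outdir``; returns the path of each.
    """
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree, selection = generate_ontology(spec)
    symbols = gene_symbols_for(spec)
    dictionary = build_dictionary(tree, selection, symbols)
    records, truth = generate_corpus(spec, tree, dictionary, selection)

    paths = {
        "ontology": outdir / "ontology.tsv",
        "gene_symbols": outdir / "gene_symbols.txt",
        "corpus": outdir / "corpus.jsonl",
        "planted_truth": outdir / "planted_truth.tsv",
    }
    with open(paths["ontology"], "w", encoding="utf-8") as fh:
        for h in tree.headings.values():
            fh.write(
                "\t".join(
                    [
                        h.heading_id,
                        h.preferred_name,
                        "|".join(h.entry_terms),
                        "|".join(h.tree_numbers),
                        str(h.abstract_count),
                    ]
                )
                + "\n"
            )
    with open(paths["gene_symbols"], "w", encoding="utf-8") as fh:
        fh.write("# synthetic gene symbols\n")
        fh.writelines(f"{s}\n" for s in symbols)
    with open(paths["corpus"], "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(
                json.dumps(
                    {
                        "id": rec.record_id,
                        "year": rec.year,
                        "title": rec.title,
                        "abstract": rec.abstract,
                        "headings": rec.annotations,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
    with open(paths["planted_truth"], "w", encoding="utf-8") as fh:
        fh.write("query_surface\ttarget_heading_id\tstrength\n")
        fh.writelines(
            f"{t.query_surface}\t{t.target_heading_id}\t{t.strength}\n" for t in truth
        )
    return paths
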