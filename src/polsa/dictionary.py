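"""Ontology Mapping: the context-specific multi-gram dictionary.

Heading names and entry terms (plus their comma-inverted display variants,
e.g. "Scleroderma, Systemic" == "Systemic Scleroderma") and gene symbols
are normalized into surface forms and indexed so that multi-word phrases
like "yellow virus fever" are matched as single semantic units rather than
bags of words.
"""

from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass, field

from .ontology import OntologyTree

logger = logging.getLogger(__name__)

__all__ = [
    "DictionaryTerm",
    "MultiGramDictionary",
    "normalize",
    "permute_comma_inverted",
    "build_dictionary",
    "MAX_NGRAM",
]

#: Longest multi-gram kept in the matcher window; longer entry terms are
#: dropped (with a log message) to bound the matching cost.
MAX_NGRAM = 6

_SOURCE_PRIORITY = {"heading": 0, "entry_term": 1, "gene_symbol": 2}


def _is_punct(ch: str) -> bool:
    # punctuation and symbol characters both separate tokens
    return unicodedata.category(ch)[0] in "PS"


def normalize(text: str) -> list[str]:
    """Lowercase, strip punctuation (keeping intra-token hyphens), split.

    >>> normalize("Scleroderma, Systemic")
    ['scleroderma', 'systemic']
    >>> normalize("beta-endorphin")
    ['beta-endorphin']
    """
    out = []
    for ch in text.lower():
        if ch == "-":
            out.append(ch)
        elif _is_punct(ch):
            out.append(" ")
        else:
            out.append(ch)
    tokens = []
    for tok in "".join(out).split():
        tok = tok.strip("-")
        if tok:
            tokens.append(tok)
    return tokens


def _surface(text: str) -> str:
    """Normalized surface form: space-joined normalized tokens."""
    return " ".join(normalize(text))


def permute_comma_inverted(name: str) -> list[str]:
    """Surface variants of a (possibly comma-inverted) ontology name.

    MeSH lists many headings in inverted display order; all rotations of the
    comma-separated segments are generated so both "scleroderma systemic"
    and "systemic scleroderma" resolve to the same term.  Output is the
    de-duplicated list of normalized surfaces, identity form first.
    """
    segments = [s.strip() for s in name.split(",") if s.strip()]
    variants: list[str] = []
    forms = [name] if len(segments) < 2 else [
        " ".join(segments[i:] + segments[:i]) for i in range(len(segments))
    ]
    for form in forms:
        s = _surface(form)
        if s and s not in variants:
            variants.append(s)
    return variants


@dataclass
class DictionaryTerm:
    """One row of the semantic model's term axis."""

    term_id: int
    canonical: str
    variants: set[str]
    source: str  # heading | entry_term | gene_symbol
    linked_heading: str | None = None

    @property
    def n_tokens(self) -> int:
        return len(self.canonical.split())


@dataclass
class MultiGramDictionary:
    """Dense term list plus an injective surface-form index."""

    terms: list[DictionaryTerm]
    surface_index: dict[str, int] = field(default_factory=dict)

    @property
    def max_ngram(self) -> int:
        return max((len(s.split()) for s in self.surface_index), default=1)

    def __len__(self) -> int:
        return len(self.terms)

    def lookup(self, text: str) -> int | None:
        """Resolve raw text to a term_id via its normalized surface."""
        return self.surface_index.get(_surface(text))

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for t in self.terms:
                variants = sorted(v for v in t.variants if v != t.canonical)
                fh.write(
                    "\t".join(
                        [str(t.term_id), t.canonical, t.source, t.linked_heading or "-"]
                        + variants
                    )
                    + "\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "MultiGramDictionary":
        """Reload a dictionary written by :meth:`to_tsv`.

        The surface index is rebuilt with the same collision priority used
        at build time, so a reload reproduces the original mapping.
        """
        terms: list[DictionaryTerm] = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                term_id, canonical, source, linked = fields[:4]
                variants = {canonical, *fields[4:]}
                terms.append(
                    DictionaryTerm(
                        term_id=int(term_id),
                        canonical=canonical,
                        variants=variants,
                        source=source,
                        linked_heading=None if linked == "-" else linked,
                    )
                )
        surface_index: dict[str, int] = {}
        claim_rank: dict[str, int] = {}
        for t in terms:
            rank = _SOURCE_PRIORITY[t.source]
            for surf in sorted(t.variants):
                if surf not in surface_index or rank < claim_rank[surf]:
                    surface_index[surf] = t.term_id
                    claim_rank[surf] = rank
        return cls(terms=terms, surface_index=surface_index)


def build_dictionary(
    tree: OntologyTree,
    selected: list[str],
    gene_symbols: list[str] | None = None,
) -> MultiGramDictionary:
    """Build the multi-gram dictionary for a selected heading set.

    One term per selected heading, in selection order, whose variants are the
    comma-rotation surfaces of the preferred name plus those of every entry
    term; then one term per gene symbol (lexicographic order) whose surface
    is not already claimed.  Surface collisions resolve by source priority
    heading > entry_term > gene_symbol, then by earlier term_id.
    """
    if not selected:
        raise ValueError("empty heading selection")
    gene_symbols = gene_symbols or []

    terms: list[DictionaryTerm] = []
    surface_index: dict[str, int] = {}
    # priority of the claim currently holding each surface
    claim_rank: dict[str, int] = {}

    def claim(surface: str, term_id: int, source: str) -> bool:
        rank = _SOURCE_PRIORITY[source]
        if surface in surface_index:
            if rank >= claim_rank[surface]:
                return False
            logger.info(
                "surface %r reassigned from term %d to term %d (%s outranks)",
                surface, surface_index[surface], term_id, source,
            )
        surface_index[surface] = term_id
        claim_rank[surface] = rank
        return True

    for hid in selected:
        heading = tree[hid]
        term_id = len(terms)
        variants: set[str] = set()
        canonical = None
        for raw, source in [(heading.preferred_name, "heading")] + [
            (e, "entry_term") for e in heading.entry_terms
        ]:
            for surf in permute_comma_inverted(raw):
                if len(surf.split()) > MAX_NGRAM:
                    logger.info("dropping over-long surface %r (> %d tokens)", surf, MAX_NGRAM)
                    continue
                if canonical is None:
                    canonical = surf
                if claim(surf, term_id, source) or surface_index.get(surf) == term_id:
                    variants.add(surf)
        if canonical is None:
            # preferred name longer than the n-gram cap: keep it anyway so the
            # heading still owns >= 1 surface
            canonical = _surface(heading.preferred_name)
            claim(canonical, term_id, "heading")
        variants.add(canonical)
        terms.append(
            DictionaryTerm(
                term_id=term_id,
                canonical=canonical,
                variants=variants,
                source="heading",
                linked_heading=hid,
            )
        )

    seen_symbols: set[str] = set()
    for symbol in sorted(gene_symbols):
        surf = _surface(symbol)
        if not surf:
            continue
        if surf in seen_symbols:
            logger.warning("duplicate gene symbol %r ignored", symbol)
            continue
        seen_symbols.add(surf)
        if surf in surface_index:
            logger.info("gene symbol %r collides with an ontology surface; dropped", symbol)
            continue
        term_id = len(terms)
        claim(surf, term_id, "gene_symbol")
        terms.append(
            DictionaryTerm(
                term_id=term_id,
                canonical=surf,
                variants={surf},
                source="gene_symbol",
                linked_heading=None,
            )
        )
    return MultiGramDictionary(terms=terms, surface_index=surface_index)


def read_gene_symbols(path) -> list[str]:
    """Read a gene-symbol list: one symbol per line, '#' comments allowed."""
    symbols = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                symbols.append(line)
    return symbols
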