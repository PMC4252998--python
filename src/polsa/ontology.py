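"""Ontology parsing, heading selection, and ancestor-chain lookup.

The semantic space is built over a set of controlled-vocabulary headings
(MeSH-style descriptors).  Each heading carries one or more dotted *tree
numbers* encoding its positions in a polyhierarchy; the first character of
a tree number is its top-level category letter (C = Diseases, D = Chemicals
and Drugs, ...).  Headings are selected for modelling by how many abstracts
are annotated with them: very rare and very common headings are excluded,
and at least half of the modelled set must come from the Disease category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "Heading",
    "OntologyTree",
    "SelectionConfig",
    "OntologyError",
    "parse_ontology",
    "select_headings",
    "ancestor_chain",
]


class OntologyError(ValueError):
    """Raised for malformed ontology input or impossible selection."""


@dataclass
class Heading:
    """A single ontology concept.

    Parameters
    ----------
    heading_id : str
        Opaque descriptor identifier (e.g. ``"D011014"``).
    preferred_name : str
        Display name; must be non-empty.
    entry_terms : list of str
        Synonym surface forms listed under the descriptor.
    tree_numbers : list of str
        Dotted hierarchy paths such as ``"C04.557.450"``.
    abstract_count : int
        Number of corpus abstracts annotated with this heading.
    """

    heading_id: str
    preferred_name: str
    entry_terms: list[str] = field(default_factory=list)
    tree_numbers: list[str] = field(default_factory=list)
    abstract_count: int = 0

    def __post_init__(self) -> None:
        if not self.preferred_name:
            raise OntologyError(f"heading {self.heading_id!r}: empty preferred name")
        if self.abstract_count < 0:
            raise OntologyError(f"heading {self.heading_id!r}: negative abstract count")

    @property
    def categories(self) -> frozenset[str]:
        """Top-level category letters, one per tree-number first character."""
        return frozenset(tn[0] for tn in self.tree_numbers if tn)


class OntologyTree:
    """Collection of :class:`Heading` objects with prefix-derived parenthood.

    The parent of tree number ``"C04.557.450"`` is ``"C04.557"``; a depth-1
    tree number's parent is its category root letter.  Cycles are impossible
    by construction.
    """

    def __init__(self, headings: list[Heading]):
        self.headings: dict[str, Heading] = {}
        self._by_tree_number: dict[str, str] = {}
        self._by_name: dict[str, str] = {}
        for h in headings:
            if h.heading_id in self.headings:
                raise OntologyError(f"duplicate heading_id {h.heading_id!r}")
            self.headings[h.heading_id] = h
        for h in headings:
            for tn in h.tree_numbers:
                self._by_tree_number[tn] = h.heading_id
            for name in [h.preferred_name, *h.entry_terms]:
                self._by_name.setdefault(name.strip().lower(), h.heading_id)

    def __len__(self) -> int:
        return len(self.headings)

    def __contains__(self, heading_id: str) -> bool:
        return heading_id in self.headings

    def __getitem__(self, heading_id: str) -> Heading:
        return self.headings[heading_id]

    def heading_for_tree_number(self, tree_number: str) -> str | None:
        return self._by_tree_number.get(tree_number)

    def heading_for_name(self, name: str) -> str | None:
        """Resolve a preferred name or entry term (case-insensitive)."""
        return self._by_name.get(name.strip().lower())

    @staticmethod
    def parent_tree_number(tree_number: str) -> str | None:
        """Prefix parent; category-letter root for depth-1; None at a letter."""
        if "." in tree_number:
            return tree_number.rsplit(".", 1)[0]
        if len(tree_number) > 1:
            return tree_number[0]
        return None


@dataclass(frozen=True)
class SelectionConfig:
    """Heading-selection heuristics.

    Headings with fewer than ``min_abstracts`` or more than ``max_abstracts``
    annotated abstracts are excluded (bounds inclusive: the endpoints
    themselves pass).  At least ``disease_fraction`` of the selected set must
    carry category C.
    """

    min_abstracts: int = 1000
    max_abstracts: int = 50000
    disease_fraction: float = 0.5
    allowed_categories: frozenset[str] = frozenset("CDFGIJMN")

    def __post_init__(self) -> None:
        if not 0 < self.disease_fraction <= 1:
            raise ValueError("disease_fraction must be in (0, 1]")
        if self.min_abstracts >= self.max_abstracts:
            raise ValueError("min_abstracts must be < max_abstracts")


# ---------------------------------------------------------------------------
# parsing


def parse_ontology(path, format: str = "tsv") -> OntologyTree:
    """Parse an ontology file into an :class:`OntologyTree`.

    ``format="mesh-xml"`` reads MeSH DescriptorRecordSet XML (descriptor UI,
    preferred name, entry terms from the concept/term lists, tree numbers);
    abstract counts are left at 0 and attached later from corpus annotation
    tallies.  ``format="tsv"`` reads the simplified 5-column dialect::

        heading_id <TAB> preferred_name <TAB> entry|terms <TAB> tree|numbers <TAB> abstract_count
    """
    if format == "mesh-xml":
        return _parse_mesh_xml(path)
    if format == "tsv":
        return _parse_tsv(path)
    raise ValueError(f"unknown ontology format {format!r}")


def _parse_mesh_xml(path) -> OntologyTree:
    try:
        doc = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise OntologyError(f"malformed ontology XML {path}: {exc}") from exc
    headings = []
    for rec in doc.iter("DescriptorRecord"):
        ui = rec.findtext("DescriptorUI")
        name = rec.findtext("DescriptorName/String")
        if not ui or not name:
            line = rec.sourceline
            raise OntologyError(f"descriptor record at line {line}: missing UI or name")
        entry_terms = []
        for term in rec.iter("Term"):
            s = term.findtext("String")
            if s and s != name and s not in entry_terms:
                entry_terms.append(s)
        tree_numbers = [tn.text for tn in rec.iter("TreeNumber") if tn.text]
        headings.append(
            Heading(
                heading_id=ui,
                preferred_name=name,
                entry_terms=entry_terms,
                tree_numbers=tree_numbers,
            )
        )
    if not headings:
        raise OntologyError(f"no descriptor records found in {path}")
    return OntologyTree(headings)


def _parse_tsv(path) -> OntologyTree:
    headings = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise OntologyError(
                    f"{path} line {lineno}: expected 5 tab-separated fields, got {len(fields)}"
                )
            hid, name, entry, trees, count = fields
            try:
                abstract_count = int(count)
            except ValueError as exc:
                raise OntologyError(f"{path} line {lineno}: bad abstract count {count!r}") from exc
            headings.append(
                Heading(
                    heading_id=hid,
                    preferred_name=name,
                    entry_terms=[t for t in entry.split("|") if t],
                    tree_numbers=[t for t in trees.split("|") if t],
                    abstract_count=abstract_count,
                )
            )
    if not headings:
        raise OntologyError(f"empty ontology file {path}")
    return OntologyTree(headings)


# ---------------------------------------------------------------------------
# selection


def select_headings(tree: OntologyTree, cfg: SelectionConfig | None = None) -> list[str]:
    """Select the modelled heading set under the balance heuristics.

    A heading qualifies when its abstract count lies within the inclusive
    ``[min_abstracts, max_abstracts]`` window and it carries at least one
    allowed category letter.  The Disease-category floor is then enforced by
    dropping non-C headings, lowest abstract count first, until at least
    ``disease_fraction`` of the remaining set carries category C — so the
    selection is maximal subject to the constraint.  Output order is
    descending abstract count with heading_id tie-break.
    """
    cfg = cfg or SelectionConfig()
    candidates = [
        h
        for h in tree.headings.values()
        if cfg.min_abstracts <= h.abstract_count <= cfg.max_abstracts
        and h.categories & cfg.allowed_categories
    ]
    if not candidates:
        raise OntologyError("empty selection: no heading satisfies the count bounds")
    candidates.sort(key=lambda h: (-h.abstract_count, h.heading_id))

    is_disease = ["C" in h.categories for h in candidates]
    if not any(is_disease):
        raise OntologyError(
            "disease fraction unachievable: no category-C heading within count bounds"
        )
    n_c = sum(is_disease)
    selected = list(candidates)
    # drop lowest-count non-C headings until the C fraction holds
    while n_c < cfg.disease_fraction * len(selected):
        for i in range(len(selected) - 1, -1, -1):
            if "C" not in selected[i].categories:
                del selected[i]
                break
        else:  # pragma: no cover - unreachable: all-C satisfies any fraction
            break
    return [h.heading_id for h in selected]


def ancestor_chain(
    tree: OntologyTree, heading_id: str, tree_number: str
) -> list[tuple[str, str]]:
    """Full path from the depth-1 ancestor down to the heading itself.

    Returns ``(name, tree_number)`` pairs; consecutive entries differ by one
    dotted component.  Intermediate positions not owned by any heading in the
    tree are named by their tree number.
    """
    heading = tree[heading_id]
    if tree_number not in heading.tree_numbers:
        raise OntologyError(
            f"tree number {tree_number!r} does not belong to heading {heading_id!r}"
        )
    parts = tree_number.split(".")
    chain = []
    for depth in range(1, len(parts) + 1):
        tn = ".".join(parts[:depth])
        owner = tree.heading_for_tree_number(tn)
        name = tree[owner].preferred_name if owner else tn
        chain.append((name, tn))
    return chain


def render_path(chain: list[tuple[str, str]]) -> str:
    """Render an ancestor chain as ``"Ancestor > ... > Heading"``."""
    return " > ".join(name for name, _ in chain)


def write_ontology_tsv(tree: OntologyTree, path) -> None:
    """Write a tree back out in the 5-column TSV dialect."""
    with open(path, "w", encoding="utf-8") as fh:
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
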