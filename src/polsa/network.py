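"""Reverse Ontology Mapping: association networks from relevant headings.

Headings judged relevant for a query are re-attached to their full ontology
ancestor chains; shared ancestors merge into single nodes, so the result is
a collapsible hierarchy rooted at the query.  A heading placed at several
tree positions (polyhierarchy) appears once per position, while
``n_relevant`` counts distinct headings.  The hierarchy serializes to the
D3 "flare" JSON dialect consumed by collapsible-tree renderers, and to a
flat edge-list TSV for generic graph tools.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from .ontology import OntologyTree, ancestor_chain
from .relevance import GROUP_LABELS, RelevanceAssignment
from .semantic import RankedHeading

logger = logging.getLogger(__name__)

__all__ = ["AssociationNode", "AssociationNetwork", "build_network", "to_json", "to_edge_list"]


@dataclass
class AssociationNode:
    name: str
    tree_number: str | None = None
    heading_id: str | None = None
    cosine: float | None = None
    group: str | None = None
    children: list["AssociationNode"] = field(default_factory=list)

    def child(self, name: str) -> "AssociationNode | None":
        for c in self.children:
            if c.name == name:
                return c
        return None

    def best_cosine(self) -> float:
        """Best cosine among this node and its descendants (-inf if none)."""
        best = self.cosine if self.cosine is not None else float("-inf")
        for c in self.children:
            best = max(best, c.best_cosine())
        return best


@dataclass
class AssociationNetwork:
    query: str
    root: AssociationNode
    n_relevant: int


def build_network(
    query: str,
    assignments: list[RelevanceAssignment],
    ranked: list[RankedHeading],
    tree: OntologyTree,
    include_groups: frozenset[str] | set[str] = frozenset({"highly", "possibly"}),
) -> AssociationNetwork:
    """Build the hierarchical association network for one query.

    Headings whose relevance group is in ``include_groups`` are attached
    under their ancestor chains (one leaf per tree number); children at each
    level are sorted by their best descendant cosine, descending, so the
    strongest associations read top-down.
    """
    unknown = set(include_groups) - set(GROUP_LABELS)
    if unknown:
        raise ValueError(f"unknown relevance groups {sorted(unknown)}")
    cosine_of = {r.heading_id: r.cosine for r in ranked}
    root = AssociationNode(name=query)
    relevant_ids: set[str] = set()
    for a in assignments:
        if a.group not in include_groups:
            continue
        if a.heading_id not in cosine_of:
            raise ValueError(f"assignment for {a.heading_id!r} has no ranked cosine")
        heading = tree[a.heading_id]
        if not heading.tree_numbers:
            logger.warning("relevant heading %s has no tree number; skipped", a.heading_id)
            continue
        relevant_ids.add(a.heading_id)
        for tn in heading.tree_numbers:
            chain = ancestor_chain(tree, a.heading_id, tn)
            node = root
            for name, chain_tn in chain[:-1]:
                nxt = node.child(name)
                if nxt is None:
                    nxt = AssociationNode(name=name, tree_number=chain_tn)
                    node.children.append(nxt)
                node = nxt
            leaf_name, leaf_tn = chain[-1]
            leaf = node.child(leaf_name)
            if leaf is None:
                leaf = AssociationNode(name=leaf_name, tree_number=leaf_tn)
                node.children.append(leaf)
            leaf.heading_id = a.heading_id
            leaf.cosine = cosine_of[a.heading_id]
            leaf.group = a.group
    if not relevant_ids:
        logger.warning("no relevant heading for query %r: root-only network", query)
    _sort_children(root)
    return AssociationNetwork(query=query, root=root, n_relevant=len(relevant_ids))


def _sort_children(node: AssociationNode) -> None:
    for c in node.children:
        _sort_children(c)
    node.children.sort(key=lambda c: (-c.best_cosine(), c.name))


def _node_dict(node: AssociationNode) -> dict:
    # key order fixed: name, cosine, group, heading_id, tree_number, children
    d: dict = {"name": node.name}
    if node.cosine is not None:
        d["cosine"] = node.cosine
    if node.group is not None:
        d["group"] = node.group
    if node.heading_id is not None:
        d["heading_id"] = node.heading_id
    if node.tree_number is not None:
        d["tree_number"] = node.tree_number
    d["children"] = [_node_dict(c) for c in node.children]
    return d


def to_json(net: AssociationNetwork) -> str:
    """Deterministic D3 flare-hierarchy JSON (byte-identical across runs)."""
    return json.dumps(_node_dict(net.root), ensure_ascii=False, indent=1) + "\n"


def from_json(text: str) -> AssociationNode:
    """Parse flare JSON back into an :class:`AssociationNode` tree."""

    def build(d: dict) -> AssociationNode:
        return AssociationNode(
            name=d["name"],
            tree_number=d.get("tree_number"),
            heading_id=d.get("heading_id"),
            cosine=d.get("cosine"),
            group=d.get("group"),
            children=[build(c) for c in d.get("children", [])],
        )

    return build(json.loads(text))


def to_edge_list(net: AssociationNetwork) -> str:
    """Flat TSV: parent_name, child_name, heading_id, cosine, group."""
    lines = ["parent_name\tchild_name\theading_id\tcosine\tgroup"]

    def walk(node: AssociationNode) -> None:
        for c in node.children:
            lines.append(
                "\t".join(
                    [
                        node.name,
                        c.name,
                        c.heading_id or "-",
                        f"{c.cosine:.6f}" if c.cosine is not None else "-",
                        c.group or "-",
                    ]
                )
            )
            walk(c)

    walk(net.root)
    return "\n".join(lines) + "\n"
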