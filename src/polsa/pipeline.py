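"""End-to-end orchestration: ontology -> dictionary -> counts -> model -> query.

Thin composition layer used by the command-line interface and the test
suite; all the science lives in the stage modules.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .corpus import AbstractRecord, accumulate_counts
from .dictionary import MultiGramDictionary, build_dictionary
from .network import AssociationNetwork, build_network
from .ontology import OntologyTree, write_ontology_tsv
from .relevance import RelevanceAssignment, RelevanceConfig, assign_groups
from .semantic import (
    ModelConfig,
    RankedHeading,
    SemanticModel,
    embed_query,
    fit,
    rank_headings,
    tfidf_weight,
)

logger = logging.getLogger(__name__)

__all__ = ["BuildResult", "QueryResult", "build_model", "run_query", "save_archive", "load_archive"]


@dataclass
class BuildResult:
    tree: OntologyTree
    selection: list[str]
    dictionary: MultiGramDictionary
    model: SemanticModel
    n_records: int


@dataclass
class QueryResult:
    query: str
    ranked: list[RankedHeading]
    assignments: list[RelevanceAssignment]
    network: AssociationNetwork


def build_model(
    tree: OntologyTree,
    selection: list[str],
    gene_symbols: list[str],
    records: Iterable[AbstractRecord],
    model_config: ModelConfig | None = None,
) -> BuildResult:
    """Run dictionary build, counting, TF-IDF and SVD in order."""
    dictionary = build_dictionary(tree, selection, gene_symbols)
    n_records = 0

    def counted(recs):
        nonlocal n_records
        for r in recs:
            n_records += 1
            yield r

    counts = accumulate_counts(counted(records), dictionary, selection)
    weighted, idf = tfidf_weight(counts)
    model = fit(weighted, counts, idf, model_config)
    return BuildResult(
        tree=tree,
        selection=selection,
        dictionary=dictionary,
        model=model,
        n_records=n_records,
    )


def run_query(
    build: BuildResult,
    query: str,
    relevance_config: RelevanceConfig | None = None,
    include_groups: frozenset[str] = frozenset({"highly", "possibly"}),
) -> QueryResult:
    """Embed, rank, group, and build the association network for one query.

    A query that resolves only to uninformative terms (idf 0: present in
    every heading column) has a zero latent vector; it is ranked as all-zero
    cosines and grouped entirely "unknown" rather than rejected.
    """
    qvec = embed_query(build.model, [query], build.dictionary)
    if not qvec.latent.any() or qvec.norm == 0:
        logger.warning("query %r carries no discriminative signal (idf 0)", query)
        ranked = [
            RankedHeading(heading_id=hid, cosine=0.0, rank=r)
            for r, hid in enumerate(sorted(build.model.heading_ids), start=1)
        ]
    else:
        ranked = rank_headings(build.model, qvec)
    assignments = assign_groups(ranked, relevance_config, lenient=True)
    net = build_network(query, assignments, ranked, build.tree, include_groups)
    return QueryResult(query=query, ranked=ranked, assignments=assignments, network=net)


# ---------------------------------------------------------------------------
# archive persistence


def _digest_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def save_archive(build: BuildResult, directory, input_paths: dict[str, str] | None = None) -> Path:
    """Write the reloadable model archive: factors, labels, dictionary,
    ontology, and a manifest with input digests."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    build.model.save(d)
    build.dictionary.to_tsv(d / "dictionary.tsv")
    write_ontology_tsv(build.tree, d / "ontology.tsv")
    (d / "selection.txt").write_text(
        "".join(f"{h}\n" for h in build.selection), encoding="utf-8"
    )
    manifest = json.loads((d / "manifest.json").read_text(encoding="utf-8"))
    manifest["n_records"] = build.n_records
    manifest["input_digests"] = {
        name: _digest_file(Path(p)) for name, p in (input_paths or {}).items()
    }
    manifest["model_digest"] = model_digest(d)
    (d / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return d


def model_digest(directory) -> str:
    """Digest of the factor matrices and labels identifying a fitted model."""
    d = Path(directory)
    h = hashlib.sha256()
    for name in ("singular_values.npy", "term_factors.npy", "heading_vectors.npy",
                 "idf.npy", "heading_ids.txt", "term_ids.txt", "dictionary.tsv"):
        h.update(name.encode())
        h.update((d / name).read_bytes())
    return h.hexdigest()


def load_archive(directory) -> BuildResult:
    """Reload a saved archive without refitting."""
    from .ontology import parse_ontology

    d = Path(directory)
    model = SemanticModel.load(d)
    dictionary = MultiGramDictionary.from_tsv(d / "dictionary.tsv")
    tree = parse_ontology(d / "ontology.tsv", format="tsv")
    selection = (d / "selection.txt").read_text(encoding="utf-8").split()
    manifest = json.loads((d / "manifest.json").read_text(encoding="utf-8"))
    return BuildResult(
        tree=tree,
        selection=selection,
        dictionary=dictionary,
        model=model,
        n_records=manifest.get("n_records", 0),
    )
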