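"""Corpus readers, multi-gram matching, and term x heading counting.

Abstracts arrive either as MEDLINE plain text (PMID-/TI-/AB-/MH-/DP- tagged
fields with continuation-line unfolding) or as JSON lines.  Each record's
title and abstract are tokenized and scanned with a greedy leftmost-longest
multi-gram matcher against the dictionary; matched term counts are pooled
into the columns of every selected heading the record is annotated with.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import scipy.io
import scipy.sparse as sp

from .dictionary import MultiGramDictionary, normalize
from .ontology import OntologyTree

logger = logging.getLogger(__name__)

__all__ = [
    "AbstractRecord",
    "TermHeadingCounts",
    "read_corpus",
    "match_multigrams",
    "accumulate_counts",
]


@dataclass
class AbstractRecord:
    record_id: str
    year: int
    title: str
    abstract: str
    annotations: list[str] = field(default_factory=list)


def read_corpus(
    path, format: str = "jsonl", tree: OntologyTree | None = None
) -> Iterator[AbstractRecord]:
    """Stream abstract records from a corpus file.

    For the MEDLINE dialect, MH values (qualifiers stripped at "/") are
    resolved to heading ids through ``tree``; unmatched values are logged and
    skipped.  The JSONL dialect carries heading ids directly under
    ``"headings"``.
    """
    if format == "jsonl":
        yield from _read_jsonl(path)
    elif format == "medline":
        if tree is None:
            raise ValueError("MEDLINE corpus requires an ontology tree for MH lookup")
        yield from _read_medline(path, tree)
    else:
        raise ValueError(f"unknown corpus format {format!r}")


def _read_jsonl(path) -> Iterator[AbstractRecord]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path} line {lineno}: invalid JSON ({exc})") from exc
            if not obj.get("id"):
                logger.warning("%s line %d: record missing id, skipped", path, lineno)
                continue
            yield AbstractRecord(
                record_id=str(obj["id"]),
                year=int(obj.get("year", 0)),
                title=obj.get("title", ""),
                abstract=obj.get("abstract", ""),
                annotations=list(obj.get("headings", [])),
            )


def _read_medline(path, tree: OntologyTree) -> Iterator[AbstractRecord]:
    with open(path, encoding="utf-8") as fh:
        fields: list[tuple[str, str]] = []
        for raw in list(fh) + [""]:
            line = raw.rstrip("\n")
            if not line.strip():
                if fields:
                    rec = _medline_record(fields, tree)
                    if rec is not None:
                        yield rec
                    fields = []
                continue
            if line.startswith("      ") and fields:
                tag, value = fields[-1]
                fields[-1] = (tag, value + " " + line.strip())
            else:
                tag, _, value = line.partition("- ")
                fields.append((tag.strip(), value.strip()))


def _medline_record(fields: list[tuple[str, str]], tree: OntologyTree) -> AbstractRecord | None:
    pmid = title = abstract = ""
    year = 0
    annotations: list[str] = []
    for tag, value in fields:
        if tag == "PMID":
            pmid = value
        elif tag == "TI":
            title = value
        elif tag == "AB":
            abstract = value
        elif tag == "DP":
            digits = "".join(c if c.isdigit() else " " for c in value).split()
            for d in digits:
                if len(d) == 4:
                    year = int(d)
                    break
        elif tag == "MH":
            name = value.lstrip("*").split("/", 1)[0].strip()
            hid = tree.heading_for_name(name)
            if hid is None:
                logger.info("unmatched MH value %r skipped", value)
            elif hid not in annotations:
                annotations.append(hid)
    if not pmid:
        logger.warning("MEDLINE record without PMID skipped")
        return None
    return AbstractRecord(pmid, year, title, abstract, annotations)


# ---------------------------------------------------------------------------
# matching


def match_multigrams(
    tokens: list[str], dictionary: MultiGramDictionary
) -> list[tuple[int, int, int]]:
    """Greedy leftmost-longest multi-gram matching.

    At each position the longest window (up to the dictionary's max n-gram)
    whose space-joined form is a known surface is consumed; matched spans
    never overlap; unmatched tokens are skipped.  Returns
    ``(term_id, start, length)`` triples in left-to-right order.
    """
    index = dictionary.surface_index
    max_n = dictionary.max_ngram
    matches = []
    i = 0
    n = len(tokens)
    while i < n:
        for length in range(min(max_n, n - i), 0, -1):
            surface = " ".join(tokens[i : i + length])
            term_id = index.get(surface)
            if term_id is not None:
                matches.append((term_id, i, length))
                i += length
                break
        else:
            i += 1
    return matches


@dataclass
class TermHeadingCounts:
    """Sparse term x heading occurrence counts.

    Row order follows dictionary term_ids, column order the heading
    selection.  Column j totals the matched-term occurrences over all records
    annotated with heading j (a record annotated with k selected headings
    contributes its full counts to all k columns).
    """

    counts: sp.csr_matrix
    term_ids: list[int]
    heading_ids: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def save(self, matrix_path, row_labels_path, col_labels_path) -> None:
        """MatrixMarket coordinate file plus sidecar label files."""
        scipy.io.mmwrite(str(matrix_path), self.counts.tocoo())
        with open(row_labels_path, "w", encoding="utf-8") as fh:
            fh.writelines(f"{t}\n" for t in self.term_ids)
        with open(col_labels_path, "w", encoding="utf-8") as fh:
            fh.writelines(f"{h}\n" for h in self.heading_ids)

    @classmethod
    def load(cls, matrix_path, row_labels_path, col_labels_path) -> "TermHeadingCounts":
        counts = sp.csr_matrix(scipy.io.mmread(str(matrix_path)))
        with open(row_labels_path, encoding="utf-8") as fh:
            term_ids = [int(line.strip()) for line in fh if line.strip()]
        with open(col_labels_path, encoding="utf-8") as fh:
            heading_ids = [line.strip() for line in fh if line.strip()]
        return cls(counts=counts, term_ids=term_ids, heading_ids=heading_ids)


def accumulate_counts(
    records: Iterable[AbstractRecord],
    dictionary: MultiGramDictionary,
    selected: list[str],
) -> TermHeadingCounts:
    """Accumulate matched-term counts over a record stream.

    Annotations outside ``selected`` are ignored; a record with no selected
    annotation contributes nothing.
    """
    col_of = {hid: j for j, hid in enumerate(selected)}
    T, H = len(dictionary), len(selected)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[int] = []
    n_records = n_contributing = 0
    for rec in records:
        n_records += 1
        heading_cols = [col_of[h] for h in rec.annotations if h in col_of]
        if not heading_cols:
            continue
        tokens = normalize(rec.title + " " + rec.abstract)
        matches = match_multigrams(tokens, dictionary)
        if not matches:
            continue
        n_contributing += 1
        term_counts: dict[int, int] = {}
        for term_id, _, _ in matches:
            term_counts[term_id] = term_counts.get(term_id, 0) + 1
        for j in heading_cols:
            for term_id, c in term_counts.items():
                rows.append(term_id)
                cols.append(j)
                vals.append(c)
    if n_contributing == 0:
        logger.warning("no record contributed any matched term: counts are all zero")
    counts = sp.coo_matrix(
        (np.asarray(vals, dtype=np.int64), (rows, cols)), shape=(T, H)
    ).tocsr()
    counts.sum_duplicates()
    return TermHeadingCounts(
        counts=counts,
        term_ids=[t.term_id for t in dictionary.terms],
        heading_ids=list(selected),
    )
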