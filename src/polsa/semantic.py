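"""Phrase-ontology LSA core: TF-IDF weighting, energy-truncated SVD,
query folding-in, and cosine ranking of headings.

The term x heading count matrix C is weighted as

    W[t, h] = C[t, h] * ln(H / df_t),     df_t = #{h : C[t, h] > 0}

(raw term frequency times log inverse document frequency, columns playing
the document role).  W = U S V' is decomposed by SVD and truncated at the
smallest rank k whose cumulative squared-singular-value ("energy") fraction
reaches the configured threshold (default 95%).  Headings live at V_k S_k
(document coordinates); a query is folded in as an idf-weighted
pseudo-document q via q' U_k and compared to headings by cosine.
"""

from __future__ import annotations

import difflib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg
import scipy.sparse as sp

from .corpus import TermHeadingCounts
from .dictionary import MultiGramDictionary, _surface, normalize

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "SemanticModel",
    "RankedHeading",
    "QueryError",
    "tfidf_weight",
    "fit",
    "embed_query",
    "rank_headings",
]


class QueryError(ValueError):
    """Raised when a query resolves to nothing usable in the model."""


@dataclass(frozen=True)
class ModelConfig:
    """Model hyperparameters.

    energy_threshold : fraction of total squared-singular-value energy the
        truncated factorization must retain (in (0, 1], default 0.95).
    query_idf_weighting : weight resolved query terms by their idf (default)
        rather than raw 0/1 indicators.
    """

    energy_threshold: float = 0.95
    query_idf_weighting: bool = True
    tfidf_variant: str = "raw-tf x log-idf"

    def __post_init__(self) -> None:
        if not 0 < self.energy_threshold <= 1:
            raise ValueError("energy_threshold must be in (0, 1]")


def tfidf_weight(counts: TermHeadingCounts) -> tuple[sp.csr_matrix, np.ndarray]:
    """Weight raw counts as tf * ln(H/df); returns (weighted matrix, idf).

    A term occurring in every heading column gets idf 0 (all-zero row); a
    term occurring nowhere also gets idf 0.
    """
    C = counts.counts.tocsr()
    if C.nnz == 0:
        raise ValueError("all-zero count matrix: nothing to weight")
    H = C.shape[1]
    df = np.asarray((C > 0).sum(axis=1)).ravel()
    idf = np.zeros(C.shape[0])
    nz = df > 0
    idf[nz] = np.log(H / df[nz])
    W = sp.diags(idf) @ C.astype(np.float64)
    return W.tocsr(), idf


@dataclass
class SemanticModel:
    """Truncated-SVD semantic space over dictionary terms and headings."""

    k: int
    singular_values: np.ndarray  # (k,), positive, non-increasing
    term_factors: np.ndarray  # (T, k)  left singular vectors U_k
    heading_vectors: np.ndarray  # (H, k)  V_k S_k document coordinates
    idf: np.ndarray  # (T,)
    energy_fraction: float
    heading_ids: list[str]
    term_ids: list[int]
    config: ModelConfig = ModelConfig()

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> None:
        """Write the model archive: factor matrices, labels, manifest."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.save(d / "singular_values.npy", self.singular_values)
        np.save(d / "term_factors.npy", self.term_factors)
        np.save(d / "heading_vectors.npy", self.heading_vectors)
        np.save(d / "idf.npy", self.idf)
        (d / "heading_ids.txt").write_text(
            "".join(f"{h}\n" for h in self.heading_ids), encoding="utf-8"
        )
        (d / "term_ids.txt").write_text(
            "".join(f"{t}\n" for t in self.term_ids), encoding="utf-8"
        )
        manifest = {
            "k": self.k,
            "energy_fraction": self.energy_fraction,
            "energy_threshold": self.config.energy_threshold,
            "query_idf_weighting": self.config.query_idf_weighting,
            "n_terms": len(self.term_ids),
            "n_headings": len(self.heading_ids),
        }
        (d / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )

    @classmethod
    def load(cls, directory) -> "SemanticModel":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text(encoding="utf-8"))
        return cls(
            k=manifest["k"],
            singular_values=np.load(d / "singular_values.npy"),
            term_factors=np.load(d / "term_factors.npy"),
            heading_vectors=np.load(d / "heading_vectors.npy"),
            idf=np.load(d / "idf.npy"),
            energy_fraction=manifest["energy_fraction"],
            heading_ids=(d / "heading_ids.txt").read_text(encoding="utf-8").split(),
            term_ids=[
                int(t) for t in (d / "term_ids.txt").read_text(encoding="utf-8").split()
            ],
            config=ModelConfig(
                energy_threshold=manifest["energy_threshold"],
                query_idf_weighting=manifest.get("query_idf_weighting", True),
            ),
        )


@dataclass(frozen=True)
class RankedHeading:
    heading_id: str
    cosine: float
    rank: int  # 1-based


@dataclass(frozen=True)
class QueryVector:
    """A folded-in query: latent coordinates plus the original norm.

    ``norm`` is the Euclidean norm of the pseudo-document in the full term
    space, kept separately because folding-in drops any component outside
    the factor span; using it as the cosine denominator makes full-rank
    latent cosines agree exactly with original-space cosines.
    """

    latent: np.ndarray
    norm: float


def fit(
    weighted: sp.spmatrix,
    counts: TermHeadingCounts,
    idf: np.ndarray,
    config: ModelConfig | None = None,
) -> SemanticModel:
    """Fit the truncated SVD at the configured energy threshold.

    Retains the smallest k with sum_{i<=k} s_i^2 / sum_all s_i^2 >= threshold;
    LAPACK's deterministic full SVD is used (the matrices here are heading
    spaces, thousands of columns at most), so repeated fits are bit-identical.
    """
    config = config or ModelConfig()
    W = np.asarray(weighted.todense() if sp.issparse(weighted) else weighted, dtype=np.float64)
    if not W.any():
        raise ValueError("weighted matrix is all zero; cannot fit")
    try:
        U, s, Vt = scipy.linalg.svd(W, full_matrices=False, lapack_driver="gesdd")
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rare LAPACK failure
        raise RuntimeError(f"SVD failed to converge: {exc}") from exc
    tol = s[0] * max(W.shape) * np.finfo(np.float64).eps
    s = s[s > tol]
    energy = s**2
    frac = np.cumsum(energy) / energy.sum()
    k = int(np.searchsorted(frac, config.energy_threshold - 1e-12) + 1)
    k = min(k, len(s))
    return SemanticModel(
        k=k,
        singular_values=s[:k].copy(),
        term_factors=U[:, :k].copy(),
        heading_vectors=(Vt[:k].T * s[:k]).copy(),
        idf=np.asarray(idf, dtype=np.float64),
        energy_fraction=float(frac[k - 1]),
        heading_ids=list(counts.heading_ids),
        term_ids=list(counts.term_ids),
        config=config,
    )


def embed_query(
    model: SemanticModel,
    query_terms: list[str],
    dictionary: MultiGramDictionary,
) -> np.ndarray:
    """Fold a query into the latent space as an idf-weighted pseudo-document.

    Each query term is resolved through the dictionary surface index (its
    full normalized surface first, then greedy multi-gram matching over its
    tokens); resolved terms contribute idf_t (or 1 if idf weighting is off)
    to a length-T pseudo-document q, projected as q' U_k.  Raises
    :class:`QueryError`, with near-miss suggestions, when nothing resolves.
    """
    q = np.zeros(len(model.term_ids))
    resolved = False
    for term in query_terms:
        term_ids = []
        tid = dictionary.lookup(term)
        if tid is not None:
            term_ids = [tid]
        else:
            from .corpus import match_multigrams

            term_ids = [m[0] for m in match_multigrams(normalize(term), dictionary)]
        for tid in term_ids:
            resolved = True
            weight = model.idf[tid] if model.config.query_idf_weighting else 1.0
            q[tid] += weight
    if not resolved:
        surfaces = list(dictionary.surface_index)
        near = difflib.get_close_matches(_surface(" ".join(query_terms)), surfaces, n=5)
        raise QueryError(
            f"query {' '.join(query_terms)!r} is out of dictionary"
            + (f"; did you mean: {', '.join(near)}?" if near else "")
        )
    return QueryVector(latent=q @ model.term_factors, norm=float(np.linalg.norm(q)))


def rank_headings(
    model: SemanticModel, query_vec: QueryVector | np.ndarray
) -> list[RankedHeading]:
    """Rank all headings by cosine similarity to the query vector.

    Descending cosine, ties broken by heading_id; all-zero heading rows get
    cosine 0; cosines are clipped to [-1, 1].  A plain array is treated as a
    latent vector whose own norm is the cosine denominator.
    """
    if isinstance(query_vec, QueryVector):
        latent, qn = query_vec.latent, query_vec.norm
    else:
        latent = np.asarray(query_vec)
        qn = float(np.linalg.norm(latent))
    if qn == 0 or not latent.any():
        raise QueryError("zero query vector cannot be ranked")
    norms = np.linalg.norm(model.heading_vectors, axis=1)
    cos = np.zeros(len(norms))
    nz = norms > 0
    cos[nz] = (model.heading_vectors[nz] @ latent) / (norms[nz] * qn)
    cos[np.abs(cos) < 1e-12] = 0.0  # rotation noise on orthogonal headings
    cos = np.clip(cos, -1.0, 1.0)
    order = sorted(range(len(cos)), key=lambda j: (-cos[j], model.heading_ids[j]))
    return [
        RankedHeading(heading_id=model.heading_ids[j], cosine=float(cos[j]), rank=r)
        for r, j in enumerate(order, start=1)
    ]
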