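"""Relevance model: fuzzy c-means over the 1-D cosine-score distribution.

Each query produces a score for every heading; rather than a fixed global
cutoff, the scores are soft-clustered into three groups — highly
associated, possibly associated, unknown — so the boundaries adapt to each
query's own score distribution (dynamic, data-driven cutoffs).

The clustering is the standard Bezdek fuzzy c-means iteration with
fuzzifier m (default 2): memberships

    u_ij = 1 / sum_l (|x_i - c_j| / |x_i - c_l|)^(2/(m-1))

and weighted-mean center updates, run until the centers move less than a
tolerance.  Centers are initialized at the 10th/50th/90th percentiles of
the scores, which makes the run deterministic without any seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .semantic import RankedHeading

logger = logging.getLogger(__name__)

__all__ = [
    "RelevanceConfig",
    "RelevanceAssignment",
    "DegenerateScoresError",
    "fuzzy_cmeans_1d",
    "assign_groups",
    "GROUP_LABELS",
]

#: Cluster labels ordered by ascending center.
GROUP_LABELS = ("unknown", "possibly", "highly")


class DegenerateScoresError(ValueError):
    """Raised when the score distribution has fewer than 3 distinct values."""


@dataclass(frozen=True)
class RelevanceConfig:
    n_clusters: int = 3
    fuzzifier: float = 2.0
    tolerance: float = 1e-6
    max_iterations: int = 300
    init: str = "percentile"

    def __post_init__(self) -> None:
        if self.n_clusters != 3:
            raise ValueError("the relevance model uses exactly 3 clusters")
        if self.fuzzifier <= 1:
            raise ValueError("fuzzifier must be > 1")


@dataclass
class RelevanceAssignment:
    """A heading's soft memberships, hard group, and the shared cutoffs.

    ``memberships`` follows :data:`GROUP_LABELS` order (unknown, possibly,
    highly); ``group`` is the label of the cutoff interval the score falls
    in; ``cutoff_low``/``cutoff_high`` are the midpoints between adjacent
    sorted cluster centers (identical across one query's assignments).
    """

    heading_id: str
    score: float
    memberships: tuple[float, float, float]
    group: str
    cutoff_low: float
    cutoff_high: float


def _fcm_memberships(x: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    """Membership matrix for points x against centers (singularity-safe)."""
    d = np.abs(x[:, None] - centers[None, :])
    u = np.zeros((len(x), len(centers)))
    exact = d < 1e-15
    hit = exact.any(axis=1)
    if hit.any():
        # a point coinciding with a center belongs there with membership 1
        # (split evenly across coincident centers if duplicated)
        u[hit] = exact[hit] / exact[hit].sum(axis=1, keepdims=True)
    free = ~hit
    if free.any():
        ratio = d[free][:, :, None] / d[free][:, None, :]
        u[free] = 1.0 / (ratio ** (2.0 / (m - 1.0))).sum(axis=2)
    return u


def fcm_objective(x: np.ndarray, centers: np.ndarray, u: np.ndarray, m: float) -> float:
    """Bezdek objective sum_ij u_ij^m (x_i - c_j)^2."""
    d2 = (x[:, None] - centers[None, :]) ** 2
    return float((u**m * d2).sum())


def fuzzy_cmeans_1d(
    scores,
    config: RelevanceConfig | None = None,
    objective_history: list[float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster 1-D scores into three fuzzy groups.

    Returns ``(centers, memberships)`` with centers sorted ascending and
    membership columns in the same order.  Raises
    :class:`DegenerateScoresError` for fewer than 3 distinct values; warns
    and returns the best iterate if the iteration has not converged within
    ``max_iterations``.  When ``objective_history`` is a list, the Bezdek
    objective after each center update is appended to it.
    """
    config = config or RelevanceConfig()
    x = np.asarray(scores, dtype=np.float64)
    if np.unique(x).size < config.n_clusters:
        raise DegenerateScoresError(
            "degenerate score distribution: need >= 3 distinct values"
        )
    m = config.fuzzifier
    centers = np.percentile(x, [10, 50, 90])
    # percentile init can duplicate centers on skewed data; nudge apart
    for j in range(1, len(centers)):
        if centers[j] <= centers[j - 1]:
            centers[j] = centers[j - 1] + 1e-9
    converged = False
    for _ in range(config.max_iterations):
        u = _fcm_memberships(x, centers, m)
        um = u**m
        new_centers = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if objective_history is not None:
            objective_history.append(fcm_objective(x, centers, _fcm_memberships(x, centers, m), m))
        if shift < config.tolerance:
            converged = True
            break
    if not converged:
        logger.warning(
            "fuzzy c-means did not converge in %d iterations; returning best iterate",
            config.max_iterations,
        )
    order = np.argsort(centers, kind="stable")
    centers = centers[order]
    u = _fcm_memberships(x, centers, m)
    return centers, u


def assign_groups(
    ranked: list[RankedHeading],
    config: RelevanceConfig | None = None,
    lenient: bool = False,
) -> list[RelevanceAssignment]:
    """Partition a ranking into highly / possibly / unknown groups.

    Clusters the cosine scores, labels clusters by center order (highest
    center = "highly"), and assigns each heading by the cutoff interval its
    score falls in, where the two cutoffs are midpoints between adjacent
    sorted centers.  Interval assignment keeps the groups contiguous in
    score even when fuzzy memberships would disagree near a boundary.

    With ``lenient=True`` a degenerate score distribution yields all-
    "unknown" assignments (with a warning) instead of an error.
    """
    if not ranked:
        raise ValueError("empty ranking")
    scores = np.array([r.cosine for r in ranked])
    try:
        centers, u = fuzzy_cmeans_1d(scores, config)
    except DegenerateScoresError:
        if not lenient:
            raise
        logger.warning("degenerate score distribution: grouping all headings as unknown")
        return [
            RelevanceAssignment(
                heading_id=r.heading_id,
                score=r.cosine,
                memberships=(1.0, 0.0, 0.0),
                group="unknown",
                cutoff_low=float("nan"),
                cutoff_high=float("nan"),
            )
            for r in ranked
        ]
    cutoff_low = float((centers[0] + centers[1]) / 2)
    cutoff_high = float((centers[1] + centers[2]) / 2)
    out = []
    for i, r in enumerate(ranked):
        if r.cosine > cutoff_high:
            group = "highly"
        elif r.cosine > cutoff_low:
            group = "possibly"
        else:
            group = "unknown"
        out.append(
            RelevanceAssignment(
                heading_id=r.heading_id,
                score=r.cosine,
                memberships=(float(u[i, 0]), float(u[i, 1]), float(u[i, 2])),
                group=group,
                cutoff_low=cutoff_low,
                cutoff_high=cutoff_high,
            )
        )
    return out


def assignments_to_tsv(
    ranked: list[RankedHeading],
    assignments: list[RelevanceAssignment],
    names: dict[str, str] | None = None,
) -> str:
    """Grouped-ranking TSV: rank, heading_id, name, cosine, group, memberships."""
    names = names or {}
    lines = ["rank\theading_id\tname\tcosine\tgroup\tm_unknown\tm_possibly\tm_highly"]
    by_id = {a.heading_id: a for a in assignments}
    for r in ranked:
        a = by_id[r.heading_id]
        lines.append(
            f"{r.rank}\t{r.heading_id}\t{names.get(r.heading_id, '')}"
            f"\t{r.cosine:.6f}\t{a.group}"
            f"\t{a.memberships[0]:.6f}\t{a.memberships[1]:.6f}\t{a.memberships[2]:.6f}"
        )
    return "\n".join(lines) + "\n"
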