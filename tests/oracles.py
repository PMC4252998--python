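"""Independent reference implementations used only to check the package.

Each oracle is written in the most direct style possible (explicit loops,
exhaustive enumeration) and never calls into the code paths it validates.
"""

from __future__ import annotations

import numpy as np


def exhaustive_leftmost_longest(tokens: list[str], surface_index: dict[str, int], max_n: int):
    """Enumerate every maximal non-overlapping match tiling and return the
    one preferred under the leftmost-longest order.

    A tiling is a sorted list of (term_id, start, length) spans; preference
    compares the sequence of (start, -length) keys lexicographically, so an
    earlier start wins, then a longer span.
    """
    n = len(tokens)
    all_matches = []
    for start in range(n):
        for length in range(1, min(max_n, n - start) + 1):
            surf = " ".join(tokens[start : start + length])
            if surf in surface_index:
                all_matches.append((surface_index[surf], start, length))

    tilings = []

    def extend(tiling, next_free):
        candidates = [m for m in all_matches if m[1] >= next_free]
        if not candidates:
            tilings.append(list(tiling))
            return
        for m in candidates:
            extend(tiling + [m], m[1] + m[2])

    extend([], 0)
    # maximal tilings only: none can be extended (guaranteed by construction
    # above, which always extends while any candidate remains)
    return min(tilings, key=lambda t: [(s, -l) for _, s, l in t]) if tilings else []


def fcm_reference(x, n_clusters=3, m=2.0, tol=1e-10, max_iter=2000, init=None):
    """Plain-loop Bezdek fuzzy c-means on 1-D data.

    Returns (centers ascending, memberships aligned to the sorted centers).
    """
    x = [float(v) for v in x]
    n = len(x)
    if init is None:
        centers = [float(np.percentile(x, p)) for p in (10, 50, 90)]
    else:
        centers = [float(c) for c in init]
    for j in range(1, n_clusters):
        if centers[j] <= centers[j - 1]:
            centers[j] = centers[j - 1] + 1e-9
    exponent = 2.0 / (m - 1.0)
    u = [[0.0] * n_clusters for _ in range(n)]
    for _ in range(max_iter):
        for i in range(n):
            dists = [abs(x[i] - c) for c in centers]
            if min(dists) < 1e-15:
                hits = [1.0 if d < 1e-15 else 0.0 for d in dists]
                total = sum(hits)
                u[i] = [h / total for h in hits]
            else:
                for j in range(n_clusters):
                    denom = 0.0
                    for l in range(n_clusters):
                        denom += (dists[j] / dists[l]) ** exponent
                    u[i][j] = 1.0 / denom
        new_centers = []
        for j in range(n_clusters):
            num = sum((u[i][j] ** m) * x[i] for i in range(n))
            den = sum(u[i][j] ** m for i in range(n))
            new_centers.append(num / den)
        shift = max(abs(a - b) for a, b in zip(new_centers, centers))
        centers = new_centers
        if shift < tol:
            break
    order = sorted(range(n_clusters), key=lambda j: centers[j])
    centers_sorted = [centers[j] for j in order]
    u_sorted = [[row[j] for j in order] for row in u]
    return np.array(centers_sorted), np.array(u_sorted)


def raw_space_cosine_ranking(weighted: np.ndarray, query_col: np.ndarray, heading_ids):
    """Cosine ranking computed directly in the original TF-IDF space."""
    cosines = []
    for j in range(weighted.shape[1]):
        col = weighted[:, j]
        denom = np.linalg.norm(col) * np.linalg.norm(query_col)
        cosines.append(0.0 if denom == 0 else float(col @ query_col / denom))
    order = sorted(range(len(cosines)), key=lambda j: (-cosines[j], heading_ids[j]))
    return [(heading_ids[j], cosines[j]) for j in order]


def best_subset_selection(candidates, disease_fraction):
    """Brute-force maximal heading subset with the category-C floor.

    candidates: list of (heading_id, abstract_count, categories) already
    inside the count bounds.  Among subsets whose C fraction meets the floor,
    prefers larger size, then larger total abstract count (keeping high-count
    headings), matching the drop-lowest-non-C rule.
    """
    from itertools import combinations

    best = None
    n = len(candidates)
    for size in range(n, 0, -1):
        feasible = []
        for combo in combinations(candidates, size):
            n_c = sum(1 for _, _, cats in combo if "C" in cats)
            if n_c >= disease_fraction * size:
                feasible.append(combo)
        if feasible:
            best = max(feasible, key=lambda combo: sum(c for _, c, _ in combo))
            break
    if best is None:
        return []
    ordered = sorted(best, key=lambda t: (-t[1], t[0]))
    return [hid for hid, _, _ in ordered]
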