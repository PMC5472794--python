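"""Distance-cutoff clustering of nano-foci and per-cluster geometry metrics.

Two nano-foci belong to the same cluster when their centroids are closer
than a cutoff distance (default 500 nm, strict inequality), extended
transitively — i.e. single-linkage connected components of the
sub-threshold distance graph. For each cluster four geometric summaries
are computed alongside the summed DNA content of its members:

* integrated cluster volume — sum of member focus volumes;
* inter-focal volume — volume of the convex hull of the member centroids
  (0, flagged degenerate, for fewer than 4 points or coplanar/collinear
  geometry);
* shortest path — length of the shortest open path visiting every member
  centroid exactly once (shortest Hamiltonian path; exact dynamic
  programming up to 10 members, nearest-neighbour + 2-opt above, flagged);
* mean inter-centroid distance — mean over all unordered member pairs.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, QhullError, cKDTree
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "cluster_foci",
    "hull_volume",
    "shortest_hamiltonian_path",
    "cluster_table",
    "cutoff_scan",
]

EXACT_PATH_LIMIT = 10


def cluster_foci(centroids_nm: np.ndarray, cutoff_nm: float = 500.0) -> np.ndarray:
    """Single-linkage clustering at a strict distance cutoff.

    Returns an int label per focus; labels are numbered 0..k-1 in order of
    first appearance. Pairs at exactly the cutoff distance are NOT linked.
    """
    if cutoff_nm <= 0:
        raise ValueError("cutoff must be positive")
    pts = np.asarray(centroids_nm, dtype=float).reshape(-1, 3)
    n = len(pts)
    if n == 0:
        return np.empty(0, dtype=int)
    pairs = cKDTree(pts).query_pairs(cutoff_nm, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
        pairs = pairs[d < cutoff_nm]
    graph = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])) if len(pairs)
        else ((), ((), ())),
        shape=(n, n),
    )
    _, raw = connected_components(graph, directed=False)
    # renumber in order of first appearance for determinism
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        labels[i] = remap.setdefault(r, len(remap))
    return labels


def hull_volume(points: np.ndarray) -> tuple[float, bool]:
    """Convex-hull volume of 3D points; (0, True) when degenerate."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 4:
        return 0.0, True
    try:
        return float(ConvexHull(pts).volume), False
    except QhullError:
        return 0.0, True


def _held_karp_path(dist: np.ndarray) -> float:
    """Exact shortest open Hamiltonian path by subset dynamic programming."""
    n = len(dist)
    full = (1 << n) - 1
    dp = [dict() for _ in range(1 << n)]
    for j in range(n):
        dp[1 << j][j] = 0.0
    for subset in range(1 << n):
        for j, cost in dp[subset].items():
            for k in range(n):
                if subset & (1 << k):
                    continue
                nxt = subset | (1 << k)
                cand = cost + dist[j, k]
                if cand < dp[nxt].get(k, np.inf):
                    dp[nxt][k] = cand
    return min(dp[full].values())


def _two_opt_path(dist: np.ndarray) -> float:
    """Nearest-neighbour construction followed by 2-opt improvement."""
    n = len(dist)
    best_order = None
    best_len = np.inf
    # nearest-neighbour from every start; keep the best
    for start in range(n):
        order = [start]
        remaining = set(range(n)) - {start}
        while remaining:
            last = order[-1]
            nxt = min(remaining, key=lambda k: dist[last, k])
            order.append(nxt)
            remaining.remove(nxt)
        length = sum(dist[a, b] for a, b in zip(order, order[1:]))
        if length < best_len:
            best_order, best_len = order, length
    order = best_order
    improved = True
    while improved:
        improved = False
        for i in range(n - 1):
            for j in range(i + 2, n):
                new = order[:i + 1] + order[i + 1:j + 1][::-1] + order[j + 1:]
                length = sum(dist[a, b] for a, b in zip(new, new[1:]))
                if length < best_len - 1e-12:
                    order, best_len = new, length
                    improved = True
    return best_len


def shortest_hamiltonian_path(
    points: np.ndarray, exact_limit: int = EXACT_PATH_LIMIT
) -> tuple[float, bool]:
    """Length of the shortest open path through all points.

    Exact (subset DP) for up to ``exact_limit`` points — cheap, since
    clusters typically hold a handful of foci — heuristic
    (nearest-neighbour + 2-opt) above, signalled by the second return
    value (``True`` when exact).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    n = len(pts)
    if n <= 1:
        return 0.0, True
    dist = squareform(pdist(pts))
    if n == 2:
        return float(dist[0, 1]), True
    if n <= exact_limit:
        return float(_held_karp_path(dist)), True
    return float(_two_opt_path(dist)), False


def cluster_table(
    foci: pd.DataFrame,
    assignments: np.ndarray,
    dna_column: str = "dna_content_kb",
) -> pd.DataFrame:
    """Per-cluster metrics table from a focus table and cluster labels.

    ``foci`` must carry centroid_{x,y,z}_nm and volume_um3; DNA content is
    summed when ``dna_column`` is present. Singleton clusters report 0 for
    the pairwise metrics (path, mean distance, hull volume).
    """
    if len(foci) != len(assignments):
        raise ValueError("assignments length must match focus table")
    pts = foci[["centroid_x_nm", "centroid_y_nm", "centroid_z_nm"]].to_numpy()
    assignments = np.asarray(assignments)
    rows = []
    for cid in np.unique(assignments):
        member_idx = np.flatnonzero(assignments == cid)
        members = foci.iloc[member_idx]
        p = pts[member_idx]
        vol_hull, degenerate = hull_volume(p)
        path, exact = shortest_hamiltonian_path(p)
        if len(p) > 1:
            mean_pair = float(pdist(p).mean())
        else:
            mean_pair = 0.0
        row = {
            "cluster_id": int(cid),
            "n_foci": int(len(member_idx)),
            "member_focus_ids": ",".join(str(int(i)) for i in members["focus_id"]),
            "integrated_volume_um3": float(members["volume_um3"].sum()),
            "interfocal_volume_um3": vol_hull / 1e9,  # nm^3 -> um^3
            "hull_degenerate": degenerate,
            "shortest_path_nm": path,
            "path_exact": exact,
            "mean_intercentroid_nm": mean_pair,
        }
        if dna_column in foci.columns:
            row["dna_content_kb"] = float(members[dna_column].sum())
        rows.append(row)
    return pd.DataFrame(rows)


def cutoff_scan(
    centroids_nm: np.ndarray,
    cutoffs_nm: np.ndarray | list[float] = tuple(range(300, 701, 50)),
) -> pd.DataFrame:
    """Cluster count for each cutoff distance (non-increasing in cutoff)."""
    rows = [
        {"cutoff_nm": float(c),
         "n_clusters": int(cluster_foci(centroids_nm, c).max() + 1)
         if len(np.asarray(centroids_nm).reshape(-1, 3)) else 0}
        for c in cutoffs_nm
    ]
    return pd.DataFrame(rows)
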