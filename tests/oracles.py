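"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own spatial-index code paths:
distances come from full O(n^2) matrices and volumes from Monte-Carlo
rejection sampling.
"""

from __future__ import annotations

import numpy as np

NOISE = -1


def brute_dbscan(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """O(n^2) DBSCAN with the deterministic border rule and size filter.

    Core point: >= min_pts neighbours within eps, the point itself included.
    Clusters are connected components of the core-core eps graph, created in
    ascending order of their smallest core id; a border point joins the
    earliest-created component among its core neighbours.  Components whose
    final size is below min_pts are discarded; labels are renumbered 0..k-1
    by ascending minimum member id.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    labels = np.full(n, NOISE, dtype=int)
    if n == 0:
        return labels
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    neigh = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neigh])

    comp = np.full(n, -1, dtype=int)
    n_comp = 0
    for i in range(n):
        if core[i] and comp[i] < 0:
            stack = [i]
            comp[i] = n_comp
            while stack:
                j = stack.pop()
                for k in neigh[j]:
                    if core[k] and comp[k] < 0:
                        comp[k] = n_comp
                        stack.append(k)
            n_comp += 1
    for i in range(n):
        if core[i]:
            labels[i] = comp[i]
        else:
            owners = [comp[k] for k in neigh[i] if core[k]]
            if owners:
                labels[i] = min(owners)

    # size filter, then renumber by ascending minimum member id
    for lab in range(n_comp):
        members = labels == lab
        if 0 < members.sum() < min_pts:
            labels[members] = NOISE
    out = np.full(n, NOISE, dtype=int)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab == NOISE:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def brute_nn_distances(source: np.ndarray, target: np.ndarray, cutoff: float) -> np.ndarray:
    """Per-source nearest-neighbour distances by full distance matrix."""
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if len(src) == 0 or len(tgt) == 0:
        return np.array([])
    d = np.linalg.norm(src[:, None, :] - tgt[None, :, :], axis=2).min(axis=1)
    return d[d <= cutoff]


def monte_carlo_hull_volume(
    points: np.ndarray, n_samples: int = 1_000_000, seed: int = 0
) -> float:
    """Convex-hull volume by rejection sampling inside the bounding box.

    A sample is inside the hull iff it satisfies every facet half-space; the
    half-spaces come from the facet equations but the volume estimate itself
    is pure Monte-Carlo counting.
    """
    from scipy.spatial import ConvexHull

    pts = np.asarray(points, dtype=float)
    hull = ConvexHull(pts)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    rng = np.random.default_rng(seed)
    samples = rng.uniform(lo, hi, size=(n_samples, 3))
    a, b = hull.equations[:, :3], hull.equations[:, 3]
    inside = np.all(samples @ a.T + b <= 1e-9, axis=1)
    box_volume = float(np.prod(hi - lo))
    return box_volume * inside.mean()


def greedy_min_distance_matching(
    pre_centroids: np.ndarray, post_centroids: np.ndarray, cutoff: float
) -> list[tuple[int, int, float]]:
    """Exhaustive greedy one-to-one matching by ascending centroid distance."""
    cands = []
    for i, p in enumerate(pre_centroids):
        for j, q in enumerate(post_centroids):
            dist = float(np.linalg.norm(np.asarray(p) - np.asarray(q)))
            if dist <= cutoff:
                cands.append((dist, i, j))
    cands.sort()
    used_i: set[int] = set()
    used_j: set[int] = set()
    out = []
    for dist, i, j in cands:
        if i not in used_i and j not in used_j:
            used_i.add(i)
            used_j.add(j)
            out.append((i, j, dist))
    return out
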