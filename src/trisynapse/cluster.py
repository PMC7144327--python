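"""DBSCAN clustering of localisation point clouds and cluster morphometry.

Clustering follows classic DBSCAN with the analysis thresholds used for
synaptic scaffold proteins: neighbourhood radius eps = 100 nm (inclusive,
3D Euclidean) and min_pts = 50 localisations, where a point's eps
neighbourhood includes the point itself.  Two deterministic rules make the
labelling reproducible: (i) clusters are seeded in ascending point id, so a
border point reachable from several clusters is claimed by the cluster
seeded first; (ii) final labels are renumbered 0..k-1 by ascending minimum
member id.  Clusters whose final size (after border assignment) falls below
min_pts are discarded as noise, so "a minimum of min_pts localisations per
cluster" holds literally for every reported cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .io import NOISE, LocalizationTable


@dataclass
class DbscanParams:
    """eps in nm (inclusive neighbourhood radius), min_pts in localisations."""

    eps: float = 100.0
    min_pts: int = 50

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.min_pts < 1:
            raise ValueError("min_pts must be >= 1")


@dataclass
class Cluster:
    """One DBSCAN cluster with its morphometric summary.

    ``hull_volume_nm3`` is 0 and ``density_per_um3`` NaN for clusters with
    fewer than 4 members or a degenerate (e.g. coplanar) geometry.
    """

    cluster_id: int
    channel: str
    member_ids: np.ndarray
    centroid_nm: np.ndarray
    hull_volume_nm3: float
    density_per_um3: float
    hull_vertex_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_locs(self) -> int:
        return len(self.member_ids)


def dbscan(points: np.ndarray, params: DbscanParams | None = None) -> np.ndarray:
    """Deterministic DBSCAN labels (NOISE = -1) for 3D points in nm."""
    params = params or DbscanParams()
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    n = len(points)
    labels = np.full(n, NOISE, dtype=int)
    if n == 0:
        return labels
    if not np.all(np.isfinite(points)):
        raise ValueError("points must be finite")

    tree = cKDTree(points)
    neighbours = tree.query_ball_point(points, r=params.eps)  # includes the point itself
    core = np.array([len(nb) >= params.min_pts for nb in neighbours])

    visited_core = np.zeros(n, dtype=bool)
    next_label = 0
    for seed in range(n):
        if not core[seed] or visited_core[seed]:
            continue
        # expand one density-connected component from this seed
        labels[seed] = next_label
        visited_core[seed] = True
        stack = [seed]
        while stack:
            j = stack.pop()
            for nb in neighbours[j]:
                if labels[nb] == NOISE:
                    labels[nb] = next_label
                if core[nb] and not visited_core[nb]:
                    visited_core[nb] = True
                    stack.append(nb)
        next_label += 1

    labels = _renumber(labels)
    # enforce the literal "minimum of min_pts localisations per cluster"
    for lab in range(labels.max() + 1 if labels.size else 0):
        members = labels == lab
        if 0 < members.sum() < params.min_pts:
            labels[members] = NOISE
    return _renumber(labels)


def _renumber(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..k-1 by ascending minimum member id."""
    out = np.full_like(labels, NOISE)
    next_label = 0
    seen: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab == NOISE:
            continue
        if lab not in seen:
            seen[lab] = next_label
            next_label += 1
        out[i] = seen[lab]
    return out


def hull_volume(points: np.ndarray) -> tuple[float, np.ndarray]:
    """Convex-hull volume (nm^3) and hull vertex indices; (0, []) if degenerate."""
    points = np.asarray(points, dtype=float)
    if len(points) < 4:
        return 0.0, np.array([], dtype=int)
    try:
        hull = ConvexHull(points)
    except QhullError:
        return 0.0, np.array([], dtype=int)
    return float(hull.volume), hull.vertices.astype(int)


def summarize_clusters(
    table: LocalizationTable, labels: np.ndarray, channel: str | None = None
) -> list[Cluster]:
    """Per-cluster morphometry: size, centroid, convex-hull volume, density.

    Density is localisations per um^3 of hull volume, NaN when the hull is
    degenerate.  ``labels`` must align with ``table`` rows.
    """
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(table):
        raise ValueError("labels must align with the table rows")
    coords = table.coords
    ids = table.df["id"].to_numpy()
    clusters: list[Cluster] = []
    for lab in sorted(set(labels[labels != NOISE])):
        sel = labels == lab
        pts = coords[sel]
        vol, verts = hull_volume(pts)
        n = int(sel.sum())
        density = n / (vol / 1e9) if vol > 0 else float("nan")
        ch = channel
        if ch is None:
            uniq = set(table.df["channel"][sel])
            ch = uniq.pop() if len(uniq) == 1 else "mixed"
        clusters.append(
            Cluster(
                cluster_id=int(lab),
                channel=ch,
                member_ids=ids[sel].copy(),
                centroid_nm=pts.mean(axis=0),
                hull_volume_nm3=vol,
                density_per_um3=density,
                hull_vertex_ids=ids[sel][verts] if len(verts) else verts,
            )
        )
    return clusters


def cluster_channel(
    table: LocalizationTable, channel: str, params: DbscanParams | None = None
) -> tuple[LocalizationTable, list[Cluster]]:
    """Filter one channel, run DBSCAN, summarise.

    Returns the single-channel table (with ``cluster_id`` column filled) and
    the cluster summaries.
    """
    from .io import filter_by_channel

    sub = filter_by_channel(table, channel)
    labels = dbscan(sub.coords, params)
    return sub.with_cluster_labels(labels), summarize_clusters(sub, labels, channel=channel)


def clusters_to_frame(clusters: list[Cluster]):
    """Tabular cluster summary in the on-disk schema."""
    import pandas as pd

    return pd.DataFrame(
        {
            "cluster_id": [c.cluster_id for c in clusters],
            "channel": [c.channel for c in clusters],
            "n_locs": [c.n_locs for c in clusters],
            "cx_nm": [c.centroid_nm[0] for c in clusters],
            "cy_nm": [c.centroid_nm[1] for c in clusters],
            "cz_nm": [c.centroid_nm[2] for c in clusters],
            "hull_volume_nm3": [c.hull_volume_nm3 for c in clusters],
            "density_per_um3": [c.density_per_um3 for c in clusters],
        }
    )
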