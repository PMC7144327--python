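"""Synapse identification and perisynaptic distance statistics.

A synapse is an opposed pair of presynaptic (bassoon) and postsynaptic
(Homer1) clusters whose centroids lie within 500 nm, matched one-to-one
greedily by ascending centroid distance.  The synapse centre is the midpoint
of the two centroids (the only symmetric choice) and the synapse axis the
unit vector from the presynaptic to the postsynaptic centroid.

Distance statistics follow the analysis conventions of trans-synaptic SMLM:
per-localisation 3D nearest-neighbour distances between the two synaptic
channels (500 nm cutoff, the approximate halfway point between neighbouring
synapses), and for every perisynaptic (GLT-1) localisation within 500 nm of
a synapse centre its distance to that centre and to the nearest member
localisation of the synapse's pre and post clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .cluster import Cluster
from .io import LocalizationTable


@dataclass
class PairingParams:
    max_center_distance_nm: float = 500.0
    search_radius_nm: float = 500.0
    nn_cutoff_nm: float = 500.0
    histogram_bin_nm: float = 10.0

    def __post_init__(self) -> None:
        for name in (
            "max_center_distance_nm",
            "search_radius_nm",
            "nn_cutoff_nm",
            "histogram_bin_nm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SynapsePair:
    synapse_id: int
    pre_cluster: Cluster
    post_cluster: Cluster
    center_nm: np.ndarray
    axis: np.ndarray  # unit vector, presynaptic -> postsynaptic centroid
    center_distance_nm: float


@dataclass
class DistanceSet:
    """A named set of distances with its histogram and summary statistics."""

    kind: str
    distances_nm: np.ndarray
    synapse_ids: np.ndarray
    bin_nm: float
    cutoff_nm: float

    @property
    def n(self) -> int:
        return len(self.distances_nm)

    @property
    def histogram(self) -> tuple[np.ndarray, np.ndarray]:
        """(bin edges, counts) over [0, cutoff] at bin_nm spacing."""
        n_bins = int(np.ceil(self.cutoff_nm / self.bin_nm))
        edges = np.arange(n_bins + 1) * self.bin_nm
        counts, _ = np.histogram(self.distances_nm, bins=edges)
        return edges, counts

    @property
    def median_nm(self) -> float:
        return float(np.median(self.distances_nm)) if self.n else float("nan")

    def summary(self) -> dict:
        return {
            "kind": self.kind,
            "n": self.n,
            "median_nm": self.median_nm,
            "mode_nm": histogram_mode(self) if self.n else None,
        }


def pair_synapses(
    pre_clusters: list[Cluster],
    post_clusters: list[Cluster],
    params: PairingParams | None = None,
) -> list[SynapsePair]:
    """Greedy one-to-one pre/post cluster matching by ascending centroid distance.

    Candidate pairs are all (pre, post) with centroid distance <= the cutoff;
    ties break on lower pre id, then lower post id; each cluster joins at
    most one pair.
    """
    params = params or PairingParams()
    candidates = []
    for pre in pre_clusters:
        for post in post_clusters:
            d = float(np.linalg.norm(pre.centroid_nm - post.centroid_nm))
            if d <= params.max_center_distance_nm:
                candidates.append((d, pre.cluster_id, post.cluster_id, pre, post))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    used_pre: set[int] = set()
    used_post: set[int] = set()
    pairs: list[SynapsePair] = []
    for d, pre_id, post_id, pre, post in candidates:
        if pre_id in used_pre or post_id in used_post:
            continue
        used_pre.add(pre_id)
        used_post.add(post_id)
        delta = post.centroid_nm - pre.centroid_nm
        axis = delta / d if d > 0 else np.zeros(3)
        pairs.append(
            SynapsePair(
                synapse_id=len(pairs),
                pre_cluster=pre,
                post_cluster=post,
                center_nm=(pre.centroid_nm + post.centroid_nm) / 2.0,
                axis=axis,
                center_distance_nm=d,
            )
        )
    return pairs


def nn_distances(
    source: LocalizationTable,
    target: LocalizationTable,
    cutoff_nm: float = 500.0,
    bin_nm: float = 10.0,
    kind: str = "pre_post_nn",
) -> DistanceSet:
    """Per-localisation 3D nearest-neighbour distances, source -> target.

    Every source localisation contributes the distance to its nearest target
    localisation; distances beyond the cutoff are discarded.
    """
    if len(source) == 0 or len(target) == 0:
        return DistanceSet(kind, np.array([]), np.array([], dtype=int), bin_nm, cutoff_nm)
    tree = cKDTree(target.coords)
    d, _ = tree.query(source.coords, k=1)
    keep = d <= cutoff_nm
    return DistanceSet(
        kind, d[keep], np.full(int(keep.sum()), -1, dtype=int), bin_nm, cutoff_nm
    )


def perisynaptic_distances(
    glt1: LocalizationTable,
    pairs: list[SynapsePair],
    pre: LocalizationTable,
    post: LocalizationTable,
    params: PairingParams | None = None,
    nearest_synapse_only: bool = False,
    use_centroid: bool = False,
) -> dict[str, DistanceSet]:
    """Distances of perisynaptic localisations to nearby synapses.

    For each GLT-1 localisation and each synapse whose centre lies within
    ``search_radius_nm`` (all such synapses by default, the nearest one only
    with ``nearest_synapse_only``) three distances are recorded: to the
    synapse centre and to the nearest member localisation of the pre and post
    clusters (or to the cluster centroids with ``use_centroid``).  Member
    distances beyond ``nn_cutoff_nm`` are discarded from their sets.
    """
    params = params or PairingParams()
    empty = lambda kind, cut: DistanceSet(  # noqa: E731
        kind, np.array([]), np.array([], dtype=int), params.histogram_bin_nm, cut
    )
    if len(glt1) == 0 or not pairs:
        return {
            "glt1_to_center": empty("glt1_to_center", params.search_radius_nm),
            "glt1_to_pre": empty("glt1_to_pre", params.nn_cutoff_nm),
            "glt1_to_post": empty("glt1_to_post", params.nn_cutoff_nm),
        }

    centers = np.array([p.center_nm for p in pairs])
    center_tree = cKDTree(centers)
    pre_ids = pre.df.set_index("id")
    post_ids = post.df.set_index("id")
    member_trees = []
    for p in pairs:
        if use_centroid:
            member_trees.append(
                (
                    cKDTree(p.pre_cluster.centroid_nm[None, :]),
                    cKDTree(p.post_cluster.centroid_nm[None, :]),
                )
            )
        else:
            pre_pts = pre_ids.loc[p.pre_cluster.member_ids, ["x_nm", "y_nm", "z_nm"]].to_numpy()
            post_pts = post_ids.loc[
                p.post_cluster.member_ids, ["x_nm", "y_nm", "z_nm"]
            ].to_numpy()
            member_trees.append((cKDTree(pre_pts), cKDTree(post_pts)))

    coords = glt1.coords
    hits = center_tree.query_ball_point(coords, r=params.search_radius_nm)
    d_center, d_pre, d_post = [], [], []
    s_center, s_pre, s_post = [], [], []
    for i, syn_list in enumerate(hits):
        if not syn_list:
            continue
        if nearest_synapse_only and len(syn_list) > 1:
            dists = np.linalg.norm(centers[syn_list] - coords[i], axis=1)
            syn_list = [syn_list[int(np.argmin(dists))]]
        for s in sorted(syn_list):
            pair = pairs[s]
            d_center.append(float(np.linalg.norm(coords[i] - pair.center_nm)))
            s_center.append(pair.synapse_id)
            dp, _ = member_trees[s][0].query(coords[i])
            dq, _ = member_trees[s][1].query(coords[i])
            if dp <= params.nn_cutoff_nm:
                d_pre.append(float(dp))
                s_pre.append(pair.synapse_id)
            if dq <= params.nn_cutoff_nm:
                d_post.append(float(dq))
                s_post.append(pair.synapse_id)

    mk = lambda kind, d, s, cut: DistanceSet(  # noqa: E731
        kind, np.asarray(d, dtype=float), np.asarray(s, dtype=int), params.histogram_bin_nm, cut
    )
    return {
        "glt1_to_center": mk("glt1_to_center", d_center, s_center, params.search_radius_nm),
        "glt1_to_pre": mk("glt1_to_pre", d_pre, s_pre, params.nn_cutoff_nm),
        "glt1_to_post": mk("glt1_to_post", d_post, s_post, params.nn_cutoff_nm),
    }


def histogram_mode(ds: DistanceSet) -> float:
    """Centre of the most populated histogram bin (ties -> lowest bin)."""
    if ds.n == 0:
        raise ValueError("histogram mode of an empty distance set is undefined")
    edges, counts = ds.histogram
    i = int(np.argmax(counts))
    return float(edges[i] + ds.bin_nm / 2.0)
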