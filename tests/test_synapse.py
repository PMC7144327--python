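import numpy as np
import pytest

from trisynapse import cluster, io, synapse
from .oracles import brute_nn_distances, greedy_min_distance_matching


def _cluster_at(cid, centroid, channel="bassoon"):
    return cluster.Cluster(
        cluster_id=cid,
        channel=channel,
        member_ids=np.array([0]),
        centroid_nm=np.asarray(centroid, dtype=float),
        hull_volume_nm3=0.0,
        density_per_um3=float("nan"),
    )


def _table(points, channel):
    n = len(points)
    return io.make_table(
        channel=np.full(n, channel, dtype=object),
        frame=np.zeros(n, dtype=int),
        xyz=np.asarray(points, dtype=float),
        photons=np.full(n, 1000.0),
        bg=np.full(n, 5.0),
        sigma_xy=np.full(n, 10.0),
        sigma_z=np.full(n, 25.0),
    )


class TestPairing:
    def test_single_opposed_pair_geometry(self):
        pre = [_cluster_at(0, (0, 0, 0))]
        post = [_cluster_at(0, (400, 0, 0), "Homer1")]
        [p] = synapse.pair_synapses(pre, post)
        np.testing.assert_allclose(p.center_nm, (200, 0, 0))
        np.testing.assert_allclose(p.axis, (1, 0, 0))
        assert p.center_distance_nm == pytest.approx(400)

    def test_beyond_cutoff_is_not_a_synapse(self):
        pre = [_cluster_at(0, (0, 0, 0))]
        post = [_cluster_at(0, (600, 0, 0), "Homer1")]
        assert synapse.pair_synapses(pre, post) == []

    def test_greedy_takes_nearest_and_is_one_to_one(self):
        pre = [_cluster_at(0, (0, 0, 0))]
        post = [_cluster_at(0, (300, 0, 0), "Homer1"), _cluster_at(1, (350, 0, 0), "Homer1")]
        pairs = synapse.pair_synapses(pre, post)
        assert len(pairs) == 1
        assert pairs[0].post_cluster.cluster_id == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_greedy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_pre, n_post = rng.integers(1, 20), rng.integers(1, 20)
        pre_c = rng.uniform(0, 2000, (n_pre, 3))
        post_c = rng.uniform(0, 2000, (n_post, 3))
        pre = [_cluster_at(i, c) for i, c in enumerate(pre_c)]
        post = [_cluster_at(j, c, "Homer1") for j, c in enumerate(post_c)]
        got = {(p.pre_cluster.cluster_id, p.post_cluster.cluster_id)
               for p in synapse.pair_synapses(pre, post)}
        want = {(i, j) for i, j, _ in greedy_min_distance_matching(pre_c, post_c, 500.0)}
        assert got == want

    def test_no_cluster_is_used_twice(self):
        rng = np.random.default_rng(3)
        pre = [_cluster_at(i, c) for i, c in enumerate(rng.uniform(0, 1500, (15, 3)))]
        post = [_cluster_at(j, c, "Homer1") for j, c in enumerate(rng.uniform(0, 1500, (15, 3)))]
        pairs = synapse.pair_synapses(pre, post)
        pre_ids = [p.pre_cluster.cluster_id for p in pairs]
        post_ids = [p.post_cluster.cluster_id for p in pairs]
        assert len(pre_ids) == len(set(pre_ids)) and len(post_ids) == len(set(post_ids))


class TestNNDistances:
    def test_single_pair_distance(self):
        ds = synapse.nn_distances(_table([(0, 0, 0)], "bassoon"), _table([(120, 0, 0)], "Homer1"))
        assert ds.n == 1
        assert ds.distances_nm[0] == pytest.approx(120.0)

    def test_cutoff_excludes_distant_targets(self):
        ds = synapse.nn_distances(_table([(0, 0, 0)], "bassoon"), _table([(501, 0, 0)], "Homer1"))
        assert ds.n == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        src = rng.uniform(0, 1500, (rng.integers(1, 300), 3))
        tgt = rng.uniform(0, 1500, (rng.integers(1, 300), 3))
        got = synapse.nn_distances(_table(src, "a"), _table(tgt, "b")).distances_nm
        want = brute_nn_distances(src, tgt, 500.0)
        np.testing.assert_allclose(np.sort(got), np.sort(want), rtol=1e-12)

    def test_histogram_counts_sum_to_n(self):
        rng = np.random.default_rng(1)
        src = rng.uniform(0, 800, (100, 3))
        tgt = rng.uniform(0, 800, (100, 3))
        ds = synapse.nn_distances(_table(src, "a"), _table(tgt, "b"))
        _, counts = ds.histogram
        assert counts.sum() == ds.n


class TestHistogramMode:
    def test_mode_bin_centre(self):
        ds = synapse.DistanceSet(
            "pre_post_nn", np.array([119.0, 121.0, 121.0, 400.0]), np.full(4, -1), 10.0, 500.0
        )
        assert synapse.histogram_mode(ds) == pytest.approx(125.0)

    def test_single_distance(self):
        ds = synapse.DistanceSet("pre_post_nn", np.array([42.0]), np.array([-1]), 10.0, 500.0)
        assert synapse.histogram_mode(ds) == pytest.approx(45.0)

    def test_empty_set_raises(self):
        ds = synapse.DistanceSet("pre_post_nn", np.array([]), np.array([], dtype=int), 10.0, 500.0)
        with pytest.raises(ValueError):
            synapse.histogram_mode(ds)


class TestPerisynaptic:
    def _one_synapse(self):
        pre_pts = [(-60, 0, 0), (-60, 50, 0), (-60, -50, 0)]
        post_pts = [(60, 0, 0), (60, 50, 0), (60, -50, 0)]
        pre_t = _table(pre_pts, "bassoon")
        post_t = _table(post_pts, "Homer1")
        pre = cluster.Cluster(0, "bassoon", np.arange(3), np.mean(pre_pts, axis=0), 0.0, np.nan)
        post = cluster.Cluster(0, "Homer1", np.arange(3), np.mean(post_pts, axis=0), 0.0, np.nan)
        pairs = synapse.pair_synapses([pre], [post])
        return pairs, pre_t, post_t

    def test_glt1_at_centre_has_zero_centre_distance(self):
        pairs, pre_t, post_t = self._one_synapse()
        ds = synapse.perisynaptic_distances(_table([(0, 0, 0)], "GLT1"), pairs, pre_t, post_t)
        assert ds["glt1_to_center"].n == 1
        assert ds["glt1_to_center"].distances_nm[0] == pytest.approx(0.0)
        assert ds["glt1_to_pre"].distances_nm[0] == pytest.approx(60.0)
        assert ds["glt1_to_post"].distances_nm[0] == pytest.approx(60.0)

    def test_outside_search_radius_contributes_nothing(self):
        pairs, pre_t, post_t = self._one_synapse()
        ds = synapse.perisynaptic_distances(_table([(600, 0, 0)], "GLT1"), pairs, pre_t, post_t)
        assert all(d.n == 0 for d in ds.values())

    def test_multi_synapse_membership_contributes_per_synapse(self):
        pairs1, pre_t, post_t = self._one_synapse()
        # second synapse 600 nm away along x; GLT-1 point halfway is within
        # 500 nm of both centres
        pre2 = cluster.Cluster(1, "bassoon", np.arange(3), np.array([540.0, 0, 0]), 0.0, np.nan)
        post2 = cluster.Cluster(1, "Homer1", np.arange(3), np.array([660.0, 0, 0]), 0.0, np.nan)
        pairs = pairs1 + synapse.pair_synapses([pre2], [post2])
        pairs[1].synapse_id = 1
        glt1 = _table([(300, 0, 0)], "GLT1")
        ds = synapse.perisynaptic_distances(glt1, pairs, pre_t, post_t, use_centroid=True)
        assert ds["glt1_to_center"].n == 2
        only_nearest = synapse.perisynaptic_distances(
            glt1, pairs, pre_t, post_t, use_centroid=True, nearest_synapse_only=True
        )
        assert only_nearest["glt1_to_center"].n == 1

    def test_every_entry_within_search_radius(self, small_imaged):
        table, _ = small_imaged
        _, pre_c = cluster.cluster_channel(table, "bassoon")
        _, post_c = cluster.cluster_channel(table, "Homer1")
        pairs = synapse.pair_synapses(pre_c, post_c)
        assert pairs
        pre_t = io.filter_by_channel(table, "bassoon")
        post_t = io.filter_by_channel(table, "Homer1")
        glt1 = io.filter_by_channel(table, "GLT1")
        ds = synapse.perisynaptic_distances(glt1, pairs, pre_t, post_t)
        assert (ds["glt1_to_center"].distances_nm <= 500.0).all()
        assert ds["glt1_to_pre"].n > 0 and ds["glt1_to_post"].n > 0


def test_modal_distance_tracks_generative_separation(small_imaged):
    """On a simulated scene the pre/post NN mode sits near (below) the
    plane separation: within the broad band expected of dense labelling."""
    table, _ = small_imaged
    ds = synapse.nn_distances(
        io.filter_by_channel(table, "bassoon"), io.filter_by_channel(table, "Homer1")
    )
    mode = synapse.histogram_mode(ds)
    assert 60.0 <= mode <= 140.0
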