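import numpy as np
import pandas as pd
import pytest

from trisynapse import simulate


def _noiseless_cfg(**kw) -> simulate.SimulationConfig:
    base = dict(
        seed=3,
        n_synapses=3,
        field_size_nm=(6000.0, 6000.0, 2000.0),
        label_displacement_sigma_nm=0.0,
        labelling_efficiency=1.0,
        blinks_per_fluorophore=1.0,
        sigma_xy_nm=0.0,
        sigma_z_nm=0.0,
        chromatic_offset_nm={"bassoon": (0, 0, 0), "GLT1": (0, 0, 0), "Homer1": (0, 0, 0)},
        false_loc_density_per_um3_per_channel=0.0,
    )
    base.update(kw)
    return simulate.SimulationConfig(**base)


def test_scene_and_table_are_deterministic(small_cfg):
    s1 = simulate.make_scene(small_cfg)
    s2 = simulate.make_scene(small_cfg)
    pd.testing.assert_frame_equal(s1.molecules, s2.molecules)
    pd.testing.assert_frame_equal(s1.synapses, s2.synapses)
    t1, side1 = simulate.image_scene(s1, small_cfg)
    t2, side2 = simulate.image_scene(s2, small_cfg)
    pd.testing.assert_frame_equal(t1.df, t2.df)
    pd.testing.assert_frame_equal(side1, side2)


def test_trans_synaptic_separation_exact_by_construction(small_scene, small_cfg):
    s = small_scene.synapses
    pre = s[["pre_cx_nm", "pre_cy_nm", "pre_cz_nm"]].to_numpy()
    post = s[["post_cx_nm", "post_cy_nm", "post_cz_nm"]].to_numpy()
    sep = np.linalg.norm(pre - post, axis=1)
    np.testing.assert_allclose(sep, small_cfg.synapse_separation_nm, rtol=1e-12)


def test_shell_molecule_count_by_construction():
    cfg = simulate.SimulationConfig(seed=5, n_synapses=10, glt1_molecules_per_synapse=80)
    scene = simulate.make_scene(cfg)
    shell = scene.molecules[
        (scene.molecules["channel"] == "GLT1") & (scene.molecules["synapse_id"] >= 0)
    ]
    assert len(shell) == 800


def test_noiseless_imaging_reproduces_molecule_positions():
    cfg = _noiseless_cfg()
    scene = simulate.make_scene(cfg)
    table, sidecar = simulate.image_scene(scene, cfg)
    assert len(table) == len(scene.molecules)
    mols = scene.molecules.set_index("molecule_id")
    got = table.coords
    want = mols.loc[sidecar["molecule_id"], ["x_nm", "y_nm", "z_nm"]].to_numpy()
    np.testing.assert_allclose(got, want, atol=1e-9)


def test_zero_labelling_efficiency_leaves_only_false_localizations():
    cfg = _noiseless_cfg(labelling_efficiency=0.0, false_loc_density_per_um3_per_channel=2.0)
    table, sidecar = simulate.image_scene(simulate.make_scene(cfg), cfg)
    assert len(table) > 0
    assert (sidecar["molecule_id"] == simulate.BACKGROUND).all()


def test_every_localization_traces_to_one_molecule(small_imaged, small_scene):
    table, sidecar = small_imaged
    assert len(sidecar) == len(table)
    real = sidecar[sidecar["molecule_id"] >= 0]
    assert real["molecule_id"].isin(small_scene.molecules["molecule_id"]).all()
    # channel of the localisation matches the channel of its generating molecule
    mols = small_scene.molecules.set_index("molecule_id")
    assert (
        mols.loc[real["molecule_id"], "channel"].to_numpy() == real["channel"].to_numpy()
    ).all()


def test_localization_count_matches_analytic_expectation():
    counts = []
    expected = None
    for seed in range(50):
        cfg = simulate.SimulationConfig(
            seed=seed, n_synapses=2, field_size_nm=(4000.0, 4000.0, 2000.0)
        )
        scene = simulate.make_scene(cfg)
        table, _ = simulate.image_scene(scene, cfg)
        counts.append(len(table))
        if expected is None:
            expected = simulate.expected_localization_count(cfg, scene)
    mean = np.mean(counts)
    sem = np.std(counts, ddof=1) / np.sqrt(len(counts))
    # scene-to-scene molecule counts vary slightly (Poisson background); 3 sigma band
    assert abs(mean - expected) < 3 * sem + 0.02 * expected


def test_localization_rms_displacement_matches_theory(small_cfg, small_scene):
    table, sidecar = simulate.image_scene(small_scene, small_cfg)
    cfg = small_cfg
    real = sidecar["molecule_id"] >= 0
    mols = small_scene.molecules.set_index("molecule_id")
    true_pos = mols.loc[sidecar.loc[real, "molecule_id"], ["x_nm", "y_nm", "z_nm"]].to_numpy()
    offsets = np.array(
        [cfg.chromatic_offset_nm[ch] for ch in sidecar.loc[real, "channel"]]
    )
    disp = table.coords[real.to_numpy()] - offsets - true_pos
    rms = np.sqrt(np.mean(np.sum(disp**2, axis=1)))
    theory = np.sqrt(
        2 * cfg.sigma_xy_nm**2 + cfg.sigma_z_nm**2 + 3 * cfg.label_displacement_sigma_nm**2
    )
    assert abs(rms - theory) / theory < 0.10


def test_empty_scene_has_only_background():
    cfg = simulate.SimulationConfig(seed=1, n_synapses=0)
    scene = simulate.make_scene(cfg)
    assert (scene.molecules["synapse_id"] == simulate.BACKGROUND).all()
    assert set(scene.molecules["channel"]) <= {"GLT1"}


def test_overcrowded_field_raises_placement_error():
    cfg = simulate.SimulationConfig(
        seed=1, n_synapses=40, field_size_nm=(3000.0, 3000.0, 2000.0)
    )
    with pytest.raises(simulate.PlacementError):
        simulate.make_scene(cfg)


def test_positions_stay_inside_field(small_scene, small_cfg):
    lo, hi = small_cfg.field_bounds()
    pos = small_scene.molecules[["x_nm", "y_nm", "z_nm"]].to_numpy()
    assert (pos >= lo - 1e-9).all() and (pos <= hi + 1e-9).all()


def test_bead_stack_has_fifty_planes_and_shared_positions():
    cfg = simulate.SimulationConfig(seed=2)
    stacks, true_xy = simulate.make_bead_stack(cfg, n_beads=3, channels=("GLT1", "bassoon"))
    for stack in stacks.values():
        assert stack.n_frames == 50
        assert np.allclose(np.diff(stack.z_samples_nm), 100.0)
    # the same true positions generate every channel (offsets applied downstream)
    assert true_xy.shape == (3, 2)


def test_bead_localizations_reflect_chromatic_offsets():
    cfg = simulate.SimulationConfig(seed=4, bead_sigma_nm=1e-9)
    tables, true = simulate.make_bead_localizations(cfg, n_beads=6)
    for ch, t in tables.items():
        np.testing.assert_allclose(
            t.coords - true, np.tile(cfg.chromatic_offset_nm[ch], (6, 1)), atol=1e-6
        )


class TestRenderFrames:
    def _one_loc_table(self, photons, z=0.0):
        return simulate.io.make_table(
            channel=np.array(["GLT1"], dtype=object),
            frame=np.array([0]),
            xyz=np.array([[3200.0, 3200.0, z]]),
            photons=np.array([photons]),
            bg=np.array([5.0]),
            sigma_xy=np.array([10.0]),
            sigma_z=np.array([25.0]),
        )

    def test_photon_split_between_planes(self, bead_calibration):
        cal, cfg = bead_calibration
        table = self._one_loc_table(1000.0)
        stack = simulate.render_frames(table, cal, cfg, fov_px=64, poisson_noise=False)
        bg_subtracted = stack.plane_a[0] - cfg.bg_photons_per_pixel
        assert bg_subtracted.sum() == pytest.approx(500.0, rel=0.01)

    def test_doubling_photons_doubles_peak(self, bead_calibration):
        cal, cfg = bead_calibration
        peaks = []
        for photons in (1000.0, 2000.0):
            stack = simulate.render_frames(
                self._one_loc_table(photons), cal, cfg, fov_px=64, poisson_noise=False
            )
            peaks.append((stack.plane_a[0] - cfg.bg_photons_per_pixel).max())
        assert peaks[1] == pytest.approx(2 * peaks[0], rel=1e-6)

    def test_empty_table_gives_background_frames(self, bead_calibration):
        cal, cfg = bead_calibration
        empty = simulate.io.make_table(
            channel=np.array([], dtype=object), frame=np.array([], dtype=int),
            xyz=np.zeros((0, 3)), photons=np.array([]), bg=np.array([]),
            sigma_xy=np.array([]), sigma_z=np.array([]),
        )
        stack = simulate.render_frames(empty, cal, cfg, fov_px=32, poisson_noise=False)
        assert np.allclose(stack.plane_a, cfg.bg_photons_per_pixel)

    def test_out_of_range_z_is_skipped_and_counted(self, bead_calibration):
        cal, cfg = bead_calibration
        table = self._one_loc_table(1000.0, z=2000.0)  # beyond the calibrated range
        stack = simulate.render_frames(table, cal, cfg, fov_px=32, poisson_noise=False)
        assert stack.n_skipped == 1
        assert np.allclose(stack.plane_a, cfg.bg_photons_per_pixel)
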