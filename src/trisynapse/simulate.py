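"""Synthetic three-colour dSTORM data: tripartite-synapse scenes and a
generative imaging model.

The ground truth emulates excitatory synapses in neuropil: a presynaptic
(bassoon) and a postsynaptic (Homer1) label layer modelled as discs of
immunolabelled molecules facing each other across the cleft, their centres a
fixed trans-synaptic distance apart (default 120 nm), plus perisynaptic
GLT-1 molecules in a spherical shell around each synapse (shifted slightly
toward the postsynaptic side) and a diffuse GLT-1 background.

The imaging model maps true molecule positions to localisations through the
physical chain of a dSTORM experiment: incomplete labelling, antibody-linkage
displacement, stochastic re-blinking of each fluorophore, anisotropic
localisation noise, per-channel chromatic offset and uniform false
localisations.  Every non-false localisation is traceable to its generating
molecule through a sidecar table, which is what makes parameter-recovery
tests possible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io
from .frames import FrameStack, add_spot, defocus_width

BACKGROUND = -1  # synapse_id sentinel for background / false localisations


class PlacementError(RuntimeError):
    """The field is too small to place the requested synapses at the minimum spacing."""


@dataclass
class SimulationConfig:
    """Generative parameters of the synthetic microscope and scene.

    Lengths are nm.  Defaults encode the study conditions: a 10 x 10 x 2 um
    field (the 2 um axial depth of a biplane stack), 120 nm trans-synaptic
    separation, and imaging parameters of realistic dSTORM magnitude.
    """

    seed: int = 0
    field_size_nm: tuple[float, float, float] = (10000.0, 10000.0, 2000.0)
    n_synapses: int = 50
    synapse_separation_nm: float = 120.0
    min_synapse_spacing_nm: float = 1200.0
    disc_radius_nm: float = 150.0
    disc_thickness_sigma_nm: float = 15.0
    molecules_per_disc: int = 60
    glt1_shell_inner_nm: float = 40.0
    glt1_shell_outer_nm: float = 250.0
    glt1_molecules_per_synapse: int = 80
    glt1_post_shift_nm: float = 20.0
    glt1_background_density_per_um3: float = 5.0
    label_displacement_sigma_nm: float = 12.0
    labelling_efficiency: float = 0.7
    blinks_per_fluorophore: float = 4.0
    sigma_xy_nm: float = 10.0
    sigma_z_nm: float = 25.0
    chromatic_offset_nm: dict = field(
        default_factory=lambda: {
            "bassoon": (15.0, -10.0, 20.0),
            "GLT1": (0.0, 0.0, 0.0),
            "Homer1": (-12.0, 8.0, -25.0),
        }
    )
    false_loc_density_per_um3_per_channel: float = 1.0
    channels: tuple[str, ...] = ("GLT1", "bassoon", "Homer1")
    roles: dict = field(
        default_factory=lambda: {
            "bassoon": io.ROLE_PRE,
            "Homer1": io.ROLE_POST,
            "GLT1": io.ROLE_PERI,
        }
    )
    n_frames: int = 5000
    photons_mean: float = 1000.0
    bg_photons_per_pixel: float = 5.0
    pixel_size_nm: float = 100.0
    # biplane PSF model: focal planes at +-plane_separation/2 around z=0
    psf_w0_nm: float = 150.0
    psf_z_r_nm: float = 450.0
    plane_separation_nm: float = 700.0
    bead_photons: float = 20000.0
    bead_sigma_nm: float = 0.5

    def validate(self) -> None:
        if any(L <= 0 for L in self.field_size_nm):
            raise ValueError("field dimensions must be positive")
        if not (0.0 <= self.labelling_efficiency <= 1.0):
            raise ValueError("labelling_efficiency must be in [0, 1]")
        if self.blinks_per_fluorophore < 1.0:
            raise ValueError("mean blinks per fluorophore must be >= 1")
        if not (0.0 <= self.glt1_shell_inner_nm < self.glt1_shell_outer_nm):
            raise ValueError("GLT-1 shell needs 0 <= inner < outer")
        for name in (
            "synapse_separation_nm",
            "disc_radius_nm",
            "disc_thickness_sigma_nm",
            "psf_w0_nm",
            "psf_z_r_nm",
            "plane_separation_nm",
            "pixel_size_nm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_synapses < 0:
            raise ValueError("n_synapses must be >= 0")

    @property
    def channel_set(self) -> io.ChannelSet:
        return io.ChannelSet(list(self.channels), dict(self.roles))

    @property
    def field_volume_um3(self) -> float:
        lx, ly, lz = self.field_size_nm
        return lx * ly * lz / 1e9

    def field_bounds(self) -> np.ndarray:
        """(2, 3) [low, high] box; z is centred on the focal plane."""
        lx, ly, lz = self.field_size_nm
        return np.array([[0.0, 0.0, -lz / 2.0], [lx, ly, lz / 2.0]])

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["field_size_nm"] = list(self.field_size_nm)
        d["channels"] = list(self.channels)
        d["chromatic_offset_nm"] = {k: list(v) for k, v in self.chromatic_offset_nm.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "field_size_nm" in d:
            d["field_size_nm"] = tuple(d["field_size_nm"])
        if "channels" in d:
            d["channels"] = tuple(d["channels"])
        if "chromatic_offset_nm" in d:
            d["chromatic_offset_nm"] = {
                k: tuple(v) for k, v in d["chromatic_offset_nm"].items()
            }
        return cls(**d)


@dataclass
class GroundTruthScene:
    """True molecule positions plus per-synapse geometry.

    ``molecules``: molecule_id, channel, x_nm, y_nm, z_nm, synapse_id
    (BACKGROUND for diffuse GLT-1).  ``synapses``: synapse_id, centre,
    unit axis (presynaptic -> postsynaptic), pre/post layer centres.
    """

    molecules: pd.DataFrame
    synapses: pd.DataFrame
    cfg: SimulationConfig

    def positions(self, channel: str) -> np.ndarray:
        sel = self.molecules[self.molecules["channel"] == channel]
        return sel[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)


def _unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _orthonormal_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return u, v


def _place_centres(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample synapse centres with a minimum mutual spacing."""
    lo, hi = cfg.field_bounds()
    margin = max(
        cfg.disc_radius_nm + cfg.synapse_separation_nm / 2 + 4 * cfg.disc_thickness_sigma_nm,
        cfg.glt1_shell_outer_nm + cfg.glt1_post_shift_nm,
    )
    low = lo + margin
    high = hi - margin
    if np.any(high <= low):
        raise PlacementError("field too small for the synapse geometry margins")
    centres: list[np.ndarray] = []
    attempts = 0
    max_attempts = 1000 * max(cfg.n_synapses, 1)
    while len(centres) < cfg.n_synapses:
        if attempts >= max_attempts:
            raise PlacementError(
                f"could not place {cfg.n_synapses} synapses with "
                f"{cfg.min_synapse_spacing_nm} nm spacing after {attempts} attempts"
            )
        attempts += 1
        c = rng.uniform(low, high)
        if all(np.linalg.norm(c - p) >= cfg.min_synapse_spacing_nm for p in centres):
            centres.append(c)
    return np.array(centres).reshape(cfg.n_synapses, 3)


def _sample_disc(
    rng: np.random.Generator, centre: np.ndarray, axis: np.ndarray, n: int, cfg: SimulationConfig
) -> np.ndarray:
    u, v = _orthonormal_basis(axis)
    r = cfg.disc_radius_nm * np.sqrt(rng.random(n))
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    thick = rng.normal(0.0, cfg.disc_thickness_sigma_nm, n)
    return (
        centre
        + np.outer(r * np.cos(theta), u)
        + np.outer(r * np.sin(theta), v)
        + np.outer(thick, axis)
    )


def _sample_shell(
    rng: np.random.Generator, centre: np.ndarray, n: int, inner: float, outer: float
) -> np.ndarray:
    r = np.cbrt(rng.uniform(inner**3, outer**3, n))
    return centre + r[:, None] * _unit_vectors(rng, n)


def make_scene(cfg: SimulationConfig) -> GroundTruthScene:
    """Build a ground-truth tripartite-synapse scene, reproducible from cfg.seed."""
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 0])
    cs = cfg.channel_set
    pre_ch, post_ch = cs.presynaptic, cs.postsynaptic
    peri = cs.perisynaptic

    centres = _place_centres(cfg, rng)
    axes = _unit_vectors(rng, cfg.n_synapses) if cfg.n_synapses else np.zeros((0, 3))
    half = cfg.synapse_separation_nm / 2.0
    pre_centres = centres - half * axes
    post_centres = centres + half * axes

    rows: list[pd.DataFrame] = []

    def emit(channel: str, pos: np.ndarray, synapse_id: int) -> None:
        if len(pos) == 0:
            return
        rows.append(
            pd.DataFrame(
                {
                    "channel": channel,
                    "x_nm": pos[:, 0],
                    "y_nm": pos[:, 1],
                    "z_nm": pos[:, 2],
                    "synapse_id": synapse_id,
                }
            )
        )

    for s in range(cfg.n_synapses):
        emit(pre_ch, _sample_disc(rng, pre_centres[s], axes[s], cfg.molecules_per_disc, cfg), s)
        emit(post_ch, _sample_disc(rng, post_centres[s], axes[s], cfg.molecules_per_disc, cfg), s)
        for ch in peri:
            shell_centre = centres[s] + cfg.glt1_post_shift_nm * axes[s]
            emit(
                ch,
                _sample_shell(
                    rng,
                    shell_centre,
                    cfg.glt1_molecules_per_synapse,
                    cfg.glt1_shell_inner_nm,
                    cfg.glt1_shell_outer_nm,
                ),
                s,
            )
    lo, hi = cfg.field_bounds()
    for ch in peri:
        n_bg = rng.poisson(cfg.glt1_background_density_per_um3 * cfg.field_volume_um3)
        emit(ch, rng.uniform(lo, hi, size=(n_bg, 3)), BACKGROUND)

    if rows:
        molecules = pd.concat(rows, ignore_index=True)
    else:
        molecules = pd.DataFrame(
            {"channel": pd.Series(dtype=object)}
            | {c: pd.Series(dtype=float) for c in ("x_nm", "y_nm", "z_nm")}
            | {"synapse_id": pd.Series(dtype=int)}
        )
    # Gaussian tails may poke out of the box; clamp so every position is in-field.
    for i, col in enumerate(("x_nm", "y_nm", "z_nm")):
        molecules[col] = molecules[col].clip(lo[i], hi[i])
    molecules.insert(0, "molecule_id", np.arange(len(molecules), dtype=int))

    synapses = pd.DataFrame(
        {
            "synapse_id": np.arange(cfg.n_synapses, dtype=int),
            "cx_nm": centres[:, 0],
            "cy_nm": centres[:, 1],
            "cz_nm": centres[:, 2],
            "ax": axes[:, 0],
            "ay": axes[:, 1],
            "az": axes[:, 2],
            "pre_cx_nm": pre_centres[:, 0],
            "pre_cy_nm": pre_centres[:, 1],
            "pre_cz_nm": pre_centres[:, 2],
            "post_cx_nm": post_centres[:, 0],
            "post_cy_nm": post_centres[:, 1],
            "post_cz_nm": post_centres[:, 2],
        }
    )
    return GroundTruthScene(molecules, synapses, cfg)


def image_scene(
    scene: GroundTruthScene, cfg: SimulationConfig | None = None
) -> tuple[io.LocalizationTable, pd.DataFrame]:
    """Pass a ground-truth scene through the generative dSTORM model.

    Returns the localisation table and a sidecar DataFrame mapping every
    localisation id to its generating molecule (``molecule_id`` = BACKGROUND
    for false localisations) and synapse.
    """
    cfg = cfg or scene.cfg
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 1])
    lo, hi = cfg.field_bounds()

    chan_col: list[np.ndarray] = []
    pos_col: list[np.ndarray] = []
    frame_col: list[np.ndarray] = []
    photons_col: list[np.ndarray] = []
    mol_col: list[np.ndarray] = []
    syn_col: list[np.ndarray] = []

    for ch in cfg.channels:
        sel = scene.molecules[scene.molecules["channel"] == ch]
        pos = sel[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
        mol_ids = sel["molecule_id"].to_numpy(dtype=int)
        syn_ids = sel["synapse_id"].to_numpy(dtype=int)
        n = len(pos)
        offset = np.asarray(cfg.chromatic_offset_nm.get(ch, (0.0, 0.0, 0.0)), dtype=float)

        labelled = rng.random(n) < cfg.labelling_efficiency
        displacement = rng.normal(0.0, cfg.label_displacement_sigma_nm, size=(n, 3))
        fluoro = pos + displacement
        n_lab = int(labelled.sum())
        blinks = rng.geometric(1.0 / cfg.blinks_per_fluorophore, size=n_lab)
        rep_pos = np.repeat(fluoro[labelled], blinks, axis=0)
        rep_mol = np.repeat(mol_ids[labelled], blinks)
        rep_syn = np.repeat(syn_ids[labelled], blinks)
        m = len(rep_pos)
        noise = rng.normal(size=(m, 3)) * np.array(
            [cfg.sigma_xy_nm, cfg.sigma_xy_nm, cfg.sigma_z_nm]
        )
        locs = rep_pos + noise + offset

        n_false = rng.poisson(
            cfg.false_loc_density_per_um3_per_channel * cfg.field_volume_um3
        )
        false_pos = rng.uniform(lo, hi, size=(n_false, 3))

        all_pos = np.vstack([locs, false_pos]) if m + n_false else np.zeros((0, 3))
        k = len(all_pos)
        chan_col.append(np.full(k, ch, dtype=object))
        pos_col.append(all_pos)
        frame_col.append(rng.integers(0, cfg.n_frames, size=k))
        photons_col.append(rng.gamma(2.0, cfg.photons_mean / 2.0, size=k))
        mol_col.append(np.concatenate([rep_mol, np.full(n_false, BACKGROUND, dtype=int)]))
        syn_col.append(np.concatenate([rep_syn, np.full(n_false, BACKGROUND, dtype=int)]))

    xyz = np.vstack(pos_col) if pos_col else np.zeros((0, 3))
    n_total = len(xyz)
    table = io.make_table(
        channel=np.concatenate(chan_col) if chan_col else np.array([], dtype=object),
        frame=np.concatenate(frame_col) if frame_col else np.array([], dtype=int),
        xyz=xyz,
        photons=np.concatenate(photons_col) if photons_col else np.array([], dtype=float),
        bg=np.full(n_total, cfg.bg_photons_per_pixel),
        sigma_xy=np.full(n_total, cfg.sigma_xy_nm),
        sigma_z=np.full(n_total, cfg.sigma_z_nm),
        meta={
            "channels": list(cfg.channels),
            "pixel_size_nm": cfg.pixel_size_nm,
            "axial_range_nm": float(cfg.field_size_nm[2]),
            "source": "trisynapse.simulate",
            "seed": int(cfg.seed),
        },
    )
    sidecar = pd.DataFrame(
        {
            "id": np.arange(n_total, dtype=int),
            "channel": table.df["channel"].to_numpy(),
            "molecule_id": np.concatenate(mol_col) if mol_col else np.array([], dtype=int),
            "synapse_id": np.concatenate(syn_col) if syn_col else np.array([], dtype=int),
        }
    )
    return table, sidecar


def expected_localization_count(cfg: SimulationConfig, scene: GroundTruthScene) -> float:
    """Analytic expectation of the localisation count for a given scene."""
    n_mol = len(scene.molecules)
    n_channels = len(cfg.channels)
    return (
        n_mol * cfg.labelling_efficiency * cfg.blinks_per_fluorophore
        + cfg.false_loc_density_per_um3_per_channel * cfg.field_volume_um3 * n_channels
    )


def make_bead_localizations(
    cfg: SimulationConfig, n_beads: int = 20
) -> tuple[dict[str, io.LocalizationTable], np.ndarray]:
    """Simulated multi-colour bead *localisations* for channel registration.

    Bead positions are identical across channels before the chromatic offset;
    each channel observes them displaced by its offset plus a small residual
    (bead_sigma_nm) reflecting that fiducial positions are averaged over many
    frames.  Returns ({channel: table}, true bead positions).
    """
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    rng = np.random.default_rng([cfg.seed, 2])
    lo, hi = cfg.field_bounds()
    margin = np.array([500.0, 500.0, 200.0])
    true = rng.uniform(lo + margin, hi - margin, size=(n_beads, 3))
    tables = {}
    for ch in cfg.channels:
        offset = np.asarray(cfg.chromatic_offset_nm.get(ch, (0.0, 0.0, 0.0)), dtype=float)
        obs = true + offset + rng.normal(0.0, cfg.bead_sigma_nm, size=(n_beads, 3))
        tables[ch] = io.make_table(
            channel=np.full(n_beads, ch, dtype=object),
            frame=np.zeros(n_beads, dtype=int),
            xyz=obs,
            photons=np.full(n_beads, cfg.bead_photons),
            bg=np.full(n_beads, cfg.bg_photons_per_pixel),
            sigma_xy=np.full(n_beads, cfg.bead_sigma_nm),
            sigma_z=np.full(n_beads, cfg.bead_sigma_nm),
            meta={"channels": [ch], "source": "trisynapse.simulate.beads"},
        )
    return tables, true


def psf_widths(cfg: SimulationConfig, z_nm) -> tuple[np.ndarray, np.ndarray]:
    """Generative biplane widths (plane A focused at +sep/2, B at -sep/2)."""
    half = cfg.plane_separation_nm / 2.0
    return (
        defocus_width(z_nm, cfg.psf_w0_nm, cfg.psf_z_r_nm, +half),
        defocus_width(z_nm, cfg.psf_w0_nm, cfg.psf_z_r_nm, -half),
    )


def make_bead_stack(
    cfg: SimulationConfig,
    n_beads: int = 5,
    channels: tuple[str, ...] | None = None,
    fov_px: int = 96,
) -> tuple[dict[str, FrameStack], np.ndarray]:
    """Simulated TetraSpeck bead z-stack: fifty planes at 100 nm steps.

    Beads sit on the coverslip (z = 0); each "frame" k images the sample with
    the stage at z_k, so the apparent defocus of a bead in channel c at plane
    k is z_k minus the channel's axial chromatic offset.  Returns
    ({channel: FrameStack}, true lateral bead positions in nm).
    """
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    channels = channels or cfg.channels
    rng = np.random.default_rng([cfg.seed, 3])
    n_planes, step = 50, 100.0
    z = (np.arange(n_planes) - (n_planes - 1) / 2.0) * step  # -2450 .. +2450
    # beads on a jittered grid so even strongly defocused PSFs stay separated
    k = int(np.ceil(np.sqrt(n_beads)))
    margin_px = 22.0
    grid = np.linspace(margin_px, fov_px - margin_px, max(k, 2))
    cells = [(gx, gy) for gy in grid for gx in grid][:n_beads]
    true_xy = (np.array(cells) + rng.uniform(-2.0, 2.0, (n_beads, 2))) * cfg.pixel_size_nm

    stacks = {}
    for ch in channels:
        offset = np.asarray(cfg.chromatic_offset_nm.get(ch, (0.0, 0.0, 0.0)), dtype=float)
        a = np.full((n_planes, fov_px, fov_px), cfg.bg_photons_per_pixel)
        b = np.full_like(a, cfg.bg_photons_per_pixel)
        for k in range(n_planes):
            z_eff = z[k] - offset[2]
            w_a, w_b = psf_widths(cfg, z_eff)
            for bead in range(n_beads):
                x_px = (true_xy[bead, 0] + offset[0]) / cfg.pixel_size_nm
                y_px = (true_xy[bead, 1] + offset[1]) / cfg.pixel_size_nm
                add_spot(a[k], x_px, y_px, float(w_a) / cfg.pixel_size_nm, cfg.bead_photons / 2)
                add_spot(b[k], x_px, y_px, float(w_b) / cfg.pixel_size_nm, cfg.bead_photons / 2)
        a = rng.poisson(a).astype(float)
        b = rng.poisson(b).astype(float)
        stacks[ch] = FrameStack(
            a, b, pixel_size_nm=cfg.pixel_size_nm, channel=ch, z_samples_nm=z.copy()
        )
    return stacks, true_xy


def render_frames(
    table: io.LocalizationTable,
    cal,
    cfg: SimulationConfig,
    fov_px: int | None = None,
    poisson_noise: bool = True,
) -> FrameStack:
    """Render a localisation table into biplane raw frames.

    Each localisation becomes a pixel-integrated Gaussian in both planes with
    widths cal.width_a(z) / cal.width_b(z), half its photons in each plane,
    on a constant background, with optional Poisson shot noise.
    Localisations whose z lies outside the calibration range are skipped and
    counted in ``FrameStack.n_skipped``.
    """
    df = table.df
    px = cfg.pixel_size_nm
    if fov_px is None:
        extent = float(max(df["x_nm"].max(), df["y_nm"].max())) if len(df) else 0.0
        fov_px = max(16, int(np.ceil(extent / px)) + 8)
    n_frames = int(df["frame"].max()) + 1 if len(df) else 1
    a = np.full((n_frames, fov_px, fov_px), cfg.bg_photons_per_pixel)
    b = np.full_like(a, cfg.bg_photons_per_pixel)
    z_lo, z_hi = cal.valid_range_nm
    skipped = 0
    for row in df.itertuples(index=False):
        if not (z_lo <= row.z_nm <= z_hi):
            skipped += 1
            continue
        w_a = float(cal.width_a(row.z_nm)) / px
        w_b = float(cal.width_b(row.z_nm)) / px
        f = int(row.frame)
        add_spot(a[f], row.x_nm / px, row.y_nm / px, w_a, row.photons / 2.0)
        add_spot(b[f], row.x_nm / px, row.y_nm / px, w_b, row.photons / 2.0)
    if poisson_noise:
        rng = np.random.default_rng([cfg.seed, 4])
        a = rng.poisson(a).astype(float)
        b = rng.poisson(b).astype(float)
    return FrameStack(
        a,
        b,
        pixel_size_nm=px,
        channel=str(df["channel"].iloc[0]) if len(df) else "",
        n_skipped=skipped,
    )
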