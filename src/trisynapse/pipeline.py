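"""End-to-end orchestration: simulate/load -> register -> cluster -> pair ->
distances [-> render], all from one config and one seed.

Every run writes its outputs plus a machine-readable ``summary.json`` into a
run directory.  A run is a pure function of (config, seed): re-running with
the same config yields byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, cluster, io, register, render, simulate, synapse

log = logging.getLogger("trisynapse")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Single-run configuration (YAML-serialisable)."""

    seed: int = 0
    input_path: str | None = None  # localisation CSV; None -> simulate
    simulation: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)
    dbscan: cluster.DbscanParams = field(default_factory=cluster.DbscanParams)
    pairing: synapse.PairingParams = field(default_factory=synapse.PairingParams)
    rendering: render.RenderConfig = field(default_factory=render.RenderConfig)
    channels: list[str] = field(default_factory=lambda: ["GLT1", "bassoon", "Homer1"])
    roles: dict = field(
        default_factory=lambda: {
            "bassoon": io.ROLE_PRE,
            "Homer1": io.ROLE_POST,
            "GLT1": io.ROLE_PERI,
        }
    )
    register_channels: bool = True
    ref_channel: str = "GLT1"
    n_registration_beads: int = 20
    nearest_synapse_only: bool = False
    write_renderings: bool = False
    log_level: str = "INFO"

    def channel_set(self) -> io.ChannelSet:
        return io.ChannelSet(list(self.channels), dict(self.roles))

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "input_path": self.input_path,
            "simulation": self.simulation.to_dict(),
            "dbscan": dataclasses.asdict(self.dbscan),
            "pairing": dataclasses.asdict(self.pairing),
            "rendering": {
                "pixel_nm": self.rendering.pixel_nm,
                "mode": self.rendering.mode,
                "point_diameter_nm": self.rendering.point_diameter_nm,
                "z_range_nm": list(self.rendering.z_range_nm),
                "colormap": self.rendering.colormap,
            },
            "channels": list(self.channels),
            "roles": dict(self.roles),
            "register_channels": self.register_channels,
            "ref_channel": self.ref_channel,
            "n_registration_beads": self.n_registration_beads,
            "nearest_synapse_only": self.nearest_synapse_only,
            "write_renderings": self.write_renderings,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulation" in d and isinstance(d["simulation"], dict):
            d["simulation"] = simulate.SimulationConfig.from_dict(d["simulation"])
        if "dbscan" in d and isinstance(d["dbscan"], dict):
            d["dbscan"] = cluster.DbscanParams(**d["dbscan"])
        if "pairing" in d and isinstance(d["pairing"], dict):
            d["pairing"] = synapse.PairingParams(**d["pairing"])
        if "rendering" in d and isinstance(d["rendering"], dict):
            r = dict(d["rendering"])
            if "z_range_nm" in r:
                r["z_range_nm"] = tuple(r["z_range_nm"])
            d["rendering"] = render.RenderConfig(**r)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _quantiles(values: list[float]) -> dict:
    if not values:
        return {"n": 0}
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        return {"n": 0}
    q = np.quantile(arr, [0.25, 0.5, 0.75])
    return {
        "n": int(arr.size),
        "min": float(arr.min()),
        "q25": float(q[0]),
        "median": float(q[1]),
        "q75": float(q[2]),
        "max": float(arr.max()),
    }


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-labelled with the stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the full analysis; returns the summary dict (also written as JSON)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cs = config.channel_set()
    config.simulation.seed = config.seed
    config.to_yaml(out / "config.yaml")

    # --- acquire localisations ------------------------------------------------
    if config.input_path is None:
        table, sidecar = _simulate(config, out)
        n_true_synapses = config.simulation.n_synapses
    else:
        table = io.read_localizations(config.input_path)
        sidecar = None
        n_true_synapses = None
    log.info("localisations: %d over channels %s", len(table), table.channels)

    # --- registration ---------------------------------------------------------
    if config.register_channels:
        table = _register(config, table, out)

    # --- clustering -----------------------------------------------------------
    pre_ch, post_ch = cs.presynaptic, cs.postsynaptic
    clustered = {}
    summaries = {}
    for ch in (pre_ch, post_ch):
        sub, clusters_ = _cluster_channel(table, ch, config.dbscan)
        clustered[ch] = sub
        summaries[ch] = clusters_
        log.info("channel %s: %d clusters", ch, len(clusters_))
    all_clusters = [c for ch in (pre_ch, post_ch) for c in summaries[ch]]
    cluster.clusters_to_frame(all_clusters).to_csv(
        out / "clusters.csv", index=False, float_format="%.6f", lineterminator="\n"
    )

    # --- pairing and distances ------------------------------------------------
    pairs = _pair(summaries[pre_ch], summaries[post_ch], config.pairing)
    _write_pairs(pairs, out / "pairs.csv")
    dsets = _distances(config, table, clustered, pairs, cs)
    _write_distances(dsets, out / "distances.csv")
    with open(out / "histograms.json", "w", encoding="utf-8") as fh:
        json.dump(_histograms(dsets), fh, sort_keys=True, indent=1)
        fh.write("\n")

    # --- optional renderings --------------------------------------------------
    if config.write_renderings:
        _render(config, table, out)

    summary = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_localizations": {ch: int((table.df["channel"] == ch).sum()) for ch in table.channels},
        "n_clusters": {ch: len(summaries[ch]) for ch in (pre_ch, post_ch)},
        "n_synapses": len(pairs),
        "n_true_synapses": n_true_synapses,
        "distance_summaries": {k: ds.summary() for k, ds in sorted(dsets.items())},
        "cluster_stats": {
            ch: {
                "n_locs": _quantiles([c.n_locs for c in summaries[ch]]),
                "hull_volume_nm3": _quantiles(
                    [c.hull_volume_nm3 for c in summaries[ch] if c.hull_volume_nm3 > 0]
                ),
                "density_per_um3": _quantiles(
                    [c.density_per_um3 for c in summaries[ch]]
                ),
            }
            for ch in (pre_ch, post_ch)
        },
    }
    if sidecar is not None:
        sidecar.to_csv(out / "ground_truth_sidecar.csv", index=False, lineterminator="\n")
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, sort_keys=True, indent=1)
        fh.write("\n")
    return summary


@_stage("simulate")
def _simulate(config: PipelineConfig, out: Path):
    scene = simulate.make_scene(config.simulation)
    table, sidecar = simulate.image_scene(scene, config.simulation)
    io.write_localizations(table, out / "localizations.csv")
    scene.molecules.to_csv(out / "ground_truth_molecules.csv", index=False, lineterminator="\n")
    scene.synapses.to_csv(out / "ground_truth_synapses.csv", index=False, lineterminator="\n")
    return table, sidecar


@_stage("register")
def _register(config: PipelineConfig, table: io.LocalizationTable, out: Path):
    if config.input_path is None:
        beads, _ = simulate.make_bead_localizations(
            config.simulation, config.n_registration_beads
        )
        transforms = register.estimate_channel_transforms(beads, config.ref_channel)
    else:
        transforms = {ch: register.ChannelTransform.identity(ch) for ch in table.channels}
    register.save_transforms(transforms, out / "transforms.json")
    registered = register.apply_transform(table, transforms, allow_identity=True)
    io.write_localizations(registered, out / "localizations_registered.csv")
    return registered


@_stage("cluster")
def _cluster_channel(table, ch, params):
    return cluster.cluster_channel(table, ch, params)


@_stage("pair")
def _pair(pre_clusters, post_clusters, params):
    return synapse.pair_synapses(pre_clusters, post_clusters, params)


@_stage("distances")
def _distances(config: PipelineConfig, table, clustered, pairs, cs: io.ChannelSet):
    pre_ch, post_ch = cs.presynaptic, cs.postsynaptic
    pre_t = io.filter_by_channel(table, pre_ch)
    post_t = io.filter_by_channel(table, post_ch)
    dsets = {
        "pre_post_nn": synapse.nn_distances(
            pre_t,
            post_t,
            cutoff_nm=config.pairing.nn_cutoff_nm,
            bin_nm=config.pairing.histogram_bin_nm,
        )
    }
    if cs.perisynaptic:
        glt1 = io.filter_by_channel(table, cs.perisynaptic[0])
        dsets.update(
            synapse.perisynaptic_distances(
                glt1,
                pairs,
                pre_t,
                post_t,
                config.pairing,
                nearest_synapse_only=config.nearest_synapse_only,
            )
        )
    return dsets


@_stage("render")
def _render(config: PipelineConfig, table, out: Path):
    images, merged = render.render_2d(table, config.rendering)
    for ch, img in images.items():
        render.save_image_tiff(img, out / f"render_{ch}.tiff")
    render.save_image_png(merged, out / "render_merged.png")
    render.export_pointcloud(table, config.rendering, out / "pointcloud.ply")


def _write_pairs(pairs, path) -> None:
    lines = ["synapse_id,pre_cluster,post_cluster,cx_nm,cy_nm,cz_nm,center_distance_nm"]
    for p in pairs:
        lines.append(
            f"{p.synapse_id},{p.pre_cluster.cluster_id},{p.post_cluster.cluster_id},"
            f"{p.center_nm[0]:.6f},{p.center_nm[1]:.6f},{p.center_nm[2]:.6f},"
            f"{p.center_distance_nm:.6f}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _write_distances(dsets: dict, path) -> None:
    lines = ["kind,distance_nm,synapse_id"]
    for kind in sorted(dsets):
        ds = dsets[kind]
        for d, s in zip(ds.distances_nm, ds.synapse_ids):
            lines.append(f"{kind},{d:.6f},{int(s)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _histograms(dsets: dict) -> dict:
    out = {}
    for kind, ds in dsets.items():
        edges, counts = ds.histogram
        out[kind] = {
            "bin_edges_nm": edges.tolist(),
            "counts": counts.tolist(),
            "n": ds.n,
            "median_nm": None if not ds.n else ds.median_nm,
            "mode_nm": None if not ds.n else synapse.histogram_mode(ds),
        }
    return out
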