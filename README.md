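# trisynapse

Analysis of three-colour 3D single-molecule localisation microscopy (dSTORM)
data of **tripartite synapses**: presynaptic bassoon, postsynaptic Homer1 and
the perisynaptic astrocytic glutamate transporter GLT-1.

Excitatory synapses are flanked by nanoscopic astrocytic processes whose
molecular arrangement is below the ~250 nm diffraction limit. dSTORM resolves
it by localising individual blinking fluorophores over thousands of frames,
yielding per-molecule 3D coordinate tables. This package implements the full
downstream analysis of such tables — and, because tissue data of this kind is
rarely deposited, a matched synthetic-data generator so every stage is
verifiable against a known ground truth:

- **`trisynapse.io`** — a documented CSV dialect for localisation tables
  (`id,channel,frame,x_nm,y_nm,z_nm,photons,bg,sigma_xy_nm,sigma_z_nm[,cluster_id]`).
- **`trisynapse.simulate`** — ground-truth scenes (apposed pre/post label
  discs 120 nm apart, perisynaptic GLT-1 shells, diffuse background) passed
  through a generative imaging model: incomplete labelling, antibody-linkage
  displacement, geometric blinking, anisotropic localisation noise, chromatic
  offsets, false localisations; optional biplane raw-frame rendering and
  TetraSpeck-style bead z-stacks.
- **`trisynapse.localize`** — a minimal biplane localiser: spot detection,
  pixel-integrated Gaussian fitting, width-vs-z calibration from a bead stack
  (fifty 100 nm steps) and axial estimation from the two detection planes.
- **`trisynapse.register`** — per-channel 3D affine chromatic-aberration
  correction from fiducial beads.
- **`trisynapse.cluster`** — deterministic DBSCAN (eps = 100 nm,
  min_pts = 50 localisations, 3D Euclidean) with per-cluster morphometry:
  localisation count, centroid, convex-hull volume, density.
- **`trisynapse.synapse`** — synapse identification as opposed pre/post
  cluster pairs (centroid distance < 500 nm, one-to-one greedy matching),
  per-localisation bassoon↔Homer1 nearest-neighbour distances, and GLT-1
  distances to synapse centres / nearest pre / nearest post localisations
  within a 500 nm search radius.
- **`trisynapse.render`** — Gaussian-splat and histogram projections,
  z-colour coding, and 30 nm constant-diameter point-cloud (PLY) export.
- **`trisynapse.pipeline` / `trisynapse` CLI** — one-command orchestration,
  reproducible from a single seed.

## Worked example

Run the default simulated experiment (50 synapses in a 10 × 10 × 2 µm field):

```sh
trisynapse run --out run1/ --seed 1
```

or equivalently from Python:

```python
from trisynapse import pipeline
summary = pipeline.run_pipeline(pipeline.PipelineConfig(seed=1), "run1/")
```

Key numbers from `run1/summary.json` at seed 1:

```
n_localizations   GLT1 14197, bassoon 8693, Homer1 8450
n_clusters        bassoon 50, Homer1 49
n_synapses        49   (50 simulated)
pre_post_nn       n=8587, mode 95 nm, median 89.4 nm
glt1_to_pre       n=11361, median 101.2 nm
glt1_to_post      n=11361, median 94.6 nm
glt1_to_center    n=11361, median 200.9 nm
bassoon clusters  63–268 locs (median 163), hull volumes ~1.8–7.0e6 nm³
```

Reading: the pipeline recovers 49 of the 50 simulated synapses as opposed
bassoon–Homer1 cluster pairs. The bassoon→Homer1 nearest-neighbour distance
distribution peaks in the 90–100 nm bin — somewhat below the generative
120 nm separation of the label layers, because a per-localisation minimum
over a densely labelled apposed disc preferentially picks up negative axial
noise fluctuations (see `docs/methods.md`). GLT-1 localisations sit closer
to the postsynaptic channel than to the presynaptic one (median 94.6 vs
101.2 nm), recovering the simulated 20 nm postsynaptic shift of the
perisynaptic shell.

Add `--render` to also write per-channel TIFF projections, a merged RGB PNG
and a 30 nm point-cloud PLY.

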