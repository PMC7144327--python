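# Methods

## The analysis model

The package treats a three-colour 3D dSTORM experiment as a point process:
every blink event yields one localisation (x, y, z in nm, channel, frame,
photons, precision estimates). Analysis proceeds in five stages.

**Channel registration.** Chromatic aberration displaces channels by tens of
nm. From matched multi-colour fiducial beads a full 3D affine transform
(3×3 linear part + translation) per moving channel is estimated by least
squares and applied to that channel's coordinates. Affine subsumes shift,
scale and shear; field-dependent residuals are out of scope. Bead
correspondence for unordered tables uses mutual nearest neighbours within
500 nm. A noiseless affine on ≥4 non-coplanar beads is recovered exactly;
fewer or coplanar beads raise a rank error.

**Clustering.** Synaptic scaffold channels are clustered with DBSCAN in 3D
Euclidean space, eps = 100 nm (inclusive) and min_pts = 50 localisations —
the point's own membership counts toward min_pts (classic DBSCAN). Two
deterministic conventions pin down the labelling: clusters are seeded in
ascending point id, so a border point reachable from several clusters
belongs to the cluster seeded first; labels are renumbered 0..k−1 by
ascending minimum member id. Because classic DBSCAN only approximately
guarantees cluster *size* ≥ min_pts, clusters whose final size falls below
min_pts are additionally discarded, making "a minimum of 50 localisations
per cluster" literally true. Morphometry per cluster: localisation count,
unweighted centroid, convex-hull volume (0 for <4 members or degenerate
configurations, with density reported as NaN), and density in
localisations/µm³ of hull volume. Counts are localisations, never molecule
numbers — blinking overcounting is deliberately not corrected.

**Synapse identification.** Synapses are opposed presynaptic/postsynaptic
cluster pairs with centroid distance ≤ 500 nm, matched one-to-one greedily
in ascending centroid distance (ties: lower pre id, then lower post id).
The synapse centre is the midpoint of the two centroids — the only symmetric
choice — and the axis is the unit vector from the pre to the post centroid.
One-to-one matching prevents a single presynaptic cluster from spawning
several synapses.

**Distance statistics.** Two families: (i) per-localisation nearest-neighbour
distances from every presynaptic to the nearest postsynaptic localisation
(500 nm cutoff, the approximate halfway point between neighbouring
synapses); (ii) for every perisynaptic (GLT-1) localisation and every
synapse whose centre lies within 500 nm, the distance to that centre and to
the nearest member localisation of that synapse's pre and post clusters. A
GLT-1 localisation within range of k synapses contributes k entries
(a `nearest_synapse_only` flag restricts to the closest; a `use_centroid`
flag substitutes centroids for nearest members). Histograms use 10 nm bins —
fine enough to resolve a ~120 nm peak with >10 bins below it; the reported
mode is the centre of the most populated bin, ties resolved toward the
lowest bin.

**Rendering.** 2D projections by Gaussian splatting (each localisation a
unit-mass kernel with σ = its lateral precision; mass conserved within 1%
for interior spots) or plain histogramming; z-colour coding maps axial
position linearly onto a colormap over the 2 µm capture range; point-cloud
export writes one 30 nm-diameter sphere per localisation as ASCII PLY.

## The synthetic-data generator

The generator emulates the tissue geometry the analysis is built for.
Synapse centres are placed uniformly (rejection-sampled, ≥1.2 µm apart —
the observed inter-synapse scale) in a 10 × 10 × 2 µm field; each synapse
gets an isotropically random axis. Pre- and postsynaptic label layers are
discs of radius 150 nm with Gaussian thickness σ = 15 nm, perpendicular to
the axis, their centres exactly 120 nm apart. Perisynaptic GLT-1 molecules
fill a spherical shell (40–250 nm) around the synapse centre shifted 20 nm
toward the postsynaptic side — the minimal model that exposes a
post-vs-pre asymmetry — plus a diffuse background of 5 molecules/µm³.

Imaging follows the physical chain of a dSTORM experiment:

| parameter | default | rationale |
|---|---|---|
| labelling efficiency | 0.7 | not all epitopes carry a detected fluorophore |
| antibody-linkage displacement | σ = 12 nm isotropic | primary+secondary antibody complex size |
| blinks per fluorophore | geometric, mean 4 | simplest memoryless blink-count law |
| localisation noise | σxy = 10 nm, σz = 25 nm | typical biplane dSTORM precision |
| chromatic offsets | ≤30 nm per channel | realistic magnitude; removed by registration |
| false localisations | 1/µm³ per channel | background detections |
| molecules per disc | 60 | gives ~170 localisations per cluster, comfortably above the 50-localisation inclusion threshold and in the range of synaptic SMLM clusters |
| photons per localisation | Gamma(k=2), mean 1000 | low-end dSTORM photon yield |
| frames | 5000 | lower end of a typical acquisition |

Every non-false localisation is traceable to its generating molecule through
a sidecar table; scenes and tables are bit-reproducible from the seed.

The generator does **not** emulate: stage drift (no drift correction exists
downstream either — a documented limitation), dark-state photophysics or
buffer chemistry beyond the blink-count law, multi-emitter PSF overlap
statistics of dense acquisitions, tissue autofluorescence, or any
vendor-specific export quirks. Passing tests therefore demonstrate
correctness of the analysis given the stated generative assumptions, not
robustness to every artefact of real tissue data.

### A known, deliberate property: the NN-distance mode undershoots the layer separation

With densely labelled apposed discs, the per-localisation nearest-neighbour
distance is a minimum over thousands of candidate localisations whose axial
coordinates carry ~35 nm pairwise spread (disc thickness ⊕ linkage ⊕
localisation noise). The minimum preferentially selects negative
fluctuations, so the modal NN distance on the default scene sits at
~95 nm rather than the generative 120 nm plane separation; with every
dispersion term switched off the mode bin is exactly [120, 130) nm. This is
an order-statistic property of the estimator at high labelling density, not
an implementation artefact, and the package reports the distance
distribution as measured. (In real tissue the converse applies: an observed
modal NN distance understates the true epitope plane separation.)

## Biplane localisation

Raw frames are rendered and fitted with **pixel-integrated** Gaussians (erf
differences over pixel edges), which conserves photons exactly and removes
pixelation bias. Detection takes local maxima of the σ = 1 px smoothed
summed planes above the frame median plus a photon threshold, with 5 px
non-maximum suppression (brighter wins; ties to the lower (row, col)).

Calibration images beads at fifty 100 nm z steps. Per plane and bead, a wide
(41 px) Gaussian fit yields width-vs-z curves, averaged across beads. Since
a defocusing Gaussian has w²(z) exactly quadratic in z, the curves are
smoothed by a quadratic fit to w² weighted by 1/w² (so the near-focus
minimum is not dominated by the numerically large defocused values). The
generative optics use w(z) = w0·√(1+((z−zf)/zR)²) with w0 = 150 nm,
zR = 450 nm and detection planes at ±350 nm — a plane separation of ~1.5×
the depth scale, which keeps the log width ratio strictly monotone over
>1.1 µm (matching the ~1 µm working range of biplane systems) and the axial
sensitivity roughly uniform across it. The valid z range is the monotone
branch of the log width ratio around the equal-width (focus) point; the
ratio reverses again at strong defocus, where z would be ambiguous.

Localisation fits both planes **jointly** with z as an explicit parameter
(shared x, y, z, photon count; per-plane widths tied to the calibration
curves; still plain least squares). Independent per-plane width fits
followed by ratio inversion were measured to give 65–80 nm axial RMS at
1000 photons — the width of a defocused PSF (up to ~3.4 px at |z| = 550 nm
with 100 nm pixels) cannot be estimated precisely from a small window — while
the joint fit reaches ~45 nm axial RMS and full recall on isolated emitters.
The monotone ratio inversion remains available (`PSFCalibration.z_from_widths`)
and is exact at the calibration samples; it seeds the joint fit. Precision
estimates use the CRLB-style scalings σxy ≈ w/√N and
σz ≈ |dz/d log-ratio|·√(2/N) — documented approximations. There is no
multi-emitter fitting: overlapping PSFs yield biased fits that enter as
noise, mirroring the reliance on sparse switching. The localiser is optional
in the main pipeline, which consumes localisation tables directly.

## Numerical and procedural choices

- All coordinates in nm throughout (every analysis threshold is stated in
  nm); z = 0 at the nominal focal plane; 0-based indices and frames.
- The canonical CSV writes metadata as leading `# key=json` lines, fixed
  column order, 6-decimal nm fields and `\n` newlines, making
  read∘write byte-identical on canonical files.
- Registration on simulated runs uses simulated bead localisation tables
  (true positions ⊕ chromatic offset ⊕ 0.5 nm residual — fiducials are
  averaged over many frames, so sub-nm effective precision is realistic);
  the image-based path (bead stack → calibration → localisation) exists and
  is exercised separately.
- Greedy pair matching and DBSCAN border assignment are deterministic by
  construction (documented tie-break rules), so identical configs and seeds
  reproduce outputs byte-for-byte, including the run summary JSON.
- Degenerate inputs: empty tables, all-noise clusterings, zero-synapse
  scenes, coplanar hulls and flat fit windows all return well-defined
  results rather than raising.

## Problem sizes used by the test suite

Oracle equivalence runs 100 random DBSCAN instances ≤500 points against a
brute-force O(n²) implementation and 50 nearest-neighbour instances ≤1000
points per channel against full distance matrices; hull volumes are checked
against 10⁶-sample Monte-Carlo rejection estimates; the localiser check uses
80 isolated emitters over 40 frames of a 64-px field; distribution-level
checks (modal distance, asymmetry ordering) use the default 50-synapse
scene, the asymmetry ordering over 100 seeds. These sizes keep the full
suite under two minutes on one CPU while leaving every estimator in the
regime it is designed for.

## Limitations

- No drift simulation or correction; no field-dependent (non-affine)
  chromatic residuals.
- Blinking is a geometric count at a fixed fluorophore position; no on/off
  kinetics, so temporal correlations within clusters are absent.
- Localisation counts are not molecule counts; no overcounting correction.
- The GLT-1 shell is a deliberately minimal geometry; real perisynaptic
  astrocytic processes are irregular sheets.
- The localiser assumes sparse emitters and an isotropic Gaussian PSF per
  plane; no sCMOS pixel-noise maps, astigmatism or multi-emitter models.
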