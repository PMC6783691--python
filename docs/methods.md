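# Methods

`casitebench` is a ground-truth benchmarking platform for calcium
release-site detection in cardiomyocytes. It builds a synthetic but
structurally plausible multi-sarcomere cell volume, simulates Ca²⁺ release
and buffered diffusion from known ryanodine-receptor (RyR) cluster
positions, renders the resulting fluorescence as confocal-like 2D image
series, runs a CLEAN-family point-source detector on those images, and
scores the detections against the known sites. Because every release site
is known exactly, recall, precision and F1 can be quantified as a function
of the *admissible window* — the through-plane distance within which a site
counts as detectable ground truth.

## Geometry

The cell cross-section is a circle of nominal diameter `diameter`
(default 8 µm for the desk profile, 11 µm for the full-scale profile)
voxelized at `resolution` nm, containing `n_mito` smoothed random
elliptical blobs labeled MITOCHONDRION whose total area is bisected to the
requested `mito_area_fraction` (default 0.3 of the non-exterior area;
achieved fraction within ±0.02 or the generator raises). Blob seeds are
dart-thrown with a minimum separation inside a 2-voxel-eroded core, so
every mitochondrial component is fully surrounded by cytosol. The section
is extruded along the longitudinal axis `l` into a volume whose label
pattern is identical at every axial index; z-disks sit at sarcomere
midpoints (1, 3, 5, … µm for 2 µm sarcomeres), so none coincides with a
domain end face. The mitochondrial volume fraction of a real myocyte
section is not tightly constrained; 0.3 is a typical mid-range value and is
configurable.

Coordinates are `(u, v, l)` with voxel centers at `(i + ½)·resolution`;
imaging planes are u–l planes with normal `v`.

## RyR cluster placement and firing

Admissible cluster sites trace the borders of the sarcolemma and
mitochondria: cytosol voxels within `shell_thickness` (250 nm) of a
non-cytosol voxel. Two density regimes are modeled per z-disk:

* **high** — 123 clusters per z-disk on the nominal 11 µm section,
  scaled by cross-sectional area for other diameters (65 per z-disk on the
  8 µm desk section; areal density 1.29 µm⁻² in both). Sampling is uniform
  over border sites subject to a 450 nm spacing floor, calibrated so the
  within-z-disk nearest-neighbor distance reproduces the ≈0.66 µm measured
  in rat ventricular myocytes. Pure uniform sampling over the 1-voxel
  border curves would put many clusters 1–2 voxels apart, a spacing
  distribution no immuno-labeling study supports.
* **low** — 51 per z-disk at full scale (27 at desk scale) with a hard
  1 µm minimum spacing, matching the constraint-based low-recruitment case.

Each z-disk draws from an independent RNG substream, so the point patterns
are unique per z-disk. Firing delays are exponential with mean 6.7 ms;
clusters whose delay exceeds the 30 ms simulation never release and are
excluded from the ground truth by default (a silent site is undetectable by
construction; `count_silent_as_truth` exposes the alternative). With
τ = 6.7 ms this affects ~1% of clusters.

## Reaction–diffusion model

The solver integrates, on the voxel grid,

    ∂C/∂t = D ∇²C + R(C) + J(x, t)

for free Ca²⁺ (effective D = 0.22 µm²/ms) and four buffers — a
fluo-family fluorescent indicator, calmodulin, ATP and (immobile)
troponin C — with mass-action binding `R = k_on·Ca·B_free − k_off·B_bound`.
All kinetic constants live in `data/buffers.yaml` (standard values from the
cardiac spark-modeling literature, e.g. Smith et al. 1998, Izu et al.
2001); nothing is hard-coded. The indicator total is derived from the
resting bound level FCa = 2.08 µM at resting free Ca²⁺ = 0.1 µM, so the
simulated fluorescence background matches the imaging background exactly,
and the initial state is exact chemical equilibrium (all reaction rates
zero).

Each cluster is a spherical volumetric source of radius 100 nm with
Gaussian-of-squared-radius weights `exp(−r²/σ_w²)` (σ_w = 50 nm; at a
215 nm grid a source occupies one voxel) and time course
`A (1 − e^(−t/τ_rise)) e^(−t/τ_decay)` with τ_rise = 1 ms, τ_decay = 5 ms.
The peak amplitude `A` is not a free choice: `calibrate_amplitude` bisects
it (from a closed-form buffered-capacity initial guess) until the bulk
cytosolic free Ca²⁺ at 30 ms reaches ≈1 µM — the physiological rise of a
normal beat, in which essentially all clusters fire, i.e. the
high-density homogeneous configuration. The calibrated amplitude is then
shared by all permutations; consequently the low-density cases produce a
smaller bulk rise (≈0.3–0.5 µM) and the mitochondria-as-obstacles cases a
larger one (the same release mass concentrates in ~70% of the volume),
both deliberate properties of the fixed-release design.

Boundaries are no-flux at the sarcolemma, and additionally at
mitochondrial faces when `mitochondria_as_obstacles` is on (mitochondrial
Ca²⁺ buffering treated as negligible; species absent inside). Time
stepping is forward Euler with an adaptive step obeying both the diffusion
bound `dt ≤ h²/(6 D_max)` and a reaction bound `dt ≤ 0.8/λ_max` with
λ_max recomputed from the current concentration maxima each step (the fast
Ca–ATP pair is the stiff mode). A fixed `dt` can be forced; violated
bounds raise instead of silently blowing up. Negative concentrations are
clamped with a mass ledger and the run aborts if clamped mass exceeds
0.01% of the total. Total Ca²⁺ (free + bound, summed over the domain)
equals the initial total plus time-integrated source input to within 0.1%,
asserted after every simulation.

Verification: a buffer-free point impulse reproduces the analytic 3D
Gaussian diffusion kernel to <1% (at 107.5 nm grid, 1 ms); halving a fixed
`dt` changes the 30 ms FCa field by <0.5%; a centered source in a cube is
exactly symmetric under axis permutation.

**Grid resolution.** The desk profile solves at 215 nm and linearly
upsamples to 107.5 nm for imaging (the imaging contract allows rendering
from a coarser solver grid). The dt-halving and Green's-function checks
above bound the cost of this choice; 107.5/53.75 nm solver grids are
available via `SolverParams` for full-scale runs.

## Image formation

FCa snapshots (every 5 ms, 7 frames over 0–30 ms) are converted to images
by: filling the exterior — and, in obstacle permutations, mitochondria —
with the 2.08 µM background; upsampling to the 107.5 nm imaging grid;
separable 3D convolution with a Gaussian PSF of FWHM 410 nm in-plane and
1800 nm axially, truncated at ±3σ and renormalized (edges padded with the
background, so a uniform rest field is invariant); extracting `n_slices`
(22) equidistant u–l planes spanning the transverse extent with
half-spacing margins; block-averaging 2×2 to 215 nm pixels (block
averaging mimics pixel integration); and adding zero-mean Gaussian noise
with σ = frame mean / SNR (SNR 100). The mean-referenced Gaussian noise
convention is declared, not unique — peak-referenced or Poisson-like noise
would be plausible alternatives and the SNR is configurable.

## Detection (CLEAN family)

The detector operates per imaging slice on the 7-frame series:

1. **Baseline.** A Gaussian-smoothed copy (σ = 2 px) of the first
   (pre-rise) frame is subtracted from every frame; the release signal is
   defined on fluorescence above the resting background. Noise σ is
   estimated from the pre-rise frame (robust MAD of its high-frequency
   residual) when not supplied.
2. **Release signal.** For each consecutive frame pair,
   `rel = clip(f_next − s·g, 0)` where `g` is the previous frame blurred
   with a diffusion-width Gaussian (3 px ≈ √(2 D Δt) for buffered
   fluorescence over 5 ms; `uniform_decay` uses the unblurred frame) and
   `s` is the global least-squares decay factor.
3. **CLEAN.** Högbom loop: repeatedly subtract `loop_gain (0.1) × peak ×
   beam` at the residual peak, crediting the extracted flux to that pixel,
   until the peak falls below `3σ` or a depth floor of 0.5% of the initial
   peak (the decay model is only ~1% accurate, so digging deeper only
   deconvolves systematic residuals). The beam is the in-plane PSF
   marginal widened, per frame pair, by the diffusive spread estimated
   from the dominant blob's half-max area (onset-pair blobs are ~σ 1.9 px,
   later pairs ~1.2 px; a fixed beam either smears components or rings).
   Component mass plus residual mass equals the input mass for interior
   sources.
4. **Segmentation.** Components summed over the six frame pairs form the
   release map; after σ = 1 px smoothing it is watershed-segmented with a
   support mask at 3σ and seeds at `3σ·√n_pairs` (near-threshold residuals
   accumulate like √n across pairs, true sites coherently). Regions
   smaller than 4 px are dropped, as are CRUs below 10% of the slice's
   90th-percentile CRU amplitude — decay-model halos carry ≲8% of their
   parent site's mass on clean single-plane scenes, and without this cut
   the far-field precision saturates around 0.8 instead of approaching 1.
   Centroids are amplitude-weighted, in continuous pixel coordinates.

These internals (gain, stopping rule, removal model, segmentation
thresholds) are this package's conventions, chosen against internal
oracle scenes (single sources, close pairs, the five-site in-plane scene);
equivalence with any specific published implementation is not claimed.
All are exposed on `CleanParams`.

## Evaluation

For a slice at position `v₀` and admissible window `w`, ground truths are
firing clusters with `|v − v₀| ≤ w`. A truth matches the nearest available
CRU whose 1-pixel-dilated region contains its projected in-plane position;
matching is globally greedy over (truth, CRU) pairs sorted by centroid
distance, each matched CRU leaving the pool, so
`TP(gt) = TP(det) + FN` holds by construction. Recall = TP(det)/TP(gt),
precision = TP(det)/(TP(det)+FP), F1 = harmonic mean, computed from the
mean recall/precision curves over slices when sweeping windows (0–1500 nm
in 10 nm steps). Degenerate conventions: recall is NaN with no ground
truths; precision is 1 with neither truths nor detections, NaN with truths
but no detections; F1 is 0 when either component is 0. The break-even
point interpolates the crossing of the mean recall and precision curves
(flagged argmin if they never cross).

Differential recall — the detection fraction per 10 nm depth band — is the
discrete derivative `ΔTP(det)/ΔTP(gt)` along the window sweep with counts
pooled over slices, so the count-weighted band mean telescopes exactly to
the cumulative recall at any window. The band series is Savitzky–Golay
smoothed (order 3, frame 21) and summarized by a single-term Gaussian fit
`a·exp(−z²/2σ²)`; σ quantifies the effective detection depth.

## Experiment profiles and scale

The `desk` profile (default) uses a 4-z-disk, 8 µm section at a 215 nm
solver grid with area-scaled cluster counts; a full experiment (4
permutations + calibration) takes ~8 minutes on one CPU. The `paper`
profile configures the full 8-sarcomere, 11 µm, 107.5 nm setup for larger
machines. Every report states the domain and grid scale, so scaled-down
results are never silently compared with full-scale claims, and every
stochastic stage derives its seed from the single experiment seed.

## What the synthetic data does and does not capture

The generator reproduces the features that drive detection performance:
areal cluster density and nearest-neighbor spacing at z-disks, border-
constrained placement, exponential firing dispersion, physiological bulk
Ca²⁺ rise, realistic PSF/pixel/noise parameters, and mitochondria as
diffusion barriers. It does not capture: real ET-derived cross-section
shapes or myofibril substructure (the border shell contains only
sarcolemma and mitochondria outlines), longitudinal structural variation,
amplitude heterogeneity between clusters (off by default), CICR feedback
(release is scheduled, not regenerative), SERCA/NCX/IP3R fluxes,
photobleaching, or Poisson photon statistics. Passing benchmarks here
therefore speak to the geometric/optical limits of 2D detection of 3D
release sites, not to every biological confound in live-cell data.

## Known limitations

* Detection performance at the desk scale runs ~0.05–0.10 below the
  full-scale published values in F1 terms for the low-density cases: the
  smaller field of view raises the relative weight of cell-rim reflection
  artifacts, and residual decay-model halos cap far-field precision near
  0.9. The qualitative structure (density ordering, depth-response
  ordering, barrier effects an order of magnitude smaller than density
  effects, break-even windows within ~20 nm of the published ones) is
  reproduced.
* The explicit solver is the cost bottleneck; the stiff Ca–ATP pair
  forces ~3–4k steps per 30 ms at 215 nm. An implicit-reaction variant
  would relax this but is not implemented.
* The matching is greedy (deterministic, pair-distance ordered), bounded
  within 1 of the optimal bipartite matching on small scenes by test, but
  not guaranteed optimal.
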