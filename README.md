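# casitebench

**Ground-truth benchmarking of calcium release-site detection in simulated
cardiomyocyte confocal imaging.**

Each heartbeat begins with Ca²⁺ release through clusters of ryanodine
receptors (RyRs) at the z-disks of cardiomyocytes, raising bulk cytosolic
[Ca²⁺] from 0.1 µM to ≈1 µM within ~30 ms. CLEAN-family algorithms detect
these release sites in live-cell confocal movies by treating them as point
sources and iteratively deconvolving the point spread function from the
fluorescence signal — but with real data there is no ground truth to say
which detections are right. `casitebench` provides that ground truth *in
silico*: it simulates the whole measurement chain, from release sites whose
positions are known exactly, through reaction–diffusion of Ca²⁺ and its
buffers, to confocal image formation and CLEAN detection, and then scores
the detector.

The core quantities, for ground-truth sites within an *admissible window*
`w` of the imaging plane:

```
recall(w)    = TP_detected / TP_ground_truth        TP_gt = TP_det + FN
precision(w) = TP_detected / (TP_detected + FP)
F1(w)        = 2 / (1/recall + 1/precision)
```

plus the precision–recall **break-even point** (where FP ≈ FN) and the
**differential recall** d TP_det / d TP_gt per 10 nm depth band, whose
single-term Gaussian fit σ measures how deep below the focal plane sites
remain detectable.

The benchmark crosses two factors into four model permutations: RyR
cluster density (high: 123 per z-disk on an 11 µm section, matching
immuno-labeling statistics with ≈0.66 µm nearest-neighbor spacing; low: 51
per z-disk with a 1 µm minimum spacing) × mitochondria as diffusion
barriers (on/off).

## Worked example

Five well-separated clusters placed exactly in one imaging plane of an
8 µm cell, simulated, rendered at SNR 100 and detected
(`examples/03_render_and_detect.py`):

```
stack: 9 slices x 7 frames, 42x19 px at 215 nm
estimated noise sigma: 0.0210 (SNR 100 of the 2.08 background)
detected 6 CRUs; true in-plane sites: 5
  CRU at ( 29.5,   4.4) px, amplitude  253.0, nearest truth 0.11 px
  CRU at ( 25.4,  14.8) px, amplitude  256.5, nearest truth 0.28 px
  CRU at ( 19.8,   5.5) px, amplitude  196.9, nearest truth 0.31 px
  CRU at ( 13.5,  13.5) px, amplitude  168.0, nearest truth 0.02 px
  CRU at (  9.6,   4.4) px, amplitude  149.6, nearest truth 0.09 px
  CRU at (  9.0,   0.7) px, amplitude   18.5, nearest truth 3.82 px
```

All five true sites are recovered to sub-pixel accuracy; the sixth, an
order of magnitude fainter, is a decay-model residual near a strong site —
exactly the kind of false positive whose rate the full benchmark
quantifies. The noise estimate matches the imaging model (2.08 µM resting
fluorescence / SNR 100 ≈ 0.021).

The full four-permutation benchmark (`examples/04_full_benchmark.py`,
~8 min) sweeps the admissible window for each permutation and prints the
peak-F1 / break-even table; low-density cases outperform high-density
ones, the detection depth σ is ~2× narrower at high density, and the
mitochondrial-barrier effect on F1 is an order of magnitude smaller than
the density effect.

Other entry points:

```python
from casitebench import pipeline as pl
cfg = pl.desk_profile(seed=1)            # 8 um / 4 z-disk / 215 nm profile
report, results = pl.run_experiment(cfg, output_dir="out")
```

or the CLI: `casitebench run -o out` (also `simulate`, `render`, `detect`,
`evaluate`, `report`; `detect` accepts externally supplied TIFF series).

## Layout

```
src/casitebench/
  geometry.py     synthetic cross-sections, extrusion, border shells
  clusters.py     RyR cluster placement, spacing statistics, firing times
  rdsolver.py     explicit reaction-diffusion solver + amplitude calibration
  imaging.py      PSF, 3D blurring, slice extraction, pixels, noise
  detector.py     release-signal estimation, Hogbom CLEAN, CRU segmentation
  evaluation.py   classification, recall/precision/F1, break-even,
                  differential recall
  pipeline.py     experiment orchestration, profiles, reports
  cli.py          thin command-line wrapper
docs/methods.md   model, parameters, conventions, limitations
examples/         narrative scripts, one per capability
```
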