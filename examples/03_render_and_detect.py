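"""Render confocal-like images of a simulated scene and detect release sites.

Builds a scene with five well-separated clusters in a known imaging plane,
renders the fluorescence stack (410/1800 nm PSF, 215 nm pixels, SNR 100),
runs the CLEAN detector on the central slice and compares the detected CRU
centroids with the true positions.
"""

import numpy as np

from casitebench import clusters as clu
from casitebench import detector as det
from casitebench import geometry as geo
from casitebench import imaging as img
from casitebench import rdsolver as rd

section = geo.generate_cross_section(8000, 0.0, 0, resolution=215, seed=0)
volume = geo.extrude(section, axial_length=4000, sarcomere_length=2000)
positions = img.slice_positions(volume, 9)
vmid = positions[4]
res = volume.resolution


def snap(u, l):
    iu, iv, il = int(u // res), int(vmid // res), int(l // res)
    return ((iu + 0.5) * res, (iv + 0.5) * res, (il + 0.5) * res)


scene = [(2000, 1000, 1.0), (4200, 1200, 5.0), (6300, 1000, 9.0), (3000, 3000, 2.0), (5500, 3100, 14.0)]
cset = clu.ClusterSet(
    [clu.RyRCluster(center=snap(u, l), zdisk_index=0, fire_time=t) for u, l, t in scene],
    "low", 5, None, 0,
)
series = rd.simulate(volume, cset, rd.SolverParams(release=rd.ReleaseParams(amplitude=3465.0)))
stack = img.render_images(
    series, volume, img.ImagingParams(n_slices=9, snr=100.0, noise_seed=5)
)
print(f"stack: {stack.n_slices} slices x {stack.n_frames} frames, "
      f"{stack.frames.shape[2]}x{stack.frames.shape[3]} px at {stack.pixel_size:.0f} nm")

result = det.detect(stack.slice_series(4), det.CleanParams(), slice_index=4)
print(f"estimated noise sigma: {result.noise_sigma:.4f} (SNR 100 of the 2.08 background)")
print(f"detected {len(result.crus)} CRUs; true in-plane sites: {len(cset)}")
truth = np.array([[c.center[0] / 215, c.center[2] / 215] for c in cset.clusters])
for cru in result.crus:
    d = np.hypot(*(truth - cru.centroid).T).min()
    print(f"  CRU at ({cru.centroid[0]:5.1f}, {cru.centroid[1]:5.1f}) px, "
          f"amplitude {cru.integrated_amplitude:6.1f}, nearest truth {d:.2f} px")
# The five true sites are recovered to sub-pixel accuracy.  A weak extra CRU
# (an order of magnitude fainter) may appear near a strong site: a residual of
# the frame-to-frame decay model, the same kind of false positive whose rate
# the full benchmark quantifies.
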