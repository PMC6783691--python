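import numpy as np
import pytest

from casitebench import clusters as clu
from casitebench import geometry as geo
from casitebench import imaging as img
from casitebench import rdsolver as rd


@pytest.fixture(scope="session")
def tiny_volume():
    """Small homogeneous two-sarcomere volume (6 um section, 215 nm grid)."""
    cs = geo.generate_cross_section(
        diameter=6000, mito_area_fraction=0.3, n_mito=6, resolution=215, seed=1
    )
    return geo.extrude(cs, axial_length=4000, sarcomere_length=2000)


@pytest.fixture(scope="session")
def plain_volume():
    """Obstacle-free cylinder for solver and imaging tests."""
    cs = geo.generate_cross_section(
        diameter=6000, mito_area_fraction=0.0, resolution=215, seed=0
    )
    return geo.extrude(cs, axial_length=4000, sarcomere_length=2000)


@pytest.fixture(scope="session")
def cube_volume():
    """All-cytosol cube (no exterior), for Green's-function and symmetry tests."""
    n = 21
    grid = np.full((n, n, n), geo.CYTOSOL, dtype=np.uint8)
    cs = geo.CrossSection(grid[:, :, 0].copy(), 215.0, n * 215.0)
    return geo.CellVolume(
        label_grid=grid,
        resolution=215.0,
        axial_length=n * 215.0,
        sarcomere_length=n * 215.0,
        zdisk_positions=np.array([n * 215.0 / 2]),
        diameter=n * 215.0,
        cross_section=cs,
    )


@pytest.fixture(scope="session")
def inplane_scene():
    """Five well-separated clusters in one imaging plane, simulated and rendered.

    The canonical end-to-end oracle: every firing cluster lies exactly in the
    central slice plane of an 8 um cell, pairwise separations exceed 2 um, so
    a coherent pipeline must recover essentially all of them with no false
    positives.
    """
    cs = geo.generate_cross_section(
        diameter=8000, mito_area_fraction=0.0, resolution=215, seed=0
    )
    vol = geo.extrude(cs, axial_length=4000, sarcomere_length=2000)
    res = vol.resolution
    positions = img.slice_positions(vol, 9)
    vmid = positions[4]

    def snap(u, l):
        iu, iv, il = int(u // res), int(vmid // res), int(l // res)
        return ((iu + 0.5) * res, (iv + 0.5) * res, (il + 0.5) * res)

    pts = [(2000, 1000, 1.0), (4200, 1200, 5.0), (6300, 1000, 9.0), (3000, 3000, 2.0), (5500, 3100, 14.0)]
    cls = [
        clu.RyRCluster(center=snap(u, l), zdisk_index=0, fire_time=t)
        for (u, l, t) in pts
    ]
    cset = clu.ClusterSet(cls, "low", len(cls), None, 0)
    params = rd.SolverParams(release=rd.ReleaseParams(amplitude=3465.0))
    series = rd.simulate(vol, cset, params)
    return vol, cset, series, positions
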