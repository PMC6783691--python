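"""Synthetic cardiomyocyte geometry: cross-sections and extruded 3D volumes.

The simulation domain emulates a transverse slice through a ventricular
cardiomyocyte at the level of a z-disk — a roughly circular cytosolic region
(~11 um across at full scale) containing mitochondrial inclusions — extruded
along the longitudinal axis over several sarcomeres.  Mitochondria are
generated as smoothed random elliptical blobs embedded strictly inside the
cytosol, so that each mitochondrial component is fully surrounded by cytosol.

Coordinate convention: axes ``(u, v, l)`` with ``l`` the extrusion
(longitudinal) axis.  Imaging planes are u-l planes with normal ``v``.
Voxel indices are 0-based; the center of voxel ``i`` lies at
``(i + 0.5) * resolution`` nm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage

EXTERIOR = 0
CYTOSOL = 1
MITOCHONDRION = 2

LABEL_NAMES = {EXTERIOR: "exterior", CYTOSOL: "cytosol", MITOCHONDRION: "mitochondrion"}


class PlacementError(RuntimeError):
    """Raised when a geometric constraint cannot be satisfied."""


@dataclass
class CrossSection:
    """2D labeled transverse slice of the cell.

    Attributes
    ----------
    label_grid : (nu, nv) uint8 array of {EXTERIOR, CYTOSOL, MITOCHONDRION}.
    resolution : voxel edge length in nm.
    diameter : nominal cell diameter in nm.
    seed : RNG seed used to generate the section (None if constructed directly).
    """

    label_grid: np.ndarray
    resolution: float
    diameter: float
    seed: int | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_grid.shape

    def mito_area_fraction(self) -> float:
        """Achieved mitochondrial fraction of the non-exterior area."""
        non_ext = int(np.count_nonzero(self.label_grid != EXTERIOR))
        mito = int(np.count_nonzero(self.label_grid == MITOCHONDRION))
        return mito / non_ext if non_ext else 0.0


@dataclass
class CellVolume:
    """3D labeled voxel grid obtained by extruding a :class:`CrossSection`.

    ``label_grid`` has shape ``(nu, nv, nl)``; every axial index carries the
    same label pattern (pure extrusion).  ``zdisk_positions`` are the axial
    (l) coordinates in nm of the z-disk planes, placed at sarcomere midpoints.
    """

    label_grid: np.ndarray
    resolution: float
    axial_length: float
    sarcomere_length: float
    zdisk_positions: np.ndarray
    diameter: float | None = None
    seed: int | None = None
    cross_section: CrossSection = field(repr=False, default=None)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.label_grid.shape

    @property
    def n_zdisks(self) -> int:
        return len(self.zdisk_positions)

    def zdisk_layer(self, zdisk_index: int) -> int:
        """Axial voxel index nearest to the given z-disk plane."""
        return int(round(self.zdisk_positions[zdisk_index] / self.resolution - 0.5))

    def voxel_volume_um3(self) -> float:
        return (self.resolution / 1000.0) ** 3


def _blob_quadratic_forms(rng, centers, r_nominal, resolution, shape):
    """Per-blob normalized elliptical distance fields (1.0 at nominal radius)."""
    uu, vv = np.meshgrid(
        (np.arange(shape[0]) + 0.5) * resolution,
        (np.arange(shape[1]) + 0.5) * resolution,
        indexing="ij",
    )
    fields = []
    for cu, cv in centers:
        aspect = rng.uniform(1.0, 2.0)
        theta = rng.uniform(0.0, np.pi)
        ra = r_nominal * np.sqrt(aspect)
        rb = r_nominal / np.sqrt(aspect)
        du, dv = uu - cu, vv - cv
        x = du * np.cos(theta) + dv * np.sin(theta)
        y = -du * np.sin(theta) + dv * np.cos(theta)
        fields.append((x / ra) ** 2 + (y / rb) ** 2)
    return np.stack(fields)


def generate_cross_section(
    diameter: float = 11_000.0,
    mito_area_fraction: float = 0.3,
    n_mito: int = 20,
    resolution: float = 53.75,
    seed: int = 0,
    area_tol: float = 0.02,
    max_retries: int = 10,
) -> CrossSection:
    """Generate a circular cell cross-section with mitochondrial blobs.

    Parameters
    ----------
    diameter : nominal cell diameter, nm.
    mito_area_fraction : requested mitochondrial fraction of non-exterior area,
        in [0, 0.5).
    n_mito : number of mitochondrial blob components.
    resolution : voxel edge, nm.
    seed : RNG seed; identical seeds give bit-identical grids.
    area_tol : maximum absolute deviation of the achieved fraction.
    max_retries : blob-placement attempts before giving up.

    Raises
    ------
    PlacementError
        If ``n_mito`` blobs at the requested fraction cannot be embedded
        without touching the exterior.
    """
    if diameter < 20 * resolution:
        raise ValueError(f"diameter {diameter} nm must be >= 20 x resolution ({resolution} nm)")
    if not 0 <= mito_area_fraction < 0.5:
        raise ValueError("mito_area_fraction must lie in [0, 0.5)")

    margin = 2
    n = int(np.ceil(diameter / resolution)) + 2 * margin
    centers_nm = (np.arange(n) + 0.5) * resolution
    c0 = n * resolution / 2.0
    uu, vv = np.meshgrid(centers_nm, centers_nm, indexing="ij")
    rr = np.hypot(uu - c0, vv - c0)
    cell = rr <= diameter / 2.0

    labels = np.full((n, n), EXTERIOR, dtype=np.uint8)
    labels[cell] = CYTOSOL

    if mito_area_fraction == 0 or n_mito == 0:
        return CrossSection(labels, resolution, diameter, seed)

    # Blobs must stay clear of the exterior: restrict to a 2-voxel-eroded core.
    allowed = ndimage.binary_erosion(cell, iterations=2)
    cell_area = int(np.count_nonzero(cell))
    target_area = int(round(mito_area_fraction * cell_area))
    blob_area = target_area / n_mito
    r_nom = np.sqrt(blob_area / np.pi) * resolution
    min_sep = 2.4 * r_nom

    rng = np.random.default_rng(seed)
    for _attempt in range(max_retries):
        # Dart-throwing for blob seed points with minimum separation.
        pts: list[tuple[float, float]] = []
        allowed_idx = np.argwhere(allowed)
        for _ in range(500 * n_mito):
            iu, iv = allowed_idx[rng.integers(len(allowed_idx))]
            p = ((iu + 0.5) * resolution, (iv + 0.5) * resolution)
            if all(np.hypot(p[0] - q[0], p[1] - q[1]) >= min_sep for q in pts):
                pts.append(p)
                if len(pts) == n_mito:
                    break
        if len(pts) < n_mito:
            continue

        q = _blob_quadratic_forms(rng, pts, r_nom, resolution, (n, n))
        qmin = q.min(axis=0)

        # Bisect a global size scale s (region = qmin <= s) to hit target_area.
        lo, hi = 0.0, 100.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            area = int(np.count_nonzero((qmin <= mid) & allowed))
            if area < target_area:
                lo = mid
            else:
                hi = mid
        region = (qmin <= hi) & allowed
        achieved = np.count_nonzero(region) / cell_area
        if abs(achieved - mito_area_fraction) > area_tol:
            continue
        n_comp = ndimage.label(region)[1]
        if n_comp != n_mito:
            continue  # blobs merged or vanished; retry with fresh placement
        out = labels.copy()
        out[region] = MITOCHONDRION
        return CrossSection(out, resolution, diameter, seed)

    raise PlacementError(
        f"could not embed {n_mito} mitochondrial blobs at area fraction "
        f"{mito_area_fraction} within the eroded interior after {max_retries} attempts"
    )


def extrude(
    cross_section: CrossSection,
    axial_length: float = 16_000.0,
    sarcomere_length: float = 2_000.0,
) -> CellVolume:
    """Extrude a cross-section into a 3D multi-sarcomere volume.

    Z-disks are placed at sarcomere midpoints, so for an 16 um / 2 um
    configuration they sit at 1, 3, ..., 15 um and never coincide with a
    domain end face.
    """
    n_sarc = axial_length / sarcomere_length
    if abs(n_sarc - round(n_sarc)) > 1e-9:
        raise ValueError(
            f"axial_length {axial_length} is not an integer multiple of "
            f"sarcomere_length {sarcomere_length}"
        )
    n_sarc = int(round(n_sarc))
    nl = int(round(axial_length / cross_section.resolution))
    grid3d = np.repeat(cross_section.label_grid[:, :, None], nl, axis=2)
    zdisks = (np.arange(n_sarc) + 0.5) * sarcomere_length
    return CellVolume(
        label_grid=grid3d,
        resolution=cross_section.resolution,
        axial_length=axial_length,
        sarcomere_length=sarcomere_length,
        zdisk_positions=zdisks,
        diameter=cross_section.diameter,
        seed=cross_section.seed,
        cross_section=cross_section,
    )


def border_shell(volume: CellVolume, shell_thickness: float) -> np.ndarray:
    """Mask of cytosol voxels within ``shell_thickness`` nm of an obstacle.

    These border sites — tracing the sarcolemma and mitochondrial outlines —
    are the admissible RyR cluster locations.  Distances are Euclidean
    between voxel centers.  Because the volume is a pure extrusion the mask
    is computed on the cross-section and tiled axially.
    """
    if shell_thickness < volume.resolution:
        raise ValueError("shell_thickness must be >= resolution")
    cs = volume.label_grid[:, :, 0]
    cyt = cs == CYTOSOL
    dist = ndimage.distance_transform_edt(cyt) * volume.resolution
    shell2d = cyt & (dist <= shell_thickness)
    return np.repeat(shell2d[:, :, None], volume.shape[2], axis=2)


def save_volume(volume: CellVolume, tiff_path, json_path=None) -> None:
    """Write the labeled volume as an 8-bit 3D TIFF plus a JSON sidecar."""
    tiff_path = str(tiff_path)
    json_path = json_path or tiff_path.rsplit(".", 1)[0] + ".json"
    tifffile.imwrite(
        tiff_path, np.moveaxis(volume.label_grid, 2, 0), photometric="minisblack"
    )
    meta = {
        "resolution_nm": volume.resolution,
        "axial_length_nm": volume.axial_length,
        "sarcomere_length_nm": volume.sarcomere_length,
        "zdisk_positions_nm": list(map(float, volume.zdisk_positions)),
        "diameter_nm": volume.diameter,
        "seed": volume.seed,
        "axis_order": "l,u,v (TIFF pages along l)",
    }
    with open(json_path, "w") as fh:
        json.dump(meta, fh, indent=2)


def load_volume(tiff_path, json_path=None) -> CellVolume:
    tiff_path = str(tiff_path)
    json_path = json_path or tiff_path.rsplit(".", 1)[0] + ".json"
    grid = np.moveaxis(tifffile.imread(tiff_path), 0, 2)
    with open(json_path) as fh:
        meta = json.load(fh)
    cs = CrossSection(
        grid[:, :, 0].copy(), meta["resolution_nm"], meta.get("diameter_nm"), meta.get("seed")
    )
    return CellVolume(
        label_grid=grid,
        resolution=meta["resolution_nm"],
        axial_length=meta["axial_length_nm"],
        sarcomere_length=meta["sarcomere_length_nm"],
        zdisk_positions=np.asarray(meta["zdisk_positions_nm"], dtype=float),
        diameter=meta.get("diameter_nm"),
        seed=meta.get("seed"),
        cross_section=cs,
    )
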