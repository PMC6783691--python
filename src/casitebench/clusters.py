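"""Ground-truth RyR cluster placement and stochastic firing times.

Clusters of ryanodine receptors sit on the borders of myofibrils,
mitochondria and the sarcolemma at each z-disk.  Two density regimes are
modeled: a *high* density matching immuno-labeling statistics (123 clusters
per z-disk on an ~11 um section) and a *low* density (51 per z-disk) with a
1 um minimum spacing between cluster centers.  Firing delays follow an
exponential distribution with a 6.7 ms characteristic time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from casitebench.geometry import CellVolume, PlacementError, border_shell

#: per-z-disk cluster counts on the nominal ~11 um section
HIGH_DENSITY_N = 123
LOW_DENSITY_N = 51
NOMINAL_DIAMETER_NM = 11_000.0
DEFAULT_MIN_SPACING_NM = 1_000.0
DEFAULT_FIRE_TAU_MS = 6.7


@dataclass(frozen=True)
class RyRCluster:
    """A single ground-truth release site."""

    center: tuple[float, float, float]  # (u, v, l) nm
    zdisk_index: int
    fire_time: float = 0.0  # ms
    amplitude_scale: float = 1.0
    source_radius: float = 100.0  # nm


@dataclass
class ClusterSet:
    clusters: list[RyRCluster]
    density_mode: str  # {"high", "low"}
    n_per_zdisk: int
    min_spacing: float | None
    seed: int | None = None
    shell_thickness: float = field(default=250.0)

    def __len__(self) -> int:
        return len(self.clusters)

    def centers(self) -> np.ndarray:
        """(n, 3) array of cluster centers in nm, (u, v, l)."""
        return np.array([c.center for c in self.clusters], dtype=float)

    def fire_times(self) -> np.ndarray:
        return np.array([c.fire_time for c in self.clusters], dtype=float)

    def firing(self, duration: float) -> list[RyRCluster]:
        """Clusters that release within the simulated window."""
        return [c for c in self.clusters if c.fire_time < duration]

    def with_fire_times(self, times: np.ndarray) -> "ClusterSet":
        new = [replace(c, fire_time=float(t)) for c, t in zip(self.clusters, times, strict=True)]
        return replace_clusters(self, new)


def replace_clusters(cs: ClusterSet, clusters: list[RyRCluster]) -> ClusterSet:
    return ClusterSet(
        clusters=clusters,
        density_mode=cs.density_mode,
        n_per_zdisk=cs.n_per_zdisk,
        min_spacing=cs.min_spacing,
        seed=cs.seed,
        shell_thickness=cs.shell_thickness,
    )


def scaled_count(reference_n: int, diameter: float, reference_diameter: float = NOMINAL_DIAMETER_NM) -> int:
    """Scale a per-z-disk cluster count to a different section diameter.

    Preserves areal density: counts scale with the cross-sectional area,
    i.e. with the squared diameter ratio.
    """
    return max(1, int(round(reference_n * (diameter / reference_diameter) ** 2)))


def place_clusters(
    volume: CellVolume,
    density_mode: str = "high",
    n_per_zdisk: int | None = None,
    min_spacing: float | None = None,
    seed: int = 0,
    shell_thickness: float = 250.0,
    max_attempts: int = 200,
) -> ClusterSet:
    """Place ground-truth clusters on border sites at each z-disk.

    High mode samples sites uniformly without replacement from the border
    shell; low mode additionally enforces ``min_spacing`` (default 1 um)
    between cluster centers within a z-disk, via rejection.  Each z-disk
    receives a unique point pattern (independent RNG substreams).

    Raises
    ------
    PlacementError
        If the spacing constraint cannot be met after bounded attempts; the
        message reports the achieved count.
    """
    if density_mode not in ("high", "low"):
        raise ValueError(f"density_mode must be 'high' or 'low', got {density_mode!r}")
    if n_per_zdisk is None:
        ref = HIGH_DENSITY_N if density_mode == "high" else LOW_DENSITY_N
        n_per_zdisk = scaled_count(ref, volume.diameter or NOMINAL_DIAMETER_NM)
    if min_spacing is None and density_mode == "low":
        min_spacing = DEFAULT_MIN_SPACING_NM

    shell = border_shell(volume, shell_thickness)
    res = volume.resolution
    sites_uv = np.argwhere(shell[:, :, 0])  # extrusion: same shell at every layer
    if len(sites_uv) < n_per_zdisk:
        raise PlacementError(
            f"only {len(sites_uv)} admissible border sites per z-disk, need {n_per_zdisk}"
        )

    ss = np.random.SeedSequence(seed)
    clusters: list[RyRCluster] = []
    for zi, child in enumerate(ss.spawn(volume.n_zdisks)):
        rng = np.random.default_rng(child)
        l_nm = float(volume.zdisk_positions[zi])
        placed = _sample_zdisk(rng, sites_uv, res, n_per_zdisk, min_spacing, max_attempts)
        if placed is None:
            raise PlacementError(
                f"z-disk {zi}: cannot place {n_per_zdisk} clusters at min spacing "
                f"{min_spacing} nm after {max_attempts} attempts"
            )
        for iu, iv in placed:
            center = ((iu + 0.5) * res, (iv + 0.5) * res, l_nm)
            clusters.append(RyRCluster(center=center, zdisk_index=zi))

    return ClusterSet(
        clusters=clusters,
        density_mode=density_mode,
        n_per_zdisk=n_per_zdisk,
        min_spacing=min_spacing,
        seed=seed,
        shell_thickness=shell_thickness,
    )


def _sample_zdisk(rng, sites_uv, res, n, min_spacing, max_attempts):
    """Sample n border sites, optionally with a minimum pairwise spacing."""
    if min_spacing is None:
        idx = rng.choice(len(sites_uv), size=n, replace=False)
        return sites_uv[idx]
    for _ in range(max_attempts):
        order = rng.permutation(len(sites_uv))
        chosen: list[np.ndarray] = []
        pts: list[np.ndarray] = []
        for k in order:
            p = sites_uv[k] * res
            if all(np.hypot(*(p - q)) >= min_spacing for q in pts):
                chosen.append(sites_uv[k])
                pts.append(p)
                if len(chosen) == n:
                    return np.array(chosen)
    return None


def sample_fire_times(n: int, tau: float = DEFAULT_FIRE_TAU_MS, seed: int = 0) -> np.ndarray:
    """Draw n release delays from Exponential(mean = tau) ms."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    return np.random.default_rng(seed).exponential(scale=tau, size=n)


def assign_fire_times(cluster_set: ClusterSet, tau: float = DEFAULT_FIRE_TAU_MS, seed: int = 0) -> ClusterSet:
    """Return a copy of the set with exponential firing delays assigned."""
    times = sample_fire_times(len(cluster_set), tau=tau, seed=seed)
    return cluster_set.with_fire_times(times)


def nn_distances(cluster_set: ClusterSet, within_zdisk: bool = False) -> np.ndarray:
    """Nearest-neighbor distance (nm) for every cluster.

    With ``within_zdisk`` the neighbor search is restricted to clusters on
    the same z-disk.
    """
    centers = cluster_set.centers()
    if len(centers) < 2:
        raise ValueError("need at least 2 clusters for nearest-neighbor distances")
    zidx = np.array([c.zdisk_index for c in cluster_set.clusters])
    d2 = np.sum((centers[:, None, :] - centers[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    if within_zdisk:
        d2[zidx[:, None] != zidx[None, :]] = np.inf
    out = np.sqrt(d2.min(axis=1))
    if within_zdisk and not np.all(np.isfinite(out)):
        raise ValueError("some z-disks contain a single cluster")
    return out


def save_clusters(cluster_set: ClusterSet, csv_path, json_path=None) -> None:
    """Persist as CSV (one row per cluster) plus a JSON sidecar."""
    csv_path = str(csv_path)
    json_path = json_path or csv_path.rsplit(".", 1)[0] + ".json"
    df = pd.DataFrame(
        {
            "u_nm": [c.center[0] for c in cluster_set.clusters],
            "v_nm": [c.center[1] for c in cluster_set.clusters],
            "l_nm": [c.center[2] for c in cluster_set.clusters],
            "zdisk_index": [c.zdisk_index for c in cluster_set.clusters],
            "fire_time_ms": [c.fire_time for c in cluster_set.clusters],
            "amplitude_scale": [c.amplitude_scale for c in cluster_set.clusters],
        }
    )
    df.to_csv(csv_path, index=False)
    meta = {
        "density_mode": cluster_set.density_mode,
        "n_per_zdisk": cluster_set.n_per_zdisk,
        "min_spacing_nm": cluster_set.min_spacing,
        "seed": cluster_set.seed,
        "shell_thickness_nm": cluster_set.shell_thickness,
    }
    with open(json_path, "w") as fh:
        json.dump(meta, fh, indent=2)


def load_clusters(csv_path, json_path=None) -> ClusterSet:
    csv_path = str(csv_path)
    json_path = json_path or csv_path.rsplit(".", 1)[0] + ".json"
    df = pd.read_csv(csv_path)
    with open(json_path) as fh:
        meta = json.load(fh)
    clusters = [
        RyRCluster(
            center=(row.u_nm, row.v_nm, row.l_nm),
            zdisk_index=int(row.zdisk_index),
            fire_time=float(row.fire_time_ms),
            amplitude_scale=float(row.amplitude_scale),
        )
        for row in df.itertuples()
    ]
    return ClusterSet(
        clusters=clusters,
        density_mode=meta["density_mode"],
        n_per_zdisk=meta["n_per_zdisk"],
        min_spacing=meta["min_spacing_nm"],
        seed=meta["seed"],
        shell_thickness=meta.get("shell_thickness_nm", 250.0),
    )
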