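"""Aromatic ring geometry, stacking classification, free-energy landscapes.

The free-energy landscape over two reaction coordinates (here the
inter-ring angle and centroid distance) is the Boltzmann inversion
G(x, y) = -RT ln H(x, y) of the sampled 2D histogram, shifted so the
global minimum is zero; empty bins are undefined rather than infinite.
Stacking orientations are classified geometrically: parallel below 30 deg,
herringbone between 30 and 60 deg, perpendicular (T-shaped) above 60 deg,
and none beyond a centroid-distance ceiling (0.85 nm default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import GeometryError
from .metrics import R_KCAL
from .model import RingDefinition, SystemTopology, Trajectory

PLANARITY_WARN_NM = 0.02


@dataclass
class RingGeometry:
    ring_id: str
    centroid: np.ndarray     # nm
    normal: np.ndarray       # unit vector
    planarity_rms: float     # nm


@dataclass
class StackingClass:
    label: str               # parallel | herringbone | perpendicular | none
    angle_deg: float
    distance_nm: float


@dataclass
class Basin:
    x_range: tuple[float, float]
    y_range: tuple[float, float]
    min_g: float
    n_bins: int


@dataclass
class LandscapeGrid:
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray          # H(x, y)
    free_energy: np.ndarray     # G = -RT ln H, min-shifted to 0; NaN if empty
    defined: np.ndarray         # bool mask where H > 0
    temperature: float
    basins: list[Basin]


def ring_geometry(coords_nm: np.ndarray, ring: RingDefinition) -> RingGeometry:
    """Centroid, unit normal and planarity of a ring in one frame.

    The normal is the smallest-variance principal axis of the ring atoms,
    sign-normalized into the +z hemisphere (ties broken toward +x, then +y);
    planarity_rms is the RMS distance of ring atoms from the best-fit plane.
    """
    pts = np.asarray(coords_nm)[list(ring.atom_ids)]
    if len(pts) < 5:
        raise GeometryError(f"ring {ring.ring_id} has fewer than 5 atoms")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-10 * max(s[0], 1e-30):
        raise GeometryError(f"ring {ring.ring_id} atoms are collinear")
    normal = vt[2]
    for comp in (2, 0, 1):
        if abs(normal[comp]) > 1e-12:
            if normal[comp] < 0:
                normal = -normal
            break
    planarity = float(np.sqrt(np.mean(np.dot(centered, normal) ** 2)))
    return RingGeometry(ring.ring_id, centroid, normal, planarity)


def ring_pair_series(
    traj: Trajectory,
    ring_a: RingDefinition,
    ring_b: RingDefinition,
):
    """Per-frame (angle deg in [0, 90], centroid distance nm) for a ring pair."""
    angles = np.empty(traj.n_frames)
    distances = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        ga = ring_geometry(traj.coordinates[f], ring_a)
        gb = ring_geometry(traj.coordinates[f], ring_b)
        cosang = abs(float(np.dot(ga.normal, gb.normal)))
        angles[f] = np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))
        distances[f] = np.linalg.norm(ga.centroid - gb.centroid)
    return angles, distances


def classify_stacking(
    angle_deg: float,
    distance_nm: float,
    parallel_max: float = 30.0,
    perpendicular_min: float = 60.0,
    distance_ceiling: float = 0.85,
) -> StackingClass:
    """Geometric stacking class from inter-ring angle and centroid distance."""
    if not 0.0 <= angle_deg <= 90.0:
        raise ValueError(f"angle {angle_deg} outside [0, 90]")
    if distance_nm <= 0:
        raise ValueError("distance must be positive")
    if distance_nm > distance_ceiling:
        label = "none"
    elif angle_deg < parallel_max:
        label = "parallel"
    elif angle_deg < perpendicular_min:
        label = "herringbone"
    else:
        label = "perpendicular"
    return StackingClass(label, float(angle_deg), float(distance_nm))


def free_energy_landscape(
    x: np.ndarray,
    y: np.ndarray,
    bins=50,
    temperature: float = 310.0,
    x_range: Optional[tuple[float, float]] = None,
    y_range: Optional[tuple[float, float]] = None,
    basin_depth: float = 1.0,
) -> LandscapeGrid:
    """-RT ln H(x, y) over two reaction coordinates, shifted to min G = 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        raise ValueError("landscape requires at least one sample")
    rng = None
    if x_range is not None or y_range is not None:
        rng = (x_range, y_range)
    counts, x_edges, y_edges = np.histogram2d(x, y, bins=bins, range=rng)
    defined = counts > 0
    g = np.full_like(counts, np.nan)
    rt = R_KCAL * temperature
    g[defined] = -rt * np.log(counts[defined])
    g -= np.nanmin(g)
    grid = LandscapeGrid(x_edges, y_edges, counts, g, defined, temperature, [])
    grid.basins = basin_detection(grid, basin_depth)
    return grid


def basin_detection(grid: LandscapeGrid, depth_threshold: float) -> list[Basin]:
    """Connected bin components with G within ``depth_threshold`` of the minimum."""
    mask = grid.defined & (grid.free_energy <= np.nanmin(grid.free_energy)
                           + depth_threshold + 1e-12)
    labels, n = ndimage.label(mask)
    basins: list[Basin] = []
    for k in range(1, n + 1):
        sel = labels == k
        xi, yi = np.nonzero(sel)
        basins.append(
            Basin(
                (float(grid.x_edges[xi.min()]), float(grid.x_edges[xi.max() + 1])),
                (float(grid.y_edges[yi.min()]), float(grid.y_edges[yi.max() + 1])),
                float(np.nanmin(grid.free_energy[sel])),
                int(sel.sum()),
            )
        )
    basins.sort(key=lambda b: b.min_g)
    return basins


def stacking_series(
    traj: Trajectory,
    topology: SystemTopology,
    ring_a_id: str,
    ring_b_id: str,
    **classify_kw,
):
    """(angles, distances, classes) for a named ring pair over a trajectory."""
    rings = {r.ring_id: r for r in topology.ring_definitions}
    angles, distances = ring_pair_series(traj, rings[ring_a_id], rings[ring_b_id])
    classes = [
        classify_stacking(a, d, **classify_kw).label
        for a, d in zip(angles, distances)
    ]
    return angles, distances, classes
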