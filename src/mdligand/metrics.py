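"""Frame-wise structural metrics.

Optimal-superposition (Kabsch) RMSD, per-residue Cα RMSF, radius of
gyration, Shrake-Rupley solvent-accessible surface area, and normalized
histogram (probability-density) summaries of any metric series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import (
    GeometryError,
    InsufficientDataError,
    ParameterError,
    SelectionError,
)
from .model import (
    SelectionSpec,
    SystemTopology,
    Trajectory,
    resolve_selection,
)

R_KCAL = 1.9872e-3  # gas constant, kcal/(mol*K)
A_PER_NM = 10.0


@dataclass
class MetricSeries:
    name: str
    times: np.ndarray   # ps
    values: np.ndarray  # unit depends on metric
    selection: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values length mismatch")


@dataclass
class DensityEstimate:
    bin_edges: np.ndarray
    probabilities: np.ndarray  # sum to 1
    peak_location: float       # modal bin center
    peak_probability: float

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile, reference, fit_atom_ids=None):
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd_fit)`` such that
    ``mobile @ rotation.T + translation`` minimizes the RMSD over the fit
    atoms; the rotation is proper (det = +1).  Coordinates in nm.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if fit_atom_ids is None:
        fit_atom_ids = np.arange(len(mobile))
    m = mobile[fit_atom_ids]
    r = reference[fit_atom_ids]
    if len(m) < 3:
        raise GeometryError("need at least 3 fit atoms")
    cm, cr = m.mean(axis=0), r.mean(axis=0)
    mc, rc = m - cm, r - cr
    # collinearity check: at least 2 non-negligible principal directions
    sv = np.linalg.svd(mc, compute_uv=False)
    if sv[1] < 1e-10 * max(sv[0], 1e-30):
        raise GeometryError("fit atoms are collinear or coincident")
    h = mc.T @ rc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cr - rot @ cm
    fitted = mc @ rot.T + cr
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - r) ** 2, axis=1))))
    return rot, trans, rmsd


def apply_transform(coords, rotation, translation):
    return np.asarray(coords) @ np.asarray(rotation).T + np.asarray(translation)


def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray,
    topology: SystemTopology,
    fit_selection: SelectionSpec,
    measure_selection: Optional[SelectionSpec] = None,
) -> MetricSeries:
    """Per-frame RMSD (nm) over ``measure_selection`` after superposing each
    frame onto ``reference`` using ``fit_selection``."""
    fit_ids = resolve_selection(fit_selection, topology)
    meas_ids = (
        fit_ids
        if measure_selection is None
        else resolve_selection(measure_selection, topology)
    )
    values = np.empty(traj.n_frames)
    ref_meas = reference[meas_ids]
    for i in range(traj.n_frames):
        rot, trans, _ = kabsch_superpose(traj.coordinates[i], reference, fit_ids)
        moved = apply_transform(traj.coordinates[i][meas_ids], rot, trans)
        values[i] = np.sqrt(np.mean(np.sum((moved - ref_meas) ** 2, axis=1)))
    label = measure_selection.label if measure_selection else fit_selection.label
    return MetricSeries("rmsd", traj.times, values, label)


def superpose_trajectory(
    traj: Trajectory, topology: SystemTopology, fit_ids: np.ndarray,
    reference: str = "mean",
) -> np.ndarray:
    """Align every frame; returns aligned coordinates (n_frames, n_atoms, 3).

    ``reference="mean"`` aligns to the first frame, recomputes the mean
    structure, and re-aligns every frame to that mean (one iteration);
    ``reference="first"`` aligns to the first frame only.
    """
    if traj.n_frames < 2:
        raise InsufficientDataError("need at least 2 frames")
    aligned = np.empty_like(traj.coordinates)
    ref = traj.coordinates[0]
    for i in range(traj.n_frames):
        rot, trans, _ = kabsch_superpose(traj.coordinates[i], ref, fit_ids)
        aligned[i] = apply_transform(traj.coordinates[i], rot, trans)
    if reference == "first":
        return aligned
    mean = aligned.mean(axis=0)
    for i in range(traj.n_frames):
        rot, trans, _ = kabsch_superpose(aligned[i], mean, fit_ids)
        aligned[i] = apply_transform(aligned[i], rot, trans)
    return aligned


def rmsf_per_residue(
    traj: Trajectory,
    topology: SystemTopology,
    fit_selection: Optional[SelectionSpec] = None,
    atom_role: str = "CA",
    reference: str = "mean",
):
    """Per-residue RMSF (nm) of the chosen role atom (default Cα).

    RMSF_i = sqrt(<|r_i - <r_i>|^2>) after superposing every frame onto the
    time-mean structure (one alignment iteration).  The trajectory is
    expected to be burn-in-trimmed by the caller; the pipeline enforces
    that.  Returns ``(residue_indices, rmsf_values)``.
    """
    role_spec = SelectionSpec("role_tag", atom_role, atom_role)
    role_ids = resolve_selection(role_spec, topology)
    fit_ids = (
        role_ids if fit_selection is None
        else resolve_selection(fit_selection, topology)
    )
    aligned = superpose_trajectory(traj, topology, fit_ids, reference)
    sub = aligned[:, role_ids, :]
    mean = sub.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((sub - mean) ** 2, axis=2), axis=0))
    res_idx = topology.residue_index[role_ids]
    return res_idx, rmsf


# ---------------------------------------------------------------------------
# Size / surface metrics
# ---------------------------------------------------------------------------

def radius_of_gyration(
    coords_nm: np.ndarray,
    topology: SystemTopology,
    atom_ids: np.ndarray,
    mass_weighted: bool = True,
) -> float:
    """Rg = sqrt(sum m_i |r_i - r_com|^2 / sum m_i), in nm."""
    if len(atom_ids) == 0:
        raise SelectionError("empty selection for radius of gyration")
    r = np.asarray(coords_nm)[atom_ids]
    w = topology.masses[atom_ids] if mass_weighted else np.ones(len(atom_ids))
    com = np.average(r, axis=0, weights=w)
    return float(np.sqrt(np.average(np.sum((r - com) ** 2, axis=1), weights=w)))


def rg_series(
    traj: Trajectory, topology: SystemTopology, selection: SelectionSpec,
    mass_weighted: bool = True,
) -> MetricSeries:
    ids = resolve_selection(selection, topology)
    values = np.array(
        [radius_of_gyration(traj.coordinates[i], topology, ids, mass_weighted)
         for i in range(traj.n_frames)]
    )
    return MetricSeries("rg", traj.times, values, selection.label)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def sasa(
    coords_nm: np.ndarray,
    topology: SystemTopology,
    atom_ids: Optional[np.ndarray] = None,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
):
    """Shrake-Rupley SASA.  Returns ``(total_nm2, per_atom_A2)``.

    ``probe_radius`` in Å; atomic radii are the topology's intrinsic radii.
    Per-atom areas (Å², aligned with ``atom_ids``) sum to the total.
    """
    if atom_ids is None:
        atom_ids = np.arange(topology.atom_count)
    atom_ids = np.asarray(atom_ids, dtype=int)
    radii = topology.intrinsic_radius[atom_ids]
    if np.any(radii <= 0):
        raise ParameterError("non-positive intrinsic radius in SASA selection")
    centers = np.asarray(coords_nm)[atom_ids] * A_PER_NM  # Å
    ext = radii + probe_radius
    unit = _sphere_points(n_sphere_points)
    n = len(atom_ids)
    per_atom = np.zeros(n)
    # neighbour lists from the full pair-distance matrix (desk-scale systems)
    diff = centers[:, None, :] - centers[None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=2))
    order = np.arange(n)
    for i in range(n):
        cutoff = ext[i] + ext
        nbr = np.flatnonzero((dist[i] < cutoff) & (order != i))
        pts = centers[i] + ext[i] * unit
        if nbr.size:
            # boundary points count as accessible, except against an exactly
            # coincident earlier twin (so duplicated atoms are counted once)
            r2 = ext[nbr] ** 2
            dup = (dist[i][nbr] == 0.0) & (ext[nbr] == ext[i]) & (nbr < i)
            r2 = np.where(dup, r2 * (1.0 + 1e-9), r2 * (1.0 - 1e-9))
            d2 = np.sum(
                (pts[:, None, :] - centers[nbr][None, :, :]) ** 2, axis=2
            )
            accessible = np.all(d2 >= r2[None, :], axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        per_atom[i] = frac * 4.0 * np.pi * ext[i] ** 2
    total_nm2 = float(per_atom.sum() / (A_PER_NM ** 2))
    return total_nm2, per_atom


def sasa_series(
    traj: Trajectory, topology: SystemTopology, selection: SelectionSpec,
    probe_radius: float = 1.4, n_sphere_points: int = 960, stride: int = 1,
) -> MetricSeries:
    ids = resolve_selection(selection, topology)
    frames = range(0, traj.n_frames, stride)
    values = [
        sasa(traj.coordinates[i], topology, ids, probe_radius, n_sphere_points)[0]
        for i in frames
    ]
    return MetricSeries(
        "sasa", traj.times[::stride], np.array(values), selection.label
    )


# ---------------------------------------------------------------------------
# Densities
# ---------------------------------------------------------------------------

def density(series, bins: int = 100) -> DensityEstimate:
    """Normalized histogram of a metric series (probabilities sum to 1)."""
    values = series.values if isinstance(series, MetricSeries) else np.asarray(series)
    if values.size == 0:
        raise InsufficientDataError("density requires at least one value")
    span = np.ptp(values)
    if span <= max(np.max(np.abs(values)), 1.0) * 1e-9:
        # constant series (to numerical precision): one occupied bin
        v = float(np.mean(values))
        width = max(abs(v) * 1e-6, 1e-9)
        edges = np.linspace(v - width, v + width, bins + 1)
        if bins % 2 == 0:
            # keep the value at a bin centre, not on an edge
            edges += width / bins
    else:
        edges = np.histogram_bin_edges(values, bins=bins)
    counts, edges = np.histogram(values, bins=edges)
    probs = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    k = int(np.argmax(probs))
    return DensityEstimate(edges, probs, float(centers[k]), float(probs[k]))
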