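"""Contact-probability maps, hydrogen bonds, salt bridges, covariance matrices.

Contacts follow the two-cutoff convention: residue-residue contacts use a
0.46 nm minimum heavy-atom distance, residue-ligand binding probability a
0.54 nm cutoff (both configurable).  Hydrogen bonds use the geometric
criterion of a donor-heavy to acceptor-heavy distance within 3.5 Å and a
D-H...A angle between 150 and 180 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import InsufficientDataError, SelectionError
from .metrics import DensityEstimate, MetricSeries, density, superpose_trajectory
from .model import (
    SelectionSpec,
    SystemTopology,
    Trajectory,
    resolve_selection,
)

A_PER_NM = 10.0


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

@dataclass
class ContactMap:
    labels_a: list[str]
    labels_b: list[str]
    residues_a: np.ndarray
    residues_b: np.ndarray
    probabilities: np.ndarray  # (len a, len b), in [0, 1]
    cutoff: float              # nm
    definition: str
    symmetric: bool


def _pair_displacement(diff: np.ndarray, box: Optional[np.ndarray]) -> np.ndarray:
    if box is not None:
        diff = diff - box * np.round(diff / box)
    return diff


def min_residue_distances(
    coords: np.ndarray,
    atoms_a: np.ndarray,
    atoms_b: np.ndarray,
    res_a: np.ndarray,
    res_b: np.ndarray,
    n_a: int,
    n_b: int,
    box: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Minimum inter-atom distance for every residue pair (n_a, n_b), nm."""
    diff = coords[atoms_a][:, None, :] - coords[atoms_b][None, :, :]
    diff = _pair_displacement(diff, box)
    dist = np.sqrt(np.sum(diff * diff, axis=2))
    out = np.full((n_a, n_b), np.inf)
    np.minimum.at(out, (res_a[:, None], res_b[None, :]), dist)
    return out


def contact_probability(
    traj: Trajectory,
    topology: SystemTopology,
    group_a: SelectionSpec,
    group_b: Optional[SelectionSpec] = None,
    cutoff: float = 0.46,
    definition: str = "min_heavy_atom_distance",
    exclude_neighbors: int = 2,
) -> ContactMap:
    """Fraction of frames in which residue pairs are in contact.

    With ``group_b`` omitted (or equal to ``group_a``) the map is the
    symmetric residue-residue map over ``group_a``, with trivially
    contacting sequence neighbours ``|i - j| <= exclude_neighbors``
    excluded.  With a distinct ``group_b`` (e.g. the ligand entity) the map
    is residue-of-a vs residue-of-b.  ``definition`` selects heavy-atom
    (default) or all-atom minimum distances.
    """
    if definition not in ("min_heavy_atom_distance", "any_atom_distance"):
        raise SelectionError(f"unknown contact definition {definition!r}")
    ids_a = resolve_selection(group_a, topology)
    symmetric = group_b is None
    ids_b = ids_a if symmetric else resolve_selection(group_b, topology)
    if not symmetric and np.intersect1d(ids_a, ids_b).size:
        raise SelectionError("contact groups overlap")
    if definition == "min_heavy_atom_distance":
        heavy = topology.heavy_mask()
        ids_a = ids_a[heavy[ids_a]]
        ids_b = ids_b[heavy[ids_b]]
    if ids_a.size == 0 or ids_b.size == 0:
        raise SelectionError("contact group empty after heavy-atom filtering")

    res_of_a = topology.residue_index[ids_a]
    res_of_b = topology.residue_index[ids_b]
    resids_a = np.unique(res_of_a)
    resids_b = np.unique(res_of_b)
    map_a = {r: i for i, r in enumerate(resids_a)}
    map_b = {r: i for i, r in enumerate(resids_b)}
    ra = np.array([map_a[r] for r in res_of_a])
    rb = np.array([map_b[r] for r in res_of_b])

    counts = np.zeros((len(resids_a), len(resids_b)))
    for f in range(traj.n_frames):
        box = traj.box[f] if traj.box is not None else None
        mind = min_residue_distances(
            traj.coordinates[f], ids_a, ids_b, ra, rb,
            len(resids_a), len(resids_b), box,
        )
        counts += mind < cutoff
    probs = counts / traj.n_frames
    if symmetric and exclude_neighbors >= 0:
        di = np.abs(resids_a[:, None] - resids_b[None, :])
        probs[di <= exclude_neighbors] = 0.0
    labels_a = [topology.residues[r].label for r in resids_a]
    labels_b = [topology.residues[r].label for r in resids_b]
    return ContactMap(
        labels_a, labels_b, resids_a, resids_b, probs, cutoff, definition, symmetric
    )


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HBondRecord:
    donor: int
    hydrogen: int
    acceptor: int
    frame: int
    distance_A: float
    angle_deg: float


def detect_hbonds(
    coords_nm: np.ndarray,
    topology: SystemTopology,
    distance_max: float = 3.5,
    angle_min: float = 150.0,
    angle_max: float = 180.0,
    selection: Optional[np.ndarray] = None,
    frame: int = 0,
) -> list[HBondRecord]:
    """Geometric hydrogen bonds in one frame.

    A donor/hydrogen/acceptor triple forms a bond when the donor-heavy to
    acceptor distance is within ``distance_max`` (Å) and the D-H...A angle
    lies in ``[angle_min, angle_max]`` degrees.  Acceptors are restricted
    to N and O by construction of the topology roles.
    """
    roles = topology.hbond_roles
    if not roles.donor_pairs or not roles.acceptors:
        return []
    allowed = None if selection is None else set(int(i) for i in selection)
    donors = [
        (d, h) for d, h in roles.donor_pairs
        if allowed is None or (d in allowed and h in allowed)
    ]
    acceptors = np.array(
        [a for a in roles.acceptors if allowed is None or a in allowed], dtype=int
    )
    if not donors or acceptors.size == 0:
        return []
    coords = np.asarray(coords_nm) * A_PER_NM  # Å
    d_ids = np.array([d for d, _ in donors])
    h_ids = np.array([h for _, h in donors])
    da = cdist(coords[d_ids], coords[acceptors])
    records: list[HBondRecord] = []
    cos_max = np.cos(np.deg2rad(angle_max))
    cos_min = np.cos(np.deg2rad(angle_min))
    for k in range(len(donors)):
        close = np.flatnonzero(da[k] <= distance_max)
        if close.size == 0:
            continue
        h = coords[h_ids[k]]
        hd = coords[d_ids[k]] - h
        hd /= np.linalg.norm(hd)
        for j in close:
            a_id = int(acceptors[j])
            if a_id == int(d_ids[k]) or a_id == int(h_ids[k]):
                continue
            ha = coords[a_id] - h
            norm = np.linalg.norm(ha)
            if norm == 0:
                continue
            cosang = float(np.dot(hd, ha / norm))
            # D-H...A angle between H->D and H->A
            if cos_max - 1e-12 <= cosang <= cos_min + 1e-12:
                angle = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
                if angle_min <= angle <= angle_max or np.isclose(angle, angle_min):
                    records.append(
                        HBondRecord(
                            int(d_ids[k]), int(h_ids[k]), a_id, frame,
                            float(da[k, j]), angle,
                        )
                    )
    return records


def hbond_count_series(
    traj: Trajectory,
    topology: SystemTopology,
    selection: Optional[SelectionSpec] = None,
    distance_max: float = 3.5,
    angle_min: float = 150.0,
    angle_max: float = 180.0,
    bins: Optional[int] = None,
):
    """Per-frame intramolecular H-bond count within ``selection``.

    Returns ``(MetricSeries, DensityEstimate)``; the density is over
    integer counts (one bin per count by default).
    """
    ids = None if selection is None else resolve_selection(selection, topology)
    counts = np.array(
        [
            len(
                detect_hbonds(
                    traj.coordinates[f], topology, distance_max,
                    angle_min, angle_max, ids, frame=f,
                )
            )
            for f in range(traj.n_frames)
        ],
        dtype=float,
    )
    series = MetricSeries(
        "hbond_count", traj.times, counts,
        selection.label if selection else "all",
    )
    if bins is None:
        lo, hi = counts.min(), counts.max()
        edges = np.arange(lo - 0.5, hi + 1.5)
        cts, edges = np.histogram(counts, bins=edges)
        probs = cts / cts.sum()
        k = int(np.argmax(probs))
        centers = 0.5 * (edges[:-1] + edges[1:])
        dens = DensityEstimate(edges, probs, float(centers[k]), float(probs[k]))
    else:
        dens = density(series, bins)
    return series, dens


# ---------------------------------------------------------------------------
# Salt bridges
# ---------------------------------------------------------------------------

_BASIC_N = {"NH1", "NH2", "NE", "NZ"}
_ACIDIC_O = {"OD1", "OD2", "OE1", "OE2"}


def saltbridge_distance(
    traj: Trajectory,
    topology: SystemTopology,
    pair: tuple[int, int],
    bins: int = 100,
):
    """Per-frame minimum basic-N to acidic-O distance (nm) for a residue pair.

    ``pair`` is (basic residue index, acidic residue index); both must carry
    charged side-chain groups.  Returns ``(MetricSeries, DensityEstimate)``.
    """
    basic, acidic = pair
    groups = {g.residue_index: g for g in topology.charged_groups
              if "side" in g.group_id}
    if basic not in groups or groups[basic].sign != +1:
        raise SelectionError(f"residue {basic} lacks a basic side-chain group")
    if acidic not in groups or groups[acidic].sign != -1:
        raise SelectionError(f"residue {acidic} lacks an acidic side-chain group")
    n_ids = np.array(
        [i for i in groups[basic].atom_ids if topology.names[i] in _BASIC_N]
    )
    o_ids = np.array(
        [i for i in groups[acidic].atom_ids if topology.names[i] in _ACIDIC_O]
    )
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        d = cdist(traj.coordinates[f][n_ids], traj.coordinates[f][o_ids])
        values[f] = d.min()
    label = f"{topology.residues[basic].label}-{topology.residues[acidic].label}"
    series = MetricSeries("saltbridge_distance", traj.times, values, label)
    return series, density(series, bins)


# ---------------------------------------------------------------------------
# Covariance / cross-correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    values: np.ndarray        # (n, n)
    mode: str                 # "covariance" (nm^2) or "normalized"
    residue_indices: np.ndarray
    defined: np.ndarray       # bool mask; False where normalization undefined


def covariance_matrix(
    traj: Trajectory,
    topology: SystemTopology,
    fit_selection: Optional[SelectionSpec] = None,
    atom_role: str = "CA",
    normalized: bool = True,
    superpose: bool = True,
) -> CorrelationMatrix:
    """Residue-residue Cα displacement covariance C_ij = <dr_i . dr_j>.

    Frames are superposed onto the mean structure first (disable with
    ``superpose=False`` for pre-aligned frames).  In normalized
    mode entries are C_ij / sqrt(C_ii C_jj) (unit diagonal, values in
    [-1, 1]); residues with zero variance are flagged undefined rather than
    propagating NaN.
    """
    if traj.n_frames < 2:
        raise InsufficientDataError("covariance needs at least 2 frames")
    role_ids = resolve_selection(
        SelectionSpec("role_tag", atom_role, atom_role), topology
    )
    fit_ids = (
        role_ids if fit_selection is None
        else resolve_selection(fit_selection, topology)
    )
    if superpose:
        aligned = superpose_trajectory(traj, topology, fit_ids, reference="mean")
    else:
        aligned = traj.coordinates
    sub = aligned[:, role_ids, :]
    delta = sub - sub.mean(axis=0)
    cov = np.einsum("fik,fjk->ij", delta, delta) / delta.shape[0]
    cov = 0.5 * (cov + cov.T)
    res_idx = topology.residue_index[role_ids]
    if not normalized:
        return CorrelationMatrix(
            cov, "covariance", res_idx, np.ones_like(cov, dtype=bool)
        )
    var = np.diag(cov).copy()
    ok = var > max(float(var.max()), 1e-300) * 1e-12
    denom = np.sqrt(np.outer(np.where(ok, var, 1.0), np.where(ok, var, 1.0)))
    norm = cov / denom
    defined = np.outer(ok, ok)
    norm[~defined] = 0.0
    np.fill_diagonal(norm, np.where(ok, 1.0, 0.0))
    return CorrelationMatrix(norm, "normalized", res_idx, defined)
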