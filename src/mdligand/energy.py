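"""MM/GB-SA binding free energy with per-residue decomposition.

The binding free energy of a ligand to its receptor is estimated per frame
in the single-trajectory approximation as

    dG_binding = dE_elec + dE_vdW + dG_polar + dG_surf

with the solute entropy term dropped.  Gas-phase terms are the receptor-
ligand cross sums of Coulomb (332.0637 q_i q_j / r) and Lennard-Jones
(Lorentz-Berthelot combination) energies; dG_polar is a generalized Born
(Still) energy difference complex - receptor - ligand with
Hawkins-Cramer-Truhlar pairwise-descreening Born radii; dG_surf is
gamma * dSASA.

Per-residue decomposition uses per-atom shares: half of every pair term to
each partner atom, self terms fully owned.  Shares aggregated by residue
(the ligand counts as one entry) sum exactly to the per-frame total, so
the decomposition is closed, including GB radii-change effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ParameterError, SelectionError, SingularityError
from .metrics import sasa
from .model import (
    AnalysisConfig,
    SelectionSpec,
    SystemTopology,
    Trajectory,
    resolve_selection,
)
from .parameters import HCT_SCREEN, HCT_SCREEN_DEFAULT

COULOMB_K = 332.0637  # kcal*Å/(mol*e^2)
A_PER_NM = 10.0
GB_DIELECTRIC_OFFSET = 0.09  # Å


# ---------------------------------------------------------------------------
# Gas-phase terms
# ---------------------------------------------------------------------------

def _cross_distances_A(coords_nm, ids_a, ids_b) -> np.ndarray:
    r = cdist(np.asarray(coords_nm)[ids_a], np.asarray(coords_nm)[ids_b]) * A_PER_NM
    if np.any(r == 0.0):
        raise SingularityError("coincident atoms in pairwise energy sum")
    return r


def coulomb_energy_matrix(coords_nm, topology, ids_a, ids_b) -> np.ndarray:
    r = _cross_distances_A(coords_nm, ids_a, ids_b)
    q = topology.charges
    return COULOMB_K * np.outer(q[ids_a], q[ids_b]) / r


def coulomb_energy(coords_nm, topology, ids_a, ids_b) -> float:
    """Cross-group Coulomb energy, kcal/mol (no cutoff)."""
    return float(coulomb_energy_matrix(coords_nm, topology, ids_a, ids_b).sum())


def lj_energy_matrix(coords_nm, topology, ids_a, ids_b) -> np.ndarray:
    r = _cross_distances_A(coords_nm, ids_a, ids_b)
    sigma = 0.5 * (
        topology.lj_sigma[ids_a][:, None] + topology.lj_sigma[ids_b][None, :]
    ) * A_PER_NM
    eps = np.sqrt(
        topology.lj_epsilon[ids_a][:, None] * topology.lj_epsilon[ids_b][None, :]
    )
    x6 = (sigma / r) ** 6
    return 4.0 * eps * (x6 * x6 - x6)


def lj_energy(coords_nm, topology, ids_a, ids_b) -> float:
    """Cross-group Lennard-Jones energy, kcal/mol (Lorentz-Berthelot)."""
    return float(lj_energy_matrix(coords_nm, topology, ids_a, ids_b).sum())


# ---------------------------------------------------------------------------
# Generalized Born
# ---------------------------------------------------------------------------

@dataclass
class BornRadii:
    atom_ids: np.ndarray
    radii: np.ndarray   # Å, aligned with atom_ids
    method: str = "HCT"


def born_radii(
    coords_nm,
    topology: SystemTopology,
    atom_ids: Optional[np.ndarray] = None,
    offset: float = GB_DIELECTRIC_OFFSET,
    method: str = "HCT",
) -> BornRadii:
    """Effective Born radii by HCT pairwise descreening (Å).

    1/R_i = 1/rho_i' - sum_j I(r_ij, S_j rho_j') with rho' the intrinsic
    radius minus the dielectric offset and S_j element-wise screening
    factors.  An isolated atom's Born radius is rho - offset.
    """
    if method != "HCT":
        raise ParameterError(f"unknown Born radius method {method!r}")
    if atom_ids is None:
        atom_ids = np.arange(topology.atom_count)
    atom_ids = np.asarray(atom_ids, dtype=int)
    rho = topology.intrinsic_radius[atom_ids] - offset
    if np.any(rho <= 0):
        raise ParameterError("intrinsic radius <= dielectric offset")
    screen = np.array(
        [HCT_SCREEN.get(e, HCT_SCREEN_DEFAULT) for e in topology.elements[atom_ids]]
    )
    pos = np.asarray(coords_nm)[atom_ids] * A_PER_NM
    n = len(atom_ids)
    inv_r = 1.0 / rho
    if n > 1:
        r = cdist(pos, pos)
        sj = screen * rho  # scaled descreening radii
        for i in range(n):
            rij = r[i]
            s = sj.copy()
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            mask &= rij + sj > rho[i]  # engulfed neighbours contribute 0
            if not mask.any():
                continue
            rm, sm = rij[mask], s[mask]
            upper = rm + sm
            lower = np.maximum(np.abs(rm - sm), rho[i])
            term = 0.5 * (
                1.0 / lower
                - 1.0 / upper
                + 0.25 * rm * (1.0 / upper**2 - 1.0 / lower**2)
                + 0.5 / rm * np.log(lower / upper)
                + 0.25 * sm**2 / rm * (1.0 / lower**2 - 1.0 / upper**2)
            )
            # atom centre inside a neighbour's scaled sphere
            inside = sm - rm > rho[i]
            if inside.any():
                term[inside] += 1.0 / rho[i] - 1.0 / lower[inside]
            inv_r[i] -= term.sum()
    radii = np.where(inv_r > 1e-8, 1.0 / np.maximum(inv_r, 1e-8), 1e8)
    radii = np.minimum(radii, 1e8)
    return BornRadii(atom_ids, radii, method)


def _gb_pair_matrix(coords_nm, topology, radii: BornRadii,
                    epsilon_in: float, epsilon_out: float) -> np.ndarray:
    """Symmetric matrix M with G_polar = sum_ij M_ij (self terms on diagonal)."""
    ids = radii.atom_ids
    q = topology.charges[ids]
    pos = np.asarray(coords_nm)[ids] * A_PER_NM
    r2 = cdist(pos, pos) ** 2
    rr = np.outer(radii.radii, radii.radii)
    f_gb = np.sqrt(r2 + rr * np.exp(-r2 / (4.0 * rr)))
    fac = -0.5 * COULOMB_K * (1.0 / epsilon_in - 1.0 / epsilon_out)
    return fac * np.outer(q, q) / f_gb


def gb_polar_energy(
    coords_nm,
    topology: SystemTopology,
    radii: BornRadii,
    epsilon_in: float = 1.0,
    epsilon_out: float = 78.5,
) -> float:
    """Still GB polar solvation energy (kcal/mol), self terms included."""
    return float(
        _gb_pair_matrix(coords_nm, topology, radii, epsilon_in, epsilon_out).sum()
    )


def gb_polar_peratom(
    coords_nm, topology, radii: BornRadii,
    epsilon_in: float = 1.0, epsilon_out: float = 78.5,
) -> np.ndarray:
    """Per-atom shares (half of each pair term, self fully); sums to the total."""
    m = _gb_pair_matrix(coords_nm, topology, radii, epsilon_in, epsilon_out)
    return 0.5 * (m.sum(axis=0) + m.sum(axis=1))


def gb_polar_binding(
    coords_nm,
    topology: SystemTopology,
    receptor_ids: np.ndarray,
    ligand_ids: np.ndarray,
    epsilon_in: float = 1.0,
    epsilon_out: float = 78.5,
):
    """dG_polar = G(complex) - G(receptor) - G(ligand), single-trajectory.

    Returns ``(dG_polar, per_atom_delta)`` where ``per_atom_delta`` is
    indexed over ``concat(receptor_ids, ligand_ids)`` and sums to dG_polar.
    """
    receptor_ids = np.asarray(receptor_ids, dtype=int)
    ligand_ids = np.asarray(ligand_ids, dtype=int)
    complex_ids = np.concatenate([receptor_ids, ligand_ids])
    g_c = gb_polar_peratom(
        coords_nm, topology, born_radii(coords_nm, topology, complex_ids),
        epsilon_in, epsilon_out,
    )
    g_r = gb_polar_peratom(
        coords_nm, topology, born_radii(coords_nm, topology, receptor_ids),
        epsilon_in, epsilon_out,
    )
    g_l = gb_polar_peratom(
        coords_nm, topology, born_radii(coords_nm, topology, ligand_ids),
        epsilon_in, epsilon_out,
    )
    delta = g_c - np.concatenate([g_r, g_l])
    return float(delta.sum()), delta


# ---------------------------------------------------------------------------
# Nonpolar (surface) term
# ---------------------------------------------------------------------------

def surf_nonpolar(
    coords_nm,
    topology: SystemTopology,
    atom_ids: Optional[np.ndarray] = None,
    gamma: float = 0.0072,
    offset: float = 0.0,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> float:
    """gamma * SASA + offset, kcal/mol (SASA in Å²)."""
    _, per_atom = sasa(coords_nm, topology, atom_ids, probe_radius, n_sphere_points)
    return float(gamma * per_atom.sum() + offset)


def surf_nonpolar_binding(
    coords_nm,
    topology: SystemTopology,
    receptor_ids: np.ndarray,
    ligand_ids: np.ndarray,
    gamma: float = 0.0072,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
):
    """dG_surf = gamma * (SASA_complex - SASA_receptor - SASA_ligand).

    Returns ``(dG_surf, per_atom_delta)`` over concat(receptor, ligand).
    """
    receptor_ids = np.asarray(receptor_ids, dtype=int)
    ligand_ids = np.asarray(ligand_ids, dtype=int)
    complex_ids = np.concatenate([receptor_ids, ligand_ids])
    _, a_c = sasa(coords_nm, topology, complex_ids, probe_radius, n_sphere_points)
    _, a_r = sasa(coords_nm, topology, receptor_ids, probe_radius, n_sphere_points)
    _, a_l = sasa(coords_nm, topology, ligand_ids, probe_radius, n_sphere_points)
    delta = gamma * (a_c - np.concatenate([a_r, a_l]))
    return float(delta.sum()), delta


# ---------------------------------------------------------------------------
# Trajectory MM/GB-SA
# ---------------------------------------------------------------------------

@dataclass
class EnergyBreakdown:
    frames: np.ndarray          # frame indices evaluated
    times: np.ndarray           # ps
    elec: np.ndarray            # per-frame, kcal/mol
    vdw: np.ndarray
    polar: np.ndarray
    surf: np.ndarray
    total: np.ndarray
    per_residue: dict           # label -> mean share, kcal/mol (incl. ligand)
    per_residue_index: dict     # label -> residue index (-1 for ligand)

    @property
    def means(self) -> dict:
        return {
            "elec": float(self.elec.mean()),
            "vdw": float(self.vdw.mean()),
            "polar": float(self.polar.mean()),
            "surf": float(self.surf.mean()),
            "total": float(self.total.mean()),
        }


def mmgbsa_frame(
    coords_nm,
    topology: SystemTopology,
    receptor_ids: np.ndarray,
    ligand_ids: np.ndarray,
    config: AnalysisConfig,
):
    """One-frame MM/GB-SA binding energy.

    Returns ``(components dict, per_atom_share)`` with per-atom shares over
    concat(receptor, ligand) summing to the total.
    """
    na, nb = len(receptor_ids), len(ligand_ids)
    e_mat = coulomb_energy_matrix(coords_nm, topology, receptor_ids, ligand_ids)
    v_mat = lj_energy_matrix(coords_nm, topology, receptor_ids, ligand_ids)
    elec = float(e_mat.sum())
    vdw = float(v_mat.sum())
    share = np.zeros(na + nb)
    share[:na] += 0.5 * (e_mat.sum(axis=1) + v_mat.sum(axis=1))
    share[na:] += 0.5 * (e_mat.sum(axis=0) + v_mat.sum(axis=0))
    polar, d_polar = gb_polar_binding(
        coords_nm, topology, receptor_ids, ligand_ids,
        config.gb_epsilon_in, config.gb_epsilon_out,
    )
    surf, d_surf = surf_nonpolar_binding(
        coords_nm, topology, receptor_ids, ligand_ids,
        config.surf_gamma, config.sasa_probe_radius, config.sasa_sphere_points,
    )
    share += d_polar + d_surf
    comps = {
        "elec": elec,
        "vdw": vdw,
        "polar": polar,
        "surf": surf,
        "total": elec + vdw + polar + surf,
    }
    return comps, share


def mmgbsa_trajectory(
    traj: Trajectory,
    topology: SystemTopology,
    receptor: SelectionSpec,
    ligand: SelectionSpec,
    config: Optional[AnalysisConfig] = None,
    frame_stride: int = 1,
) -> EnergyBreakdown:
    """MM/GB-SA over a (burn-in-trimmed) trajectory.

    Receptor and ligand coordinates are extracted from the complex frames
    (single-trajectory approximation); per-frame totals are averaged and
    per-atom shares aggregated into a closed per-residue decomposition.
    """
    config = config or AnalysisConfig()
    receptor_ids = resolve_selection(receptor, topology)
    ligand_ids = resolve_selection(ligand, topology)
    if np.intersect1d(receptor_ids, ligand_ids).size:
        raise SelectionError("receptor and ligand selections overlap")
    frames = np.arange(0, traj.n_frames, frame_stride)
    comps = {k: np.empty(len(frames)) for k in ("elec", "vdw", "polar", "surf", "total")}
    share_sum = np.zeros(len(receptor_ids) + len(ligand_ids))
    for k, f in enumerate(frames):
        c, share = mmgbsa_frame(
            traj.coordinates[f], topology, receptor_ids, ligand_ids, config
        )
        for key in comps:
            comps[key][k] = c[key]
        share_sum += share
    share_mean = share_sum / len(frames)

    all_ids = np.concatenate([receptor_ids, ligand_ids])
    is_ligand = np.zeros(len(all_ids), dtype=bool)
    is_ligand[len(receptor_ids):] = True
    per_residue: dict[str, float] = {}
    per_residue_index: dict[str, int] = {}
    for aid, val, lig in zip(all_ids, share_mean, is_ligand):
        if lig:
            label, ridx = "LIG", -1
        else:
            ridx = int(topology.residue_index[aid])
            label = topology.residues[ridx].label
        per_residue[label] = per_residue.get(label, 0.0) + float(val)
        per_residue_index[label] = ridx
    return EnergyBreakdown(
        frames, traj.times[frames],
        comps["elec"], comps["vdw"], comps["polar"], comps["surf"], comps["total"],
        per_residue, per_residue_index,
    )


def rank_binding_residues(
    breakdown: EnergyBreakdown, threshold: float = -1.0
) -> list[tuple[str, float]]:
    """Protein residues whose mean contribution is below ``threshold``
    (kcal/mol), strongest (most negative) first, labelled in author numbering."""
    hits = [
        (label, value)
        for label, value in breakdown.per_residue.items()
        if breakdown.per_residue_index[label] >= 0 and value < threshold
    ]
    hits.sort(key=lambda t: t[1])
    return hits
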