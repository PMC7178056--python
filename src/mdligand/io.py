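"""Structure / trajectory readers and writers.

PDB and GRO structures and multi-model-PDB / XTC / DCD trajectories are
parsed and written through MDAnalysis; this module converts between its
Å/ps frames and the package's nm/ps :class:`~mdligand.model.Trajectory`,
and assembles a :class:`~mdligand.model.SystemTopology` with auto-derived
hydrogen-bond roles, charged groups and aromatic-ring definitions.
"""

from __future__ import annotations

import os
import warnings
from typing import Optional, Sequence

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda

from .errors import (
    FormatError,
    SelectionError,
    TrajectoryMismatchError,
)
from .model import (
    Atom,
    ChargedGroup,
    HBondRoles,
    PROTEIN_RESIDUES,
    Residue,
    RingDefinition,
    SystemTopology,
    Trajectory,
)
from .parameters import SidecarTable, builtin_parameters, guess_element

A_PER_NM = 10.0

# aromatic ring memberships by residue type (standard PDB atom names)
AROMATIC_RING_ATOMS: dict[str, list[list[str]]] = {
    "PHE": [["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]],
    "TYR": [["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]],
    "HIS": [["CG", "ND1", "CE1", "NE2", "CD2"]],
    "TRP": [
        ["CG", "CD1", "NE1", "CE2", "CD2"],
        ["CE2", "CD2", "CE3", "CZ3", "CH2", "CZ2"],
    ],
}

# basic-nitrogen / acidic-oxygen terminal atoms for salt-bridge groups
CHARGED_GROUP_ATOMS: dict[str, tuple[int, list[str]]] = {
    "ARG": (+1, ["NE", "NH1", "NH2"]),
    "LYS": (+1, ["NZ"]),
    "ASP": (-1, ["OD1", "OD2"]),
    "GLU": (-1, ["OE1", "OE2"]),
}

_COVALENT_H_CUTOFF_NM = 0.125


def derive_hbond_roles(
    elements: np.ndarray, coords_nm: np.ndarray
) -> HBondRoles:
    """Tag donors/hydrogens/acceptors from elements and geometry.

    N and O are acceptors; an N or O with a hydrogen within covalent range
    (1.25 Å) is a donor, paired with that hydrogen.  Each hydrogen is
    assigned to its nearest heavy N/O parent.
    """
    acceptors = tuple(int(i) for i in np.flatnonzero(np.isin(elements, ("N", "O"))))
    h_ids = np.flatnonzero(elements == "H")
    donor_pairs = []
    heavy = np.array(acceptors, dtype=int)
    if heavy.size and h_ids.size:
        for h in h_ids:
            d = np.linalg.norm(coords_nm[heavy] - coords_nm[h], axis=1)
            j = int(np.argmin(d))
            if d[j] <= _COVALENT_H_CUTOFF_NM:
                donor_pairs.append((int(heavy[j]), int(h)))
    return HBondRoles(tuple(donor_pairs), acceptors)


def derive_charged_groups(
    residues: Sequence[Residue], names: np.ndarray
) -> list[ChargedGroup]:
    """Charged side-chain terminals for Arg/Lys/Asp/Glu plus charged termini."""
    groups: list[ChargedGroup] = []
    for res in residues:
        if res.name in CHARGED_GROUP_ATOMS:
            sign, wanted = CHARGED_GROUP_ATOMS[res.name]
            ids = tuple(i for i in res.atom_ids if names[i] in wanted)
            if ids:
                groups.append(
                    ChargedGroup(f"{res.label}:side", sign, ids, res.index)
                )
    protein = [r for r in residues if r.name in PROTEIN_RESIDUES]
    if protein:
        first, last = protein[0], protein[-1]
        nterm = tuple(i for i in first.atom_ids if names[i] == "N")
        if nterm:
            groups.append(ChargedGroup(f"{first.label}:Nterm", +1, nterm, first.index))
        oxt = tuple(i for i in last.atom_ids if names[i] in ("OXT", "OT2"))
        if oxt:
            cterm = tuple(
                i for i in last.atom_ids if names[i] in ("O", "OXT", "OT1", "OT2")
            )
            groups.append(ChargedGroup(f"{last.label}:Cterm", -1, cterm, last.index))
    return groups


def derive_rings(residues: Sequence[Residue], names: np.ndarray) -> list[RingDefinition]:
    rings: list[RingDefinition] = []
    for res in residues:
        patterns = AROMATIC_RING_ATOMS.get(res.name)
        if not patterns:
            continue
        for k, pattern in enumerate(patterns):
            by_name = {names[i]: i for i in res.atom_ids}
            if all(n in by_name for n in pattern):
                rings.append(
                    RingDefinition(
                        f"{res.label}:ring{k}",
                        tuple(by_name[n] for n in pattern),
                        "protein",
                        res.index,
                    )
                )
    return rings


def read_topology(
    structure_file,
    parameter_sidecar=None,
    ligand_rings: Optional[Sequence[Sequence[int]]] = None,
) -> SystemTopology:
    """Build a SystemTopology from a PDB/GRO structure plus parameter sidecar.

    ``parameter_sidecar`` is a CSV path (or SidecarTable); when omitted the
    built-in per-element table supplies LJ/radius defaults and the standard
    charged-residue charges.  ``ligand_rings`` optionally lists atom-id
    rings for non-protein entities (rings of standard aromatic residues are
    auto-detected from atom names).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(structure_file))
    table = None
    if parameter_sidecar is not None:
        table = (
            parameter_sidecar
            if isinstance(parameter_sidecar, SidecarTable)
            else SidecarTable.from_csv(parameter_sidecar)
        )

    atoms: list[Atom] = []
    residues: list[Residue] = []
    protein_res: list[int] = []
    ligand_res: list[int] = []
    atom_id = 0
    for ri, res in enumerate(u.residues):
        ids = []
        resname = str(res.resname).strip()
        for a in res.atoms:
            name = str(a.name).strip()
            element = guess_element(name)
            if table is not None:
                charge, sigma, eps, radius = table.lookup(name, resname, element)
            else:
                charge, sigma, eps, radius = builtin_parameters(name, resname, element)
            atoms.append(
                Atom(atom_id, name, element, ri, resname, charge, sigma, eps, radius)
            )
            ids.append(atom_id)
            atom_id += 1
        residues.append(Residue(ri, resname, tuple(ids), int(res.resid)))
        (protein_res if resname in PROTEIN_RESIDUES else ligand_res).append(ri)

    seen = len({a.atom_id for a in atoms})
    if seen != len(atoms):
        raise FormatError("duplicate atom ids in structure")

    molecules: dict[str, tuple[int, ...]] = {}
    if protein_res:
        molecules["protein"] = tuple(protein_res)
    if ligand_res:
        molecules["ligand"] = tuple(ligand_res)

    coords_nm = u.atoms.positions.astype(float) / A_PER_NM
    names = np.array([a.name for a in atoms])
    rings = derive_rings(residues, names)
    if ligand_rings:
        for k, ring in enumerate(ligand_rings):
            owner_res = atoms[ring[0]].residue_index
            rings.append(
                RingDefinition(f"LIG:ring{k}", tuple(int(i) for i in ring),
                               "ligand", owner_res)
            )
    return SystemTopology(
        atoms=atoms,
        residues=residues,
        molecules=molecules,
        ring_definitions=rings,
        charged_groups=derive_charged_groups(residues, names),
        hbond_roles=derive_hbond_roles(np.array([a.element for a in atoms]), coords_nm),
        reference_coordinates=coords_nm,
    )


# ---------------------------------------------------------------------------
# Trajectory I/O
# ---------------------------------------------------------------------------

_READERS = {
    ".pdb": "PDB",
    ".gro": "GRO",
    ".xtc": "XTC",
    ".dcd": "DCD",
}


def read_trajectory(trajectory_file, topology: SystemTopology) -> Trajectory:
    """Load a multi-model PDB / GRO / XTC / DCD trajectory (nm, ps)."""
    path = str(trajectory_file)
    ext = os.path.splitext(path)[1].lower()
    if ext not in _READERS:
        raise FormatError(f"unsupported trajectory format {ext!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reader = mda.coordinates.core.reader(path)
        if reader.n_atoms != topology.atom_count:
            raise TrajectoryMismatchError(
                f"trajectory has {reader.n_atoms} atoms, topology has "
                f"{topology.atom_count}"
            )
        times, coords, boxes = [], [], []
        has_box = True
        for ts in reader:
            times.append(float(ts.time))
            coords.append(ts.positions.astype(float) / A_PER_NM)
            if ts.dimensions is None or not np.all(ts.dimensions[:3] > 0):
                has_box = False
            else:
                boxes.append(np.asarray(ts.dimensions[:3], dtype=float) / A_PER_NM)
    times_arr = np.asarray(times)
    if len(times_arr) > 1 and not np.all(np.diff(times_arr) > 0):
        if np.allclose(times_arr, times_arr[0]):
            # format carries no time information; fall back to frame index
            times_arr = np.arange(len(times_arr), dtype=float)
        else:
            raise FormatError("trajectory times are not strictly increasing")
    box = np.asarray(boxes) if has_box and len(boxes) == len(coords) else None
    return Trajectory(times_arr, np.asarray(coords), box)


def _universe_from_topology(topology: SystemTopology) -> "mda.Universe":
    n_res = len(topology.residues)
    resindex = topology.residue_index
    u = mda.Universe.empty(
        topology.atom_count,
        n_residues=n_res,
        atom_resindex=resindex,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [a.name for a in topology.atoms])
    u.add_TopologyAttr("elements", [a.element for a in topology.atoms])
    u.add_TopologyAttr("resnames", [r.name for r in topology.residues])
    u.add_TopologyAttr("resids", [r.display_number for r in topology.residues])
    return u


def write_trajectory(traj: Trajectory, topology: SystemTopology, path) -> None:
    """Write a trajectory as multi-model PDB, XTC or DCD (by extension)."""
    path = str(path)
    ext = os.path.splitext(path)[1].lower()
    if ext not in (".pdb", ".xtc", ".dcd"):
        raise FormatError(f"unsupported output format {ext!r}")
    u = _universe_from_topology(topology)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(path, n_atoms=topology.atom_count, multiframe=True) as w:
            for i in range(traj.n_frames):
                u.atoms.positions = traj.coordinates[i] * A_PER_NM
                ts = u.trajectory.ts
                ts.time = traj.times[i]
                ts.frame = i
                if traj.box is not None:
                    ts.dimensions = [*(traj.box[i] * A_PER_NM), 90.0, 90.0, 90.0]
                elif ext == ".xtc":
                    # XTC requires a box; use a large dummy cell
                    ts.dimensions = [9999.0, 9999.0, 9999.0, 90.0, 90.0, 90.0]
                w.write(u.atoms)


def write_structure(coords_nm: np.ndarray, topology: SystemTopology, path) -> None:
    """Write a single frame as PDB/GRO."""
    u = _universe_from_topology(topology)
    u.atoms.positions = np.asarray(coords_nm) * A_PER_NM
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))
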