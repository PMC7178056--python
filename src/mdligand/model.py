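"""Core data model: topology, trajectory, selections, analysis configuration.

Conventions used throughout the package:

* coordinates and distances in **nm**, times in **ps**,
* energies in **kcal/mol**, charges in elementary charges,
* intrinsic (GB) radii and H-bond cutoffs in **Å** where noted,
* residues indexed 0-based and densely internally; the original structure
  numbering is kept as ``display_number`` so reports can print labels such
  as ``PHE64`` in author numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml

from .errors import (
    ConfigError,
    EmptyTrajectoryError,
    FormatError,
    SelectionError,
)
from .parameters import ELEMENT_MASS

PROTEIN_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class Atom:
    atom_id: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    partial_charge: float  # e
    lj_sigma: float        # nm
    lj_epsilon: float      # kcal/mol
    intrinsic_radius: float  # Å


@dataclass(frozen=True)
class Residue:
    index: int
    name: str
    atom_ids: tuple[int, ...]
    display_number: int  # author / PDB numbering

    @property
    def label(self) -> str:
        return f"{self.name}{self.display_number}"


@dataclass(frozen=True)
class RingDefinition:
    ring_id: str
    atom_ids: tuple[int, ...]
    owner: str  # "protein" or "ligand"
    residue_index: int


@dataclass(frozen=True)
class ChargedGroup:
    group_id: str
    sign: int  # +1 or -1
    atom_ids: tuple[int, ...]
    residue_index: int


@dataclass(frozen=True)
class HBondRoles:
    donor_pairs: tuple[tuple[int, int], ...]  # (donor heavy atom, hydrogen)
    acceptors: tuple[int, ...]


class SystemTopology:
    """Static description of the system: atoms, residues, entities, roles.

    ``molecules`` partitions residue indices into named entities (at least
    ``"protein"``; ``"ligand"`` when present).  ``reference_coordinates``
    (nm) are optional and hold the coordinates of the structure the
    topology was read/built from.
    """

    def __init__(
        self,
        atoms: Sequence[Atom],
        residues: Sequence[Residue],
        molecules: dict[str, tuple[int, ...]],
        ring_definitions: Sequence[RingDefinition] = (),
        charged_groups: Sequence[ChargedGroup] = (),
        hbond_roles: Optional[HBondRoles] = None,
        reference_coordinates: Optional[np.ndarray] = None,
    ):
        self.atoms = list(atoms)
        self.residues = list(residues)
        self.molecules = dict(molecules)
        self.ring_definitions = list(ring_definitions)
        self.charged_groups = list(charged_groups)
        self.hbond_roles = hbond_roles or HBondRoles((), ())
        self.reference_coordinates = (
            None if reference_coordinates is None
            else np.asarray(reference_coordinates, dtype=float)
        )
        self._validate()
        # cached per-atom arrays
        n = len(self.atoms)
        self.names = np.array([a.name for a in self.atoms])
        self.elements = np.array([a.element for a in self.atoms])
        self.residue_index = np.array([a.residue_index for a in self.atoms])
        self.charges = np.array([a.partial_charge for a in self.atoms])
        self.lj_sigma = np.array([a.lj_sigma for a in self.atoms])
        self.lj_epsilon = np.array([a.lj_epsilon for a in self.atoms])
        self.intrinsic_radius = np.array([a.intrinsic_radius for a in self.atoms])
        self.masses = np.array(
            [ELEMENT_MASS.get(a.element, 12.011) for a in self.atoms]
        )
        assert len(self.names) == n

    # -- validation ----------------------------------------------------
    def _validate(self) -> None:
        ids = [a.atom_id for a in self.atoms]
        if ids != list(range(len(ids))):
            raise FormatError("atom ids must be dense, unique and 0-based")
        res_indices = {r.index for r in self.residues}
        for a in self.atoms:
            if a.residue_index not in res_indices:
                raise FormatError(
                    f"atom {a.atom_id} references unknown residue {a.residue_index}"
                )
        for ring in self.ring_definitions:
            if len(ring.atom_ids) < 5:
                raise FormatError(f"ring {ring.ring_id} has fewer than 5 atoms")
        seen_h: dict[int, int] = {}
        for donor, hydrogen in self.hbond_roles.donor_pairs:
            if hydrogen in seen_h:
                raise FormatError(
                    f"hydrogen {hydrogen} assigned to two donors "
                    f"({seen_h[hydrogen]}, {donor})"
                )
            seen_h[hydrogen] = donor
        # entities must not share atoms
        owned: set[int] = set()
        for name, res_idx in self.molecules.items():
            atoms = set()
            for ri in res_idx:
                atoms.update(self.residues[ri].atom_ids)
            if owned & atoms:
                raise FormatError(f"entity {name!r} overlaps another entity")
            owned |= atoms

    # -- convenience ---------------------------------------------------
    @property
    def atom_count(self) -> int:
        return len(self.atoms)

    def entity_residues(self, entity: str) -> tuple[int, ...]:
        if entity not in self.molecules:
            raise SelectionError(f"unknown entity {entity!r}")
        return self.molecules[entity]

    def entity_atom_ids(self, entity: str) -> np.ndarray:
        ids: list[int] = []
        for ri in self.entity_residues(entity):
            ids.extend(self.residues[ri].atom_ids)
        return np.array(sorted(ids), dtype=int)

    def residue_atom_ids(self, residue_index: int) -> np.ndarray:
        return np.array(self.residues[residue_index].atom_ids, dtype=int)

    def heavy_mask(self) -> np.ndarray:
        return self.elements != "H"

    def atoms_named(self, residue_index: int, name: str) -> list[int]:
        res = self.residues[residue_index]
        return [i for i in res.atom_ids if self.atoms[i].name == name]

    def atom_label(self, atom_id: int) -> str:
        a = self.atoms[atom_id]
        return f"{self.residues[a.residue_index].label}:{a.name}"


# ---------------------------------------------------------------------------
# Trajectory
# ---------------------------------------------------------------------------

class Trajectory:
    """Ordered coordinate frames: times (ps), coordinates (n_frames, n_atoms, 3) nm.

    ``box`` is either None (non-periodic) or an (n_frames, 3) array of
    orthorhombic edge lengths in nm.
    """

    def __init__(self, times, coordinates, box=None):
        self.times = np.asarray(times, dtype=float)
        self.coordinates = np.asarray(coordinates, dtype=float)
        self.box = None if box is None else np.asarray(box, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise FormatError("coordinates must have shape (n_frames, n_atoms, 3)")
        if len(self.times) != self.coordinates.shape[0]:
            raise FormatError("times and coordinates disagree on frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise FormatError("frame times must be strictly increasing")
        if not np.all(np.isfinite(self.coordinates)):
            raise FormatError("coordinates contain non-finite values")
        if self.box is not None and self.box.shape != (len(self.times), 3):
            raise FormatError("box must have shape (n_frames, 3)")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def atom_count(self) -> int:
        return self.coordinates.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coordinates[i]

    def __len__(self) -> int:
        return self.n_frames


def discard_burn_in(traj: Trajectory, burn_in: float) -> Trajectory:
    """Drop the initial ``burn_in`` ps, keeping frames with t >= t0 + burn_in.

    The equilibration segment of a production run is discarded before any
    equilibrium statistic (RMSF, densities, energies) is accumulated.
    """
    if burn_in < 0:
        raise ConfigError("burn_in must be >= 0")
    keep = traj.times >= traj.times[0] + burn_in
    if not keep.any():
        raise EmptyTrajectoryError(
            f"burn-in of {burn_in} ps removes all {traj.n_frames} frames"
        )
    return Trajectory(
        traj.times[keep],
        traj.coordinates[keep],
        None if traj.box is None else traj.box[keep],
    )


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionSpec:
    """Declarative atom subset.

    Modes:
      * ``residue_range``: payload ``(first, last)`` inclusive residue indices
      * ``atom_names``: payload iterable of atom names
      * ``entity``: payload ``"protein"`` or ``"ligand"``
      * ``role_tag``: payload one of ``"CA"``/``"calpha"``, ``"backbone"``,
        ``"heavy"``, ``"all"``
    """

    mode: str
    payload: object
    label: str = ""

    def __post_init__(self):
        if self.mode not in {"residue_range", "atom_names", "entity", "role_tag"}:
            raise SelectionError(f"unknown selection mode {self.mode!r}")


def resolve_selection(spec: SelectionSpec, topology: SystemTopology) -> np.ndarray:
    """Resolve a SelectionSpec to a sorted, duplicate-free atom-id array."""
    if spec.mode == "entity":
        ids = topology.entity_atom_ids(str(spec.payload))
    elif spec.mode == "residue_range":
        first, last = spec.payload  # type: ignore[misc]
        if first > last or first < 0 or last >= len(topology.residues):
            raise SelectionError(f"residue range {spec.payload} out of bounds")
        ids_list: list[int] = []
        for ri in range(int(first), int(last) + 1):
            ids_list.extend(topology.residues[ri].atom_ids)
        ids = np.array(ids_list, dtype=int)
    elif spec.mode == "atom_names":
        wanted = set(spec.payload)  # type: ignore[arg-type]
        ids = np.array(
            [a.atom_id for a in topology.atoms if a.name in wanted], dtype=int
        )
    elif spec.mode == "role_tag":
        tag = str(spec.payload).lower()
        if tag in ("ca", "calpha", "cα"):
            ids = np.array(
                [a.atom_id for a in topology.atoms if a.name == "CA"], dtype=int
            )
        elif tag == "backbone":
            ids = np.array(
                [
                    a.atom_id
                    for a in topology.atoms
                    if a.name in BACKBONE_NAMES
                    and a.residue_name in PROTEIN_RESIDUES
                ],
                dtype=int,
            )
        elif tag == "heavy":
            ids = np.flatnonzero(topology.heavy_mask()).astype(int)
        elif tag == "all":
            ids = np.arange(topology.atom_count, dtype=int)
        else:
            raise SelectionError(f"unknown role tag {spec.payload!r}")
    else:  # pragma: no cover - guarded in __post_init__
        raise SelectionError(f"unknown selection mode {spec.mode!r}")
    ids = np.unique(ids)
    if ids.size == 0:
        raise SelectionError(f"selection {spec.label or spec.mode!r} is empty")
    return ids


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """All analysis constants in one place.

    Defaults encode the study conditions: 100 ns burn-in, 310 K, the two
    contact definitions (0.46 nm residue-residue, 0.54 nm residue-ligand),
    the 3.5 Å / 150-180 deg geometric H-bond criterion, and standard GB-SA
    solvation constants.
    """

    burn_in: float = 100_000.0        # ps (100 ns)
    temperature: float = 310.0        # K
    contact_cutoff_pair: float = 0.46    # nm, residue-residue
    contact_cutoff_ligand: float = 0.54  # nm, residue-ligand
    hbond_distance_max: float = 3.5   # Å, donor-heavy to acceptor-heavy
    hbond_angle_min: float = 150.0    # deg, D-H...A
    hbond_angle_max: float = 180.0
    sasa_probe_radius: float = 1.4    # Å
    sasa_sphere_points: int = 960
    histogram_bins: int = 100
    gb_epsilon_in: float = 1.0
    gb_epsilon_out: float = 78.5
    surf_gamma: float = 0.0072        # kcal/(mol*Å^2)
    surf_offset: float = 0.0          # kcal/mol
    rng_seed: int = 0

    def __post_init__(self):
        if self.burn_in < 0:
            raise ConfigError("burn_in must be >= 0")
        if self.temperature <= 0:
            raise ConfigError("temperature must be > 0")
        for name in ("contact_cutoff_pair", "contact_cutoff_ligand",
                     "hbond_distance_max", "sasa_probe_radius"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if not (0 <= self.hbond_angle_min < self.hbond_angle_max <= 180):
            raise ConfigError("need 0 <= hbond_angle_min < hbond_angle_max <= 180")
        if self.sasa_sphere_points < 8:
            raise ConfigError("sasa_sphere_points must be >= 8")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def replace(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)
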