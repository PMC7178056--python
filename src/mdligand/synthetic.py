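"""Synthetic protein-ligand topologies and trajectories with planted ground truth.

The generator emulates an equilibrating MD run of a toy protein with an
inserted multi-ring ligand:

* idealized extended backbone with side-chain stubs; PHE/TRP carry their
  real aromatic ring atom sets, ARG/LYS/ASP/GLU their charged terminals;
* an optional ligand of fused six-membered carbon rings "in a line" plus a
  small polar tail (an acceptor oxygen and a tail carbon);
* an initial rigid-body drift phase (linear translation decaying to zero)
  that deliberately violates stationarity, so burn-in discarding has a
  measurable effect;
* a stationary phase of per-residue rigid isotropic Gaussian displacements
  with block-correlated residues (Cholesky/eigen factor of the block
  covariance), making RMSF and covariance ground truth analytic;
* planted hydrogen bonds, a salt-bridge distance trace, residue-ligand
  contacts and aromatic stacking geometries, each realized by construction
  in a stated fraction of stationary frames.

Every planted quantity is returned in a :class:`GroundTruth` record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .errors import SyntheticSpecError
from .io import derive_charged_groups, derive_hbond_roles, derive_rings
from .model import (
    Atom,
    Residue,
    RingDefinition,
    SystemTopology,
    Trajectory,
)
from .parameters import builtin_parameters

RESIDUE_SPACING = 0.38  # nm along the chain axis
RING_BOND = 0.139       # nm, aromatic C-C

# backbone template: name -> offset (nm) from the residue origin
_BACKBONE = {
    "N": (0.00, 0.00, 0.00),
    "H": (0.00, -0.10, 0.00),
    "CA": (0.15, 0.05, 0.00),
    "C": (0.28, 0.00, 0.00),
    "O": (0.28, 0.12, 0.00),
}


def _hexagon(center, radius=RING_BOND, phase=-90.0):
    ang = np.deg2rad(phase + 60.0 * np.arange(6))
    return [
        (center[0] + radius * np.cos(a), center[1] + radius * np.sin(a), center[2])
        for a in ang
    ]


def _sidechain(resname: str) -> dict[str, tuple[float, float, float]]:
    """Side-chain atom offsets relative to the residue origin."""
    ca = np.array(_BACKBONE["CA"])
    cb = ca + (0.0, 0.15, 0.0)
    out: dict[str, tuple] = {}
    if resname == "GLY":
        return out
    out["CB"] = tuple(cb)
    if resname in ("ALA",):
        return out
    if resname == "SER":
        og = cb + (0.0, 0.14, 0.0)
        out["OG"] = tuple(og)
        out["HG"] = tuple(og + (0.08, 0.06, 0.0))
    elif resname == "PHE":
        center = cb + (0.0, 0.25, 0.0)
        names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
        for n, p in zip(names, _hexagon(center)):
            out[n] = p
    elif resname == "TRP":
        c6 = cb + (0.0, 0.32, 0.0)
        hexa = {
            n: np.array(p)
            for n, p in zip(
                ["CE2", "CD2", "CE3", "CZ3", "CH2", "CZ2"],
                _hexagon(c6, phase=150.0),
            )
        }
        # pentagon fused on the CE2-CD2 edge, on the -x side of the hexagon
        edge_mid = 0.5 * (hexa["CE2"] + hexa["CD2"])
        apothem = RING_BOND / (2.0 * np.tan(np.deg2rad(36.0)))
        r5 = RING_BOND / (2.0 * np.sin(np.deg2rad(36.0)))
        c5 = edge_mid + (edge_mid - c6) / np.linalg.norm(edge_mid - c6) * apothem
        for n, angle in (("NE1", 108.0), ("CD1", 180.0), ("CG", 252.0)):
            a = np.deg2rad(angle)
            out[n] = tuple(c5 + r5 * np.array([np.cos(a), np.sin(a), 0.0]))
        for n, p in hexa.items():
            out[n] = tuple(p)
    elif resname == "ARG":
        ne = cb + (0.0, 0.15, 0.0)
        cz = ne + (0.0, 0.13, 0.0)
        nh1 = cz + (-0.11, 0.08, 0.0)
        nh2 = cz + (0.11, 0.08, 0.0)
        out.update(
            NE=tuple(ne), HE=tuple(ne + (0.10, 0.0, 0.0)), CZ=tuple(cz),
            NH1=tuple(nh1), HH1=tuple(nh1 + (-0.06, 0.08, 0.0)),
            NH2=tuple(nh2), HH2=tuple(nh2 + (0.06, 0.08, 0.0)),
        )
    elif resname == "LYS":
        nz = cb + (0.0, 0.18, 0.0)
        out["NZ"] = tuple(nz)
        out["HZ1"] = tuple(nz + (0.0, 0.10, 0.0))
    elif resname == "ASP":
        cg = cb + (0.0, 0.14, 0.0)
        out["CG"] = tuple(cg)
        out["OD1"] = tuple(cg + (-0.11, 0.07, 0.0))
        out["OD2"] = tuple(cg + (0.11, 0.07, 0.0))
    elif resname == "GLU":
        cg = cb + (0.0, 0.14, 0.0)
        cd = cg + (0.0, 0.14, 0.0)
        out["CG"] = tuple(cg)
        out["CD"] = tuple(cd)
        out["OE1"] = tuple(cd + (-0.11, 0.07, 0.0))
        out["OE2"] = tuple(cd + (0.11, 0.07, 0.0))
    else:
        raise SyntheticSpecError(f"unsupported residue name {resname!r}")
    return out


# ---------------------------------------------------------------------------
# Specification
# ---------------------------------------------------------------------------

@dataclass
class CorrelationBlock:
    residues: tuple[int, ...]
    rho: float


@dataclass
class PlantedHBond:
    donor_residue: int          # backbone N-H of this residue donates
    acceptor_residue: int       # this residue's named atom is the acceptor
    fraction: float
    acceptor_atom: str = "O"
    distance_nm: float = 0.29   # donor-heavy to acceptor distance when bonded
    angle_deg: float = 165.0    # D-H...A angle when bonded
    off_distance_nm: float = 0.45


@dataclass
class PlantedSaltBridge:
    basic_residue: int
    acidic_residue: int
    distance_nm: Union[float, np.ndarray] = 0.18  # constant or per-frame trace


@dataclass
class PlantedStacking:
    protein_ring: str           # ring_id of a protein aromatic ring
    ligand_ring: int            # index among the ligand's rings
    angle_deg: float
    distance_nm: float
    fraction: float


@dataclass
class PlantedContact:
    residue: int
    fraction: float
    distance_in_nm: float = 0.35
    distance_out_nm: float = 0.90


@dataclass
class SyntheticSpec:
    n_residues: int
    residue_plan: Optional[Sequence[str]] = None  # default: all ALA
    ligand_rings: int = 0
    ligand_offset_nm: tuple[float, float, float] = (0.0, 1.6, 0.0)
    ligand_charges: dict = field(default_factory=dict)  # atom name -> e
    n_frames: int = 100
    dt: float = 1.0  # ps
    fluct_sigma: Union[float, Sequence[float]] = 0.02  # nm, per residue
    ligand_fluct_sigma: float = 0.0
    correlation_blocks: Sequence[CorrelationBlock] = ()
    planted_hbonds: Sequence[PlantedHBond] = ()
    planted_saltbridge: Optional[PlantedSaltBridge] = None
    planted_stacking: Sequence[PlantedStacking] = ()
    planted_contacts: Sequence[PlantedContact] = ()
    drift_frames: int = 0
    drift_offset_nm: tuple[float, float, float] = (0.8, 0.0, 0.0)
    # residues displaced during the drift phase; None = the N-terminal third
    # of the chain (a whole-body rigid drift would be absorbed exactly by
    # superposition and hence be invisible to RMSD/RMSF)
    drift_residues: Optional[Sequence[int]] = None
    seed: int = 0

    def plan(self) -> list[str]:
        if self.residue_plan is None:
            return ["ALA"] * self.n_residues
        plan = list(self.residue_plan)
        if len(plan) != self.n_residues:
            raise SyntheticSpecError(
                f"residue_plan has {len(plan)} entries for n_residues="
                f"{self.n_residues}"
            )
        return plan

    def validate(self) -> None:
        self.plan()
        if self.n_frames <= self.drift_frames:
            raise SyntheticSpecError("n_frames must exceed drift_frames")
        for b in self.correlation_blocks:
            if abs(b.rho) > 1:
                raise SyntheticSpecError(f"|rho| > 1 in block {b}")
        for h in self.planted_hbonds:
            if not 0 <= h.fraction <= 1:
                raise SyntheticSpecError("H-bond fraction outside [0, 1]")
        for c in self.planted_contacts:
            if not 0 <= c.fraction <= 1:
                raise SyntheticSpecError("contact fraction outside [0, 1]")
        total = 0.0
        for s in self.planted_stacking:
            if not 0 <= s.fraction <= 1:
                raise SyntheticSpecError("stacking fraction outside [0, 1]")
            total += s.fraction
        if total > 1.0 + 1e-12:
            raise SyntheticSpecError("stacking fractions sum to more than 1")
        if (self.planted_stacking or self.planted_contacts) and not self.ligand_rings:
            raise SyntheticSpecError("ligand plants require ligand_rings >= 1")


# ---------------------------------------------------------------------------
# Topology construction
# ---------------------------------------------------------------------------

def build_topology(spec: SyntheticSpec) -> SystemTopology:
    """Idealized topology + reference coordinates for a SyntheticSpec."""
    spec.validate()
    plan = spec.plan()
    atoms: list[Atom] = []
    residues: list[Residue] = []
    coords: list[tuple[float, float, float]] = []
    atom_id = 0
    for ri, resname in enumerate(plan):
        # small alternating z offset keeps the C-alpha trace non-collinear,
        # so superposition on C-alphas is well-posed even at zero fluctuation
        origin = np.array([RESIDUE_SPACING * ri, 0.0, 0.04 * (ri % 2)])
        placed = dict(_BACKBONE)
        placed.update(_sidechain(resname))
        ids = []
        for name, offset in placed.items():
            element = name.lstrip("0123456789")[0]
            charge, sigma, eps, radius = builtin_parameters(name, resname, element)
            atoms.append(
                Atom(atom_id, name, element, ri, resname, charge, sigma, eps, radius)
            )
            coords.append(tuple(origin + np.array(offset)))
            ids.append(atom_id)
            atom_id += 1
        residues.append(Residue(ri, resname, tuple(ids), ri + 1))

    molecules: dict[str, tuple[int, ...]] = {"protein": tuple(range(len(plan)))}
    ligand_ring_defs: list[tuple[str, list[int]]] = []
    if spec.ligand_rings > 0:
        ri = len(residues)
        chain_mid = RESIDUE_SPACING * (spec.n_residues - 1) / 2.0
        lig_origin = np.array([chain_mid - 0.25 * (spec.ligand_rings - 1) / 2.0, 0, 0])
        lig_origin = lig_origin + np.array(spec.ligand_offset_nm)
        ids = []
        for j in range(spec.ligand_rings):
            center = lig_origin + np.array([0.25 * j, 0.0, 0.0])
            ring_ids = []
            for k, p in enumerate(_hexagon(center)):
                name = f"C{j}{k + 1}"
                charge = float(spec.ligand_charges.get(name, 0.0))
                _, sigma, eps, radius = builtin_parameters(name, "LIG", "C")
                atoms.append(
                    Atom(atom_id, name, "C", ri, "LIG", charge, sigma, eps, radius)
                )
                coords.append(tuple(p))
                ring_ids.append(atom_id)
                ids.append(atom_id)
                atom_id += 1
            ligand_ring_defs.append((f"LIG:ring{j}", ring_ids))
        tail_base = lig_origin + np.array([0.25 * spec.ligand_rings, 0.0, 0.0])
        for name, off, element in (
            ("O1", (0.0, 0.0, 0.0), "O"),
            ("CT1", (0.15, 0.0, 0.0), "C"),
        ):
            charge = float(spec.ligand_charges.get(name, 0.0))
            _, sigma, eps, radius = builtin_parameters(name, "LIG", element)
            atoms.append(
                Atom(atom_id, name, element, ri, "LIG", charge, sigma, eps, radius)
            )
            coords.append(tuple(tail_base + np.array(off)))
            ids.append(atom_id)
            atom_id += 1
        residues.append(Residue(ri, "LIG", tuple(ids), 1))
        molecules["ligand"] = (ri,)

    names = np.array([a.name for a in atoms])
    elements = np.array([a.element for a in atoms])
    ref = np.array(coords, dtype=float)
    rings = derive_rings(residues, names)
    for ring_id, ring_ids in ligand_ring_defs:
        rings.append(
            RingDefinition(ring_id, tuple(ring_ids), "ligand", len(plan))
        )
    return SystemTopology(
        atoms=atoms,
        residues=residues,
        molecules=molecules,
        ring_definitions=rings,
        charged_groups=derive_charged_groups(residues, names),
        hbond_roles=derive_hbond_roles(elements, ref),
        reference_coordinates=ref,
    )


# ---------------------------------------------------------------------------
# Ground truth record
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    n_frames: int
    drift_frames: int
    fluct_sigma: np.ndarray                 # per protein residue, nm
    correlation_blocks: list
    hbond_masks: list                        # bool arrays, len n_frames
    saltbridge_trace: Optional[np.ndarray]   # nm; NaN where not planted
    stacking_masks: list                     # bool arrays per stacking plant
    stacking_geometry: list                  # (angle_deg, distance_nm) per plant
    contact_masks: list
    planted_binding_residue: Optional[int] = None
    drift_residues: tuple = ()

    @property
    def stationary(self) -> slice:
        return slice(self.drift_frames, self.n_frames)

    def to_json(self, path) -> None:
        def arr(a):
            return np.asarray(a).tolist()

        payload = {
            "n_frames": self.n_frames,
            "drift_frames": self.drift_frames,
            "drift_residues": list(self.drift_residues),
            "fluct_sigma": arr(self.fluct_sigma),
            "correlation_blocks": [
                {"residues": list(b.residues), "rho": b.rho}
                for b in self.correlation_blocks
            ],
            "hbond_masks": [arr(m.astype(int)) for m in self.hbond_masks],
            "saltbridge_trace": (
                None if self.saltbridge_trace is None
                else [None if np.isnan(v) else v for v in self.saltbridge_trace]
            ),
            "stacking_masks": [arr(m.astype(int)) for m in self.stacking_masks],
            "stacking_geometry": [list(g) for g in self.stacking_geometry],
            "contact_masks": [arr(m.astype(int)) for m in self.contact_masks],
            "planted_binding_residue": self.planted_binding_residue,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# Trajectory generation
# ---------------------------------------------------------------------------

def _covariance_factor(sigma: np.ndarray, blocks) -> np.ndarray:
    """Symmetric factor F with F F^T = block covariance (eigen square root)."""
    n = len(sigma)
    cov = np.diag(sigma ** 2)
    for b in blocks:
        for i in b.residues:
            for j in b.residues:
                if i != j:
                    cov[i, j] = b.rho * sigma[i] * sigma[j]
    w, v = np.linalg.eigh(cov)
    if w.min() < -1e-10 * max(w.max(), 1e-30):
        raise SyntheticSpecError(
            "correlation blocks define a non-positive-semidefinite covariance "
            "(pairwise rho < 0 is only feasible for blocks of 2 residues)"
        )
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def _ring_frame(coords: np.ndarray):
    """(centroid, unit normal, in-plane unit axis) of a ring atom set."""
    c = coords.mean(axis=0)
    centered = coords - c
    _, _, vt = np.linalg.svd(centered)
    normal = vt[2]
    e1 = centered[0] - np.dot(centered[0], normal) * normal
    e1 /= np.linalg.norm(e1)
    return c, normal, e1


def _perp(v: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(v, ref)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    p = np.cross(v, ref)
    return p / np.linalg.norm(p)


def generate_trajectory(topology: SystemTopology, spec: SyntheticSpec):
    """Generate (Trajectory, GroundTruth) realizing every planted feature."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ref = topology.reference_coordinates
    if ref is None:
        raise SyntheticSpecError("topology carries no reference coordinates")

    n_res = spec.n_residues
    sigma = np.asarray(
        np.broadcast_to(np.asarray(spec.fluct_sigma, dtype=float), (n_res,))
    ).copy()
    factor = _covariance_factor(sigma, spec.correlation_blocks)

    prot_atom_res = topology.residue_index.copy()
    lig_ids = (
        topology.entity_atom_ids("ligand") if "ligand" in topology.molecules
        else np.array([], dtype=int)
    )
    lig_res_index = len(topology.residues) - 1 if lig_ids.size else None

    rings_by_id = {r.ring_id: r for r in topology.ring_definitions}
    lig_rings = [r for r in topology.ring_definitions if r.owner == "ligand"]
    for s in spec.planted_stacking:
        if s.protein_ring not in rings_by_id:
            raise SyntheticSpecError(f"unknown protein ring {s.protein_ring!r}")
        if s.ligand_ring >= len(lig_rings):
            raise SyntheticSpecError(f"ligand has no ring index {s.ligand_ring}")
        pr = rings_by_id[s.protein_ring]
        ra = _ring_radius(ref, pr.atom_ids)
        rb = _ring_radius(ref, lig_rings[s.ligand_ring].atom_ids)
        if s.distance_nm < ra + rb:
            raise SyntheticSpecError(
                f"stacking distance {s.distance_nm} nm smaller than ring radii "
                f"sum {ra + rb:.3f} nm"
            )

    n_frames = spec.n_frames
    drift = np.asarray(spec.drift_offset_nm, dtype=float)
    drift_res = (
        set(range(int(np.ceil(n_res / 3)))) if spec.drift_residues is None
        else set(int(r) for r in spec.drift_residues)
    )
    drift_atoms = np.flatnonzero(
        np.isin(topology.residue_index, sorted(drift_res))
        & (topology.residue_index < n_res)
    )
    times = np.arange(n_frames, dtype=float) * spec.dt
    coords_out = np.empty((n_frames, topology.atom_count, 3))

    hb_masks = [np.zeros(n_frames, dtype=bool) for _ in spec.planted_hbonds]
    ct_masks = [np.zeros(n_frames, dtype=bool) for _ in spec.planted_contacts]
    st_masks = [np.zeros(n_frames, dtype=bool) for _ in spec.planted_stacking]
    sb_trace = (
        np.full(n_frames, np.nan) if spec.planted_saltbridge is not None else None
    )

    sb = spec.planted_saltbridge
    if sb is not None:
        sb_values = np.broadcast_to(
            np.asarray(sb.distance_nm, dtype=float),
            (n_frames - spec.drift_frames,),
        )

    for f in range(n_frames):
        z = rng.standard_normal((n_res, 3))
        u_res = factor @ z  # (n_res, 3) per-residue rigid displacements
        frame = ref.copy()
        prot_mask = prot_atom_res < n_res
        frame[prot_mask] += u_res[prot_atom_res[prot_mask]]
        if lig_ids.size:
            u_lig = spec.ligand_fluct_sigma * rng.standard_normal(3)
            frame[lig_ids] += u_lig
        stationary = f >= spec.drift_frames
        if not stationary:
            frame[drift_atoms] += drift * (1.0 - f / max(spec.drift_frames, 1))
        else:
            s_idx = f - spec.drift_frames
            if sb is not None:
                d = float(sb_values[s_idx])
                _plant_saltbridge(frame, topology, sb, d)
                sb_trace[f] = d
            for k, hb in enumerate(spec.planted_hbonds):
                bonded = rng.random() < hb.fraction
                _plant_hbond(frame, topology, hb, bonded)
                hb_masks[k][f] = bonded
            if spec.planted_stacking:
                u = rng.random()
                cum = 0.0
                chosen = None
                for k, s in enumerate(spec.planted_stacking):
                    cum += s.fraction
                    if u < cum:
                        chosen = k
                        break
                if chosen is not None:
                    s = spec.planted_stacking[chosen]
                    _plant_stacking(
                        frame, topology, rings_by_id[s.protein_ring],
                        lig_rings[s.ligand_ring], lig_ids, s,
                    )
                    st_masks[chosen][f] = True
            for k, c in enumerate(spec.planted_contacts):
                present = rng.random() < c.fraction
                _plant_contact(frame, topology, c, present)
                ct_masks[k][f] = present
        coords_out[f] = frame

    gt = GroundTruth(
        n_frames=n_frames,
        drift_frames=spec.drift_frames,
        drift_residues=tuple(sorted(drift_res)),
        fluct_sigma=sigma,
        correlation_blocks=list(spec.correlation_blocks),
        hbond_masks=hb_masks,
        saltbridge_trace=sb_trace,
        stacking_masks=st_masks,
        stacking_geometry=[(s.angle_deg, s.distance_nm) for s in spec.planted_stacking],
        contact_masks=ct_masks,
        planted_binding_residue=(
            rings_by_id[spec.planted_stacking[0].protein_ring].residue_index
            if spec.planted_stacking else None
        ),
    )
    return Trajectory(times, coords_out), gt


def _ring_radius(coords: np.ndarray, atom_ids) -> float:
    ring = coords[list(atom_ids)]
    c = ring.mean(axis=0)
    return float(np.max(np.linalg.norm(ring - c, axis=1)))


def _basic_anchor(topology: SystemTopology, residue: int):
    """(anchor N atom id, direction-defining inner atom id) for Arg/Lys."""
    name = topology.residues[residue].name
    if name == "ARG":
        return (
            topology.atoms_named(residue, "NH1")[0],
            topology.atoms_named(residue, "CZ")[0],
        )
    if name == "LYS":
        return (
            topology.atoms_named(residue, "NZ")[0],
            topology.atoms_named(residue, "CB")[0],
        )
    raise SyntheticSpecError(f"residue {residue} ({name}) is not basic")


def _acidic_oxygens(topology: SystemTopology, residue: int):
    name = topology.residues[residue].name
    pair = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}.get(name)
    if pair is None:
        raise SyntheticSpecError(f"residue {residue} ({name}) is not acidic")
    return [topology.atoms_named(residue, n)[0] for n in pair]


def _plant_saltbridge(frame, topology, sb: PlantedSaltBridge, d: float) -> None:
    n_id, inner_id = _basic_anchor(topology, sb.basic_residue)
    o1, o2 = _acidic_oxygens(topology, sb.acidic_residue)
    anchor = frame[n_id]
    e = anchor - frame[inner_id]
    e /= np.linalg.norm(e)
    perp = _perp(e)
    frame[o1] = anchor + d * e
    frame[o2] = anchor + (d + 0.06) * e + 0.03 * perp


def _plant_hbond(frame, topology, hb: PlantedHBond, bonded: bool) -> None:
    n_id = topology.atoms_named(hb.donor_residue, "N")[0]
    h_id = topology.atoms_named(hb.donor_residue, "H")[0]
    a_id = topology.atoms_named(hb.acceptor_residue, hb.acceptor_atom)[0]
    n, h = frame[n_id], frame[h_id]
    nh = h - n
    d_nh = np.linalg.norm(nh)
    dirv = nh / d_nh
    if not bonded:
        frame[a_id] = n + hb.off_distance_nm * dirv
        return
    theta = np.deg2rad(hb.angle_deg)
    a_dir = np.cos(theta) * (-dirv) + np.sin(theta) * _perp(dirv)
    b = np.dot(nh, a_dir)  # (h - n) . a_dir
    d = hb.distance_nm
    s = -b + np.sqrt(b * b - (d_nh * d_nh - d * d))
    frame[a_id] = h + s * a_dir


def _plant_contact(frame, topology, c: PlantedContact, present: bool) -> None:
    ca = topology.atoms_named(c.residue, "CA")[0]
    tail = None
    lig_res = topology.molecules["ligand"][0]
    ids = topology.atoms_named(lig_res, "CT1")
    tail = ids[0]
    d = c.distance_in_nm if present else c.distance_out_nm
    frame[tail] = frame[ca] + np.array([0.0, 0.0, d])


def _plant_stacking(frame, topology, protein_ring, ligand_ring, lig_ids, s) -> None:
    c_p, n_p, _ = _ring_frame(frame[list(protein_ring.atom_ids)])
    # keep the protein ring's normal pointing toward the ligand's rest side
    axis = _perp(n_p)
    alpha = np.deg2rad(s.angle_deg)
    n_t = np.cos(alpha) * n_p + np.sin(alpha) * axis
    c_t = c_p + s.distance_nm * n_p
    e_t = np.cross(n_t, axis)
    e_t /= np.linalg.norm(e_t)
    c_l, n_l, e_l = _ring_frame(frame[list(ligand_ring.atom_ids)])
    basis_l = np.column_stack([n_l, e_l, np.cross(n_l, e_l)])
    basis_t = np.column_stack([n_t, e_t, np.cross(n_t, e_t)])
    rot = basis_t @ basis_l.T
    frame[lig_ids] = (frame[lig_ids] - c_l) @ rot.T + c_t
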