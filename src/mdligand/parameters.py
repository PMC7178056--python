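"""Built-in nonbonded parameter table and sidecar CSV loading.

Force-field parameters (partial charge, Lennard-Jones sigma/epsilon,
intrinsic GB radius) are supplied either by a sidecar CSV or by the
built-in minimal table below.  The built-in table carries per-element LJ
and radius defaults plus AMBER-flavoured charges for the backbone amide
and for the titratable side chains (Arg/Lys positive, Asp/Glu negative),
matching the convention that those residues are simulated in their
charged states at neutral pH.

Sidecar CSV columns: ``atom_name, residue_name, charge_e, sigma_nm,
epsilon_kcal, radius_A``.  Matching precedence for an atom:

1. exact ``(atom_name, residue_name)`` row,
2. ``(atom_name, "*")`` row,
3. per-element wildcard ``(element, "*")`` row,
4. ``("*", "*")`` row.

Units: charges in elementary charges, sigma in nm, epsilon in kcal/mol,
intrinsic radius in Å (mbondi-style radii used by GB).
"""

from __future__ import annotations

import pandas as pd

from .errors import FormatError, ParameterError

# element -> (sigma_nm, epsilon_kcal, radius_A)
ELEMENT_LJ_RADIUS: dict[str, tuple[float, float, float]] = {
    "H": (0.107, 0.0157, 1.20),
    "C": (0.340, 0.0860, 1.70),
    "N": (0.325, 0.1700, 1.55),
    "O": (0.296, 0.2100, 1.50),
    "S": (0.356, 0.2500, 1.80),
    "P": (0.374, 0.2000, 1.85),
}

ELEMENT_MASS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
}

# HCT pairwise-descreening scaling factors by element.
HCT_SCREEN: dict[str, float] = {
    "H": 0.85,
    "C": 0.72,
    "N": 0.79,
    "O": 0.85,
    "S": 0.96,
    "P": 0.86,
}
HCT_SCREEN_DEFAULT = 0.80

# Backbone amide charges (AMBER-like); CA tweaked so N,H,CA,C,O sum to zero,
# keeping every synthetic residue with an uncharged side chain net neutral.
_BACKBONE_CHARGE = {
    "N": -0.4157,
    "H": 0.2719,
    "CA": 0.1144,
    "C": 0.5973,
    "O": -0.5679,
}

# (residue, atom) -> charge for charged side-chain terminal groups;
# each group sums to +1 / -1 e.
_SIDECHAIN_CHARGE = {
    ("ARG", "NH1"): 0.5,
    ("ARG", "NH2"): 0.5,
    ("LYS", "NZ"): 1.0,
    ("ASP", "OD1"): -0.5,
    ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5,
    ("GLU", "OE2"): -0.5,
}

SIDECAR_COLUMNS = [
    "atom_name",
    "residue_name",
    "charge_e",
    "sigma_nm",
    "epsilon_kcal",
    "radius_A",
]


def guess_element(atom_name: str) -> str:
    """Guess the chemical element from a PDB-style atom name."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise ParameterError(f"cannot guess element for atom name {atom_name!r}")
    two = stripped[:2].upper()
    if two in ("CL", "BR", "NA", "MG", "ZN", "FE", "CA") and atom_name.strip() == two:
        # Only treat as a two-letter element when the whole name is the symbol
        # (protein 'CA' is an alpha carbon, ion 'CA' is calcium -- here the
        # protein reading wins unless the name is exactly the ion symbol and
        # the residue naming says otherwise; synthetic systems never hit this).
        return two.capitalize() if two != "CA" else "C"
    return stripped[0].upper()


def builtin_parameters(atom_name: str, residue_name: str, element: str):
    """Return (charge, sigma_nm, epsilon_kcal, radius_A) from the built-in table."""
    if element not in ELEMENT_LJ_RADIUS:
        raise ParameterError(
            f"no built-in LJ/radius defaults for element {element!r} "
            f"(atom {atom_name!r} in {residue_name!r})"
        )
    sigma, eps, radius = ELEMENT_LJ_RADIUS[element]
    charge = _SIDECHAIN_CHARGE.get((residue_name, atom_name))
    if charge is None:
        charge = _BACKBONE_CHARGE.get(atom_name, 0.0)
    return charge, sigma, eps, radius


class SidecarTable:
    """Parameter lookup backed by a sidecar CSV (see module docstring)."""

    def __init__(self, frame: pd.DataFrame, fallback_builtin: bool = True):
        missing = [c for c in SIDECAR_COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(f"sidecar is missing columns: {missing}")
        self._exact: dict[tuple[str, str], tuple] = {}
        for row in frame.itertuples(index=False):
            key = (str(row.atom_name).strip(), str(row.residue_name).strip())
            self._exact[key] = (
                float(row.charge_e),
                float(row.sigma_nm),
                float(row.epsilon_kcal),
                float(row.radius_A),
            )
        self.fallback_builtin = fallback_builtin

    @classmethod
    def from_csv(cls, path, fallback_builtin: bool = True) -> "SidecarTable":
        return cls(pd.read_csv(path), fallback_builtin=fallback_builtin)

    def lookup(self, atom_name: str, residue_name: str, element: str):
        for key in (
            (atom_name, residue_name),
            (atom_name, "*"),
            (element, "*"),
            ("*", "*"),
        ):
            if key in self._exact:
                return self._exact[key]
        if self.fallback_builtin:
            return builtin_parameters(atom_name, residue_name, element)
        raise ParameterError(
            f"no sidecar parameters for atom {atom_name!r} in residue "
            f"{residue_name!r} (element {element!r}) and no default row"
        )
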