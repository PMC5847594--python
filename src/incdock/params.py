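"""Force-field parameters and amino-acid residue templates.

The scoring machinery follows the AutoDock-4 family of semi-empirical
free-energy force fields: a united-atom representation (nonpolar hydrogens
merged into their parent carbon, polar hydrogens explicit), pairwise 12-6
dispersion/repulsion, 12-10 hydrogen bonding between donor hydrogens and
acceptor heteroatoms, Coulomb electrostatics with a sigmoidal
distance-dependent dielectric, and a Gaussian-volume desolvation term.
Bit-exact parity with any external engine is not claimed; the tables below
are a self-contained parameter set in the same functional form.

Residue templates cover the 20 standard amino acids: heavy-atom topology,
polar-hydrogen attachment, per-atom partial charges (elementary charges;
each neutral residue template sums to 0, charged side chains to +/-1), and
aromatic-ring membership.
"""

from __future__ import annotations

import math

# ---------------------------------------------------------------------------
# Atom classes (united-atom convention)
# ---------------------------------------------------------------------------

CARBON_ALIPHATIC = "carbon_aliphatic"
CARBON_AROMATIC = "carbon_aromatic"
NITROGEN_ACCEPTOR = "nitrogen_acceptor"
NITROGEN_DONOR_H = "nitrogen_donor_H"
OXYGEN_ACCEPTOR = "oxygen_acceptor"
OXYGEN_DONOR_H = "oxygen_donor_H"
SULFUR = "sulfur"
POLAR_HYDROGEN = "polar_hydrogen"

ATOM_CLASSES = (
    CARBON_ALIPHATIC,
    CARBON_AROMATIC,
    NITROGEN_ACCEPTOR,
    NITROGEN_DONOR_H,
    OXYGEN_ACCEPTOR,
    OXYGEN_DONOR_H,
    SULFUR,
    POLAR_HYDROGEN,
)

#: heteroatom classes that can accept a hydrogen bond
ACCEPTOR_CLASSES = frozenset(
    {NITROGEN_ACCEPTOR, OXYGEN_ACCEPTOR, OXYGEN_DONOR_H}
)
#: classes counted as hydrogen-bond capable when ranking fragment roots
HBOND_CAPABLE_CLASSES = frozenset(
    {NITROGEN_ACCEPTOR, NITROGEN_DONOR_H, OXYGEN_ACCEPTOR, OXYGEN_DONOR_H}
)

# ---------------------------------------------------------------------------
# Free-energy weights (dimensionless multipliers on each term)
# ---------------------------------------------------------------------------

W_VDW = 0.1662
W_HBOND = 0.1209
W_ELEC = 0.1406
W_DESOLV = 0.1322
#: torsional entropy penalty per active rotatable bond, kcal/mol
W_TORSION = 0.2983

#: Coulomb constant for q in elementary charges, r in A, E in kcal/mol
COULOMB_K = 332.0637

#: Gaussian width of the desolvation kernel, A
DESOLV_SIGMA = 3.6
#: charge-dependent addition to the atomic solvation parameter, 1/A^3 per e
QASP = 0.01097

#: nonbonded interaction cutoff, A
NB_CUTOFF = 8.0
#: half-width of the pairwise potential smoothing window, A: within
#: +/- this of the equilibrium distance the 12-6/12-10 wells are flat,
#: which widens basins of attraction without moving their minima
SMOOTH_HALF = 0.25
#: pairwise energies are clamped at this value (repulsive wall stays finite)
ENERGY_CLAMP = 1.0e5

# ---------------------------------------------------------------------------
# Per-class van der Waals / solvation parameters
# (Rii: sum of radii at the pair minimum for a like pair, A;
#  epsii: well depth, kcal/mol; vol: atomic volume, A^3;
#  solpar: atomic solvation parameter, kcal/(mol A^3))
# ---------------------------------------------------------------------------

VDW_PARAMS: dict[str, tuple[float, float]] = {
    CARBON_ALIPHATIC: (4.00, 0.150),
    CARBON_AROMATIC: (4.00, 0.150),
    NITROGEN_ACCEPTOR: (3.50, 0.160),
    NITROGEN_DONOR_H: (3.50, 0.160),
    OXYGEN_ACCEPTOR: (3.20, 0.200),
    OXYGEN_DONOR_H: (3.20, 0.200),
    SULFUR: (4.00, 0.200),
    POLAR_HYDROGEN: (2.00, 0.020),
}

SOLV_PARAMS: dict[str, tuple[float, float]] = {
    CARBON_ALIPHATIC: (33.51, -0.00143),
    CARBON_AROMATIC: (33.51, -0.00052),
    NITROGEN_ACCEPTOR: (22.45, -0.00162),
    NITROGEN_DONOR_H: (22.45, -0.00162),
    OXYGEN_ACCEPTOR: (17.15, -0.00251),
    OXYGEN_DONOR_H: (17.15, -0.00251),
    SULFUR: (33.51, -0.00214),
    POLAR_HYDROGEN: (0.0, 0.00051),
}

#: 12-10 hydrogen-bond well: equilibrium distance (A) and depth (kcal/mol)
HBOND_R = 1.90
HBOND_EPS = 5.0


def is_hbond_pair(class_a: str, class_b: str) -> bool:
    """True when the pair interacts through the 12-10 hydrogen-bond well.

    One partner must be a polar (donor) hydrogen and the other an acceptor
    heteroatom.
    """
    return (class_a == POLAR_HYDROGEN and class_b in ACCEPTOR_CLASSES) or (
        class_b == POLAR_HYDROGEN and class_a in ACCEPTOR_CLASSES
    )


def effective_pair_params(class_a: str, class_b: str) -> tuple[float, float, bool]:
    """Effective pair potential parameters used verbatim by the scorer.

    Returns ``(r_eq, eps_eff, hbond)`` where ``eps_eff`` already includes the
    free-energy weight of the corresponding term, so the pair energy at the
    equilibrium separation is exactly ``-eps_eff``.
    """
    if is_hbond_pair(class_a, class_b):
        return HBOND_R, HBOND_EPS * W_HBOND, True
    ra, ea = VDW_PARAMS[class_a]
    rb, eb = VDW_PARAMS[class_b]
    return 0.5 * (ra + rb), math.sqrt(ea * eb) * W_VDW, False


# Mehler-Solmajer sigmoidal distance-dependent dielectric
_MS_A = -8.5525
_MS_B = 78.4 - _MS_A
_MS_LAMBDA = 0.003627
_MS_K = 7.7839


def dielectric(r):
    """Sigmoidal distance-dependent dielectric epsilon(r) (r in A)."""
    import numpy as np

    return _MS_A + _MS_B / (1.0 + _MS_K * np.exp(-_MS_LAMBDA * _MS_B * r))


# ---------------------------------------------------------------------------
# Residue templates
# ---------------------------------------------------------------------------

BACKBONE_HEAVY = ("N", "CA", "C", "O")
BACKBONE_BONDS = (("N", "CA"), ("CA", "C"), ("C", "O"))
# charges: internal residue; each neutral template sums to exactly 0
BACKBONE_CHARGES = {"N": -0.35, "H": 0.25, "CA": 0.10, "C": 0.55, "O": -0.55}
# N-terminal replacement (adds +1 overall)
NTERM_CHARGES = {"N": -0.30, "H1": 0.35, "H2": 0.35, "H3": 0.35, "CA": 0.25}
# C-terminal replacement (adds -1 overall)
CTERM_CHARGES = {"C": 0.40, "O": -0.70, "OXT": -0.70}

# side chain tables: heavy atom names, bonds (incl. CA attachment), polar
# hydrogens {H name: parent}, charges (atoms absent from the dict are 0),
# aromatic atom-name set, ring bonds are detected from the graph
_SC = {
    "ALA": dict(heavy=["CB"], bonds=[("CA", "CB")], polar_h={}, charges={}, arom=[]),
    "ARG": dict(
        heavy=["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
        bonds=[("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"),
               ("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2")],
        polar_h={"HE": "NE", "HH11": "NH1", "HH12": "NH1",
                 "HH21": "NH2", "HH22": "NH2"},
        charges={"CD": 0.20, "NE": -0.40, "HE": 0.30, "CZ": 0.50,
                 "NH1": -0.40, "NH2": -0.40, "HH11": 0.30, "HH12": 0.30,
                 "HH21": 0.30, "HH22": 0.30},
        arom=[],
    ),
    "ASN": dict(
        heavy=["CB", "CG", "OD1", "ND2"],
        bonds=[("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")],
        polar_h={"HD21": "ND2", "HD22": "ND2"},
        charges={"CG": 0.55, "OD1": -0.55, "ND2": -0.60,
                 "HD21": 0.30, "HD22": 0.30},
        arom=[],
    ),
    "ASP": dict(
        heavy=["CB", "CG", "OD1", "OD2"],
        bonds=[("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
        polar_h={},
        charges={"CB": -0.10, "CG": 0.30, "OD1": -0.60, "OD2": -0.60},
        arom=[],
    ),
    "CYS": dict(
        heavy=["CB", "SG"],
        bonds=[("CA", "CB"), ("CB", "SG")],
        polar_h={"HG": "SG"},
        charges={"CB": 0.10, "SG": -0.30, "HG": 0.20},
        arom=[],
    ),
    "GLN": dict(
        heavy=["CB", "CG", "CD", "OE1", "NE2"],
        bonds=[("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
               ("CD", "NE2")],
        polar_h={"HE21": "NE2", "HE22": "NE2"},
        charges={"CD": 0.55, "OE1": -0.55, "NE2": -0.60,
                 "HE21": 0.30, "HE22": 0.30},
        arom=[],
    ),
    "GLU": dict(
        heavy=["CB", "CG", "CD", "OE1", "OE2"],
        bonds=[("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
               ("CD", "OE2")],
        polar_h={},
        charges={"CG": -0.10, "CD": 0.30, "OE1": -0.60, "OE2": -0.60},
        arom=[],
    ),
    "GLY": dict(heavy=[], bonds=[], polar_h={}, charges={}, arom=[]),
    "HIS": dict(  # neutral, NE2-H tautomer: ND1 acceptor, NE2 donor
        heavy=["CB", "CG", "ND1", "CD2", "CE1", "NE2"],
        bonds=[("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"),
               ("ND1", "CE1"), ("CD2", "NE2"), ("CE1", "NE2")],
        polar_h={"HE2": "NE2"},
        charges={"CG": 0.10, "ND1": -0.40, "CD2": 0.09, "CE1": 0.25,
                 "NE2": -0.36, "HE2": 0.32},
        arom=["CG", "ND1", "CD2", "CE1", "NE2"],
    ),
    "ILE": dict(
        heavy=["CB", "CG1", "CG2", "CD1"],
        bonds=[("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
        polar_h={}, charges={}, arom=[],
    ),
    "LEU": dict(
        heavy=["CB", "CG", "CD1", "CD2"],
        bonds=[("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
        polar_h={}, charges={}, arom=[],
    ),
    "LYS": dict(
        heavy=["CB", "CG", "CD", "CE", "NZ"],
        bonds=[("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"),
               ("CE", "NZ")],
        polar_h={"HZ1": "NZ", "HZ2": "NZ", "HZ3": "NZ"},
        charges={"CE": 0.25, "NZ": -0.30, "HZ1": 0.35, "HZ2": 0.35,
                 "HZ3": 0.35},
        arom=[],
    ),
    "MET": dict(
        heavy=["CB", "CG", "SD", "CE"],
        bonds=[("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
        polar_h={},
        charges={"CG": 0.06, "SD": -0.12, "CE": 0.06},
        arom=[],
    ),
    "PHE": dict(
        heavy=["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
        bonds=[("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
               ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")],
        polar_h={}, charges={},
        arom=["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    ),
    "PRO": dict(
        heavy=["CB", "CG", "CD"],
        bonds=[("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")],
        polar_h={}, charges={}, arom=[],
    ),
    "SER": dict(
        heavy=["CB", "OG"],
        bonds=[("CA", "CB"), ("CB", "OG")],
        polar_h={"HG": "OG"},
        charges={"CB": 0.15, "OG": -0.55, "HG": 0.40},
        arom=[],
    ),
    "THR": dict(
        heavy=["CB", "OG1", "CG2"],
        bonds=[("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")],
        polar_h={"HG1": "OG1"},
        charges={"CB": 0.15, "OG1": -0.55, "HG1": 0.40},
        arom=[],
    ),
    "TRP": dict(
        heavy=["CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3",
               "CH2"],
        bonds=[("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
               ("CD1", "NE1"), ("NE1", "CE2"), ("CD2", "CE2"),
               ("CD2", "CE3"), ("CE2", "CZ2"), ("CE3", "CZ3"),
               ("CZ2", "CH2"), ("CZ3", "CH2")],
        polar_h={"HE1": "NE1"},
        charges={"CD1": 0.06, "NE1": -0.35, "HE1": 0.25, "CE2": 0.04},
        arom=["CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    ),
    "TYR": dict(
        heavy=["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
        bonds=[("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
               ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"),
               ("CZ", "OH")],
        polar_h={"HH": "OH"},
        charges={"CZ": 0.15, "OH": -0.55, "HH": 0.40},
        arom=["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    ),
    "VAL": dict(
        heavy=["CB", "CG1", "CG2"],
        bonds=[("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")],
        polar_h={}, charges={}, arom=[],
    ),
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})


class ResidueTemplate:
    """Topology, charges and typing for one standard residue."""

    def __init__(self, name: str, sc: dict):
        self.name = name
        self.heavy = list(BACKBONE_HEAVY) + list(sc["heavy"])
        self.bonds = [tuple(b) for b in BACKBONE_BONDS] + [
            tuple(b) for b in sc["bonds"]
        ]
        self.polar_h = dict(sc["polar_h"])
        if name != "PRO":
            self.polar_h["H"] = "N"  # backbone amide hydrogen
        self.charges = dict(BACKBONE_CHARGES)
        if name == "PRO":  # no amide H; keep the template neutral
            del self.charges["H"]
            self.charges["N"] = -0.10
        self.charges.update(sc["charges"])
        self.aromatic = frozenset(sc["arom"])

    def charge_of(self, atom_name: str, nterm: bool = False,
                  cterm: bool = False) -> float:
        if nterm and atom_name in NTERM_CHARGES:
            return NTERM_CHARGES[atom_name]
        if cterm and atom_name in CTERM_CHARGES:
            return CTERM_CHARGES[atom_name]
        if atom_name == "OXT":
            return CTERM_CHARGES["OXT"]
        return self.charges.get(atom_name, 0.0)

    def net_charge(self) -> float:
        """Net charge of the internal-residue template."""
        return sum(self.charges.values())


RESIDUE_TEMPLATES: dict[str, ResidueTemplate] = {
    name: ResidueTemplate(name, sc) for name, sc in _SC.items()
}


def element_of(atom_name: str) -> str:
    """Chemical element from a PDB atom name (peptide atoms only)."""
    stripped = atom_name.strip()
    if not stripped:
        raise ValueError("empty atom name")
    first = stripped[0]
    if first.isdigit():  # e.g. hydrogen names like 1HB
        first = stripped[1]
    return first.upper()


def classify_atom(residue_name: str, atom_name: str,
                  has_polar_h: bool) -> str:
    """Assign the united-atom class for one template atom."""
    tmpl = RESIDUE_TEMPLATES[residue_name]
    elem = element_of(atom_name)
    if elem == "H":
        return POLAR_HYDROGEN
    if elem == "C":
        return CARBON_AROMATIC if atom_name in tmpl.aromatic else CARBON_ALIPHATIC
    if elem == "N":
        return NITROGEN_DONOR_H if has_polar_h else NITROGEN_ACCEPTOR
    if elem == "O":
        return OXYGEN_DONOR_H if has_polar_h else OXYGEN_ACCEPTOR
    if elem == "S":
        return SULFUR
    raise KeyError(f"no parameters for element {elem!r} ({residue_name}/{atom_name})")
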