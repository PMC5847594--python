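"""Reading, filtering, typing and writing of peptide/protein structures.

PDB parsing and serialization are delegated to :mod:`gemmi`; this module
adds the preprocessing rules used when preparing re-docking inputs from
crystal structures (water removal, occupancy-based alternate-location
selection, first-copy selection for crystals with several complexes per
asymmetric unit), template-based bond perception, and united-atom typing
with partial charges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import gemmi
import networkx as nx
import numpy as np

from . import params
from .params import RESIDUE_TEMPLATES, WATER_NAMES

PEPTIDE_BOND_CUTOFF = 1.7  # A, C(i)-N(i+1)
#: synthetic groove pseudo-residues (single-atom sites, no template)
PSEUDO_RESIDUES = frozenset({"GRV"})
_H_BOND_LENGTH = {"N": 1.01, "O": 0.96, "S": 1.34}


class PDBError(ValueError):
    """Malformed or unusable PDB input."""


class TypingError(ValueError):
    """A residue or element without template parameters."""


class SelectionError(ValueError):
    """A ligand selector that matches nothing."""


@dataclass
class PreprocessOptions:
    """Filters applied while reading a crystal structure.

    remove_waters: drop HOH/WAT residues (they are not scored).
    altloc_best_occupancy: for alternate side-chain locations keep only the
        highest-occupancy set (alphabetical altloc wins ties).
    first_copy_only: when several copies of the complex share one
        asymmetric unit, keep only the first chain set in file order.
    """

    remove_waters: bool = True
    altloc_best_occupancy: bool = True
    first_copy_only: bool = True


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    partial_charge: float = 0.0
    atom_class: str | None = None

    def copy(self) -> "Atom":
        return replace(self, position=np.array(self.position, dtype=float))


@dataclass
class TypedMolecule:
    """An ordered atom list plus a covalent bond graph."""

    atoms: list[Atom]
    bonds: set[frozenset[int]] = field(default_factory=set)
    role: str = "ligand"  # "receptor" | "ligand"

    # -- conveniences -------------------------------------------------
    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for atom, xyz in zip(self.atoms, coords):
            atom.position = np.array(xyz, dtype=float)

    def serial_index(self) -> dict[int, int]:
        return {a.serial: i for i, a in enumerate(self.atoms)}

    def atom_by_serial(self, serial: int) -> Atom:
        for a in self.atoms:
            if a.serial == serial:
                return a
        raise KeyError(serial)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(a.serial for a in self.atoms)
        g.add_edges_from(tuple(b) for b in self.bonds)
        return g

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element != "H"]

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, residue_seq, residue_name) triples."""
        seen: list[tuple[str, int, str]] = []
        for a in self.atoms:
            key = (a.chain_id, a.residue_seq, a.residue_name)
            if not seen or seen[-1] != key:
                if key not in seen:
                    seen.append(key)
        return seen

    def sequence(self) -> str:
        return "".join(
            params.THREE_TO_ONE.get(name, "X") for _, _, name in self.residues()
        )

    def neighbors(self, serial: int) -> list[int]:
        out = []
        for b in self.bonds:
            pair = tuple(b)
            if pair[0] == serial:
                out.append(pair[1])
            elif pair[1] == serial:
                out.append(pair[0])
        return sorted(out)

    def copy(self) -> "TypedMolecule":
        return TypedMolecule(
            atoms=[a.copy() for a in self.atoms],
            bonds=set(self.bonds),
            role=self.role,
        )


@dataclass
class ComplexStructure:
    receptor: TypedMolecule
    ligand: TypedMolecule
    source_id: str = ""


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _filter_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep the highest-occupancy alternate-location set of a residue."""
    groups: dict[str, list[gemmi.Atom]] = {}
    plain: list[gemmi.Atom] = []
    for atom in residue:
        if atom.altloc and atom.altloc != "\x00":
            groups.setdefault(atom.altloc, []).append(atom)
        else:
            plain.append(atom)
    if not groups:
        return plain
    # highest mean occupancy wins; alphabetical altloc breaks ties
    def rank(item):
        alt, atoms = item
        occ = sum(a.occ for a in atoms) / len(atoms)
        return (-occ, alt)

    best_alt = sorted(groups.items(), key=rank)[0][0]
    return plain + groups[best_alt]


def read_pdb(text: str, options: PreprocessOptions | None = None) -> list[TypedMolecule]:
    """Parse PDB text into one molecule per chain, applying input filters.

    Bonds are perceived from residue templates plus inter-residue peptide
    (C-N) bonds closer than 1.7 A. Raises :class:`PDBError` on empty input
    and :class:`TypingError` for residues without a template.
    """
    options = options or PreprocessOptions()
    structure = gemmi.read_pdb_string(text)
    if len(structure) == 0:
        raise PDBError("no models in PDB input")
    model = structure[0]  # later models are additional copies by definition

    molecules: list[TypedMolecule] = []
    seen_sequences: set[tuple[str, ...]] = set()
    serial = 0
    for chain in model:
        residues = []
        for residue in chain:
            if options.remove_waters and residue.name in WATER_NAMES:
                continue
            residues.append(residue)
        if not residues:
            continue
        signature = tuple(r.name for r in residues)
        if options.first_copy_only and signature in seen_sequences:
            continue
        seen_sequences.add(signature)

        atoms: list[Atom] = []
        for residue in residues:
            if (residue.name not in RESIDUE_TEMPLATES
                    and residue.name not in PSEUDO_RESIDUES
                    and residue.name not in WATER_NAMES):
                raise TypingError(
                    f"no residue template for {residue.name!r} "
                    f"(chain {chain.name}, residue {residue.seqid.num})"
                )
            ratoms = (
                _filter_altlocs(residue)
                if options.altloc_best_occupancy
                else list(residue)
            )
            for atom in ratoms:
                serial += 1
                atoms.append(
                    Atom(
                        serial=atom.serial if atom.serial > 0 else serial,
                        name=atom.name,
                        element=atom.element.name.upper() or params.element_of(atom.name),
                        residue_name=residue.name,
                        residue_seq=residue.seqid.num,
                        chain_id=chain.name,
                        position=np.array(
                            [atom.pos.x, atom.pos.y, atom.pos.z], dtype=float
                        ),
                        occupancy=atom.occ,
                        altloc="" if atom.altloc in ("", "\x00") else atom.altloc,
                    )
                )
        mol = TypedMolecule(atoms=atoms, bonds=set())
        _perceive_bonds(mol)
        molecules.append(mol)

    if not molecules:
        raise PDBError("no ATOM/HETATM records after filtering")
    return molecules


def _perceive_bonds(mol: TypedMolecule) -> None:
    """Template bonds inside residues + distance-based peptide bonds."""
    by_residue: dict[tuple[str, int], dict[str, Atom]] = {}
    for a in mol.atoms:
        by_residue.setdefault((a.chain_id, a.residue_seq), {})[a.name] = a

    for (chain, seq), atoms in by_residue.items():
        name = next(iter(atoms.values())).residue_name
        if name in PSEUDO_RESIDUES or name in WATER_NAMES:
            continue
        tmpl = RESIDUE_TEMPLATES[name]
        for x, y in tmpl.bonds:
            if x in atoms and y in atoms:
                mol.bonds.add(frozenset({atoms[x].serial, atoms[y].serial}))
        # hydrogens present in the input: bond to their template parent
        for hname, parent in tmpl.polar_h.items():
            if hname in atoms and parent in atoms:
                mol.bonds.add(frozenset({atoms[hname].serial, atoms[parent].serial}))
        for hname in ("H1", "H2", "H3"):
            if hname in atoms and "N" in atoms:
                mol.bonds.add(frozenset({atoms[hname].serial, atoms["N"].serial}))
        if "OXT" in atoms and "C" in atoms:
            mol.bonds.add(frozenset({atoms["OXT"].serial, atoms["C"].serial}))

    # peptide bonds: C of one residue to N of another, < 1.7 A
    carbons = [a for a in mol.atoms if a.name == "C"]
    nitrogens = [a for a in mol.atoms if a.name == "N"]
    for c in carbons:
        for n in nitrogens:
            if (c.chain_id, c.residue_seq) == (n.chain_id, n.residue_seq):
                continue
            if float(np.linalg.norm(c.position - n.position)) < PEPTIDE_BOND_CUTOFF:
                mol.bonds.add(frozenset({c.serial, n.serial}))


# ---------------------------------------------------------------------------
# Complex splitting
# ---------------------------------------------------------------------------

def merge(molecules: list[TypedMolecule], role: str = "receptor") -> TypedMolecule:
    """Combine molecules; colliding atom serials are renumbered."""
    out = TypedMolecule(atoms=[], bonds=set(), role=role)
    used: set[int] = set()
    for mol in molecules:
        remap: dict[int, int] = {}
        next_serial = max(used, default=0)
        for a in mol.atoms:
            atom = a.copy()
            if atom.serial in used:
                next_serial = max(next_serial, max(used)) + 1
                remap[a.serial] = next_serial
                atom.serial = next_serial
            used.add(atom.serial)
            out.atoms.append(atom)
        for bond in mol.bonds:
            x, y = tuple(bond)
            out.bonds.add(frozenset({remap.get(x, x), remap.get(y, y)}))
    return out


def split_complex(
    molecules: list[TypedMolecule] | TypedMolecule,
    ligand_selector: str | tuple[int, int],
) -> tuple[TypedMolecule, TypedMolecule]:
    """Split a parsed complex into (receptor, ligand).

    The selector is either a chain id or an inclusive ``(first, last)``
    residue-number range. The union of the two outputs is exactly the input
    atom set.
    """
    if isinstance(molecules, TypedMolecule):
        molecules = [molecules]
    whole = merge(molecules)

    if isinstance(ligand_selector, str):
        picked = {a.serial for a in whole.atoms if a.chain_id == ligand_selector}
    else:
        lo, hi = ligand_selector
        picked = {
            a.serial for a in whole.atoms if lo <= a.residue_seq <= hi
        }
    if not picked:
        raise SelectionError(f"ligand selector {ligand_selector!r} matches no atoms")

    ligand = TypedMolecule(
        atoms=[a.copy() for a in whole.atoms if a.serial in picked],
        bonds={b for b in whole.bonds if set(b) <= picked},
        role="ligand",
    )
    receptor = TypedMolecule(
        atoms=[a.copy() for a in whole.atoms if a.serial not in picked],
        bonds={b for b in whole.bonds if not (set(b) & picked)},
        role="receptor",
    )
    n_res = len({(a.chain_id, a.residue_seq) for a in ligand.atoms})
    if n_res < 2:
        raise SelectionError(
            f"ligand selector {ligand_selector!r} selects {n_res} residue(s); "
            "a peptide of >= 2 residues is required"
        )
    return receptor, ligand


# ---------------------------------------------------------------------------
# Typing, charges, united-atom hydrogens
# ---------------------------------------------------------------------------

def _residue_groups(mol: TypedMolecule):
    groups: dict[tuple[str, int], list[Atom]] = {}
    for a in mol.atoms:
        groups.setdefault((a.chain_id, a.residue_seq), []).append(a)
    return groups


def _terminal_flags(mol: TypedMolecule):
    """Which residues are chain N-/C-terminal (by residue numbering)."""
    groups = _residue_groups(mol)
    by_chain: dict[str, list[int]] = {}
    for chain, seq in groups:
        by_chain.setdefault(chain, []).append(seq)
    flags = {}
    for key in groups:
        chain, seq = key
        seqs = by_chain[chain]
        flags[key] = (seq == min(seqs), seq == max(seqs))
    return flags


def _ideal_hydrogens(parent: Atom, neighbor_pos: list[np.ndarray],
                     count: int) -> list[np.ndarray]:
    """Place ``count`` hydrogens on ``parent`` with ideal geometry."""
    length = _H_BOND_LENGTH.get(parent.element, 1.0)
    p = parent.position
    if not neighbor_pos:
        dirs = [np.array([1.0, 0.0, 0.0])]
        return [p + length * d for d in dirs[:count]]
    if len(neighbor_pos) >= 2 and count == 1:
        # bisector rule (e.g. backbone amide H)
        u = np.zeros(3)
        for q in neighbor_pos:
            v = p - q
            u += v / np.linalg.norm(v)
        norm = np.linalg.norm(u)
        if norm < 1e-9:
            u = np.array([1.0, 0.0, 0.0]); norm = 1.0
        return [p + length * u / norm]
    # one heavy neighbor: cone at the ideal valence angle
    d = p - neighbor_pos[0]
    d /= np.linalg.norm(d)
    # sp2 for a single in-plane pair (amide NH2), sp3 otherwise
    theta = math.radians(120.0) if count == 2 else math.radians(109.5)
    axes = np.eye(3)
    ref = axes[int(np.argmin(np.abs(d)))]
    e1 = np.cross(d, ref); e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    out = []
    for i in range(count):
        phi = 2.0 * math.pi * i / max(count, 1)
        h_dir = (
            math.cos(math.pi - theta) * (-d)
            + math.sin(math.pi - theta)
            * (math.cos(phi) * e1 + math.sin(phi) * e2)
        )
        # angle(h_dir, -d) = pi - theta so angle(h_dir, d) = theta
        out.append(p + length * h_dir / np.linalg.norm(h_dir))
    return out


def assign_types_and_charges(mol: TypedMolecule) -> TypedMolecule:
    """Return a united-atom typed copy of ``mol``.

    Nonpolar hydrogens are merged into their parent carbons, missing polar
    hydrogens are constructed with ideal geometry, and every atom receives
    an atom class and a template partial charge. Terminal residues get
    charged-terminus (NH3+/COO-) charge sets when the corresponding atoms
    (H1..H3, OXT) are present or buildable.
    """
    mol = mol.copy()
    flags = _terminal_flags(mol)
    groups = _residue_groups(mol)
    max_serial = max((a.serial for a in mol.atoms), default=0)

    new_atoms: list[Atom] = []
    new_bonds: set[frozenset[int]] = set()
    drop: set[int] = set()

    # drop nonpolar hydrogens (united-atom merge)
    serial_to_atom = {a.serial: a for a in mol.atoms}
    for a in mol.atoms:
        if a.element != "H":
            continue
        tmpl = RESIDUE_TEMPLATES.get(a.residue_name)
        if tmpl is None:
            raise TypingError(f"no residue template for {a.residue_name!r}")
        polar_names = set(tmpl.polar_h) | {"H1", "H2", "H3"}
        if a.name.strip() not in polar_names:
            drop.add(a.serial)

    for key, atoms in groups.items():
        nterm, cterm = flags[key]
        name = atoms[0].residue_name
        tmpl = RESIDUE_TEMPLATES[name]
        present = {a.name: a for a in atoms if a.serial not in drop}
        heavy_graph_pos = {
            a.name: a.position for a in atoms if a.element != "H"
        }

        wanted_h: list[tuple[str, str]] = []
        if nterm and name != "PRO":
            wanted_h.extend([("H1", "N"), ("H2", "N"), ("H3", "N")])
        elif name != "PRO":
            wanted_h.append(("H", "N"))
        for hname, parent in tmpl.polar_h.items():
            if hname != "H":
                wanted_h.append((hname, parent))
        if nterm and ("H" in present):
            drop.add(present["H"].serial)  # replaced by the NH3+ set
            del present["H"]

        # group missing hydrogens by parent so multi-H sets get a tripod
        missing_by_parent: dict[str, list[str]] = {}
        for hname, parent in wanted_h:
            if hname not in present and parent in present:
                missing_by_parent.setdefault(parent, []).append(hname)
        for parent_name, hnames in missing_by_parent.items():
            parent = present[parent_name]
            neigh = [
                serial_to_atom[s].position
                for s in mol.neighbors(parent.serial)
                if serial_to_atom[s].element != "H"
                and serial_to_atom[s].serial not in drop
            ]
            positions = _ideal_hydrogens(parent, neigh, len(hnames))
            for hname, pos in zip(hnames, positions):
                max_serial += 1
                h = Atom(
                    serial=max_serial, name=hname, element="H",
                    residue_name=name, residue_seq=atoms[0].residue_seq,
                    chain_id=atoms[0].chain_id, position=pos,
                )
                present[hname] = h
                mol.bonds.add(frozenset({h.serial, parent.serial}))
                serial_to_atom[h.serial] = h

        # typing + charges
        h_parents = {parent for _, parent in wanted_h}
        for atom in present.values():
            if atom.element == "H":
                atom.atom_class = params.POLAR_HYDROGEN
            else:
                has_h = atom.name in h_parents and any(
                    h in present for h, par in wanted_h if par == atom.name
                )
                atom.atom_class = params.classify_atom(name, atom.name, has_h)
            atom.partial_charge = tmpl.charge_of(atom.name, nterm, cterm)
        new_atoms.extend(
            sorted(present.values(), key=lambda a: a.serial)
        )

    keep = {a.serial for a in new_atoms}
    new_bonds = {b for b in mol.bonds if set(b) <= keep}
    order = {a.serial: i for i, a in enumerate(mol.atoms)}
    new_atoms.sort(key=lambda a: order.get(a.serial, 10**9 + a.serial))
    return TypedMolecule(atoms=new_atoms, bonds=new_bonds, role=mol.role)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_pdb(obj: TypedMolecule | ComplexStructure) -> str:
    """Serialize a molecule or complex back to PDB text (via gemmi)."""
    if isinstance(obj, ComplexStructure):
        mol = merge([obj.receptor, obj.ligand])
    else:
        mol = obj
    for a in mol.atoms:
        if not np.all(np.isfinite(a.position)):
            raise PDBError(f"non-finite coordinates on atom serial {a.serial}")
        if len(a.name.strip()) > 4:
            raise PDBError(f"atom name {a.name!r} exceeds the PDB field width")
        if a.serial > 99999:
            raise PDBError("atom serial exceeds the PDB field width")

    structure = gemmi.Structure()
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for a in mol.atoms:
        chain = chains.get(a.chain_id)
        if chain is None:
            chain = gemmi.Chain(a.chain_id or "A")
            chains[a.chain_id] = chain
        if (
            len(chain) == 0
            or chain[-1].seqid.num != a.residue_seq
            or chain[-1].name != a.residue_name
        ):
            residue = gemmi.Residue()
            residue.name = a.residue_name
            residue.seqid = gemmi.SeqId(a.residue_seq, " ")
            chain.add_residue(residue)
        atom = gemmi.Atom()
        atom.name = a.name
        atom.element = gemmi.Element(a.element)
        atom.pos = gemmi.Position(*[float(x) for x in a.position])
        atom.occ = a.occupancy
        atom.serial = a.serial
        chain[-1].add_atom(atom)
    for chain in chains.values():
        model.add_chain(chain)
    structure.add_model(model)
    structure.setup_entities()
    return structure.make_pdb_string()


def write_models_pdb(mols: list[TypedMolecule]) -> str:
    """Serialize several conformations of one molecule as MODEL blocks."""
    blocks = []
    for i, mol in enumerate(mols, start=1):
        body = "\n".join(
            line
            for line in write_pdb(mol).splitlines()
            if line.startswith(("ATOM", "HETATM", "TER"))
        )
        blocks.append(f"MODEL     {i:>4}\n{body}\nENDMDL")
    return "\n".join(blocks) + "\nEND\n"
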