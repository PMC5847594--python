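"""Torsion-tree decomposition of a peptide ligand and pose reconstruction.

A flexible ligand is decomposed into rigid groups connected by rotatable
bonds. A bond is rotatable iff it is a single acyclic bond between two
heavy atoms, each of which is bonded to at least one further heavy atom or
polar hydrogen; amide (peptide and side-chain amide) C-N bonds, guanidinium
bonds and ring bonds are rigid. Torsions that would move only nonpolar
hydrogens cannot occur because the molecules are united-atom. Hydroxyl,
thiol and terminal-ammonium torsions (moving only polar hydrogens) are
rotatable: they carry hydrogen-bond geometry.

A :class:`Pose` is (translation, orientation quaternion, torsion vector);
torsions are deltas relative to the reference conformation, right-hand rule
about the parent->child bond axis, stored in (-pi, pi].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from numba import njit
from scipy.spatial.transform import Rotation

from .structio import TypedMolecule


class TopologyError(ValueError):
    """Ligand bond graph unusable for torsion-tree construction."""


@dataclass
class Pose:
    translation: np.ndarray
    orientation: np.ndarray  # quaternion, scipy (x, y, z, w) order
    torsions: np.ndarray

    def __post_init__(self):
        self.translation = np.asarray(self.translation, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        self.torsions = np.asarray(self.torsions, dtype=float)
        norm = float(np.linalg.norm(self.orientation))
        if abs(norm - 1.0) > 1e-9:
            if norm == 0.0:
                raise ValueError("zero quaternion")
            self.orientation = self.orientation / norm

    @classmethod
    def identity(cls, n_torsions: int) -> "Pose":
        return cls(np.zeros(3), np.array([0.0, 0.0, 0.0, 1.0]),
                   np.zeros(n_torsions))

    def copy(self) -> "Pose":
        return Pose(self.translation.copy(), self.orientation.copy(),
                    self.torsions.copy())


@dataclass
class TorsionTree:
    """Rigid-group decomposition rooted at ``root_atom``.

    ``rotatable_bonds`` are (parent_serial, child_serial) pairs oriented
    away from the root and ordered breadth-first from the root group (ties
    broken by child atom serial): index ``k`` is DoF ``k``.
    """

    root_atom: int
    atom_serials: tuple[int, ...]
    rigid_groups: list[frozenset[int]]
    rotatable_bonds: list[tuple[int, int]]
    #: tree edges over group indices, parallel to rotatable_bonds
    group_edges: list[tuple[int, int]] = field(default_factory=list)
    #: per-DoF array of atom indices (into atom_serials) moved by the DoF
    downstream: list[np.ndarray] = field(default_factory=list)
    #: BFS depth of each DoF (number of tree edges from the root group)
    dof_depth: list[int] = field(default_factory=list)

    @property
    def n_dofs(self) -> int:
        return len(self.rotatable_bonds)

    @property
    def index_of(self) -> dict[int, int]:
        return {s: i for i, s in enumerate(self.atom_serials)}

    def group_of(self, serial: int) -> int:
        for gi, group in enumerate(self.rigid_groups):
            if serial in group:
                return gi
        raise KeyError(serial)

    @property
    def root_group(self) -> frozenset[int]:
        return self.rigid_groups[self.group_of(self.root_atom)]


def _is_amide_like(graph: nx.Graph, elements: dict[int, str], a: int, b: int) -> bool:
    """C-N bonds of amide or guanidinium groups (held planar/rigid)."""
    for c, n in ((a, b), (b, a)):
        if elements[c] != "C" or elements[n] != "N":
            continue
        n_nitrogens = sum(
            1 for x in graph.neighbors(c) if elements[x] == "N"
        )
        if n_nitrogens >= 2:  # guanidinium carbon
            return True
        for x in graph.neighbors(c):
            if x == n or elements[x] != "O":
                continue
            # carbonyl / carboxylate oxygen: no heavy neighbor besides c
            others = [
                y for y in graph.neighbors(x) if y != c and elements[y] != "H"
            ]
            if not others:
                return True
    return False


def detect_rotatable_bonds(
    ligand: TypedMolecule, root: int | None = None
) -> TorsionTree:
    """Build the torsion tree of a typed ligand.

    ``root`` is an atom serial; when omitted the lowest-serial heavy atom
    is used (the fragmenter's root heuristics re-root the tree explicitly).
    """
    serials = tuple(a.serial for a in ligand.atoms)
    elements = {a.serial: a.element for a in ligand.atoms}
    graph = ligand.graph()
    if graph.number_of_nodes() and not nx.is_connected(graph):
        raise TopologyError("ligand bond graph is disconnected")

    heavy_graph = graph.subgraph(
        [s for s in serials if elements[s] != "H"]
    )
    ring_bonds: set[frozenset[int]] = set()
    for cycle in nx.cycle_basis(heavy_graph):
        for i in range(len(cycle)):
            ring_bonds.add(frozenset({cycle[i], cycle[(i + 1) % len(cycle)]}))

    rotatable: set[frozenset[int]] = set()
    for bond in ligand.bonds:
        a, b = tuple(bond)
        if elements[a] == "H" or elements[b] == "H":
            continue
        if bond in ring_bonds:
            continue
        if _is_amide_like(graph, elements, a, b):
            continue
        ok = True
        for end, other in ((a, b), (b, a)):
            # needs a substituent beyond the bond (heavy or polar hydrogen)
            if not any(x != other for x in graph.neighbors(end)):
                ok = False
        if ok:
            rotatable.add(bond)

    # rigid groups: connected components after removing rotatable bonds
    rigid_graph = graph.copy()
    rigid_graph.remove_edges_from(tuple(b) for b in rotatable)
    groups = [frozenset(c) for c in nx.connected_components(rigid_graph)]
    group_of = {s: gi for gi, grp in enumerate(groups) for s in grp}

    if root is None:
        root = min(s for s in serials if elements[s] != "H")
    if root not in group_of:
        raise TopologyError(f"root serial {root} not in ligand")

    # orient and order bonds breadth-first from the root group
    group_adj: dict[int, list[tuple[int, int, int]]] = {}
    for bond in rotatable:
        a, b = sorted(bond)
        ga, gb = group_of[a], group_of[b]
        group_adj.setdefault(ga, []).append((gb, a, b))
        group_adj.setdefault(gb, []).append((ga, b, a))

    ordered_bonds: list[tuple[int, int]] = []
    group_edges: list[tuple[int, int]] = []
    depths: list[int] = []
    root_gi = group_of[root]
    visited = {root_gi}
    frontier = [(root_gi, 0)]
    while frontier:
        gi, depth = frontier.pop(0)
        edges = sorted(group_adj.get(gi, []), key=lambda e: e[2])
        for gj, parent_atom, child_atom in edges:
            if gj in visited:
                continue
            visited.add(gj)
            ordered_bonds.append((parent_atom, child_atom))
            group_edges.append((gi, gj))
            depths.append(depth + 1)
            frontier.append((gj, depth + 1))
    if len(visited) != len(groups):
        raise TopologyError("torsion tree does not span all rigid groups")

    # downstream atom index arrays: atoms in the subtree past each bond
    index_of = {s: i for i, s in enumerate(serials)}
    children: dict[int, list[int]] = {}
    for k, (gi, gj) in enumerate(group_edges):
        children.setdefault(gi, []).append(k)
    downstream: list[np.ndarray] = [None] * len(ordered_bonds)  # type: ignore

    def collect(k: int) -> set[int]:
        gj = group_edges[k][1]
        atoms = set(groups[gj])
        for k2 in children.get(gj, []):
            atoms |= collect(k2)
        return atoms

    for k in range(len(ordered_bonds)):
        moved = collect(k)
        downstream[k] = np.array(
            sorted(index_of[s] for s in moved), dtype=int
        )

    return TorsionTree(
        root_atom=root,
        atom_serials=serials,
        rigid_groups=groups,
        rotatable_bonds=ordered_bonds,
        group_edges=group_edges,
        downstream=downstream,
        dof_depth=depths,
    )


def count_dofs(tree: TorsionTree) -> int:
    return len(tree.rotatable_bonds)


def apply_conformation(
    tree: TorsionTree, reference_coords: np.ndarray, pose: Pose
) -> np.ndarray:
    """Cartesian coordinates of the ligand under ``pose``.

    Torsions are applied root-to-leaves as delta rotations about the
    current bond axes; the whole ligand is then rotated about the root
    rigid group's reference centroid and translated. The identity pose
    reproduces ``reference_coords`` exactly.
    """
    reference_coords = np.asarray(reference_coords, dtype=float)
    if reference_coords.shape != (len(tree.atom_serials), 3):
        raise ValueError("reference coordinates do not cover all ligand atoms")
    if len(pose.torsions) != tree.n_dofs:
        raise ValueError(
            f"torsion vector length {len(pose.torsions)} != DoF count {tree.n_dofs}"
        )
    coords = reference_coords.copy()
    parent_idx, child_idx, ds_flat, ds_off, root_idx = _kernel_arrays(tree)
    if tree.n_dofs:
        _torsion_kernel(
            coords, parent_idx, child_idx,
            np.asarray(pose.torsions, dtype=float), ds_flat, ds_off,
        )
    center = reference_coords[root_idx].mean(axis=0)
    rot = Rotation.from_quat(pose.orientation)
    coords = (coords - center) @ rot.as_matrix().T + center + pose.translation
    return coords


@njit(cache=True)
def _torsion_kernel(coords, parent_idx, child_idx, thetas, ds_flat, ds_off):
    for k in range(len(thetas)):
        theta = thetas[k]
        if theta == 0.0:
            continue
        ox, oy, oz = coords[parent_idx[k]]
        ax = coords[child_idx[k], 0] - ox
        ay = coords[child_idx[k], 1] - oy
        az = coords[child_idx[k], 2] - oz
        norm = math.sqrt(ax * ax + ay * ay + az * az)
        if norm < 1e-12:
            continue
        ax /= norm; ay /= norm; az /= norm
        c = math.cos(theta)
        s = math.sin(theta)
        for j in range(ds_off[k], ds_off[k + 1]):
            i = ds_flat[j]
            vx = coords[i, 0] - ox
            vy = coords[i, 1] - oy
            vz = coords[i, 2] - oz
            dot = vx * ax + vy * ay + vz * az
            cx = ay * vz - az * vy
            cy = az * vx - ax * vz
            cz = ax * vy - ay * vx
            coords[i, 0] = ox + vx * c + cx * s + ax * dot * (1.0 - c)
            coords[i, 1] = oy + vy * c + cy * s + ay * dot * (1.0 - c)
            coords[i, 2] = oz + vz * c + cz * s + az * dot * (1.0 - c)


def _kernel_arrays(tree: TorsionTree):
    """Cached flat index arrays driving the torsion kernel."""
    cached = getattr(tree, "_kernel_arrays_cache", None)
    if cached is None:
        index_of = tree.index_of
        parent_idx = np.array(
            [index_of[pa] for pa, _ in tree.rotatable_bonds], dtype=np.int64
        )
        child_idx = np.array(
            [index_of[ca] for _, ca in tree.rotatable_bonds], dtype=np.int64
        )
        offsets = np.zeros(tree.n_dofs + 1, dtype=np.int64)
        flat: list[int] = []
        for k, idx in enumerate(tree.downstream):
            flat.extend(idx.tolist())
            offsets[k + 1] = len(flat)
        ds_flat = np.array(flat, dtype=np.int64)
        root_idx = np.array(
            sorted(index_of[s] for s in tree.root_group), dtype=int
        )
        cached = (parent_idx, child_idx, ds_flat, offsets, root_idx)
        object.__setattr__(tree, "_kernel_arrays_cache", cached)
    return cached
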