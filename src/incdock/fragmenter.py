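"""Fragment planning for incremental docking.

The ligand is grown over a series of docking rounds. Round 1 docks a small
initial fragment around a root atom with at most ``window_size`` (default
6) active rotatable bonds; each later round adds ``advance`` (default 3)
new rotatable bonds together with their atoms, keeps a sliding window of
the most recently added bonds active, and freezes the remainder at their
best sampled values. The process ends when the full ligand has been
reconstructed, after ``1 + ceil(max(0, D - window) / advance)`` rounds for
a ligand with ``D`` rotatable bonds.

Two root-selection heuristics are provided: ``max_hbond`` picks the root
whose initial fragment carries the most hydrogen-bond donors/acceptors;
``random`` picks a uniformly random heavy atom. Fragment expansion is
either breadth-first (geometrically contiguous growth) or ``max_hbond``
(frontier bonds adding the most donors/acceptors first).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import HBOND_CAPABLE_CLASSES
from .structio import TypedMolecule
from .torsion import TorsionTree


class ScheduleError(ValueError):
    """Invalid fragment-schedule parameters or exhausted schedule."""


@dataclass
class Fragment:
    """One round's ligand subset and DoF activity pattern."""

    atom_serials: frozenset[int]
    active_dofs: tuple[int, ...]
    frozen_dofs: tuple[int, ...]
    round_index: int  # 1-based
    frozen_values: dict[int, float] = field(default_factory=dict)


@dataclass
class FragmentSchedule:
    rounds: list[Fragment]
    window_size: int
    advance: int
    dof_order: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.rounds)


def _group_adjacency(tree: TorsionTree):
    """Undirected group adjacency: gi -> [(gj, bond_index)]."""
    adj: dict[int, list[tuple[int, int]]] = {}
    for k, (gi, gj) in enumerate(tree.group_edges):
        adj.setdefault(gi, []).append((gj, k))
        adj.setdefault(gj, []).append((gi, k))
    return adj


def _bfs_dof_order(tree: TorsionTree, start_group: int) -> list[int]:
    """Rotatable bonds in breadth-first discovery order from a group.

    Ties at equal depth are broken by the bond's smaller atom serial.
    """
    adj = _group_adjacency(tree)
    order: list[int] = []
    visited = {start_group}
    frontier = [start_group]
    while frontier:
        gi = frontier.pop(0)
        edges = sorted(
            adj.get(gi, []), key=lambda e: min(tree.rotatable_bonds[e[1]])
        )
        for gj, k in edges:
            if gj in visited:
                continue
            visited.add(gj)
            order.append(k)
            frontier.append(gj)
    return order


def _fragment_atoms(tree: TorsionTree, dofs: list[int], root_group: int) -> frozenset[int]:
    atoms = set(tree.rigid_groups[root_group])
    included = {root_group}
    for k in dofs:
        gi, gj = tree.group_edges[k]
        new = gj if gi in included else gi
        included.add(new)
        atoms |= tree.rigid_groups[new]
    return frozenset(atoms)


def _hbond_count(ligand: TypedMolecule, serials: frozenset[int]) -> int:
    return sum(
        1
        for a in ligand.atoms
        if a.serial in serials and a.atom_class in HBOND_CAPABLE_CLASSES
    )


def select_root(
    tree: TorsionTree,
    ligand: TypedMolecule,
    heuristic: str = "max_hbond",
    seed: int = 0,
    window_size: int = 6,
) -> int:
    """Choose the root atom of the torsion tree.

    ``max_hbond`` maximizes the donor+acceptor count of the initial
    fragment (the candidate rigid group plus the groups reached by the
    first ``window_size`` breadth-first rotatable bonds); ties go to the
    lowest heavy-atom serial. ``random`` draws a uniform heavy atom,
    reproducibly from ``seed``.
    """
    heavy = [a for a in ligand.atoms if a.element != "H"]
    if heuristic == "random":
        rng = np.random.default_rng(seed)
        return int(heavy[int(rng.integers(len(heavy)))].serial)
    if heuristic != "max_hbond":
        raise ValueError(f"unknown root heuristic {heuristic!r}")

    hydrogens = {a.serial for a in ligand.atoms if a.element == "H"}
    best: tuple[int, int] | None = None  # (-count, candidate serial)
    best_root = None
    for gi, group in enumerate(tree.rigid_groups):
        heavy_in_group = sorted(group - hydrogens)
        if not heavy_in_group:
            continue
        order = _bfs_dof_order(tree, gi)
        window = order[: min(window_size, len(order))]
        atoms = _fragment_atoms(tree, window, gi)
        count = _hbond_count(ligand, atoms)
        key = (-count, heavy_in_group[0])
        if best is None or key < best:
            best = key
            best_root = heavy_in_group[0]
    assert best_root is not None
    return int(best_root)


def plan_rounds(
    tree: TorsionTree,
    root: int | None = None,
    window_size: int = 6,
    advance: int = 3,
    expansion_heuristic: str = "bfs",
    ligand: TypedMolecule | None = None,
) -> FragmentSchedule:
    """Plan the incremental rounds for a rooted torsion tree.

    ``root``, when given, must match the tree's root (re-root the tree with
    :func:`incdock.torsion.detect_rotatable_bonds` first). The total round
    count is ``1 + ceil(max(0, D - window_size) / advance)``.
    """
    if window_size < 1:
        raise ScheduleError("window_size must be >= 1")
    if not (1 <= advance <= window_size):
        raise ScheduleError("advance must satisfy 1 <= advance <= window_size")
    if root is not None and root != tree.root_atom:
        raise ScheduleError(
            "schedule root differs from the tree root; re-root the tree first"
        )

    root_group = tree.group_of(tree.root_atom)
    if expansion_heuristic == "bfs":
        dof_order = _bfs_dof_order(tree, root_group)
    elif expansion_heuristic == "max_hbond":
        if ligand is None:
            raise ScheduleError("max_hbond expansion requires the typed ligand")
        dof_order = _greedy_hbond_order(tree, ligand, root_group)
    else:
        raise ScheduleError(f"unknown expansion heuristic {expansion_heuristic!r}")

    d = tree.n_dofs
    n_rounds = 1 + max(0, math.ceil(max(0, d - window_size) / advance))
    rounds: list[Fragment] = []
    added = list(dof_order[: min(window_size, d)])
    for r in range(1, n_rounds + 1):
        if r > 1:
            remaining = [k for k in dof_order if k not in added]
            added.extend(remaining[:advance])
        active = tuple(added[-min(window_size, len(added)):])
        frozen = tuple(k for k in added if k not in active)
        rounds.append(
            Fragment(
                atom_serials=_fragment_atoms(tree, added, root_group),
                active_dofs=active,
                frozen_dofs=frozen,
                round_index=r,
            )
        )
    assert len(added) == d, "schedule failed to cover all DoFs"
    return FragmentSchedule(
        rounds=rounds, window_size=window_size, advance=advance,
        dof_order=tuple(dof_order),
    )


def _greedy_hbond_order(
    tree: TorsionTree, ligand: TypedMolecule, root_group: int
) -> list[int]:
    """Frontier bonds sorted by donor/acceptor yield of their added atoms."""
    bfs_rank = {k: i for i, k in enumerate(_bfs_dof_order(tree, root_group))}
    adj = _group_adjacency(tree)
    included = {root_group}
    frontier: dict[int, int] = {}  # bond index -> new group

    def refresh(gi: int):
        for gj, k in adj.get(gi, []):
            if gj not in included:
                frontier[k] = gj

    refresh(root_group)
    order: list[int] = []
    while frontier:
        def score(item):
            k, gj = item
            count = _hbond_count(ligand, frozenset(tree.rigid_groups[gj]))
            return (-count, bfs_rank[k])

        k, gj = sorted(frontier.items(), key=score)[0]
        order.append(k)
        included.add(gj)
        frontier = {
            kk: gg for kk, gg in frontier.items() if gg not in included
        }
        refresh(gj)
    return order


def expand_fragment(
    previous: Fragment,
    schedule: FragmentSchedule,
    best_torsions: dict[int, float],
) -> Fragment:
    """The next round's fragment with newly frozen DoFs fixed.

    ``best_torsions`` maps DoF index to the angle at which it is frozen; it
    must cover every DoF frozen in the next round that was active before.
    """
    if previous.round_index >= len(schedule.rounds):
        raise ScheduleError("schedule exhausted: no round after the final one")
    nxt = schedule.rounds[previous.round_index]  # round_index is 1-based
    frozen_values = dict(previous.frozen_values)
    frozen_values.update(best_torsions)
    missing = [k for k in nxt.frozen_dofs if k not in frozen_values]
    if missing:
        raise ScheduleError(f"no frozen value supplied for DoFs {missing}")
    return Fragment(
        atom_serials=nxt.atom_serials,
        active_dofs=nxt.active_dofs,
        frozen_dofs=nxt.frozen_dofs,
        round_index=nxt.round_index,
        frozen_values={k: frozen_values[k] for k in nxt.frozen_dofs},
    )
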